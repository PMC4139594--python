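"""Intersect the two human screens and map the result against the mouse module.

The screens' pass lists intersect in the core human VZ/SVZ list (407 genes in
this simulation); mapping the 13-gene mouse module to human symbols and
intersecting yields the 7-gene cross-species core.
"""

from _common import INPUT_DIR, RESULTS_DIR, ensure_inputs
from cortexseek import PipelineConfig, read_expression_matrix
from cortexseek.orthology import intersect_lists, map_orthologs, overlap_report
from cortexseek.screen import contrast_for, pass_list, run_screen
from cortexseek.spatial import build_vz_network, mask_for
from cortexseek.symbols import GeneList, read_ortholog_table, write_gene_list

ensure_inputs()
config = PipelineConfig()

mouse = read_expression_matrix(INPUT_DIR / "mouse_matrix.tsv", INPUT_DIR / "mouse_samples.tsv")
vz_net = build_vz_network(mouse, mask_for(mouse, target_structures="VZ",
                                          target_ages="E15.5"), config)
mouse_module = GeneList("mouse_vz_module", vz_net.nodes, species="mouse")

lists = {}
for label, matrix_file, samples_file, kwargs in (
        ("spatial", "human_spatial_matrix.tsv", "human_spatial_samples.tsv",
         {"target_structures": ("VZ", "SVZ")}),
        ("temporal", "human_temporal_matrix.tsv", "human_temporal_samples.tsv", {})):
    matrix = read_expression_matrix(INPUT_DIR / matrix_file, INPUT_DIR / samples_file)
    if not kwargs:
        kwargs = {"target_ages": list(matrix.samples["age"].unique())[0]}
    table = run_screen(matrix, contrast_for(matrix, label, **kwargs), config)
    lists[label] = GeneList(label, pass_list(table), species="human")

core = intersect_lists(lists["spatial"], lists["temporal"], name="human_core")
write_gene_list(core, RESULTS_DIR / "human_core_list.txt")

orthologs = read_ortholog_table(INPUT_DIR / "orthologs.tsv")
mouse_mapped = map_orthologs(mouse_module, orthologs, "mouse_to_human")
cross = intersect_lists(mouse_mapped, core, name="cross_species_core")
write_gene_list(cross, RESULTS_DIR / "cross_species_core.txt")

counts, _ = overlap_report({"spatial": lists["spatial"], "temporal": lists["temporal"],
                            "mouse_module": mouse_mapped})
counts.to_csv(RESULTS_DIR / "overlap_counts.tsv", sep="\t")

print(f"spatial pass list: {len(lists['spatial'])}; temporal: {len(lists['temporal'])}")
print(f"human core (intersection): {len(core)} genes")
print(f"cross-species core (mouse module ∩ human core): {len(cross)} genes: "
      f"{', '.join(cross.members)}")
print(f"wrote lists and overlap table under {RESULTS_DIR}")
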