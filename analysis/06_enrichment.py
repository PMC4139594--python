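"""Annotation-set over-representation of the human core list.

Hypergeometric upper-tail p per set against the annotated universe, BH FDR
across sets, reported in the C/O/E/R/rawP/adjP layout.
"""

from _common import INPUT_DIR, RESULTS_DIR, ensure_inputs
from cortexseek.enrichment import EnrichmentContext, enrich
from cortexseek.genesets import read_gene_sets
from cortexseek.symbols import read_gene_list

ensure_inputs()
core_path = RESULTS_DIR / "human_core_list.txt"
if not core_path.exists():
    raise SystemExit("run analysis/04_cross_species_overlap.py first")

query = read_gene_list(core_path, species="human")
sets = read_gene_sets(INPUT_DIR / "annotations.gmt")
table = enrich(EnrichmentContext(query=query, sets=sets))
table.to_csv(RESULTS_DIR / "enrichment.tsv", sep="\t", index=False)

print(f"universe: {table.attrs['universe']} (N={table.attrs['N']}), "
      f"query in universe: n={table.attrs['n']}")
print(f"{int(table['significant'].sum())} of {len(table)} sets at adjP < 0.05")
print(table.head(10).to_string(index=False,
      formatters={"E": "{:.2f}".format, "R": "{:.2f}".format,
                  "rawP": "{:.2e}".format, "adjP": "{:.2e}".format}))
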