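"""Run the two human differential screens: VZ/SVZ vs rest and 8-9 pcw vs later.

Each screen applies the six-fold filter first, then Holm-Bonferroni at
alpha = 1e-9 over the fold-passing family.
"""

from _common import INPUT_DIR, RESULTS_DIR, ensure_inputs
from cortexseek import PipelineConfig, read_expression_matrix
from cortexseek.pipeline import _write_screen
from cortexseek.screen import contrast_for, pass_list, run_screen

ensure_inputs()
config = PipelineConfig()

spatial = read_expression_matrix(INPUT_DIR / "human_spatial_matrix.tsv",
                                 INPUT_DIR / "human_spatial_samples.tsv")
contrast = contrast_for(spatial, "vz_svz_vs_rest", target_structures=("VZ", "SVZ"))
sp_table = run_screen(spatial, contrast, config)
_write_screen(sp_table.head(100), RESULTS_DIR / "human_spatial_screen_top100.tsv")
print(f"spatial screen: {sp_table['family_size'].iloc[0]} genes >= {config.fold_min}-fold, "
      f"{len(pass_list(sp_table))} pass Holm at alpha={config.alpha:g}")

temporal = read_expression_matrix(INPUT_DIR / "human_temporal_matrix.tsv",
                                  INPUT_DIR / "human_temporal_samples.tsv")
stages = list(temporal.samples["age"].unique())
contrast = contrast_for(temporal, "early_vs_later", target_ages=stages[0])
tm_table = run_screen(temporal, contrast, config)
_write_screen(tm_table.head(100), RESULTS_DIR / "human_temporal_screen_top100.tsv")
print(f"temporal screen ({stages[0]} vs later): "
      f"{tm_table['family_size'].iloc[0]} genes >= {config.fold_min}-fold, "
      f"{len(pass_list(tm_table))} pass Holm at alpha={config.alpha:g}")
print(f"wrote top-100 tables under {RESULTS_DIR}")
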