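"""Shared locations and input bootstrapping for the analysis drivers."""

from pathlib import Path

from cortexseek.pipeline import simulate_inputs

ROOT = Path(__file__).resolve().parent.parent
INPUT_DIR = ROOT / "scratch" / "inputs"      # large simulated matrices
RESULTS_DIR = ROOT / "results"               # small summary tables
SEED = 1


def ensure_inputs() -> Path:
    """Simulate the full input set once (seed fixed) if not already present."""
    if not (INPUT_DIR / "ground_truth.json").exists():
        print(f"simulating inputs under {INPUT_DIR} (seed={SEED}) ...")
        simulate_inputs(INPUT_DIR, seed=SEED)
    RESULTS_DIR.mkdir(exist_ok=True)
    return INPUT_DIR
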