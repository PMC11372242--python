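"""Shared locations and study conditions for the analysis drivers.

The bundle lives under scratch/ (regenerated on demand, deterministic for
SEED); derived tables go to results/analysis/.
"""

from pathlib import Path

from faerspv.synthetic import SyntheticConfig, generate_bundle

ROOT = Path(__file__).resolve().parent.parent
BUNDLE_DIR = ROOT / "scratch" / "bundle"
RESULTS_DIR = ROOT / "results" / "analysis"
SEED = 17


def ensure_bundle():
    """Generate the default-conditions bundle if it is not already there."""
    if not (BUNDLE_DIR / "groundtruth.json").exists():
        generate_bundle(SyntheticConfig(seed=SEED), BUNDLE_DIR)
    return BUNDLE_DIR
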