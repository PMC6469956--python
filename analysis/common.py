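"""Shared study conditions for the numbered analysis drivers.

Every driver regenerates the same seeded synthetic cohort, so the scripts
can run independently and in any order while describing one consistent
dataset.  Outputs land under results/analysis/.
"""

from pathlib import Path

from mgscope.synth import SyntheticSpec, generate_bundle

SEED = 1
RESULTS = Path(__file__).resolve().parents[1] / "results" / "analysis"


def study_bundle():
    RESULTS.mkdir(parents=True, exist_ok=True)
    return generate_bundle(SyntheticSpec(rng_seed=SEED))
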