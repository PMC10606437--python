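"""Shared configuration for the analysis drivers."""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
SEED = 42


def study_scale_config(seed: int = SEED, **overrides):
    """Study-conditions synthetic configuration (sequence-free by default:
    interval statistics don't need circle sequences)."""
    from circulome.simulate import SimConfig

    kwargs = dict(seed=seed, emit_sequences=False)
    kwargs.update(overrides)
    return SimConfig(**kwargs)


def sequence_config(seed: int = SEED, circles_per_sample: int = 40, **overrides):
    """Full-sequence configuration for alignment-based stages; the inventory
    is kept small because pairwise alignment of ~7 kb circles is costly."""
    from circulome.simulate import SimConfig

    kwargs = dict(seed=seed, circles_per_sample=circles_per_sample,
                  duplicate_fraction=0.15)
    kwargs.update(overrides)
    return SimConfig(**kwargs)
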