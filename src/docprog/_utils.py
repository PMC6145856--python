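"""Shared numerical helpers."""

from __future__ import annotations

import numpy as np

#: Fisher z is clipped so that r = +-1 stays finite on degenerate inputs.
R_CLIP = 1.0 - 1e-7


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """atanh transform of a Pearson correlation, clipped at |r| = 1 - 1e-7."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def spawn_seed(rng: np.random.Generator) -> int:
    """Draw a sub-seed below 2**31 from a master generator."""
    return int(rng.integers(0, 2**31 - 1))


def check_finite(arr: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
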