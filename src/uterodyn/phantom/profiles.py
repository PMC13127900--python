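"""Temporal envelopes for simulated contraction events.

A profile is a unimodal smooth bump p(x) on x = (t - onset)/duration in
[0, 1], with p = 0 outside, peak value 1, and a closed-form half-maximum
width so event ground truth never depends on rasterised data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class RaisedCosineProfile:
    """p(x) = (1 - cos 2πx)/2: half-maximum crossings at x = 1/4 and 3/4."""

    name: str = "raised_cosine"

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = 0.5 * (1.0 - np.cos(2.0 * np.pi * x))
        return np.where((x >= 0.0) & (x <= 1.0), out, 0.0)

    @property
    def halfmax_fraction(self) -> float:
        return 0.5


@dataclass(frozen=True)
class TukeyProfile:
    """Cosine-tapered plateau: flat top of width 1 - 2*taper_fraction.

    The plateau keeps the peak amplitude invariant under short moving-average
    smoothing; half-maximum crossings sit at the middle of each taper, so the
    half-maximum width is 1 - taper_fraction.
    """

    taper_fraction: float = 0.25
    name: str = "tukey"

    def __post_init__(self) -> None:
        if not 0.0 < self.taper_fraction <= 0.5:
            raise ValueError("taper_fraction must lie in (0, 0.5]")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        f = self.taper_fraction
        out = np.ones_like(x)
        rising = (x >= 0.0) & (x < f)
        falling = (x > 1.0 - f) & (x <= 1.0)
        out = np.where(rising, 0.5 * (1.0 - np.cos(np.pi * x / f)), out)
        out = np.where(falling, 0.5 * (1.0 - np.cos(np.pi * (1.0 - x) / f)), out)
        return np.where((x >= 0.0) & (x <= 1.0), out, 0.0)

    @property
    def halfmax_fraction(self) -> float:
        return 1.0 - self.taper_fraction


def make_profile(name: str, **kwargs) -> RaisedCosineProfile | TukeyProfile:
    if name == "raised_cosine":
        return RaisedCosineProfile()
    if name == "tukey":
        return TukeyProfile(**kwargs)
    raise ValueError(f"unknown profile {name!r}; use 'raised_cosine' or 'tukey'")
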