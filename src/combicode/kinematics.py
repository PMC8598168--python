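"""Whisker-bend curvature and a contact-force proxy from tracked whisker paths.

The planar signed curvature of a tracked whisker shaft,

    kappa = (x' y'' - x'' y') / (x'^2 + y'^2)^(3/2)

is evaluated by central finite differences after resampling the path to
uniform arc length, and averaged over a configurable segment of the shaft
(default: the lower third, nearest the base, where bending against a contact
surface is expressed).  Subtracting the free-whisking intrinsic curvature
gives a per-frame proxy for the force applied at the contact.

Sign convention: positive kappa turns counterclockwise in image coordinates;
reflection (x, y) -> (x, -y) flips the sign, rigid motions leave |kappa|
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class WhiskerPath:
    """Ordered planar points along a whisker, base first, in pixel units."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if self.x.size < 5:
            raise ValueError("a whisker path needs at least 5 points")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("whisker path coordinates must be finite")

    @property
    def arc_length(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(self.x), np.diff(self.y)))])

    @classmethod
    def from_tsv(cls, path) -> "WhiskerPath":
        df = pd.read_csv(path, sep="\t")
        return cls(x=df["x"].to_numpy(), y=df["y"].to_numpy())


def _resample_uniform(p: WhiskerPath, n: int):
    s = p.arc_length
    if s[-1] <= 0:
        raise ValueError("degenerate whisker path (repeated points)")
    u = np.linspace(0, s[-1], n)
    return np.interp(u, s, p.x), np.interp(u, s, p.y), u[1] - u[0]


def curvature(p: WhiskerPath, segment=(0.0, 1.0 / 3.0), n_resample: int = 200) -> float:
    """Mean signed curvature (1/pixel) over a fraction-of-length segment.

    ``segment`` is (start, end) as fractions of total arc length measured
    from the path's first point (the base); the default is the lower third.
    """
    lo, hi = segment
    if not (0 <= lo < hi <= 1):
        raise ValueError("segment must satisfy 0 <= start < end <= 1")
    x, y, ds = _resample_uniform(p, n_resample)
    xp = np.gradient(x, ds)
    yp = np.gradient(y, ds)
    xpp = np.gradient(xp, ds)
    ypp = np.gradient(yp, ds)
    denom = (xp**2 + yp**2) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = (xp * ypp - xpp * yp) / denom
    i0, i1 = int(np.floor(lo * n_resample)), int(np.ceil(hi * n_resample))
    seg = kappa[max(i0, 1) : min(i1, n_resample - 1)]  # drop one-sided edge stencils
    if seg.size < 5:
        raise ValueError("segment contains too few resampled points")
    return float(np.mean(seg))


def bend_force_proxy(kappa_trial, kappa_free) -> np.ndarray:
    """Contact-force proxy: trial curvature minus the free-whisking baseline."""
    return np.asarray(kappa_trial, dtype=float) - float(kappa_free)
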