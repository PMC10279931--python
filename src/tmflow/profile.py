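"""Circumferential binning and tracer intensity profiles.

The straightened TM band is cut into rectangular bins of ~212 um target
width spanning the full anterior-posterior height.  Per-bin NaN-excluded
mean intensities of the two tracers form the "tracer intensity profile";
the blue channel is rescaled by the least-squares factor sum(R*B)/sum(B^2)
to compensate for brightness mismatch between the tracer colours, and each
bin is labelled by the circumferential quadrant (nasal / temporal /
superior / inferior) it falls in, anchored at the corneal puncture site.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .straighten import StraightenedTM

__all__ = [
    "BinGrid",
    "TracerProfile",
    "compute_bins",
    "bin_means",
    "scaling_factor",
    "scaling_factor_pixels",
    "apply_scaling",
    "assign_quadrants",
    "DEFAULT_BIN_WIDTH_UM",
]

DEFAULT_BIN_WIDTH_UM = 212.0

#: quadrant sequence around the circumference starting at the puncture site;
#: the puncture lands inferior for OD and superior for OS, and the two sides
#: are mirror images of each other (superior <-> inferior swap).
_QUADRANT_ORDER = {
    "OD": ("inferior", "nasal", "superior", "temporal"),
    "OS": ("superior", "nasal", "inferior", "temporal"),
}


@dataclass(frozen=True)
class BinGrid:
    """Half-open column bins [edges[i], edges[i+1]) over a straightened band."""

    n_bins: int
    edges: np.ndarray
    target_width_um: float
    actual_width_um: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=int)
        object.__setattr__(self, "edges", e)
        if e[0] != 0 or len(e) != self.n_bins + 1 or np.any(np.diff(e) <= 0):
            raise ValueError("edges must start at 0, be strictly increasing, length n_bins+1")

    @property
    def total_width_px(self) -> int:
        return int(self.edges[-1])

    @property
    def centres_um(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0 * self.pixel_size_um


@dataclass
class TracerProfile:
    """Per-bin mean tracer intensities around the TM circumference."""

    red_mean: np.ndarray
    blue_mean: np.ndarray
    centre_um: np.ndarray
    valid_fraction: np.ndarray
    circumference_um: float
    quadrant: Optional[np.ndarray] = None
    scaling_factor_applied: float = 1.0
    eye_id: str = ""
    delta_t_days: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.red_mean)
        for name in ("blue_mean", "centre_um", "valid_fraction"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != n_bins")
        vf = np.asarray(self.valid_fraction, dtype=float)
        if np.any((vf < 0) | (vf > 1)):
            raise ValueError("valid_fraction must lie in [0, 1]")

    @property
    def n_bins(self) -> int:
        return len(self.red_mean)

    @property
    def valid(self) -> np.ndarray:
        """Bins usable downstream: at least one valid pixel in both channels."""
        return (
            (np.asarray(self.valid_fraction) > 0)
            & np.isfinite(self.red_mean)
            & np.isfinite(self.blue_mean)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "eye_id": self.eye_id,
                "bin_index": np.arange(self.n_bins),
                "centre_um": self.centre_um,
                "quadrant": self.quadrant if self.quadrant is not None else "",
                "red_mean": self.red_mean,
                "blue_mean_scaled": self.blue_mean,
                "valid_fraction": self.valid_fraction,
            }
        )


def compute_bins(
    total_width_px: int,
    pixel_size_um: float,
    target_width_um: float = DEFAULT_BIN_WIDTH_UM,
) -> BinGrid:
    """Split a straightened band into near-equal circumferential bins.

    The bin count is ``round(width_um / target_width_um)`` (minimum 1), which
    keeps the achieved width as close to the target as an integer count
    allows; the integer column widths are distributed largest-remainder
    style, so they differ by at most one column.
    """
    if total_width_px < 1:
        raise ValueError("total_width_px must be >= 1")
    if target_width_um <= 0:
        raise ValueError("target_width_um must be positive")
    total_um = total_width_px * pixel_size_um
    n = max(1, int(round(total_um / target_width_um)))
    n = min(n, total_width_px)  # never more bins than columns
    base, rem = divmod(total_width_px, n)
    widths = np.full(n, base, dtype=int)
    widths[:rem] += 1
    edges = np.concatenate([[0], np.cumsum(widths)])
    return BinGrid(
        n_bins=n,
        edges=edges,
        target_width_um=target_width_um,
        actual_width_um=total_um / n,
        pixel_size_um=pixel_size_um,
    )


def bin_means(straightened: StraightenedTM, bins: BinGrid) -> TracerProfile:
    """NaN-excluded per-bin mean intensity of each tracer (pre-scaling).

    Only pixels valid in *both* channels enter the means, so red and blue
    are averaged over identical pixel sets.  Bins with no valid pixel get
    NaN means and ``valid_fraction`` 0; they are flagged, not fatal, and all
    downstream sums skip them.
    """
    if bins.total_width_px != straightened.width:
        raise ValueError("bin grid width does not match the straightened band")
    red = straightened.channels["red"]
    blue = straightened.channels["blue"]
    valid = np.isfinite(red) & np.isfinite(blue)
    n = bins.n_bins
    red_mean = np.full(n, np.nan)
    blue_mean = np.full(n, np.nan)
    frac = np.zeros(n)
    for i in range(n):
        sl = slice(bins.edges[i], bins.edges[i + 1])
        v = valid[:, sl]
        cnt = int(v.sum())
        frac[i] = cnt / v.size
        if cnt:
            red_mean[i] = red[:, sl][v].mean()
            blue_mean[i] = blue[:, sl][v].mean()
    return TracerProfile(
        red_mean=red_mean,
        blue_mean=blue_mean,
        centre_um=bins.centres_um,
        valid_fraction=frac,
        circumference_um=straightened.circumference_um,
    )


def scaling_factor(red_means: np.ndarray, blue_means: np.ndarray) -> float:
    """Least-squares brightness factor sum(R_i B_i) / sum(B_i^2).

    Multiplying the blue tracer by this factor minimises
    ``sum((R_i - s * B_i)^2)`` over the valid bins, i.e. it gives the best
    match between the two tracer patterns in the least-squares sense while
    leaving their Pearson correlation unchanged.
    """
    r = np.asarray(red_means, dtype=float)
    b = np.asarray(blue_means, dtype=float)
    keep = np.isfinite(r) & np.isfinite(b)
    r, b = r[keep], b[keep]
    if r.size < 2:
        raise ValueError("need at least 2 valid bins")
    denom = float(np.sum(b * b))
    if denom == 0.0:
        raise ZeroDivisionError("blue channel is identically zero; scaling factor undefined")
    return float(np.sum(r * b) / denom)


def scaling_factor_pixels(straightened: StraightenedTM) -> float:
    """Scaling factor computed over raw TM pixels instead of bin means."""
    red = straightened.channels["red"]
    blue = straightened.channels["blue"]
    keep = np.isfinite(red) & np.isfinite(blue)
    denom = float(np.sum(blue[keep] ** 2))
    if denom == 0.0:
        raise ZeroDivisionError("blue channel is identically zero; scaling factor undefined")
    return float(np.sum(red[keep] * blue[keep]) / denom)


def apply_scaling(profile: TracerProfile, factor: Optional[float] = None) -> TracerProfile:
    """Multiply the blue means by the scaling factor (computed if omitted)."""
    if factor is None:
        factor = scaling_factor(profile.red_mean, profile.blue_mean)
    return replace(
        profile,
        blue_mean=np.asarray(profile.blue_mean, dtype=float) * factor,
        scaling_factor_applied=profile.scaling_factor_applied * factor,
    )


def assign_quadrants(profile: TracerProfile, side: str = "OD") -> TracerProfile:
    """Label each bin with its circumferential quadrant.

    The circumferential origin (position 0) is the puncture-site landmark,
    which sits at the *centre* of its quadrant: inferior for OD, superior
    for OS.  Each bin takes the quadrant containing its centre; OD and OS
    are mirrored (superior and inferior swap, nasal and temporal keep their
    place in the traversal order).
    """
    if side not in _QUADRANT_ORDER:
        raise ValueError(f"side must be 'OD' or 'OS', got {side!r}")
    order = _QUADRANT_ORDER[side]
    frac = np.asarray(profile.centre_um) / profile.circumference_um
    idx = np.floor(((frac + 0.125) % 1.0) * 4).astype(int) % 4
    labels = np.array([order[i] for i in idx])
    return replace(profile, quadrant=labels)
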