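"""Lateral self-diffusion from mean-square displacements (Einstein relation).

The lateral diffusion coefficient of a membrane protein follows from the
long-time slope of the in-plane mean-square displacement,
D = lim MSD(τ)/(4τ), fitted by least squares on a short-lag window
(default 5–20 ns) where the MSD of these systems is linear.  The MSD is
averaged over the beads of the protein and over sliding time origins; the
centre-of-mass drift of the protein–membrane system can be removed per
frame before displacements are accumulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiffusionResult", "msd", "fit_diffusion", "NM2_PER_NS_TO_1E7_CM2_PER_S"]

#: 1 nm²/ns = 1e-5 cm²/s = 1000 × 10⁻⁷ cm²/s
NM2_PER_NS_TO_1E7_CM2_PER_S = 1000.0


@dataclass
class DiffusionResult:
    lags_ns: np.ndarray
    msd_nm2: np.ndarray
    fit_window_ns: tuple[float, float]
    D_nm2_per_ns: float
    D_1e7_cm2_per_s: float
    r_squared: float


def msd(
    times_ns: np.ndarray,
    coords_nm: np.ndarray,
    com_removal: bool = False,
    com_group_coords: np.ndarray | None = None,
    max_lag_fraction: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Lateral (xy) MSD curve averaged over beads and time origins.

    Parameters
    ----------
    times_ns : (F,) frame times, uniformly spaced.
    coords_nm : (F, B, 3) bead positions of the protein.
    com_removal : subtract the per-frame centre of mass of
        ``com_group_coords`` (the protein–membrane system; defaults to the
        protein beads themselves) before accumulating displacements.
    max_lag_fraction : largest lag as a fraction of the trajectory length;
        longer lags average over too few origins to be reliable.
    """
    t = np.asarray(times_ns, dtype=float)
    x = np.asarray(coords_nm, dtype=float)[..., :2].copy()
    if x.ndim != 3:
        raise ValueError("coords must have shape (frames, beads, 3)")
    n = len(t)
    if n < 2:
        raise ValueError("need at least two frames")
    if com_removal:
        group = x if com_group_coords is None else \
            np.asarray(com_group_coords, dtype=float)[..., :2]
        x = x - group.mean(axis=1, keepdims=True)
    max_lag = max(1, int(np.floor(max_lag_fraction * (n - 1))))
    lags = np.arange(0, max_lag + 1)
    out = np.zeros(lags.size)
    for idx, lag in enumerate(lags[1:], start=1):
        disp = x[lag:] - x[:-lag]
        out[idx] = np.mean(np.sum(disp**2, axis=-1))
    dt = t[1] - t[0]
    return lags * dt, out


def fit_diffusion(
    lags_ns: np.ndarray,
    msd_nm2: np.ndarray,
    window_ns: tuple[float, float] = (5.0, 20.0),
) -> DiffusionResult:
    """Fit D = slope/4 on the stated lag window of an MSD curve."""
    lags = np.asarray(lags_ns, dtype=float)
    curve = np.asarray(msd_nm2, dtype=float)
    lo, hi = window_ns
    if lo < lags.min() or hi > lags.max():
        raise ValueError("fit window outside available lags")
    mask = (lags >= lo) & (lags <= hi)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 MSD points in the fit window")
    slope, intercept = np.polyfit(lags[mask], curve[mask], 1)
    pred = slope * lags[mask] + intercept
    ss_res = float(np.sum((curve[mask] - pred) ** 2))
    ss_tot = float(np.sum((curve[mask] - curve[mask].mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    d = float(slope) / 4.0
    return DiffusionResult(
        lags_ns=lags,
        msd_nm2=curve,
        fit_window_ns=window_ns,
        D_nm2_per_ns=d,
        D_1e7_cm2_per_s=d * NM2_PER_NS_TO_1E7_CM2_PER_S,
        r_squared=r2,
    )
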