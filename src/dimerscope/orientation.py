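"""Relative orientation angles of receptor pairs and binding-position densities.

Each receptor gets a molecular frame: origin at the centre of mass of its
TM backbone beads, z along the membrane normal (+z extracellular), and the
in-plane x axis along the principal component of the xy-projected TM
backbone beads.  The principal axis is only defined up to sign; the sign is
fixed so that the TM1 backbone centroid lies at an azimuth in [−90°, 90°),
making the frame deterministic and fully rotation-equivariant.

For a dimer, three angles describe the configuration (all degrees,
counterclockwise viewed from the extracellular side, wrapped to [0, 360)):

* β — azimuth of partner B's origin in A's frame (where B binds on A),
* φ — rotation of B about its own z axis relative to A,
* χ = (180° + β − φ) mod 360 — the reciprocal binding azimuth on B, i.e.
  the azimuth of A's origin measured in B's frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_io import HELIX_LABELS, ReceptorModel

__all__ = [
    "FrameError",
    "MolecularFrame",
    "OrientationSample",
    "HelixAngularMap",
    "build_frame",
    "relative_angles",
    "helix_angular_map",
    "binding_position_density",
    "wrap_deg",
    "circular_mean_deg",
]


class FrameError(ValueError):
    """Raised when a molecular frame cannot be constructed."""


def wrap_deg(angle) -> np.ndarray | float:
    """Wrap angle(s) to the half-open interval [0, 360)."""
    return np.mod(angle, 360.0)


def circular_mean_deg(angles_deg: np.ndarray) -> float:
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    return float(wrap_deg(math.degrees(math.atan2(np.mean(np.sin(a)),
                                                  np.mean(np.cos(a))))))


@dataclass(frozen=True)
class MolecularFrame:
    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def azimuth_of(self, point: np.ndarray) -> float:
        """Azimuth (deg, [0,360)) of a lab-frame point seen from this frame."""
        d = np.asarray(point, dtype=float) - self.origin
        x, y = float(d @ self.x_axis), float(d @ self.y_axis)
        if x == 0.0 and y == 0.0:
            raise FrameError("point coincides with the frame origin")
        return float(wrap_deg(math.degrees(math.atan2(y, x))))


@dataclass(frozen=True)
class OrientationSample:
    time: float  # ns
    beta: float
    phi: float
    chi: float
    replica_id: str = ""

    def __post_init__(self) -> None:
        expected = wrap_deg(180.0 + self.beta - self.phi)
        if abs(wrap_deg(self.chi - expected + 180.0) - 180.0) > 1e-9:
            raise ValueError("chi inconsistent with (180 + beta - phi) mod 360")


@dataclass
class HelixAngularMap:
    """Angular footprint of each helix on the 1°-binned azimuth circle.

    ``intervals`` maps helix label -> (start, end) degrees, a circular
    interval traversed counterclockwise from start to end.  ``exposure``
    holds, per 1° bin, the label of the surface-exposed helix there (the
    one with maximal mean radial distance among occupants) or '' when no
    helix covers the bin.
    """

    intervals: dict[str, tuple[float, float]]
    exposure: np.ndarray  # (360,) of str
    mean_radius: dict[str, float]

    def exposed_helices(self, angle_deg: float, half_width_deg: float = 0.0) -> list[str]:
        """Helix labels exposed at ``angle_deg`` (± an optional half-width)."""
        bins = np.arange(360)
        dist = np.abs((bins - angle_deg + 180.0) % 360.0 - 180.0)
        labels = {str(h) for h in self.exposure[dist <= half_width_deg + 0.5] if h}
        return sorted(labels, key=lambda h: HELIX_LABELS.index(h))


def build_frame(receptor: ReceptorModel, coords: np.ndarray) -> MolecularFrame:
    """Construct the molecular frame of a receptor for one coordinate frame.

    ``coords`` indexes all beads of the underlying system (nm); only the TM
    backbone beads of ``receptor`` are used, making the frame robust to
    loop fluctuations.  Translation-invariant and z-rotation-equivariant.
    """
    coords = np.asarray(coords, dtype=float)
    bb = receptor.tm_backbone_indices()
    pts = coords[bb]
    origin = pts.mean(axis=0)
    xy = pts[:, :2] - origin[:2]
    cov = xy.T @ xy / len(xy)
    evals, evecs = np.linalg.eigh(cov)
    # eigh returns ascending order; principal direction is the last column
    if evals[1] - evals[0] <= 1e-12 * max(evals[1], 1e-30):
        raise FrameError("principal axes undefined (isotropic xy projection)")
    x2d = evecs[:, 1]

    tm1 = [receptor.backbone_bead_index[r] for r in receptor.helix_residues("TM1")]
    tm1_c = coords[tm1][:, :2].mean(axis=0) - origin[:2]
    dx, dy = float(tm1_c @ x2d), float(tm1_c @ np.array([-x2d[1], x2d[0]]))
    # sign convention: TM1 centroid azimuth in [-90, 90)
    if dx < 0 or (dx == 0 and dy >= 0):
        x2d = -x2d
    x_axis = np.array([x2d[0], x2d[1], 0.0])
    z_axis = np.array([0.0, 0.0, 1.0])
    y_axis = np.cross(z_axis, x_axis)
    return MolecularFrame(origin=origin, x_axis=x_axis, y_axis=y_axis, z_axis=z_axis)


def relative_angles(
    frame_a: MolecularFrame,
    frame_b: MolecularFrame,
    time: float = 0.0,
    replica_id: str = "",
    max_tilt_deg: float = 15.0,
) -> OrientationSample:
    """Compute (β, φ, χ) for a pair of molecular frames.

    Requires the two membrane normals to agree within ``max_tilt_deg``
    (quasi-planar membrane assumption).
    """
    cos_tilt = float(np.clip(frame_a.z_axis @ frame_b.z_axis, -1.0, 1.0))
    if math.degrees(math.acos(cos_tilt)) > max_tilt_deg:
        raise FrameError("frames do not share a membrane normal")
    beta = frame_a.azimuth_of(frame_b.origin)
    phi = wrap_deg(math.degrees(math.atan2(frame_b.x_axis @ frame_a.y_axis,
                                           frame_b.x_axis @ frame_a.x_axis)))
    chi = wrap_deg(180.0 + beta - phi)
    return OrientationSample(time=time, beta=float(beta), phi=float(phi),
                             chi=float(chi), replica_id=replica_id)


def helix_angular_map(receptor: ReceptorModel, coords: np.ndarray) -> HelixAngularMap:
    """Map each helix to its azimuth interval in the receptor's own frame.

    Every 1° bin covered by more than one helix is attributed to the helix
    with the largest mean radial distance there (surface exposure by the
    radial-maximum rule); inner helices occluded by an outer helix at the
    same azimuth are marked unexposed in those bins.
    """
    coords = np.asarray(coords, dtype=float)
    frame = build_frame(receptor, coords)

    intervals: dict[str, tuple[float, float]] = {}
    radii: dict[str, float] = {}
    cover = {}
    for label in HELIX_LABELS:
        if label not in receptor.helix_map:
            continue
        bb = [receptor.backbone_bead_index[r] for r in receptor.helix_residues(label)]
        pts = coords[bb]
        az = np.array([frame.azimuth_of(p) for p in pts])
        rad = np.linalg.norm(
            (pts - frame.origin) @ np.column_stack([frame.x_axis, frame.y_axis]),
            axis=1)
        radii[label] = float(rad.mean())
        start, end = _circular_span(az)
        intervals[label] = (start, end)
        width = wrap_deg(end - start)
        bins = wrap_deg(np.round(np.arange(start, start + width + 0.5))).astype(int) % 360
        cover[label] = np.unique(bins)

    exposure = np.full(360, "", dtype=object)
    best_r = np.full(360, -np.inf)
    for label, bins in cover.items():
        better = radii[label] > best_r[bins]
        exposure[bins[better]] = label
        best_r[bins[better]] = radii[label]
    return HelixAngularMap(intervals=intervals, exposure=exposure, mean_radius=radii)


def _circular_span(angles_deg: np.ndarray) -> tuple[float, float]:
    """Smallest circular arc (start, end) containing all angles."""
    a = np.sort(wrap_deg(np.asarray(angles_deg, dtype=float)))
    if a.size == 1:
        return float(a[0]), float(a[0])
    gaps = np.diff(np.concatenate([a, [a[0] + 360.0]]))
    i = int(np.argmax(gaps))
    start = a[(i + 1) % a.size]
    end = a[i]
    return float(start), float(end)


def binding_position_density(
    samples: list[OrientationSample],
    homodimer: bool = True,
    bandwidth_deg: float = 10.0,
    grid_deg: float = 1.0,
):
    """Circular KDE of binding positions over [0, 360).

    Homodimers: β and χ describe the same binding position on either
    protomer, so the density pools both angles.  Heterodimers: returns two
    densities, β on receptor A and χ on receptor B.  Each density is a
    wrapped-Gaussian KDE on a ``grid_deg`` grid normalised so that its
    integral over the full circle is 1.
    """
    if not samples:
        raise ValueError("no orientation samples")
    beta = np.array([s.beta for s in samples])
    chi = np.array([s.chi for s in samples])
    grid = np.arange(0.0, 360.0, grid_deg)
    if homodimer:
        return grid, _wrapped_kde(np.concatenate([beta, chi]), grid, bandwidth_deg)
    return grid, {
        "A": _wrapped_kde(beta, grid, bandwidth_deg),
        "B": _wrapped_kde(chi, grid, bandwidth_deg),
    }


def _wrapped_kde(angles: np.ndarray, grid: np.ndarray, bw: float) -> np.ndarray:
    delta = (grid[:, None] - angles[None, :] + 180.0) % 360.0 - 180.0
    dens = np.exp(-0.5 * (delta / bw) ** 2).sum(axis=1)
    step = grid[1] - grid[0] if grid.size > 1 else 360.0
    dens /= dens.sum() * step
    return dens
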