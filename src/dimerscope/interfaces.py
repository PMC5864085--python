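"""Dimer-interface classification on the (β, χ) angle torus.

Last-window (β, χ) samples of all dimer-forming replicas are turned into a
doubly periodic kernel-density height-field on a 1° grid.  Local maxima of
the field are the candidate dimer interfaces; watershed segmentation of the
negated field (with the maxima as markers, periodic boundaries handled by
3×3 tiling) partitions the torus into interface basins.  Each replica is
assigned to a basin by its circular-mean last-window angles, basin
populations are reported as fractions of dimer-forming replicas, and basins
are named by the helices that each protomer contributes at the contact
azimuths (labels like ``TM1,H8/TM4,5``).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage.segmentation import watershed

from .orientation import HelixAngularMap, circular_mean_deg, wrap_deg

__all__ = [
    "HeightFieldBasins",
    "RepresentativePick",
    "kde_heightfield",
    "watershed_basins",
    "assign_and_count",
    "label_basin",
    "select_representative",
    "torus_distance_deg",
]

GRID = 360  # 1 degree resolution on each axis


def torus_distance_deg(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Wrapped Euclidean distance between two points on the angle torus."""
    db = abs((a[0] - b[0] + 180.0) % 360.0 - 180.0)
    dc = abs((a[1] - b[1] + 180.0) % 360.0 - 180.0)
    return math.hypot(db, dc)


@dataclass
class HeightFieldBasins:
    """Periodic (β, χ) density grid with watershed basins and populations."""

    grid: np.ndarray  # (360, 360), grid[i, j] ~ density at beta=i, chi=j
    bandwidth_deg: float
    maxima: list[tuple[float, float, float]] = field(default_factory=list)
    basin_map: np.ndarray | None = None  # (360, 360) int basin ids, 1-based
    populations: dict[int, tuple[int, float]] = field(default_factory=dict)
    labels: dict[int, str] = field(default_factory=dict)
    degenerate: bool = False

    def basin_of(self, beta: float, chi: float) -> int:
        if self.basin_map is None:
            raise ValueError("watershed has not been run")
        i = int(np.round(beta)) % GRID
        j = int(np.round(chi)) % GRID
        return int(self.basin_map[i, j])

    def top_basins(self, n: int) -> list[int]:
        """Basin ids of the n most populated basins (population order)."""
        ranked = sorted(self.populations, key=lambda b: -self.populations[b][0])
        return ranked[:n]


@dataclass(frozen=True)
class RepresentativePick:
    basin_id: int
    replica_id: str
    beta: float
    chi: float
    energy: float
    distance_deg: float


def kde_heightfield(
    beta: np.ndarray,
    chi: np.ndarray,
    bandwidth_deg: float = 10.0,
    noise_floor: float = 0.05,
) -> HeightFieldBasins:
    """Doubly periodic KDE of (β, χ) samples on the 1° torus grid.

    Samples are binned to the nearest grid node and smoothed with a
    periodic Gaussian of width ``bandwidth_deg``.  Local maxima below
    ``noise_floor`` × (global maximum) are pruned; their mass drains into
    the nearest surviving basin during watershed.
    """
    beta = np.asarray(beta, dtype=float)
    chi = np.asarray(chi, dtype=float)
    if beta.size == 0:
        raise ValueError("no samples")
    hist = np.zeros((GRID, GRID))
    bi = np.round(beta).astype(int) % GRID
    cj = np.round(chi).astype(int) % GRID
    np.add.at(hist, (bi, cj), 1.0)
    grid = ndi.gaussian_filter(hist, sigma=bandwidth_deg, mode="wrap")
    grid /= grid.sum()

    footprint = ndi.maximum_filter(grid, size=int(2 * bandwidth_deg) + 1, mode="wrap")
    peak_mask = grid >= footprint
    degenerate = False
    floor = noise_floor * grid.max()
    peak_mask &= grid > floor
    # collapse plateaus (including the fully uniform field) to one cell each
    lab, n_lab = ndi.label(peak_mask, structure=np.ones((3, 3)))
    lab = _merge_wrapped_labels(lab)
    maxima = []
    for lid in np.unique(lab):
        if lid == 0:
            continue
        cells = np.argwhere(lab == lid)
        i, j = cells[np.lexsort((cells[:, 1], cells[:, 0]))][0]
        maxima.append((float(i), float(j), float(grid[i, j])))
    if not maxima:  # e.g. perfectly uniform field
        degenerate = True
        maxima = [(0.0, 0.0, float(grid[0, 0]))]
    if np.allclose(grid, grid.flat[0]):
        degenerate = True
        maxima = maxima[:1]
    maxima.sort(key=lambda m: -m[2])
    return HeightFieldBasins(grid=grid, bandwidth_deg=bandwidth_deg,
                             maxima=maxima, degenerate=degenerate)


def _merge_wrapped_labels(lab: np.ndarray) -> np.ndarray:
    """Union plateau labels that touch across the periodic boundaries."""
    n = lab.shape[0]
    parent = {}

    def find(x):
        while parent.get(x, x) != x:
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for i in range(n):
        for (a, b) in ((lab[i, 0], lab[i, -1]), (lab[0, i], lab[-1, i])):
            if a and b:
                union(int(a), int(b))
    out = lab.copy()
    for lid in np.unique(lab):
        if lid:
            out[lab == lid] = find(int(lid))
    return out


def watershed_basins(basins: HeightFieldBasins) -> HeightFieldBasins:
    """Segment the torus into one basin per retained maximum.

    Watershed floods the negated height-field from the maxima; periodicity
    is honoured by tiling the field 3×3 (markers replicated with identical
    ids) and extracting the central tile, so basins wrap seamlessly.
    """
    markers = np.zeros((GRID, GRID), dtype=np.int32)
    for bid, (i, j, _h) in enumerate(basins.maxima, start=1):
        markers[int(i) % GRID, int(j) % GRID] = bid
    tiled_field = np.tile(-basins.grid, (3, 3))
    tiled_markers = np.tile(markers, (3, 3))
    seg = watershed(tiled_field, tiled_markers)
    basins.basin_map = seg[GRID:2 * GRID, GRID:2 * GRID].astype(np.int32)
    return basins


def assign_and_count(
    replica_samples: dict[str, tuple[np.ndarray, np.ndarray]],
    basins: HeightFieldBasins,
    min_samples: int = 1,
) -> dict[str, int]:
    """Assign each dimer-forming replica to a basin; fill basin populations.

    ``replica_samples`` maps replica_id -> (β array, χ array) over the last
    analysis window.  Replicas with fewer than ``min_samples`` frames (the
    dimer did not survive the window) are excluded with a warning.
    Populations are stored on ``basins`` as (count, fraction of assigned
    replicas).
    """
    assignment: dict[str, int] = {}
    for rid, (b, c) in replica_samples.items():
        b = np.atleast_1d(np.asarray(b, dtype=float))
        c = np.atleast_1d(np.asarray(c, dtype=float))
        if b.size < min_samples:
            warnings.warn(f"replica {rid}: only {b.size} frames in the analysis "
                          "window; excluded from interface populations",
                          stacklevel=2)
            continue
        assignment[rid] = basins.basin_of(circular_mean_deg(b), circular_mean_deg(c))
    total = len(assignment)
    counts: dict[int, int] = {}
    for bid in assignment.values():
        counts[bid] = counts.get(bid, 0) + 1
    basins.populations = {
        bid: (cnt, cnt / total if total else math.nan) for bid, cnt in counts.items()
    }
    return assignment


_TM_NUM = re.compile(r"^TM(\d)$")


def _compress(labels: list[str]) -> str:
    """Render a helix set as the conventional compact label (e.g. TM5-7)."""
    nums = sorted(int(_TM_NUM.match(h).group(1)) for h in labels if _TM_NUM.match(h))
    parts: list[str] = []
    i = 0
    while i < len(nums):
        j = i
        while j + 1 < len(nums) and nums[j + 1] == nums[j] + 1:
            j += 1
        if j - i >= 2:
            parts.append(f"TM{nums[i]}-{nums[j]}")
        else:
            parts.extend(f"TM{n}" for n in nums[i:j + 1])
        i = j + 1
    if "H8" in labels:
        parts.append("H8")
    return ",".join(parts) if parts else "?"


def label_basin(
    maximum: tuple[float, float],
    helix_map_a: HelixAngularMap,
    helix_map_b: HelixAngularMap,
    contact_half_width_deg: float = 15.0,
) -> str:
    """Helix-pair label of a basin maximum (β*, χ*).

    Side A lists the helices exposed within the contact half-width of β* on
    receptor A; side B likewise for χ* on receptor B.  A maximum falling in
    an unexposed azimuth is attributed to the nearest exposed helix (with a
    warning).
    """
    sides = []
    for angle, hmap in ((maximum[0], helix_map_a), (maximum[1], helix_map_b)):
        helices = hmap.exposed_helices(angle, contact_half_width_deg)
        if not helices:
            nearest = _nearest_exposed(angle, hmap)
            warnings.warn(f"basin maximum at {angle:.0f} deg is not on an exposed "
                          f"helix; using nearest ({nearest})", stacklevel=2)
            helices = [nearest]
        sides.append(_compress(helices))
    return "/".join(sides)


def _nearest_exposed(angle: float, hmap: HelixAngularMap) -> str:
    bins = np.arange(360)
    occupied = np.array([bool(h) for h in hmap.exposure])
    dist = np.abs((bins - angle + 180.0) % 360.0 - 180.0)
    dist[~occupied] = np.inf
    return str(hmap.exposure[int(np.argmin(dist))])


def select_representative(
    members: list[tuple[str, float, float, float]],
    maximum: tuple[float, float],
    basin_id: int = 0,
    decile: float = 0.1,
) -> RepresentativePick:
    """Pick the structure representing a basin.

    ``members`` holds ``(replica_id, β, χ, final interaction energy)`` of
    the basin's replicas.  Among the members whose angular distance to the
    basin maximum lies in the lowest decile, the one with the lowest (most
    negative) final interaction energy is chosen — closest to the maximum
    while showing a compact, strongly interacting interface.
    """
    if not members:
        raise ValueError("basin has no members")
    dist = np.array([torus_distance_deg((b, c), maximum) for _, b, c, _ in members])
    n_keep = max(1, math.ceil(decile * len(members)))
    order = np.argsort(dist, kind="stable")
    threshold = dist[order[n_keep - 1]] + 1e-9  # distance ties all make the cut
    shortlist = [i for i in range(len(members)) if dist[i] <= threshold]
    best = min(shortlist, key=lambda i: members[i][3])
    rid, b, c, e = members[best]
    return RepresentativePick(basin_id=basin_id, replica_id=rid, beta=b, chi=c,
                              energy=e, distance_deg=float(dist[best]))
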