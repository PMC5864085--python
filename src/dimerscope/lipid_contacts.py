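"""Cholesterol–receptor contact analysis.

Occupancy: a residue counts as cholesterol-bound in a frame if any bead of
any cholesterol molecule lies within the contact cutoff (0.62 nm,
inclusive) of any bead of that residue; its occupancy is the fraction of
analysed frames in which it is bound.  Martini cholesterol carries 8 beads
of which the hydroxyl headgroup bead is named ROH.

Spatial densities: per frame the cholesterol molecules are ranked by their
minimum bead distance to the receptor, the beads of the N nearest
(default 5) molecules are accumulated on a 3D grid in the receptor-fixed
frame (each frame least-squares superposed onto the reference pose via the
TM backbone beads), and the headgroup beads of the same molecules are
accumulated separately.  Periodic boundaries are honoured via
minimum-image distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_io import ReceptorModel, ResultTable
from .structure_metrics import kabsch_fit

__all__ = [
    "ContactParams",
    "OccupancyProfile",
    "SpatialDensity",
    "residue_occupancy",
    "nearest_n_density",
    "occupancy_report",
]


@dataclass(frozen=True)
class ContactParams:
    cutoff_nm: float = 0.62
    n_nearest: int = 5
    chol_beads_per_molecule: int = 8
    headgroup_bead_name: str = "ROH"
    equilibration_discard_ns: float = 200.0
    grid_spacing_nm: float = 0.1

    def __post_init__(self) -> None:
        if self.cutoff_nm <= 0:
            raise ValueError("cutoff must be > 0")
        if self.n_nearest < 1:
            raise ValueError("n_nearest must be >= 1")


@dataclass
class OccupancyProfile:
    resids: np.ndarray
    occupancy: np.ndarray  # fraction of frames, per residue
    n_frames: int
    helix_occupancy: dict[str, float] = field(default_factory=dict)

    def of(self, resid: int) -> float:
        i = int(np.flatnonzero(self.resids == resid)[0])
        return float(self.occupancy[i])


@dataclass
class SpatialDensity:
    grid_all: np.ndarray  # all cholesterol beads, counts per frame
    grid_headgroup: np.ndarray  # ROH beads only
    origin_nm: np.ndarray
    spacing_nm: float
    n_frames: int
    raw_counts_all: float  # before per-frame normalisation
    raw_counts_headgroup: float

    def argmax_position_nm(self, headgroup: bool = False) -> np.ndarray:
        g = self.grid_headgroup if headgroup else self.grid_all
        ijk = np.unravel_index(int(np.argmax(g)), g.shape)
        return self.origin_nm + (np.asarray(ijk) + 0.5) * self.spacing_nm


def _min_image(delta: np.ndarray, box_nm: np.ndarray | None) -> np.ndarray:
    if box_nm is None:
        return delta
    box = np.asarray(box_nm, dtype=float)[:3]
    return delta - box * np.round(delta / box)


def _pair_min_dist(a: np.ndarray, b: np.ndarray, box_nm) -> np.ndarray:
    """(len(a), len(b)) matrix of minimum-image distances."""
    delta = a[:, None, :] - b[None, :, :]
    return np.linalg.norm(_min_image(delta, box_nm), axis=-1)


def iter_universe_frames(universe, params: ContactParams,
                         chol_resname: str = "CHOL"):
    """Yield (protein coords, per-molecule chol coords, ROH coords, box) in nm,
    skipping frames before the equilibration discard."""
    chol = universe.select_atoms(f"resname {chol_resname}")
    n_mol = chol.n_residues
    for ts in universe.trajectory:
        if ts.time / 1000.0 < params.equilibration_discard_ns:
            continue
        box = None if ts.dimensions is None else ts.dimensions[:3] / 10.0
        prot = universe.atoms.positions / 10.0
        chol_xyz = chol.positions.reshape(n_mol, -1, 3) / 10.0
        roh = chol.select_atoms(f"name {params.headgroup_bead_name}").positions / 10.0
        yield prot, chol_xyz, roh, box


def residue_occupancy(
    frames,
    receptor: ReceptorModel,
    params: ContactParams | None = None,
) -> OccupancyProfile:
    """Residue-resolved cholesterol occupancy over a frame stream.

    ``frames`` iterates ``(all_coords_nm, chol_coords_nm, box_nm)`` where
    ``chol_coords_nm`` has shape (n_molecules, beads_per_molecule, 3);
    receptor bead indices refer to ``all_coords_nm``.  The contact test is
    min over all residue beads × all cholesterol beads, inclusive at the
    cutoff.
    """
    params = params or ContactParams()
    resids = np.array([r for r, _, _ in receptor.residues])
    bead_groups = [np.asarray(b, dtype=int) for _, _, b in receptor.residues]
    bound_frames = np.zeros(len(resids), dtype=int)
    n_frames = 0
    saw_chol = False
    for coords, chol, box in frames:
        n_frames += 1
        chol = np.asarray(chol, dtype=float)
        if chol.size == 0:
            continue
        saw_chol = True
        chol_flat = chol.reshape(-1, 3)
        prot = np.asarray(coords, dtype=float)
        for i, beads in enumerate(bead_groups):
            d = _pair_min_dist(prot[beads], chol_flat, box)
            # inclusive boundary, robust to rounding in the norm
            if d.min() <= params.cutoff_nm + 1e-9:
                bound_frames[i] += 1
    if n_frames == 0:
        raise ValueError("no frames after the equilibration discard")
    if not saw_chol:
        warnings.warn("no cholesterol present: occupancy profile is all zero",
                      stacklevel=2)
    occ = bound_frames / n_frames
    helix_occ = {}
    for label in receptor.helix_map:
        members = np.isin(resids, receptor.helix_residues(label))
        helix_occ[label] = float(occ[members].mean()) if members.any() else np.nan
    return OccupancyProfile(resids=resids, occupancy=occ, n_frames=n_frames,
                            helix_occupancy=helix_occ)


def nearest_n_density(
    frames,
    receptor: ReceptorModel,
    params: ContactParams | None = None,
    headgroup_index: int = 0,
    extent_nm: float = 4.0,
) -> SpatialDensity:
    """3D densities of the N nearest cholesterol molecules around a receptor.

    ``frames`` iterates ``(all_coords_nm, chol_coords_nm, box_nm)`` as in
    :func:`residue_occupancy`; ``headgroup_index`` selects the ROH bead
    within each molecule.  Each frame is rigid-body superposed onto the
    receptor reference pose (TM backbone beads) before accumulation, so
    grids live in the receptor-fixed frame.  Before normalisation, the
    all-bead grid total equals frames × n_nearest × beads_per_molecule
    (fewer if a frame has fewer molecules than requested, with a warning).
    """
    params = params or ContactParams()
    if receptor.reference_coords is None:
        raise ValueError("receptor has no reference coordinates")
    bb = receptor.tm_backbone_indices()
    ref_bb = receptor.reference_coords[bb]
    ref_com = ref_bb.mean(axis=0)
    half = extent_nm + np.ptp(receptor.reference_coords, axis=0).max() / 2.0
    spacing = params.grid_spacing_nm
    n_side = int(np.ceil(2 * half / spacing))
    origin = ref_com - n_side * spacing / 2.0
    edges = [origin[k] + spacing * np.arange(n_side + 1) for k in range(3)]
    grid_all = np.zeros((n_side,) * 3)
    grid_roh = np.zeros((n_side,) * 3)

    prot_beads = receptor.bead_indices
    n_frames = 0
    short = False
    for coords, chol, box in frames:
        coords = np.asarray(coords, dtype=float)
        chol = np.asarray(chol, dtype=float)
        n_frames += 1
        if chol.size == 0:
            short = True
            continue
        n_mol = chol.shape[0]
        if n_mol < params.n_nearest:
            short = True
        prot = coords[prot_beads]
        # rank molecules by min bead distance to any receptor bead
        d = _pair_min_dist(chol.reshape(-1, 3), prot, box).min(axis=1)
        d_mol = d.reshape(n_mol, -1).min(axis=1)
        take = np.argsort(d_mol, kind="stable")[: params.n_nearest]
        # minimum-image the molecules next to the receptor COM, then superpose
        com = prot.mean(axis=0)
        sel = chol[take]
        mol_ref = sel[:, headgroup_index, :]
        shift = _min_image(mol_ref - com, box) - (mol_ref - com)
        sel = sel + shift[:, None, :]
        R, t = kabsch_fit(coords[bb], ref_bb)
        sel_fit = sel.reshape(-1, 3) @ R.T + t
        h, _ = np.histogramdd(sel_fit, bins=edges)
        grid_all += h
        roh = sel[:, headgroup_index, :] @ R.T + t
        h, _ = np.histogramdd(roh, bins=edges)
        grid_roh += h
    if n_frames == 0:
        raise ValueError("no frames after the equilibration discard")
    if short:
        warnings.warn("some frames had fewer cholesterol molecules than "
                      "n_nearest; used all available", stacklevel=2)
    raw_all, raw_roh = float(grid_all.sum()), float(grid_roh.sum())
    return SpatialDensity(
        grid_all=grid_all / n_frames,
        grid_headgroup=grid_roh / n_frames,
        origin_nm=origin,
        spacing_nm=spacing,
        n_frames=n_frames,
        raw_counts_all=raw_all,
        raw_counts_headgroup=raw_roh,
    )


def occupancy_report(
    profile: OccupancyProfile,
    receptor: ReceptorModel,
    highlight: list[int] | None = None,
) -> ResultTable:
    """Ranked residue occupancy table with helix labels and highlight flags.

    ``highlight`` lists externally supplied residues of interest (e.g. the
    experimentally addressed Ile52/Val150 of CCR5, Val64/Ile163 of CCR2);
    residues absent from the model are reported as 'not in model'.
    """
    order = np.argsort(-profile.occupancy, kind="stable")
    resids = profile.resids[order]
    rows = {
        "resid": resids,
        "occupancy": profile.occupancy[order],
        "helix": [receptor.helix_of(int(r)) or "" for r in resids],
    }
    units = {"resid": "", "occupancy": "fraction", "helix": ""}
    if highlight is not None:
        known = set(int(r) for r in profile.resids)
        rows["highlight"] = [
            "yes" if int(r) in set(highlight) else "" for r in resids
        ]
        units["highlight"] = ""
        missing = [r for r in highlight if r not in known]
        df = pd.DataFrame(rows)
        for r in missing:
            df = pd.concat(
                [df, pd.DataFrame({"resid": [r], "occupancy": [np.nan],
                                   "helix": [""], "highlight": ["not in model"]})],
                ignore_index=True)
        return ResultTable(df, units=units,
                           provenance={"n_frames": str(profile.n_frames)})
    return ResultTable(pd.DataFrame(rows), units=units,
                       provenance={"n_frames": str(profile.n_frames)})
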