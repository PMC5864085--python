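"""Domain data model and readers/writers for the dimerization pipeline.

Unit conventions used throughout the package: distances in nm, energies in
kJ/mol, times in ns (kinetics summaries additionally report rates per µs).
MDAnalysis returns Å internally for every coordinate format, so all
coordinates are divided by 10 at the read boundary.
"""

from __future__ import annotations

import dataclasses
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ManifestError",
    "StructureError",
    "XVGError",
    "EnsembleManifest",
    "ReplicaEntry",
    "ReceptorModel",
    "EnergyTrace",
    "Event",
    "ResultTable",
    "HELIX_LABELS",
    "read_manifest",
    "write_manifest",
    "read_structure",
    "read_energy_xvg",
    "write_energy_xvg",
    "write_table",
    "read_table",
    "write_opendx",
]

#: Recognised helix labels of the seven-transmembrane architecture plus the
#: amphipathic helix 8.  H8 is optional (it is e.g. unresolved in available
#: CXCR4 crystal structures).
HELIX_LABELS = ("TM1", "TM2", "TM3", "TM4", "TM5", "TM6", "TM7", "H8")
REQUIRED_HELICES = HELIX_LABELS[:7]


class ManifestError(ValueError):
    """Raised for malformed or inconsistent ensemble manifests."""


class StructureError(ValueError):
    """Raised for unusable coordinate/helix-assignment inputs."""


class XVGError(ValueError):
    """Raised for malformed interaction-energy time series files."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReplicaEntry:
    replica_id: str
    coordinates: str | None = None
    trajectory: str | None = None
    energy: str | None = None


@dataclass
class EnsembleManifest:
    """Inventory of one self-assembly simulation ensemble.

    ``t_sim_us`` is the per-replica simulation length in µs, ``dt_out_ns``
    the trajectory/energy output interval in ns.  ``area_density_per_nm2``
    records the receptor surface density of the setup (≈0.015 nm⁻² for the
    ensembles this package was written for) and is metadata only.
    """

    ensemble_id: str
    receptor_a: str
    receptor_b: str
    popc_fraction: float
    cholesterol_fraction: float
    n_replicas: int
    t_sim_us: float
    dt_out_ns: float
    replicas: list[ReplicaEntry]
    temperature_K: float = 310.0
    area_density_per_nm2: float = 0.015
    missing_files: list[str] = field(default_factory=list)

    @property
    def is_homodimer(self) -> bool:
        return self.receptor_a == self.receptor_b

    def validate(self) -> None:
        if self.t_sim_us <= 0:
            raise ManifestError("t_sim_us must be > 0")
        if not 0.0 <= self.cholesterol_fraction <= 1.0:
            raise ManifestError(
                f"cholesterol_fraction {self.cholesterol_fraction} outside [0, 1]"
            )
        if self.n_replicas != len(self.replicas):
            raise ManifestError(
                f"n_replicas={self.n_replicas} but {len(self.replicas)} replica "
                "entries listed"
            )
        ids = [r.replica_id for r in self.replicas]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ManifestError(f"duplicate replica_id(s): {dupes}")


@dataclass
class ReceptorModel:
    """Coarse-grained receptor: residues, bead bookkeeping and helix ranges.

    ``residues`` is an ordered list of ``(resid, resname, bead_indices)``;
    ``backbone_bead_index`` maps resid -> index of the single backbone bead;
    ``helix_map`` maps a helix label to an inclusive residue-number range.
    ``reference_coords`` holds bead positions (nm) of a reference frame.
    """

    name: str
    residues: list[tuple[int, str, tuple[int, ...]]]
    helix_map: dict[str, tuple[int, int]]
    backbone_bead_index: dict[int, int]
    reference_coords: np.ndarray | None = None
    #: relax to allow reduced test bundles with fewer than 7 TM helices
    require_full_tm: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        resids = [r[0] for r in self.residues]
        resid_set = set(resids)
        for label in self.helix_map:
            if label not in HELIX_LABELS:
                raise StructureError(f"unknown helix label: {label!r}")
        if self.require_full_tm:
            for label in REQUIRED_HELICES:
                if label not in self.helix_map:
                    raise StructureError(f"helix {label} missing from helix_map")
        covered: set[int] = set()
        for label, (lo, hi) in self.helix_map.items():
            members = set(range(lo, hi + 1))
            missing = sorted(members - resid_set)
            if missing:
                raise StructureError(
                    f"helix {label} references absent residues: {missing}"
                )
            if covered & members:
                raise StructureError(f"helix {label} overlaps another helix range")
            covered |= members
        for resid, _resname, beads in self.residues:
            if len(beads) < 1:
                raise StructureError(f"residue {resid} has no beads")
            if resid not in self.backbone_bead_index:
                raise StructureError(f"residue {resid} has no backbone bead")
            if self.backbone_bead_index[resid] not in beads:
                raise StructureError(
                    f"backbone bead of residue {resid} not among its beads"
                )

    # -- convenience selections -------------------------------------------
    def helix_residues(self, label: str) -> list[int]:
        lo, hi = self.helix_map[label]
        return [r for r, _, _ in self.residues if lo <= r <= hi]

    def helix_of(self, resid: int) -> str | None:
        for label, (lo, hi) in self.helix_map.items():
            if lo <= resid <= hi:
                return label
        return None

    @property
    def bead_indices(self) -> np.ndarray:
        return np.concatenate([np.asarray(b, dtype=int) for _, _, b in self.residues])

    def tm_backbone_indices(self, include_h8: bool = False) -> np.ndarray:
        """Backbone bead indices of the transmembrane helices (TM1..TM7)."""
        labels = HELIX_LABELS if include_h8 else REQUIRED_HELICES
        idx = []
        for label in labels:
            if label in self.helix_map:
                idx.extend(self.backbone_bead_index[r] for r in self.helix_residues(label))
        return np.asarray(idx, dtype=int)


@dataclass(frozen=True)
class Event:
    time: float  # ns
    kind: str  # "dimerization" | "dissociation"


@dataclass
class EnergyTrace:
    """TM–TM interaction energy (LJ + Coulomb, kJ/mol) of one replica."""

    replica_id: str
    times: np.ndarray  # ns
    energies: np.ndarray  # kJ/mol
    state: np.ndarray | None = None  # per frame: 0 monomer, 1 dimer
    events: list[Event] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.times.size == 0:
            raise XVGError(f"energy trace {self.replica_id!r} is empty")
        if self.times.shape != self.energies.shape:
            raise XVGError("times and energies differ in length")
        if np.any(np.diff(self.times) <= 0):
            raise XVGError(f"non-monotone time axis in trace {self.replica_id!r}")

    def __len__(self) -> int:
        return self.times.size


class ResultTable:
    """A column table with per-column units and a provenance header.

    Thin wrapper around a pandas DataFrame; serialised as TSV with '#'
    comment lines carrying units and provenance so that
    ``read_table(write_table(t)) == t``.
    """

    def __init__(
        self,
        data: pd.DataFrame | Mapping[str, Sequence],
        units: Mapping[str, str] | None = None,
        provenance: Mapping[str, str] | None = None,
    ) -> None:
        self.data = pd.DataFrame(data)
        self.units = dict(units or {})
        self.provenance = dict(provenance or {})
        lengths = {len(self.data[c]) for c in self.data.columns}
        if len(lengths) > 1:  # pragma: no cover - DataFrame enforces this
            raise ValueError("column lengths differ")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ResultTable):
            return NotImplemented
        return (
            self.data.equals(other.data)
            and self.units == other.units
            and self.provenance == other.provenance
        )

    def __repr__(self) -> str:
        return f"ResultTable({list(self.data.columns)}, n={len(self.data)})"


# ---------------------------------------------------------------------------
# manifest I/O
# ---------------------------------------------------------------------------


def read_manifest(path: str | os.PathLike) -> EnsembleManifest:
    """Read and validate an ensemble manifest (YAML schema).

    Schema (keys at top level)::

        ensemble_id: ccr5_ccr5_popc
        receptor_a: CCR5
        receptor_b: CCR5
        membrane: {popc_fraction: 1.0, cholesterol_fraction: 0.0}
        n_replicas: 2
        t_sim_us: 3.0
        dt_out_ns: 1.0
        temperature_K: 310.0          # optional, default 310
        area_density_per_nm2: 0.015   # optional metadata
        replicas:
          - {replica_id: rep-001, coordinates: r1.gro, trajectory: r1.xtc,
             energy: r1.xvg}

    File paths are interpreted relative to the manifest location; referenced
    files are checked for existence and reported in ``missing_files``
    (a warning, not a failure — e.g. a replica without an energy file is
    later excluded from kinetics).
    """
    path = os.fspath(path)
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ManifestError(f"manifest does not parse as YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ManifestError("manifest root must be a mapping")

    def need(key):
        if key not in raw:
            raise ManifestError(f"manifest missing required field {key!r}")
        return raw[key]

    membrane = need("membrane")
    if not isinstance(membrane, dict) or "cholesterol_fraction" not in membrane:
        raise ManifestError("field 'membrane' must map popc/cholesterol fractions")

    base = os.path.dirname(os.path.abspath(path))
    replicas = []
    for entry in need("replicas") or []:
        if not isinstance(entry, dict) or "replica_id" not in entry:
            raise ManifestError("field 'replicas': each entry needs a replica_id")
        replicas.append(
            ReplicaEntry(
                replica_id=str(entry["replica_id"]),
                coordinates=entry.get("coordinates"),
                trajectory=entry.get("trajectory"),
                energy=entry.get("energy"),
            )
        )

    manifest = EnsembleManifest(
        ensemble_id=str(need("ensemble_id")),
        receptor_a=str(need("receptor_a")),
        receptor_b=str(need("receptor_b")),
        popc_fraction=float(membrane.get("popc_fraction", 1.0)),
        cholesterol_fraction=float(membrane["cholesterol_fraction"]),
        n_replicas=int(need("n_replicas")),
        t_sim_us=float(need("t_sim_us")),
        dt_out_ns=float(need("dt_out_ns")),
        temperature_K=float(raw.get("temperature_K", 310.0)),
        area_density_per_nm2=float(raw.get("area_density_per_nm2", 0.015)),
        replicas=replicas,
    )
    manifest.validate()
    missing = []
    for rep in replicas:
        for p in (rep.coordinates, rep.trajectory, rep.energy):
            if p is not None and not os.path.exists(os.path.join(base, p)):
                missing.append(p)
    if missing:
        warnings.warn(f"manifest references missing files: {missing}", stacklevel=2)
    manifest.missing_files = missing
    return manifest


def write_manifest(manifest: EnsembleManifest, path: str | os.PathLike) -> None:
    doc = {
        "ensemble_id": manifest.ensemble_id,
        "receptor_a": manifest.receptor_a,
        "receptor_b": manifest.receptor_b,
        "membrane": {
            "popc_fraction": manifest.popc_fraction,
            "cholesterol_fraction": manifest.cholesterol_fraction,
        },
        "n_replicas": manifest.n_replicas,
        "t_sim_us": manifest.t_sim_us,
        "dt_out_ns": manifest.dt_out_ns,
        "temperature_K": manifest.temperature_K,
        "area_density_per_nm2": manifest.area_density_per_nm2,
        "replicas": [
            {k: v for k, v in dataclasses.asdict(r).items() if v is not None}
            for r in manifest.replicas
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# structure I/O
# ---------------------------------------------------------------------------


def read_structure(
    path: str | os.PathLike,
    helix_table: Mapping[str, tuple[int, int]],
    name: str | None = None,
    backbone_bead: str = "BB",
    protein_selection: str | None = None,
) -> ReceptorModel:
    """Read a GRO/PDB coordinate file into a :class:`ReceptorModel`.

    ``helix_table`` maps helix labels (TM1..TM7, optional H8) to inclusive
    residue-number ranges.  Coordinates come out in nm regardless of the
    input convention.  Residues are taken to belong to the receptor if they
    contain a bead named ``backbone_bead`` (Martini convention), unless an
    explicit MDAnalysis ``protein_selection`` is given.
    """
    import MDAnalysis as mda

    for label in helix_table:
        if label not in HELIX_LABELS:
            raise StructureError(f"unknown helix label: {label!r}")
    u = mda.Universe(os.fspath(path))
    if protein_selection is not None:
        atoms = u.select_atoms(protein_selection)
    else:
        resindices = [
            res.resindex for res in u.residues if backbone_bead in res.atoms.names
        ]
        atoms = u.residues[resindices].atoms if resindices else u.atoms[:0]
    if atoms.n_atoms == 0:
        raise StructureError(
            f"no receptor residues (no bead named {backbone_bead!r}) in {path}"
        )

    residues = []
    backbone = {}
    for res in atoms.residues:
        beads = tuple(int(i) for i in res.atoms.indices)
        residues.append((int(res.resid), str(res.resname), beads))
        names = list(res.atoms.names)
        if backbone_bead in names:
            backbone[int(res.resid)] = beads[names.index(backbone_bead)]
        else:
            backbone[int(res.resid)] = beads[0]
    coords = u.atoms.positions.astype(float) / 10.0  # Å -> nm
    return ReceptorModel(
        name=name or os.path.splitext(os.path.basename(os.fspath(path)))[0],
        residues=residues,
        helix_map={k: (int(v[0]), int(v[1])) for k, v in helix_table.items()},
        backbone_bead_index=backbone,
        reference_coords=coords,
    )


def read_helix_table(path: str | os.PathLike) -> dict[str, tuple[int, int]]:
    """Read a helix-range table: whitespace-separated ``label start end``."""
    table = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise StructureError(f"helix table line {lineno}: need 'label lo hi'")
            table[parts[0]] = (int(parts[1]), int(parts[2]))
    return table


def iter_frames(topology: str, trajectory: str | None = None):
    """Stream trajectory frames as (time_ns, coords_nm, box_nm) tuples.

    Frame-by-frame iterator so large ensembles never need whole-trajectory
    residency.
    """
    import MDAnalysis as mda

    u = mda.Universe(topology) if trajectory is None else mda.Universe(topology, trajectory)
    for ts in u.trajectory:
        box = None if ts.dimensions is None else ts.dimensions.copy()
        if box is not None:
            box[:3] /= 10.0
        yield ts.time / 1000.0, u.atoms.positions.astype(float) / 10.0, box


# ---------------------------------------------------------------------------
# energy time series (XVG dialect)
# ---------------------------------------------------------------------------


def read_energy_xvg(path: str | os.PathLike, replica_id: str | None = None) -> EnergyTrace:
    """Read a two-column XVG-dialect file (time ns, energy kJ/mol).

    Lines starting with '#' or '@' are comments/format directives and are
    skipped; data rows are whitespace separated.
    """
    times, energies = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped or stripped[0] in "#@":
                continue
            parts = stripped.replace("−", "-").split()
            if len(parts) < 2:
                raise XVGError(f"{path}: line {lineno}: expected >=2 columns")
            try:
                times.append(float(parts[0]))
                energies.append(float(parts[1]))
            except ValueError as exc:
                raise XVGError(f"{path}: line {lineno}: {exc}") from exc
    if not times:
        raise XVGError(f"{path}: no data rows")
    rid = replica_id or os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return EnergyTrace(replica_id=rid, times=np.array(times), energies=np.array(energies))


def write_energy_xvg(trace: EnergyTrace, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write('@ title "TM-TM interaction energy"\n')
        fh.write('@ xaxis label "time (ns)"\n')
        fh.write('@ yaxis label "E (kJ/mol)"\n')
        for t, e in zip(trace.times, trace.energies):
            fh.write(f"{t:.6g} {e:.10g}\n")


# ---------------------------------------------------------------------------
# result tables and density grids
# ---------------------------------------------------------------------------


def write_table(table: ResultTable, path: str | os.PathLike) -> None:
    """Write a :class:`ResultTable` as TSV with a '#' provenance header."""
    with open(path, "w") as fh:
        for key, value in table.provenance.items():
            fh.write(f"# provenance: {key}={value}\n")
        for col in table.data.columns:
            unit = table.units.get(col, "")
            fh.write(f"# unit: {col}={unit}\n")
        table.data.to_csv(fh, sep="\t", index=False)


def read_table(path: str | os.PathLike) -> ResultTable:
    provenance, units = {}, {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("provenance:"):
                key, _, value = body[len("provenance:"):].strip().partition("=")
                provenance[key] = value
            elif body.startswith("unit:"):
                key, _, value = body[len("unit:"):].strip().partition("=")
                units[key] = value
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        data = pd.read_csv(fh, sep="\t")
    return ResultTable(data, units=units, provenance=provenance)


def write_opendx(
    grid: np.ndarray,
    origin_nm: Sequence[float],
    spacing_nm: float | Sequence[float],
    path: str | os.PathLike,
) -> None:
    """Write a 3D density grid in OpenDX format (Å, the format's convention)."""
    from gridData import Grid

    spacing = np.broadcast_to(np.asarray(spacing_nm, dtype=float), (3,))
    g = Grid(
        np.asarray(grid, dtype=float),
        origin=np.asarray(origin_nm, dtype=float) * 10.0,
        delta=spacing * 10.0,
    )
    g.export(os.fspath(path), file_format="dx")
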