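"""Synthetic fixtures with machine-readable ground truth.

Every analysis stage of the package has a generator here that emulates the
statistical structure of the coarse-grained self-assembly ensembles the
pipeline targets — ~500 replicas per ensemble, exponential first-passage
dimerization at rates of order 0.05–0.3 µs⁻¹, rare dissociations,
interface-specific (β, χ) orientation modes, idealised 7-TM bead bundles,
8-bead cholesterol (one polar ROH bead) with residue-specific hotspots and
2D Brownian lateral diffusion with known D.  The generators return exact
ground truth so recovery tests are possible without any MD, and can
materialise the same file formats the readers consume (GRO/XTC/XVG/
manifest) so I/O paths are exercised too.

All randomness flows through explicit integer seeds and
``numpy.random.default_rng``; a fixed seed reproduces byte-identical
output on any platform.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np

from .model_io import (
    EnergyTrace,
    EnsembleManifest,
    ReceptorModel,
    ReplicaEntry,
    write_energy_xvg,
    write_manifest,
)
from .orientation import build_frame, wrap_deg

__all__ = [
    "EnergyEnsemble",
    "gen_energy_ensemble",
    "gen_bundle",
    "place_dimer",
    "gen_angle_mixture",
    "CholFieldFrames",
    "gen_chol_field",
    "gen_random_walk",
    "make_universe",
]


# ---------------------------------------------------------------------------
# interaction-energy ensembles
# ---------------------------------------------------------------------------


@dataclass
class EnergyEnsemble:
    traces: list[EnergyTrace]
    first_dimerization_us: list[float | None]  # ground truth, None = censored
    true_events: list[list[tuple[float, str]]]  # (time ns, kind)
    params: dict = field(default_factory=dict)

    def materialize(self, outdir: str) -> str:
        """Write XVG energy files plus a manifest; returns the manifest path."""
        os.makedirs(outdir, exist_ok=True)
        replicas = []
        for tr in self.traces:
            fname = f"{tr.replica_id}.xvg"
            write_energy_xvg(tr, os.path.join(outdir, fname))
            replicas.append(ReplicaEntry(replica_id=tr.replica_id, energy=fname))
        manifest = EnsembleManifest(
            ensemble_id=self.params.get("ensemble_id", "synthetic"),
            receptor_a="SYNA", receptor_b="SYNB",
            popc_fraction=1.0, cholesterol_fraction=0.0,
            n_replicas=len(self.traces),
            t_sim_us=self.params["t_sim_us"],
            dt_out_ns=self.params["dt_ns"],
            replicas=replicas,
        )
        path = os.path.join(outdir, "manifest.yaml")
        write_manifest(manifest, path)
        return path


def gen_energy_ensemble(
    k_on_per_us: float = 0.25,
    p_diss: float = 0.2,
    mean_dimer_energy: float = -150.0,
    n_replicas: int = 500,
    t_sim_us: float = 3.0,
    dt_ns: float = 1.0,
    seed: int = 0,
    k_off_per_us: float = 2.0,
    k_rebind_per_us: float = 10.0,
    sigma: float = 15.0,
    tau_ns: float = 50.0,
) -> EnergyEnsemble:
    """Generate TM–TM interaction-energy traces with known event times.

    Per replica: the first dimerization time is exponential with rate
    ``k_on_per_us`` (censored at ``t_sim_us``).  Each formed dimer
    dissociates with probability ``p_diss`` after an Exp(``k_off_per_us``)
    lifetime and then re-dimerizes after Exp(``k_rebind_per_us``);
    otherwise it persists to the horizon.  Monomeric stretches carry
    uniform energy jitter in [−1, 0]; dimeric stretches fluctuate around
    ``mean_dimer_energy`` as an Ornstein–Uhlenbeck process (σ, correlation
    time τ), clipped at −60 kJ/mol so the generating state sequence is
    exactly recoverable by the −50/−1 kJ/mol criterion.

    Defaults mirror the study conditions the package targets: 500 replicas
    of 3 µs, POPC-range association rate 0.25 µs⁻¹, strongly interacting
    dimers near −150 kJ/mol.
    """
    if not 0.0 <= p_diss <= 1.0:
        raise ValueError("p_diss must be in [0, 1]")
    if k_on_per_us < 0:
        raise ValueError("k_on must be >= 0")
    if dt_ns >= t_sim_us * 1000.0:
        raise ValueError("dt must be smaller than the simulation length")
    if mean_dimer_energy >= -60.0:
        raise ValueError("mean dimer energy must lie below -60 kJ/mol")
    rng = np.random.default_rng(seed)
    t_sim_ns = t_sim_us * 1000.0
    times = np.arange(0.0, t_sim_ns + 0.5 * dt_ns, dt_ns)
    n_frames = times.size
    alpha = math.exp(-dt_ns / tau_ns)
    noise_scale = sigma * math.sqrt(1.0 - alpha * alpha)

    traces, firsts, all_events = [], [], []
    for rep in range(n_replicas):
        # exact piecewise state path (times in ns)
        events: list[tuple[float, str]] = []
        t = math.inf if k_on_per_us == 0 else rng.exponential(1.0 / k_on_per_us) * 1000.0
        first = t / 1000.0 if t < t_sim_ns else None
        while t < t_sim_ns:
            events.append((t, "dimerization"))
            if rng.random() < p_diss:
                t_off = t + rng.exponential(1.0 / k_off_per_us) * 1000.0
                if t_off >= t_sim_ns:
                    break
                events.append((t_off, "dissociation"))
                t = t_off + rng.exponential(1.0 / k_rebind_per_us) * 1000.0
            else:
                break

        state = np.zeros(n_frames, dtype=np.int8)
        for when, kind in events:
            i = int(np.searchsorted(times, when, side="left"))
            state[i:] = 1 if kind == "dimerization" else 0

        e = rng.uniform(-1.0, 0.0, size=n_frames)
        dimer = state == 1
        if dimer.any():
            ou = np.empty(int(dimer.sum()))
            shocks = rng.standard_normal(ou.size)
            prev = mean_dimer_energy + sigma * shocks[0]
            # OU restarted at each dimer stretch would need bookkeeping; a
            # single chain over the dimeric frames is statistically adequate
            for i in range(ou.size):
                prev = mean_dimer_energy + alpha * (prev - mean_dimer_energy) \
                    + noise_scale * shocks[i]
                ou[i] = prev
            e[dimer] = np.minimum(ou, -60.0)
        traces.append(EnergyTrace(replica_id=f"rep-{rep:04d}", times=times.copy(),
                                  energies=e))
        firsts.append(first)
        all_events.append(events)
    return EnergyEnsemble(
        traces=traces,
        first_dimerization_us=firsts,
        true_events=all_events,
        params=dict(k_on_per_us=k_on_per_us, p_diss=p_diss,
                    mean_dimer_energy=mean_dimer_energy, t_sim_us=t_sim_us,
                    dt_ns=dt_ns, seed=seed, k_off_per_us=k_off_per_us,
                    k_rebind_per_us=k_rebind_per_us),
    )


# ---------------------------------------------------------------------------
# idealised 7-TM bundles and dimer placement
# ---------------------------------------------------------------------------


def gen_bundle(
    n_helices: int = 7,
    residues_per_helix: int = 10,
    ring_radii_nm: tuple[float, float] = (2.0, 1.5),
    rise_nm: float = 0.3,
    include_h8: bool = False,
    name: str = "bundle",
    z_offset_nm: float = 0.0,
) -> tuple[ReceptorModel, np.ndarray]:
    """Idealised transmembrane bundle with helices at known azimuths.

    Helix i stands vertically at azimuth 360·i/n on an ellipse with the
    given semi-axes (the anisotropy makes the principal in-plane axis well
    defined; TM1 sits on the +x major axis, so the molecular frame of the
    reference pose has x_axis = (1, 0, 0)).  One backbone bead ("BB") per
    residue.  ``include_h8`` appends a short in-plane helix 8 pointing
    outward at the TM7 side near the intracellular face.
    """
    if not 3 <= n_helices <= 7:
        raise ValueError("need between 3 and 7 transmembrane helices")
    a, b = ring_radii_nm
    residues: list[tuple[int, str, tuple[int, ...]]] = []
    backbone: dict[int, int] = {}
    helix_map: dict[str, tuple[int, int]] = {}
    coords = []
    resid = 0
    for h in range(n_helices):
        az = 2.0 * math.pi * h / n_helices
        x0, y0 = a * math.cos(az), b * math.sin(az)
        lo = resid + 1
        for k in range(residues_per_helix):
            resid += 1
            z = (k - (residues_per_helix - 1) / 2.0) * rise_nm + z_offset_nm
            coords.append((x0, y0, z))
            idx = len(coords) - 1
            residues.append((resid, "ALA", (idx,)))
            backbone[resid] = idx
        helix_map[f"TM{h + 1}"] = (lo, resid)
    if include_h8:
        lo = resid + 1
        z = -(residues_per_helix - 1) / 2.0 * rise_nm + z_offset_nm
        for k in range(4):
            resid += 1
            coords.append((a + 0.4 + 0.3 * k, -0.6, z))
            idx = len(coords) - 1
            residues.append((resid, "ALA", (idx,)))
            backbone[resid] = idx
        helix_map["H8"] = (lo, resid)
    coords = np.asarray(coords, dtype=float)
    model = ReceptorModel(name=name, residues=residues, helix_map=helix_map,
                          backbone_bead_index=backbone, reference_coords=coords,
                          require_full_tm=(n_helices >= 7))
    return model, coords


def _rot_z(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def place_dimer(
    model_a: ReceptorModel,
    coords_a: np.ndarray,
    model_b: ReceptorModel,
    coords_b: np.ndarray,
    beta: float,
    phi: float,
    separation_nm: float = 4.5,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float, float]]:
    """Place B relative to A at exact ground-truth angles (β, φ).

    B's frame origin is put at azimuth β in A's frame at the given
    separation, and B is rotated so that its own x axis leads A's by φ.
    Returns (coords_a, placed coords_b, (β, φ, χ)) with χ from the
    reciprocal-angle formula.  A warning is emitted for overlapping
    placements (separation below half the bundle diameter), not an error.
    """
    import warnings

    frame_a = build_frame(model_a, coords_a)
    frame_b0 = build_frame(model_b, coords_b)
    diameter = 2.0 * max(np.linalg.norm(
        (coords_a - frame_a.origin)[:, :2], axis=1).max(),
        np.linalg.norm((coords_b - frame_b0.origin)[:, :2], axis=1).max())
    if separation_nm <= 0.5 * diameter:
        warnings.warn("dimer placement overlaps the bundles", stacklevel=2)
    az_a = math.degrees(math.atan2(frame_a.x_axis[1], frame_a.x_axis[0]))
    az_b0 = math.degrees(math.atan2(frame_b0.x_axis[1], frame_b0.x_axis[0]))
    rot = _rot_z(az_a + phi - az_b0)
    target = frame_a.origin + separation_nm * (
        math.cos(math.radians(beta)) * frame_a.x_axis
        + math.sin(math.radians(beta)) * frame_a.y_axis)
    placed = (coords_b - frame_b0.origin) @ rot.T + target
    chi = float(wrap_deg(180.0 + beta - phi))
    return coords_a, placed, (float(wrap_deg(beta)), float(wrap_deg(phi)), chi)


# ---------------------------------------------------------------------------
# (β, χ) angle mixtures
# ---------------------------------------------------------------------------


def gen_angle_mixture(
    modes: list[tuple[float, float, float, float]],
    n: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (β, χ) samples from a wrapped-normal mixture with source labels.

    ``modes`` lists (β, χ, weight, σ degrees); weights must sum to 1.
    Returns (beta, chi, labels) with labels indexing the generating mode.
    """
    weights = np.array([m[2] for m in modes], dtype=float)
    if not math.isclose(weights.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("mode weights must sum to 1")
    if any(m[3] <= 0 for m in modes):
        raise ValueError("mode sigma must be > 0")
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(modes), size=n, p=weights)
    beta = np.empty(n)
    chi = np.empty(n)
    for i, (b0, c0, _w, s) in enumerate(modes):
        sel = labels == i
        k = int(sel.sum())
        beta[sel] = wrap_deg(b0 + s * rng.standard_normal(k))
        chi[sel] = wrap_deg(c0 + s * rng.standard_normal(k))
    return beta, chi, labels


# ---------------------------------------------------------------------------
# cholesterol contact fields
# ---------------------------------------------------------------------------


@dataclass
class CholFieldFrames:
    """Frames of a receptor in a cholesterol-containing patch.

    ``frames`` iterates (all protein coords, per-molecule chol coords, box)
    in the layout :func:`dimerscope.lipid_contacts.residue_occupancy`
    consumes; bead 0 of each cholesterol is the polar ROH headgroup.
    """

    model: ReceptorModel
    protein_coords: np.ndarray
    chol_coords: np.ndarray  # (n_frames, n_chol, 8, 3)
    box_nm: np.ndarray
    truth_occupancy: dict[int, float]

    def __iter__(self):
        for f in range(self.chol_coords.shape[0]):
            yield self.protein_coords, self.chol_coords[f], self.box_nm

    def truth_site(self, resid: int) -> np.ndarray:
        """Expected ROH (headgroup) position of a hotspot residue (nm)."""
        anchor = self.protein_coords[self.model.backbone_bead_index[resid]]
        u = _outward(anchor, self._centre)
        return anchor + 0.5 * (self._shell[0] + self._shell[1]) * u


def gen_chol_field(
    model: ReceptorModel,
    coords: np.ndarray,
    hotspots: dict[int, float],
    n_chol: int = 25,
    n_frames: int = 200,
    box_nm: tuple[float, float, float] = (30.0, 30.0, 12.0),
    seed: int = 0,
    contact_shell_nm: tuple[float, float] = (0.25, 0.55),
    clearance_nm: float = 1.0,
) -> CholFieldFrames:
    """Cholesterol frames with planted residue hotspots of known occupancy.

    Each frame, each hotspot residue is contacted with its stated
    probability by a dedicated cholesterol whose ROH bead is placed inside
    the contact shell around the residue's backbone bead, along the fixed
    outward radial direction of that residue (the remaining 7 beads trail
    further outward in a tight stack) — so the planted binding site of a
    hotspot is the well-defined point returned by :meth:`CholFieldFrames
    .truth_site`.  All other molecules are uniform in the box but rejected
    within ``clearance_nm`` of the receptor, so the planted probabilities
    are the exact expected occupancies of the hotspot residues (choose
    hotspot residues on different helices to keep them independent).
    """
    rng = np.random.default_rng(seed)
    resids = {r for r, _, _ in model.residues}
    for r in hotspots:
        if r not in resids:
            raise ValueError(f"hotspot residue {r} not in the bundle")
    if len(hotspots) > n_chol:
        raise ValueError("more simultaneous hotspots than cholesterol molecules")
    box = np.asarray(box_nm, dtype=float)
    coords = np.asarray(coords, dtype=float)
    centre = box / 2.0
    prot = coords - coords.mean(axis=0) + centre  # receptor centred in the box
    prot_beads = prot[model.bead_indices]

    out = np.empty((n_frames, n_chol, 8, 3))
    for f in range(n_frames):
        mol = 0
        for resid, p in hotspots.items():
            if rng.random() < p:
                anchor = prot[model.backbone_bead_index[resid]]
                u = _outward(anchor, centre)
                r = rng.uniform(*contact_shell_nm)
                head = anchor + r * u
                out[f, mol] = head + np.outer(np.arange(8) * 0.25, u)
            else:
                out[f, mol] = _uniform_molecule(rng, box, prot_beads, clearance_nm)
            mol += 1
        while mol < n_chol:
            out[f, mol] = _uniform_molecule(rng, box, prot_beads, clearance_nm)
            mol += 1
    field = CholFieldFrames(model=model, protein_coords=prot, chol_coords=out,
                            box_nm=box, truth_occupancy=dict(hotspots))
    field._shell = contact_shell_nm
    field._centre = centre
    return field


def _outward(anchor: np.ndarray, centre: np.ndarray) -> np.ndarray:
    """In-plane outward unit vector from the receptor axis through ``anchor``."""
    u = np.array([anchor[0] - centre[0], anchor[1] - centre[1], 0.0])
    n = np.linalg.norm(u)
    return u / n if n > 1e-12 else np.array([1.0, 0.0, 0.0])


def _uniform_molecule(rng, box, prot_beads, clearance) -> np.ndarray:
    while True:
        head = rng.uniform(0.0, 1.0, 3) * box
        delta = prot_beads - head
        delta -= box * np.round(delta / box)
        if np.linalg.norm(delta, axis=1).min() > clearance + 0.25 * 7:
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            return head + np.outer(np.arange(8) * 0.25, u)


# ---------------------------------------------------------------------------
# Brownian walks
# ---------------------------------------------------------------------------


def gen_random_walk(
    D_nm2_per_ns: float,
    n_steps: int,
    dt_ns: float = 1.0,
    n_beads: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Rigid 2D Brownian motion of a bead cloud with known D.

    Steps are Gaussian with total in-plane variance 4·D·dt (2·D·dt per
    axis), applied rigidly to the whole cloud; z stays fixed.  Returns
    (times_ns, coords (n_steps+1, n_beads, 3)).
    """
    if D_nm2_per_ns < 0:
        raise ValueError("D must be >= 0")
    rng = np.random.default_rng(seed)
    cloud = rng.uniform(-1.0, 1.0, size=(n_beads, 3))
    steps = rng.standard_normal((n_steps, 2)) * math.sqrt(2.0 * D_nm2_per_ns * dt_ns)
    path = np.zeros((n_steps + 1, 3))
    path[1:, :2] = np.cumsum(steps, axis=0)
    coords = path[:, None, :] + cloud[None, :, :]
    times = np.arange(n_steps + 1) * dt_ns
    return times, coords


# ---------------------------------------------------------------------------
# MDAnalysis bridging
# ---------------------------------------------------------------------------


def make_universe(field: CholFieldFrames, dt_ns: float = 1.0):
    """Build an in-memory MDAnalysis Universe from cholesterol-field frames.

    Protein beads are named BB (resname per the model); cholesterol
    molecules get resname CHOL with beads ROH, R1..R7.  Also usable to
    write GRO/XTC files so the file-reading paths can be exercised.
    """
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    model = field.model
    n_prot = len(field.protein_coords)
    n_frames, n_chol = field.chol_coords.shape[:2]
    n_atoms = n_prot + n_chol * 8
    n_res = len(model.residues) + n_chol

    atom_res = np.empty(n_atoms, dtype=int)
    names = np.empty(n_atoms, dtype=object)
    resnames, resids = [], []
    for ri, (resid, resname, beads) in enumerate(model.residues):
        resnames.append(resname)
        resids.append(resid)
        for b in beads:
            atom_res[b] = ri
            names[b] = "BB" if b == model.backbone_bead_index[resid] else "SC1"
    base = len(model.residues)
    for m in range(n_chol):
        resnames.append("CHOL")
        resids.append(1000 + m)
        for k in range(8):
            i = n_prot + m * 8 + k
            atom_res[i] = base + m
            names[i] = "ROH" if k == 0 else f"R{k}"

    u = mda.Universe.empty(n_atoms, n_residues=n_res, atom_resindex=atom_res,
                           trajectory=True)
    u.add_TopologyAttr("names", list(names))
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", resids)

    frames = np.empty((n_frames, n_atoms, 3), dtype=np.float32)
    for f in range(n_frames):
        frames[f, :n_prot] = field.protein_coords * 10.0  # nm -> Å
        frames[f, n_prot:] = field.chol_coords[f].reshape(-1, 3) * 10.0
    dims = np.tile(np.concatenate([field.box_nm * 10.0, [90.0, 90.0, 90.0]]),
                   (n_frames, 1))
    u.load_new(frames, format=MemoryReader, dimensions=dims, dt=dt_ns * 1000.0)
    return u
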