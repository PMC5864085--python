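"""Association/dissociation kinetics from TM–TM interaction-energy traces.

Two receptors count as a dimer once their transmembrane interaction energy
(Lennard-Jones + Coulomb) drops below ``e_on`` (default −50 kJ/mol); an
existing dimer dissociates only when the energy rises above ``e_off``
(default −1 kJ/mol).  The band in between is hysteretic (Schmitt trigger):
it neither creates nor destroys a dimer.

From ensembles of annotated traces the module derives

* the first-order dimerization rate ``k`` from the decay of the surviving
  monomer fraction f(t) = exp(−k t), with a censored-exponential
  maximum-likelihood estimate as an independent cross-check,
* dimerization and dissociation propensities,
* the ratio P0/P1 of post-dissociation monomeric time to dimeric time, and
  from it a coarse-grained lower-bound binding free energy via
  K_D = (P0/P1)/(N_Av·V)  (in mol/L),   ΔG = R·T·ln(K_D/c°).

The printed form of the K_D relation in the source material multiplies the
volume factor; that is dimensionally consistent only if the factor divides,
which is the reading implemented here (see docs/methods.md).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .model_io import EnergyTrace, Event

__all__ = [
    "EventThresholds",
    "RateFit",
    "KineticsSummary",
    "DimerKinetics",
    "annotate_events",
    "fit_first_order_rate",
    "dimerization_propensity",
    "dissociation_propensity",
    "accumulate_P0_P1",
    "lower_bound_binding_free_energy",
    "rate_reduction_percent",
    "AVOGADRO",
    "GAS_CONSTANT_KJ",
]

AVOGADRO = 6.02214076e23  # 1/mol
GAS_CONSTANT_KJ = 8.31446261815324e-3  # kJ/(mol K)
STANDARD_CONCENTRATION = 1.0  # mol/L
_NM3_TO_L = 1e-24


@dataclass(frozen=True)
class EventThresholds:
    """Energy thresholds of the two-threshold dimerization criterion.

    ``scan_levels`` lists alternative (tighter) dimerization criteria used
    to probe increasingly compact dimers.
    """

    e_on: float = -50.0
    e_off: float = -1.0
    scan_levels: tuple[float, ...] = (-50.0, -100.0, -150.0, -200.0)

    def __post_init__(self) -> None:
        if not (self.e_on < self.e_off <= 0.0):
            raise ValueError("require e_on < e_off <= 0")
        if self.scan_levels == type(self).scan_levels:
            # default scan: keep only criteria at least as tight as e_on
            object.__setattr__(self, "scan_levels",
                               tuple(l for l in self.scan_levels if l <= self.e_on))
        if any(level > self.e_on for level in self.scan_levels):
            raise ValueError("scan levels must be <= e_on")

    def at_level(self, level: float) -> "EventThresholds":
        return EventThresholds(e_on=level, e_off=self.e_off, scan_levels=(level,))


def annotate_events(trace: EnergyTrace, thresholds: EventThresholds | None = None) -> EnergyTrace:
    """Return a copy of ``trace`` with per-frame state and events filled in.

    A replica starts monomeric unless its first frame is already below
    ``e_on``, in which case it is dimeric from t=0 with no recorded event
    (left-censored; such replicas contribute no first-passage time).
    Dimerization fires at the first frame with energy < e_on from a
    monomeric state; dissociation at the first frame with energy > e_off
    from a dimeric state.  Events therefore strictly alternate.
    """
    thresholds = thresholds or EventThresholds()
    e = trace.energies
    # Vectorised Schmitt trigger: -1 marks "hold previous state".
    raw = np.full(e.shape, -1, dtype=np.int8)
    raw[e < thresholds.e_on] = 1
    raw[e > thresholds.e_off] = 0
    if raw[0] == -1:
        raw[0] = 0  # starts monomeric inside the hysteresis band
    # forward-fill the holds
    idx = np.arange(e.size)
    defined = raw >= 0
    last = np.maximum.accumulate(np.where(defined, idx, 0))
    state = raw[last]
    changes = np.flatnonzero(np.diff(state.astype(np.int8)))
    events = [
        Event(time=float(trace.times[i + 1]),
              kind="dimerization" if state[i + 1] == 1 else "dissociation")
        for i in changes
    ]
    return replace(trace, state=state, events=events)


@dataclass
class RateFit:
    """First-order rate estimate (per µs) with uncertainty and diagnostics."""

    k: float  # µs^-1, from the ln f(t) weighted least-squares fit
    k_stderr: float
    k_mle: float  # censored-exponential MLE cross-check
    k_mle_stderr: float
    n_events: int
    n_replicas: int
    at_resolution_limit: bool = False
    degenerate: bool = False


def fit_survivor_curve(
    times_us: np.ndarray,
    fraction: np.ndarray,
    weights: np.ndarray | None = None,
) -> float:
    """Fit f(t) = exp(−k t) through the origin by (weighted) least squares.

    Operates on ln f over the points with f > 0; exact on noiseless
    exponential input.  Returns k in µs⁻¹.
    """
    t = np.asarray(times_us, dtype=float)
    f = np.asarray(fraction, dtype=float)
    mask = (f > 0) & (t >= 0)
    t, f = t[mask], f[mask]
    if t.size == 0 or not np.any(t > 0):
        raise ValueError("survivor curve has no usable points")
    w = np.ones_like(t) if weights is None else np.asarray(weights, float)[mask]
    den = np.sum(w * t**2)
    if den == 0:
        raise ValueError("survivor curve has no positive times")
    return float(-np.sum(w * t * np.log(f)) / den)


def fit_first_order_rate(
    first_times_us: np.ndarray,
    horizon_us: float,
    n_replicas: int | None = None,
    dt_out_us: float | None = None,
) -> RateFit:
    """Fit k from per-replica first-dimerization times with right censoring.

    ``first_times_us`` holds the observed first-dimerization times (µs) of
    the replicas that dimerized; replicas that stayed monomeric up to
    ``horizon_us`` are censored.  The survivor fraction
    f(t) = (replicas still monomeric at t)/n is fitted as ln f(t) = −k t by
    least squares weighted with the surviving counts; the censored
    exponential MLE  k̂ = d / (Σ t_i + Σ T_censored)  is reported alongside.
    """
    times = np.sort(np.asarray(first_times_us, dtype=float))
    if horizon_us <= 0:
        raise ValueError("horizon must be > 0")
    n = int(n_replicas) if n_replicas is not None else times.size
    if n < 1:
        raise ValueError("need at least one replica")
    d = times.size
    if d == 0:
        warnings.warn("no dimerization events: rate is degenerate 0", stacklevel=2)
        return RateFit(0.0, math.nan, 0.0, math.nan, 0, n, degenerate=True)

    n_censored = n - d
    total_time = times.sum() + n_censored * horizon_us
    k_mle = d / total_time
    k_mle_stderr = k_mle / math.sqrt(d)

    # survivor curve at the observed event times
    surviving = n - np.arange(1, d + 1)
    mask = surviving > 0
    t_fit = times[mask]
    f = surviving[mask] / n
    if t_fit.size >= 1 and np.any(t_fit > 0):
        w = surviving[mask].astype(float)  # var(ln f) shrinks with count at risk
        num = np.sum(w * t_fit * np.log(f))
        den = np.sum(w * t_fit**2)
        k_wls = -num / den if den > 0 else k_mle
        resid = np.log(f) + k_wls * t_fit
        dof = max(t_fit.size - 1, 1)
        k_stderr = math.sqrt(np.sum(w * resid**2) / dof / den) if den > 0 else math.nan
    else:  # all events in the very first frame
        k_wls, k_stderr = k_mle, math.nan

    at_limit = False
    if dt_out_us is not None and d > 0:
        at_limit = bool(np.all(times <= dt_out_us))
        if at_limit:
            warnings.warn("rate at resolution limit: all events in first frame",
                          stacklevel=2)
    return RateFit(float(k_wls), float(k_stderr), float(k_mle),
                   float(k_mle_stderr), d, n, at_resolution_limit=at_limit)


def dimerization_propensity(n_dimers_final: int, n_replicas: int, t_sim_us: float,
                            per_replica: bool = True) -> float:
    """Relative number of dimers formed per microsecond.

    Default normalisation divides the final dimer count by the replica count
    and the per-replica simulation time (configurable via ``per_replica``).
    """
    if t_sim_us <= 0:
        raise ValueError("t_sim must be > 0")
    if n_dimers_final > n_replicas:
        raise ValueError("more final dimers than replicas")
    norm = n_replicas if per_replica else 1
    return (n_dimers_final / norm) / t_sim_us


def dissociation_propensity(
    traces: list[EnergyTrace],
    include_replicas: set[str] | None = None,
) -> float:
    """Total dissociation events over total dimerization events.

    ``include_replicas`` restricts the count to replicas whose final dimer
    belongs to the most populated interfaces (top-3 for homodimers, top-5
    for heterodimers, supplied by the interface-classification stage).
    Undefined (NaN) when no dimerization occurred.
    """
    n_dim = n_diss = 0
    for trace in traces:
        if trace.events is None:
            raise ValueError("traces must be annotated first")
        if include_replicas is not None and trace.replica_id not in include_replicas:
            continue
        n_dim += sum(1 for ev in trace.events if ev.kind == "dimerization")
        n_diss += sum(1 for ev in trace.events if ev.kind == "dissociation")
    if n_dim == 0:
        return math.nan
    return n_diss / n_dim


def accumulate_P0_P1(
    traces: list[EnergyTrace],
    include_replicas: set[str] | None = None,
) -> tuple[float, float, float]:
    """Return (P0/P1, P0, P1) in ns over an annotated ensemble.

    P1 is the total time spent dimeric.  P0 is the monomeric time occurring
    *after* the first dissociation of a replica (pre-first-dimerization
    monomer time never counts); a re-dimerization closes a P0 interval.
    NaN ratio when P1 = 0.
    """
    p0 = p1 = 0.0
    for trace in traces:
        if trace.state is None or trace.events is None:
            raise ValueError("traces must be annotated first")
        if include_replicas is not None and trace.replica_id not in include_replicas:
            continue
        t, s = trace.times, trace.state
        dt = np.diff(t)
        p1 += float(np.sum(dt[s[:-1] == 1]))
        first_diss = next((ev.time for ev in trace.events if ev.kind == "dissociation"),
                          None)
        if first_diss is not None:
            after = t[:-1] >= first_diss
            p0 += float(np.sum(dt[after & (s[:-1] == 0)]))
    if p1 == 0.0:
        return math.nan, p0, p1
    return p0 / p1, p0, p1


def lower_bound_binding_free_energy(
    p0_over_p1: float,
    volume_nm3: float,
    temperature_K: float = 310.0,
) -> tuple[float, float]:
    """Coarse-grained lower-bound (K_D in mol/L, ΔG in kJ/mol).

    K_D = (P0/P1)/(N_Av·V); ΔG = R·T·ln(K_D/c°) with c° = 1 mol/L.
    P0/P1 = 0 (dissociation never observed) yields K_D = 0 and ΔG = −inf as
    an "unbound-never-observed" sentinel.
    """
    if p0_over_p1 < 0:
        raise ValueError("P0/P1 must be >= 0")
    if volume_nm3 <= 0:
        raise ValueError("volume must be > 0")
    if p0_over_p1 == 0.0:
        return 0.0, -math.inf
    kd = p0_over_p1 / (AVOGADRO * volume_nm3 * _NM3_TO_L)
    dg = GAS_CONSTANT_KJ * temperature_K * math.log(kd / STANDARD_CONCENTRATION)
    return kd, dg


def invert_binding_free_energy(dg_kj_mol: float, temperature_K: float = 310.0) -> float:
    """K_D (mol/L) corresponding to a lower-bound ΔG at temperature T."""
    return STANDARD_CONCENTRATION * math.exp(dg_kj_mol / (GAS_CONSTANT_KJ * temperature_K))


def rate_reduction_percent(k_reference: float, k_perturbed: float) -> float:
    """Percent reduction of a rate constant, 100·(1 − k_perturbed/k_ref)."""
    if k_reference <= 0:
        raise ValueError("reference rate must be > 0")
    return 100.0 * (1.0 - k_perturbed / k_reference)


# ---------------------------------------------------------------------------
# ensemble-level model object
# ---------------------------------------------------------------------------


@dataclass
class KineticsSummary:
    """Ensemble kinetics in the shape of the published summary tables."""

    ensemble_id: str
    n_replicas: int
    t_sim_us: float
    e_on: float
    k: RateFit
    n_dimers_final: int
    n_dimerizations: int
    n_dissociations: int
    dimerization_propensity_per_us: float
    dissociation_propensity: float
    p0_over_p1: float
    volume_nm3: float
    temperature_K: float
    K_D_molar: float
    dG_lower_bound_kj_mol: float

    def summary(self) -> str:
        rows = [
            ("replicas", f"{self.n_replicas}"),
            ("simulation length", f"{self.t_sim_us:g} us"),
            ("dimerization criterion", f"{self.e_on:g} kJ/mol"),
            ("k (survivor fit)", f"{self.k.k:.3f} /us (se {self.k.k_stderr:.3f})"),
            ("k (censored MLE)", f"{self.k.k_mle:.3f} /us"),
            ("final dimers", f"{self.n_dimers_final}"),
            ("dimerization events", f"{self.n_dimerizations}"),
            ("dissociation events", f"{self.n_dissociations}"),
            ("dimerization propensity", f"{self.dimerization_propensity_per_us:.3f} /us"),
            ("dissociation propensity", f"{self.dissociation_propensity:.3f}"),
            ("P0/P1", f"{self.p0_over_p1:.4f}"),
            ("slab volume", f"{self.volume_nm3:.1f} nm^3"),
            ("K_D", f"{self.K_D_molar:.3e} M"),
            ("dG lower bound", f"{self.dG_lower_bound_kj_mol:.2f} kJ/mol"),
        ]
        width = max(len(k) for k, _ in rows)
        head = f"Dimerization kinetics: {self.ensemble_id}\n" + "-" * 46 + "\n"
        return head + "\n".join(f"{k:<{width}}  {v}" for k, v in rows)


class DimerKinetics:
    """Kinetics model over an ensemble of interaction-energy traces.

    Parameters
    ----------
    traces : list of EnergyTrace
        Raw (unannotated) per-replica energy time series.
    t_sim_us : float
        Censoring horizon, i.e. per-replica simulation length in µs.
    volume_nm3 : float
        Volume of the protein–lipid slab used in the K_D conversion.  The
        conventional choice is box xy-area × a 4 nm slab.
    thresholds : EventThresholds, optional
    temperature_K : float

    ``fit()`` annotates all traces and returns a :class:`KineticsSummary`.
    """

    def __init__(
        self,
        traces: list[EnergyTrace],
        t_sim_us: float,
        volume_nm3: float,
        thresholds: EventThresholds | None = None,
        temperature_K: float = 310.0,
        ensemble_id: str = "ensemble",
    ) -> None:
        if not traces:
            raise ValueError("need at least one trace")
        self.traces = traces
        self.t_sim_us = float(t_sim_us)
        self.volume_nm3 = float(volume_nm3)
        self.thresholds = thresholds or EventThresholds()
        self.temperature_K = float(temperature_K)
        self.ensemble_id = ensemble_id

    @classmethod
    def from_manifest(cls, manifest, slab_thickness_nm: float = 4.0,
                      box_area_nm2: float | None = None,
                      thresholds: EventThresholds | None = None):
        """Build from an :class:`EnsembleManifest`, reading XVG energy files.

        Replicas without a readable energy file are excluded with a warning.
        If ``box_area_nm2`` is not given it is estimated from the area
        density metadata (2 receptors / area_density).
        """
        import os

        from .model_io import read_energy_xvg

        base = getattr(manifest, "_base_dir", "")
        traces = []
        for rep in manifest.replicas:
            if rep.energy is None:
                warnings.warn(f"replica {rep.replica_id}: no energy file listed; "
                              "excluded from kinetics", stacklevel=2)
                continue
            path = os.path.join(base, rep.energy)
            if not os.path.exists(path):
                warnings.warn(f"replica {rep.replica_id}: energy file missing; "
                              "excluded from kinetics", stacklevel=2)
                continue
            traces.append(read_energy_xvg(path, replica_id=rep.replica_id))
        if box_area_nm2 is None:
            box_area_nm2 = 2.0 / manifest.area_density_per_nm2
        return cls(
            traces,
            t_sim_us=manifest.t_sim_us,
            volume_nm3=box_area_nm2 * slab_thickness_nm,
            thresholds=thresholds,
            temperature_K=manifest.temperature_K,
            ensemble_id=manifest.ensemble_id,
        )

    def fit(self, include_replicas: set[str] | None = None,
            e_on: float | None = None) -> KineticsSummary:
        thr = self.thresholds if e_on is None else self.thresholds.at_level(e_on)
        annotated = [annotate_events(tr, thr) for tr in self.traces]
        self.annotated_ = annotated

        first_times, n_dim, n_diss, n_final = [], 0, 0, 0
        dt_us = None
        for tr in annotated:
            if len(tr.times) > 1 and dt_us is None:
                dt_us = float(tr.times[1] - tr.times[0]) / 1000.0
            for ev in tr.events:
                if ev.kind == "dimerization":
                    n_dim += 1
                else:
                    n_diss += 1
            dims = [ev.time for ev in tr.events if ev.kind == "dimerization"]
            if dims:
                first_times.append(dims[0] / 1000.0)  # ns -> µs
            if tr.state[-1] == 1:
                n_final += 1

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rate = fit_first_order_rate(
                np.asarray(first_times), self.t_sim_us,
                n_replicas=len(annotated), dt_out_us=dt_us)
        p0p1, _, _ = accumulate_P0_P1(annotated, include_replicas)
        diss_prop = dissociation_propensity(annotated, include_replicas)
        if math.isnan(p0p1):
            kd, dg = math.nan, math.nan
        else:
            kd, dg = lower_bound_binding_free_energy(
                p0p1, self.volume_nm3, self.temperature_K)
        return KineticsSummary(
            ensemble_id=self.ensemble_id,
            n_replicas=len(annotated),
            t_sim_us=self.t_sim_us,
            e_on=thr.e_on,
            k=rate,
            n_dimers_final=n_final,
            n_dimerizations=n_dim,
            n_dissociations=n_diss,
            dimerization_propensity_per_us=dimerization_propensity(
                n_final, len(annotated), self.t_sim_us),
            dissociation_propensity=diss_prop,
            p0_over_p1=p0p1,
            volume_nm3=self.volume_nm3,
            temperature_K=self.temperature_K,
            K_D_molar=kd,
            dG_lower_bound_kj_mol=dg,
        )

    def scan(self, include_replicas: set[str] | None = None) -> list[KineticsSummary]:
        """Re-run the analysis at each scan level (tighter dimer criteria)."""
        return [self.fit(include_replicas, e_on=level)
                for level in self.thresholds.scan_levels]
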