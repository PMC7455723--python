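"""Virtual cohorts and the NHL virtual population.

Workflow: random-search perturbation around the reference virtual cyno,
acceptance against data-derived envelopes (capturing the observed
variability of the multi-dose study), translation of accepted cynos to
human physiology, crossing with sampled tumor/disease variability, and
importance-weighting so the simulated end-of-treatment tumor-change
distribution under the reference blinatumomab regimen matches the
clinical target waterfall.

All sampling is driven by ``numpy`` SeedSequence spawning, so cohorts
and populations are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import SimulationError, SolverSettings, Trajectory, simulate
from .params import PB, TU, Physiology, SubjectParameters
from .pk import PKForcing, Regimen, TwoCompartmentForcing, TwoCompartmentPKParams
from .synthetic import ClinicalTargets, PDDataset
from .reference import pk_defaults

#: parameters randomized in the cohort random search (log-uniform folds)
DEFAULT_PERTURBATION = {
    "drugs.mosunetuzumab.vmax_max": 3.0,
    "drugs.mosunetuzumab.ec50_act": 3.0,
    "drugs.mosunetuzumab.k_kill": 3.0,
    "drugs.blinatumomab.vmax_max": 3.0,
    "drugs.blinatumomab.ec50_act": 3.0,
    "drugs.blinatumomab.k_kill": 3.0,
    "tcell.k_prol": 2.0,
    "tcell.k_adeath_act": 2.0,
    "tcell.pb_exit.activated": 2.0,
    "tcell.stress_amplitude": 2.0,
    "cytokine.k_prod": 3.0,
    "cytokine.f_tiss": 3.0,
}


@dataclass(frozen=True)
class PerturbationSpec:
    """Per-parameter fold-ranges for local random search."""

    folds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PERTURBATION))

    def __post_init__(self):
        for path, fold in self.folds.items():
            if fold < 1.0:
                raise ValueError(f"fold-range for {path} must be >= 1")


def sample_candidate(
    reference: SubjectParameters,
    spec: PerturbationSpec,
    rng: np.random.Generator,
    subject_id: Optional[str] = None,
) -> SubjectParameters:
    """Log-uniform independent draws within [ref/fold, ref*fold].

    Parameters not named in the spec are untouched. Draws violating a
    hard invariant (e.g. f_tiss >= 1) raise the validation error of the
    parameter container.
    """
    updates = {}
    for path in sorted(spec.folds):
        fold = spec.folds[path]
        ref = reference.get(path)
        if fold == 1.0 or ref == 0.0:
            updates[path] = ref
            continue
        u = rng.uniform(-1.0, 1.0)
        updates[path] = ref * fold**u
    out = reference.replace(updates)
    if subject_id is not None:
        out = out.with_id(subject_id)
    return out


@dataclass(frozen=True)
class AcceptanceEnvelope:
    """Lower/upper acceptance band for one observable under one regimen."""

    analyte: str
    dose_group: float
    times: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    threshold: float = 0.8  # required fraction of points inside

    def __post_init__(self):
        t = np.asarray(self.times, float)
        lo = np.asarray(self.lower, float)
        hi = np.asarray(self.upper, float)
        if not (t.shape == lo.shape == hi.shape):
            raise ValueError("envelope arrays must be congruent")
        if np.any(lo > hi):
            raise ValueError("envelope lower bound exceeds upper bound")
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    def fraction_inside(self, traj: Trajectory) -> float:
        series = traj.observable(self.analyte)
        model = np.interp(self.times, traj.time, series)
        ok = (model >= self.lower) & (model <= self.upper)
        return float(np.mean(ok))


def envelopes_from_study(
    dataset: PDDataset,
    margin: float = 1.5,
    threshold: float = 0.8,
    analytes: Sequence[str] = ("CD8_count", "pct_CD69", "B_count", "IL6"),
) -> list[AcceptanceEnvelope]:
    """Build acceptance envelopes from the range of study measurements.

    Per dose group and analyte the envelope is the across-animal min/max
    at each sample time, widened multiplicatively by ``margin`` (and by
    ±margin absolute for near-zero values so fully-depleted phases do
    not impose measure-zero bands).
    """
    out = []
    df = dataset.data
    for (group, analyte), sub in df[df["analyte"].isin(analytes)].groupby(
        ["dose_group", "analyte"]
    ):
        g = sub.groupby("time_day")["value"]
        lo, hi = g.min(), g.max()
        times = lo.index.to_numpy(float)
        scale = max(float(hi.max()), 1e-9)
        slack = 1e-3 * scale
        out.append(
            AcceptanceEnvelope(
                analyte=str(analyte),
                dose_group=float(group),
                times=times,
                lower=np.maximum(lo.to_numpy() / margin - slack, 0.0),
                upper=hi.to_numpy() * margin + slack,
                threshold=threshold,
            )
        )
    return out


@dataclass
class VirtualSubject:
    parameters: SubjectParameters
    accepted: bool
    record: dict  # per-envelope fraction inside, or failure cause
    lineage: dict  # reference id + perturbation seed


def accept_subject(
    candidate: SubjectParameters,
    envelopes: Sequence[AcceptanceEnvelope],
    regimens: dict[float, Regimen],
    forcings: dict[float, PKForcing],
    t_end: float = 35.0,
    settings: SolverSettings = SolverSettings(rtol=1e-6),
    drug: str = "mosunetuzumab",
) -> tuple[bool, dict]:
    """All-or-nothing acceptance of one candidate against every envelope.

    Simulation failure rejects with the cause logged rather than
    raising: a parameter draw that the solver cannot integrate is not a
    plausible subject.
    """
    groups = sorted({e.dose_group for e in envelopes})
    trajs = {}
    for g in groups:
        if g not in regimens:
            raise KeyError(f"no regimen provided for dose group {g}")
        try:
            trajs[g] = simulate(
                candidate, regimens[g], forcings[g], t_end=t_end,
                settings=settings, drug=drug,
                extra_times=np.unique(np.concatenate(
                    [e.times for e in envelopes if e.dose_group == g]
                )),
            )
        except SimulationError as e:
            return False, {"failure": f"group {g}: {e}"}
    record = {}
    ok = True
    for env in envelopes:
        frac = env.fraction_inside(trajs[env.dose_group])
        record[f"{env.analyte}@{env.dose_group}"] = frac
        ok = ok and frac >= env.threshold
    return ok, record


def generate_cohort(
    reference: SubjectParameters,
    perturbation: PerturbationSpec,
    envelopes: Sequence[AcceptanceEnvelope],
    regimens: dict[float, Regimen],
    forcings: dict[float, PKForcing],
    n_target: int,
    max_draws: int = 1000,
    seed: int = 0,
    t_end: float = 35.0,
    settings: SolverSettings = SolverSettings(rtol=1e-6),
    drug: str = "mosunetuzumab",
    validation: Optional[tuple[Sequence[AcceptanceEnvelope], dict, dict]] = None,
) -> tuple[list[VirtualSubject], dict]:
    """Random-search virtual cohort with envelope acceptance.

    Draws candidates around the reference until ``n_target`` accepted or
    ``max_draws`` exhausted. Each candidate's RNG derives from
    ``SeedSequence(seed).spawn`` keyed by draw index, so any accepted
    subject can be regenerated from its recorded lineage.

    ``validation`` optionally holds (envelopes, regimens, forcings) of a
    held-out regimen never used for acceptance; coverage against it is
    reported in the summary.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    root = np.random.SeedSequence(seed)
    accepted: list[VirtualSubject] = []
    n_draws = 0
    n_failures = 0
    while len(accepted) < n_target and n_draws < max_draws:
        child = np.random.SeedSequence(entropy=seed, spawn_key=(n_draws,))
        rng = np.random.default_rng(child)
        try:
            cand = sample_candidate(
                reference, perturbation, rng, subject_id=f"{reference.subject_id}_vc{n_draws}"
            )
        except ValueError:
            n_draws += 1
            n_failures += 1
            continue
        ok, record = accept_subject(
            cand, envelopes, regimens, forcings, t_end=t_end, settings=settings, drug=drug
        )
        if "failure" in record:
            n_failures += 1
        if ok:
            accepted.append(
                VirtualSubject(
                    parameters=cand,
                    accepted=True,
                    record=record,
                    lineage={"reference": reference.subject_id, "seed": seed, "draw": n_draws},
                )
            )
        n_draws += 1
    if not accepted:
        raise RuntimeError(
            f"no candidates accepted in {n_draws} draws; widen the envelopes "
            "or narrow the perturbation fold-ranges"
        )
    summary = {
        "n_accepted": len(accepted),
        "n_draws": n_draws,
        "n_sim_failures": n_failures,
        "acceptance_rate": len(accepted) / n_draws,
        "seed": seed,
    }
    if validation is not None:
        venv, vreg, vforce = validation
        cov = []
        for vs in accepted:
            okv, rec = accept_subject(
                vs.parameters, venv, vreg, vforce, t_end=t_end, settings=settings, drug=drug
            )
            cov.append(okv)
        summary["validation_pass_fraction"] = float(np.mean(cov))
    return accepted, summary


# --- translation and the NHL population -------------------------------


def translate_to_human(
    subject: SubjectParameters,
    human_physiology: Physiology,
    subject_id: Optional[str] = None,
) -> SubjectParameters:
    """Swap in human compartment volumes and baseline cell numbers.

    Dimensionless and per-cell kinetic parameters are preserved; the
    baseline cell concentrations of the translated subject match the
    target physiology exactly by construction. PK clearance scaling is
    handled by the PK layer (allometric defaults per species).
    """
    for c in subject.physiology.compartments:
        if c != TU and c not in human_physiology.volumes:
            raise ValueError(f"human physiology lacks compartment {c}")
    return subject.model_copy(
        update={
            "physiology": human_physiology,
            "subject_id": subject_id or f"{subject.subject_id}_hu",
        }
    )


@dataclass(frozen=True)
class NHLTumorParams:
    """Disease-specific tumor variability of one NHL virtual patient."""

    burden: float  # cells
    doubling_time: float  # day
    bt_ratio: float  # tumor B : resident T, >> 1 for B-cell dense mass
    t_access: float  # fraction of PB-exiting activated T entering the tumor
    cells_per_liter: float = 1e12

    def __post_init__(self):
        for f in ("burden", "doubling_time", "bt_ratio", "t_access"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be > 0")


@dataclass(frozen=True)
class TumorVariabilitySpec:
    """Log-uniform sampling ranges for NHL disease variability."""

    burden: tuple[float, float] = (1e9, 1e11)
    doubling_time: tuple[float, float] = (20.0, 100.0)
    bt_ratio: tuple[float, float] = (1e5, 1e7)
    t_access: tuple[float, float] = (1e-6, 1e-4)
    baseline_fold: float = 3.0  # PB B and T baseline jitter

    def sample(self, rng: np.random.Generator) -> NHLTumorParams:
        def logu(lo, hi):
            return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

        return NHLTumorParams(
            burden=logu(*self.burden),
            doubling_time=logu(*self.doubling_time),
            bt_ratio=logu(*self.bt_ratio),
            t_access=logu(*self.t_access),
        )


def apply_tumor(
    subject: SubjectParameters,
    tumor: NHLTumorParams,
    baseline_factors: Optional[dict[str, float]] = None,
    tumor_partition: float = 0.35,
    subject_id: Optional[str] = None,
) -> SubjectParameters:
    """Add a B-cell-dense nodal tumor compartment to a human subject.

    Only activated T cells infiltrate the tumor (fraction ``t_access``
    of their PB exit flux); resting and post-activated partitioning is
    unchanged. ``baseline_factors`` optionally rescales PB baselines
    (disease-related variability).
    """
    phys = subject.physiology
    if TU in phys.volumes:
        raise ValueError("subject already has a tumor compartment")
    vol = dict(phys.volumes)
    vol[TU] = max(tumor.burden / tumor.cells_per_liter, 1e-5)
    t_base = dict(phys.t_baseline)
    b_base = dict(phys.b_baseline)
    if baseline_factors:
        t_base[PB] = t_base[PB] * baseline_factors.get("t_pb", 1.0)
        b_base[PB] = b_base[PB] * baseline_factors.get("b_pb", 1.0)
    t_base[TU] = tumor.burden / tumor.bt_ratio
    b_base[TU] = 0.0
    part = dict(phys.partition)
    part[TU] = tumor_partition
    new_phys = Physiology(
        species=phys.species + "_nhl",
        volumes=vol,
        serum_volume=phys.serum_volume,
        t_baseline=t_base,
        b_baseline=b_base,
        prob_baseline=phys.prob_baseline,
        tumor_baseline=tumor.burden,
        partition=part,
    )
    pf = {s: dict(d) for s, d in subject.tcell.partition_frac.items()}
    act = pf.get("activated", {})
    total = sum(act.values()) or 1.0
    pf["activated"] = {k: v * (1.0 - tumor.t_access) / total for k, v in act.items()}
    pf["activated"][TU] = tumor.t_access
    tcell = subject.tcell.model_copy(update={"partition_frac": pf})
    bcell = subject.bcell.model_copy(update={"tumor_doubling_time": tumor.doubling_time})
    return subject.model_copy(
        update={
            "physiology": new_phys,
            "tcell": tcell,
            "bcell": bcell,
            "subject_id": subject_id or f"{subject.subject_id}_tu",
        }
    )


@dataclass
class VirtualPopulation:
    """Weighted NHL virtual patients with matching diagnostics."""

    subjects: list[SubjectParameters]
    weights: np.ndarray
    pct_change: np.ndarray  # end-of-treatment % tumor change per subject
    diagnostics: dict
    n_candidates: int

    def __post_init__(self):
        w = np.asarray(self.weights, float)
        if np.any(w < 0):
            raise ValueError("weights must be >= 0")
        s = w.sum()
        if s <= 0:
            raise ValueError("weights must not all vanish")
        object.__setattr__(self, "weights", w / s)

    def __len__(self) -> int:
        return len(self.subjects)

    def weighted_quantile(self, values: np.ndarray, q) -> np.ndarray:
        return weighted_quantile(values, self.weights, q)

    def waterfall(self) -> np.ndarray:
        return np.sort(self.pct_change)[::-1]

    def responder_fraction(self) -> float:
        return float(np.sum(self.weights[self.pct_change <= -50.0]))

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for subj, w, pc in zip(self.subjects, self.weights, self.pct_change):
                fh.write(
                    json.dumps(
                        {"weight": float(w), "pct_change": float(pc),
                         "parameters": subj.model_dump()}
                    )
                    + "\n"
                )


def weighted_quantile(values, weights, q) -> np.ndarray:
    """Quantiles of a weighted sample (inverse weighted CDF, midpoint)."""
    v = np.asarray(values, float)
    w = np.asarray(weights, float)
    order = np.argsort(v)
    v, w = v[order], w[order]
    cdf = np.cumsum(w) - 0.5 * w
    cdf /= w.sum()
    return np.interp(np.atleast_1d(q), cdf, v)


def match_weights_to_waterfall(
    pct_change: np.ndarray,
    targets: ClinicalTargets,
    n_bins: int = 6,
) -> tuple[np.ndarray, dict]:
    """Importance weights so the weighted % change matches the target.

    The target waterfall is split into ``n_bins`` equal-probability bins
    (complete responses at -100 form their own bin); candidates in each
    bin share that bin's target mass equally. Raises if any non-empty
    target bin has no candidate.
    """
    pct = np.asarray(pct_change, float)
    target = targets.waterfall
    cr_mass = float(np.mean(target <= -99.5))
    rest = target[target > -99.5]
    edges = [-np.inf, -99.5]
    if rest.size:
        qs = np.linspace(0, 1, n_bins)[1:-1]
        inner = np.quantile(rest, qs)
        # the responder cut is always an edge so the weighted responder
        # fraction matches the target exactly up to empty-bin effects;
        # quantile edges close to it are dropped to avoid sliver bins
        inner = inner[np.abs(inner - (-50.0)) > 5.0]
        inner = np.concatenate([inner, [-50.0]])
        inner = inner[(inner > -99.5)]
        edges += list(np.unique(inner)) + [np.inf]
    else:
        edges += [np.inf]
    edges = np.array(edges)
    masses = np.empty(len(edges) - 1)
    masses[0] = cr_mass
    for k in range(1, len(edges) - 1):
        masses[k] = np.mean((target > edges[k]) & (target <= edges[k + 1]))
    masses = masses / masses.sum()

    weights = np.zeros(pct.size)
    empty = []
    for k in range(len(edges) - 1):
        if masses[k] <= 0:
            continue
        sel = (pct > edges[k]) & (pct <= edges[k + 1])
        if not np.any(sel):
            empty.append((float(edges[k]), float(edges[k + 1]), float(masses[k])))
            continue
        weights[sel] = masses[k] / sel.sum()
    if empty:
        raise RuntimeError(
            "no candidates available for target waterfall bins "
            f"{[(lo, hi) for lo, hi, _ in empty]}; enlarge the candidate set "
            "or widen disease variability"
        )
    weights /= weights.sum()
    diag = {
        "bin_edges": edges.tolist(),
        "target_masses": masses.tolist(),
        "achieved_masses": [
            float(weights[(pct > edges[k]) & (pct <= edges[k + 1])].sum())
            for k in range(len(edges) - 1)
        ],
    }
    return weights, diag


def build_nhl_population(
    cohort: Sequence[VirtualSubject],
    human_physiology: Physiology,
    tumor_spec: TumorVariabilitySpec,
    targets: ClinicalTargets,
    regimen: Regimen,
    n_out: int,
    seed: int = 0,
    pk_params: Optional[TwoCompartmentPKParams] = None,
    settings: SolverSettings = SolverSettings(rtol=1e-6),
    t_end: Optional[float] = None,
    max_failure_fraction: float = 0.2,
) -> VirtualPopulation:
    """Cross the healthy cohort with tumor variability and weight-match.

    Each candidate patient is a cohort member translated to human
    physiology, given sampled tumor/disease parameters, and simulated
    under the reference blinatumomab regimen; importance weights then
    match the end-of-treatment % tumor change distribution to the
    clinical target waterfall. Candidates whose simulation fails are
    dropped (counted in diagnostics; more than ``max_failure_fraction``
    aborts).
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    if targets.waterfall.size == 0:
        raise ValueError("targets must be non-empty")
    pk_params = pk_params or pk_defaults(regimen.drug, "human")
    forcing = TwoCompartmentForcing(pk_params, regimen)
    horizon = t_end if t_end is not None else regimen.end_time()

    subjects: list[SubjectParameters] = []
    changes: list[float] = []
    n_failed = 0
    for i in range(n_out):
        child = np.random.SeedSequence(entropy=seed, spawn_key=(i,))
        rng = np.random.default_rng(child)
        member = cohort[i % len(cohort)].parameters
        human = translate_to_human(member, human_physiology, subject_id=f"pt{i}")
        tumor = tumor_spec.sample(rng)
        factors = {
            "t_pb": tumor_spec.baseline_fold ** rng.uniform(-1, 1),
            "b_pb": tumor_spec.baseline_fold ** rng.uniform(-1, 1),
        }
        patient = apply_tumor(human, tumor, baseline_factors=factors, subject_id=f"pt{i}")
        try:
            traj = simulate(
                patient, regimen, forcing, t_end=horizon, settings=settings,
                drug=regimen.drug, extra_times=[horizon],
            )
        except SimulationError:
            n_failed += 1
            continue
        tum = traj.tumor_cells()
        change = 100.0 * (tum[-1] - tum[0]) / tum[0]
        if tum[-1] < 1e-3 * tum[0] / 100.0:  # below detection: complete response
            change = -100.0
        subjects.append(patient)
        changes.append(float(max(change, -100.0)))
    if n_failed > max_failure_fraction * n_out:
        raise RuntimeError(f"{n_failed}/{n_out} patient simulations failed")

    pct = np.array(changes)
    # adaptive binning: coarsen when a sliver bin catches no candidate;
    # genuinely infeasible matching still raises (at the coarsest bins)
    last_err = None
    for bins in (6, 5, 4, 3):
        try:
            weights, diag = match_weights_to_waterfall(pct, targets, n_bins=bins)
            break
        except RuntimeError as e:
            last_err = e
    else:
        raise last_err
    diag.update(
        {
            "n_candidates": n_out,
            "n_simulated": len(subjects),
            "n_failed": n_failed,
            "seed": seed,
            "regimen": regimen.label,
            "target_responder_fraction": targets.responder_fraction,
            "achieved_responder_fraction": float(weights[pct <= -50.0].sum()),
        }
    )
    return VirtualPopulation(
        subjects=subjects,
        weights=weights,
        pct_change=pct,
        diagnostics=diag,
        n_candidates=n_out,
    )
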