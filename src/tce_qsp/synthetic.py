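"""Synthetic stand-in datasets with the statistical structure of the
study inputs.

Everything downstream (calibration, cohort acceptance, population
matching) is exercised against data produced here: a multi-dose cyno
study with per-animal parameter jitter, measurement noise and
ADA-driven exposure loss, and clinical NHL targets (a waterfall of
end-of-treatment tumor changes plus IL6 envelope curves).

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import SolverSettings, Trajectory, simulate
from .params import SubjectParameters
from .pk import (
    Regimen,
    SampledPK,
    TwoCompartmentForcing,
    TwoCompartmentPKParams,
    build_regimen,
    pk_from_samples,
)
from .reference import CYNO_BSA_M2, CYNO_WEIGHT_KG, mosunetuzumab_pk_cyno

ANALYTES = ("CD8_count", "pct_CD69", "B_count", "IL6", "BT_ratio_tissue")
UNITS = {
    "CD8_count": "cells/uL",
    "pct_CD69": "%",
    "B_count": "cells/uL",
    "IL6": "pg/mL",
    "BT_ratio_tissue": "ratio",
}

# ADA incidence per ascending weekly dose group (fraction of animals)
ADA_INCIDENCE = {0.01: 1.0, 0.1: 0.5, 1.0: 0.25}

# parameters jittered across animals (multiplicative lognormal)
ANIMAL_JITTER_PATHS = (
    "drugs.mosunetuzumab.vmax_max",
    "drugs.mosunetuzumab.k_kill",
    "tcell.k_prol",
    "tcell.pb_exit.activated",
    "tcell.stress_amplitude",
    "cytokine.k_prod",
)


@dataclass
class PDDataset:
    """Tabular pharmacodynamic observations plus study metadata."""

    data: pd.DataFrame  # subject_id, time_day, compartment, analyte, value, units, dose_group, ada
    study: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        required = {"subject_id", "time_day", "compartment", "analyte", "value", "units"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"PDDataset missing columns {sorted(missing)}")
        if (self.data["value"] < 0).any():
            raise ValueError("PD values must be >= 0")

    def to_csv(self, path, manifest_path=None) -> None:
        self.data.to_csv(path, index=False)
        if manifest_path is not None:
            with open(manifest_path, "w") as fh:
                json.dump({"study": self.study, **self.metadata}, fh, indent=2, default=str)

    def subset(self, **filters) -> pd.DataFrame:
        df = self.data
        for col, val in filters.items():
            df = df[df[col] == val]
        return df


@dataclass
class ClinicalTargets:
    """Clinical matching targets for the NHL virtual population."""

    waterfall: np.ndarray  # per-patient % change at end of treatment, sorted desc
    il6_envelopes: dict[str, pd.DataFrame] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        w = np.sort(np.asarray(self.waterfall, float))[::-1]
        if np.any(w < -100):
            raise ValueError("% change cannot fall below -100")
        object.__setattr__(self, "waterfall", w)
        for name, env in self.il6_envelopes.items():
            if not {"time_day", "p5", "p50", "p95"} <= set(env.columns):
                raise ValueError(f"envelope {name!r} needs time_day/p5/p50/p95")
            if ((env["p5"] > env["p50"]) | (env["p50"] > env["p95"])).any():
                raise ValueError(f"envelope {name!r} percentiles must be ordered")

    @property
    def responder_fraction(self) -> float:
        return float(np.mean(self.waterfall <= -50.0))


def lognormal_factor(rng: np.random.Generator, cv: float, size=None) -> np.ndarray | float:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


def generate_ada_pk(
    pk_params: TwoCompartmentPKParams,
    regimen: Regimen,
    sample_times: Sequence[float],
    ada: bool = False,
    ada_onset_day: float = 7.0,
    clearance_multiplier: float = 10.0,
    subject_id: str = "animal",
) -> SampledPK:
    """Two-compartment PK profile with optional ADA clearance step-up.

    From ``ada_onset_day`` on, clearance is multiplied by
    ``clearance_multiplier`` (>1: antidrug antibodies accelerate
    elimination), reproducing the loss of exposure from the second dose
    on. The piecewise-linear system is integrated numerically with
    bolus doses applied as amount jumps in the central compartment.
    """
    if ada_onset_day < 0:
        raise ValueError("ada_onset_day must be >= 0")
    if clearance_multiplier < 1:
        raise ValueError("ADA accelerates clearance: multiplier must be >= 1")
    times = np.asarray(sorted(sample_times), float)

    def cl_at(t: float) -> float:
        if ada and t >= ada_onset_day:
            return pk_params.cl * clearance_multiplier
        return pk_params.cl

    def rhs(t, a):
        rate = 0.0
        for e in regimen.events:
            if e.route == "infusion" and e.time <= t < e.time + float(e.duration):
                rate += regimen.infusion_rate_mg_per_day(e)
        k10 = cl_at(t) / pk_params.v1
        k12 = pk_params.q / pk_params.v1
        k21 = pk_params.q / pk_params.v2
        return [rate - (k10 + k12) * a[0] + k21 * a[1], k12 * a[0] - k21 * a[1]]

    breaks = {0.0, float(times[-1])}
    breaks.update(e.time for e in regimen.events)
    breaks.update(e.time + float(e.duration) for e in regimen.events if e.route == "infusion")
    if ada:
        breaks.add(float(ada_onset_day))
    seg = sorted(b for b in breaks if b <= times[-1])
    if seg[-1] < times[-1]:
        seg.append(float(times[-1]))

    a = np.zeros(2)
    bolus_by_time: dict[float, float] = {}
    for e in regimen.events:
        if e.route == "bolus":
            bolus_by_time[e.time] = bolus_by_time.get(e.time, 0.0) + regimen.dose_mg(e)
    conc_at: dict[float, float] = {}
    # samples falling exactly on a dose time are pre-dose (troughs)
    if times[0] == seg[0]:
        conc_at[float(times[0])] = a[0] / pk_params.v1 * 1e3
    for lo, hi in zip(seg[:-1], seg[1:]):
        if lo in bolus_by_time:
            a[0] += bolus_by_time[lo]
        t_eval = times[(times > lo) & (times <= hi)]
        sol = solve_ivp(
            rhs,
            (lo, hi),
            a,
            method="LSODA",
            rtol=1e-10,
            atol=1e-12,
            t_eval=np.unique(np.concatenate([t_eval, [hi]])),
        )
        if not sol.success:
            raise RuntimeError(f"PK integration failed: {sol.message}")
        for tt, aa in zip(sol.t, sol.y[0]):
            if np.isin(tt, t_eval):
                conc_at[float(tt)] = aa / pk_params.v1 * 1e3  # mg/L -> ng/mL
        a = sol.y[:, -1]
    tt = np.array(sorted(conc_at))
    return SampledPK(subject_id=subject_id, times=tt, conc=np.array([conc_at[x] for x in tt]))


def cyno_pd_sample_times(n_doses: int = 4, t_end: float = 35.0) -> np.ndarray:
    """Realistic PD sampling: pre-dose, 2/6/24 h post each dose, then twice weekly."""
    pts = [0.0]
    for i in range(n_doses):
        td = 7.0 * i
        pts += [td + 2 / 24, td + 6 / 24, td + 1.0]
    pts += list(np.arange(3.5, t_end + 1e-9, 3.5))
    return np.unique(np.round(np.array(pts), 6))


def pk_sample_times(n_doses: int = 4, t_end: float = 35.0) -> np.ndarray:
    pts = []
    for i in range(n_doses):
        td = 7.0 * i
        pts += [td, td + 1 / 24, td + 2 / 24, td + 6 / 24, td + 1.0, td + 2.0, td + 4.0]
    pts += list(np.arange(0.0, t_end + 1e-9, 1.0))
    return np.unique(np.round(np.array(pts), 6))


def generate_cyno_study(
    generator_subject: SubjectParameters,
    doses: Sequence[float] = (0.01, 0.1, 1.0),
    n_per_group: int = 4,
    noise_cv: float = 0.25,
    jitter_cv: float = 0.15,
    seed: int = 0,
    t_end: float = 35.0,
    necropsy_day: float = 28.0,
    pk_params: Optional[TwoCompartmentPKParams] = None,
    ada_clearance_multiplier: float = 10.0,
    settings: SolverSettings = SolverSettings(rtol=1e-6),
) -> tuple[PDDataset, dict[str, SampledPK]]:
    """Emulate the multi-dose cyno study (weekly x4 dosing, 3 dose groups).

    Each animal is the generator subject with lognormal parameter
    jitter, simulated under its own (possibly ADA-affected) PK trace
    used as a forcing function, sampled on a realistic schedule, with
    multiplicative lognormal measurement noise. ADA+ animals per group
    follow the published incidence (4/4, 2/4, 1/4 at 0.01/0.1/1 mg/kg
    for n=4). Tissue B:T ratios are collected at necropsy, 7 days after
    the last dose. ``noise_cv = jitter_cv = 0`` reproduces the generator
    trajectory exactly.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    pk_params = pk_params or mosunetuzumab_pk_cyno()
    n_doses = int(min(4, t_end // 7 + 1))
    pd_times = cyno_pd_sample_times(n_doses=n_doses, t_end=t_end)
    pk_times = pk_sample_times(n_doses=n_doses, t_end=t_end)

    rows = []
    pk_traces: dict[str, SampledPK] = {}
    for dose in doses:
        regimen = build_regimen(
            "cyno_weeklyx4",
            body_weight_kg=CYNO_WEIGHT_KG,
            body_surface_m2=CYNO_BSA_M2,
            dose_mg_per_kg=dose,
        )
        if regimen.events[-1].time > t_end:  # shortened study window
            regimen = regimen.model_copy(
                update={"events": tuple(e for e in regimen.events if e.time <= t_end)}
            )
        frac = ADA_INCIDENCE.get(dose, 0.0)
        n_ada = int(round(frac * n_per_group))
        for k in range(n_per_group):
            sid = f"g{dose}_a{k}"
            ada = k < n_ada
            trace = generate_ada_pk(
                pk_params,
                regimen,
                pk_times,
                ada=ada,
                clearance_multiplier=ada_clearance_multiplier,
                subject_id=sid,
            )
            pk_traces[sid] = trace
            subj = generator_subject
            if jitter_cv > 0:
                subj = subj.replace(
                    {
                        p: generator_subject.get(p) * lognormal_factor(rng, jitter_cv)
                        for p in ANIMAL_JITTER_PATHS
                    }
                )
            else:
                rng.bit_generator.advance(0)  # keep stream layout explicit
            traj = simulate(
                subj.with_id(sid),
                regimen,
                pk_from_samples(trace),
                t_end=t_end,
                settings=settings,
                extra_times=pd_times,
                drug=regimen.drug,
            )
            rows.append(_sample_animal(traj, sid, dose, ada, pd_times, necropsy_day, noise_cv, rng))
    data = pd.concat(rows, ignore_index=True)
    meta = {
        "seed": seed,
        "doses_mg_per_kg": list(doses),
        "n_per_group": n_per_group,
        "noise_cv": noise_cv,
        "jitter_cv": jitter_cv,
        "t_end": t_end,
        "necropsy_day": necropsy_day,
        "ada_clearance_multiplier": ada_clearance_multiplier,
        "generator_subject": generator_subject.subject_id,
        "schema_version": 1,
    }
    return PDDataset(data=data, study="synthetic_cyno_multidose", metadata=meta), pk_traces


def _sample_animal(
    traj: Trajectory,
    sid: str,
    dose: float,
    ada: bool,
    pd_times: np.ndarray,
    necropsy_day: float,
    noise_cv: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    recs = []
    for analyte in ("CD8_count", "pct_CD69", "B_count", "IL6"):
        series = traj.observable(analyte)
        vals = np.interp(pd_times, traj.time, series)
        noisy = vals * lognormal_factor(rng, noise_cv, size=vals.size)
        for t, v in zip(pd_times, noisy):
            recs.append((sid, t, "PB" if analyte != "IL6" else "serum", analyte, max(v, 0.0), UNITS[analyte], dose, ada))
    for comp in ("SP", "LN"):
        bt = traj.value_at(traj.tissue_bt_ratio(comp), necropsy_day)
        bt = bt * lognormal_factor(rng, noise_cv)
        recs.append((sid, necropsy_day, comp, "BT_ratio_tissue", max(bt, 0.0), UNITS["BT_ratio_tissue"], dose, ada))
    return pd.DataFrame(
        recs,
        columns=["subject_id", "time_day", "compartment", "analyte", "value", "units", "dose_group", "ada"],
    )


DEFAULT_RESPONSE_MIX = {
    # component -> (weight, % change range); CR pinned at -100
    "complete_response": (0.17, (-100.0, -100.0)),
    "deep_partial": (0.20, (-99.0, -50.0)),
    "minor_or_stable": (0.23, (-50.0, 0.0)),
    "progression": (0.40, (0.0, 150.0)),
}


def generate_nhl_targets(
    n_patients: int = 18,
    response_mix: Optional[dict] = None,
    seed: int = 0,
    il6_envelopes: Optional[dict[str, pd.DataFrame]] = None,
) -> ClinicalTargets:
    """Synthetic clinical targets: waterfall spanning PD to CR.

    Per-patient end-of-treatment % tumor change is drawn from a mixture
    of response categories (defaults give ~37% of patients a >50%
    reduction). IL6 envelope curves can be attached (typically built by
    simulating a seed population; see the population module).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    mix = response_mix or DEFAULT_RESPONSE_MIX
    weights = np.array([w for w, _ in mix.values()], float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("response_mix weights must sum to 1")
    rng = np.random.default_rng(seed)
    comps = list(mix.values())
    idx = rng.choice(len(comps), size=n_patients, p=weights)
    lo = np.array([comps[i][1][0] for i in idx])
    hi = np.array([comps[i][1][1] for i in idx])
    changes = lo + (hi - lo) * rng.random(n_patients)
    return ClinicalTargets(
        waterfall=changes,
        il6_envelopes=il6_envelopes or {},
        metadata={"seed": seed, "n_patients": n_patients, "mix": {k: v[0] for k, v in mix.items()}},
    )
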