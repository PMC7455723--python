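"""End-to-end study workflows at desk scale.

These functions chain the pipeline stages — synthetic study, reference
calibration, virtual cohort, NHL population, regimen endpoints — with
the package's default study conditions. The analysis drivers, the test
suite and the acceptance script all run the same code paths; only
problem sizes differ (documented per function).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .calibration import (
    CalibrationSpec,
    FreeParameter,
    FitResult,
    calibrate_reference,
    problem_from_study,
)
from .metrics import RegimenMetrics, simulate_population
from .model import SolverSettings, simulate
from .pk import Regimen, build_regimen
from .population import (
    PerturbationSpec,
    TumorVariabilitySpec,
    VirtualPopulation,
    VirtualSubject,
    build_nhl_population,
    envelopes_from_study,
    generate_cohort,
    weighted_quantile,
)
from .reference import human_physiology, reference_cyno
from .synthetic import generate_cyno_study, generate_nhl_targets

FAST = SolverSettings(rtol=1e-6)

#: default free parameters for the reference-cyno fit
DEFAULT_FREE = [
    FreeParameter("drugs.mosunetuzumab.vmax_max", 10.0, 1000.0),
    FreeParameter("drugs.mosunetuzumab.ec50_act", 500.0, 50000.0),
]


def calibrate_reference_cyno(
    seed: int,
    noise_cv: float = 0.0,
    free: Optional[list[FreeParameter]] = None,
    start_factor: float = 1.7,
    max_nfev: int = 25,
    t_end: float = 14.0,
) -> tuple[FitResult, "object"]:
    """Calibrate the reference virtual cyno to a synthetic multi-dose study.

    The study uses the three dose groups (0.01/0.1/1 mg/kg weekly) with
    the stated ADA incidence; the fit starts ``start_factor``-fold away
    from the generating values. Returns the fit and the bound problem.
    Desk scale: a 2-dose (14-day) window keeps the fit under two
    minutes on one CPU.
    """
    generator = reference_cyno()
    dataset, traces = generate_cyno_study(
        generator, noise_cv=noise_cv, jitter_cv=0.0, seed=seed, t_end=t_end,
    )
    problem = problem_from_study(dataset, traces, t_end=t_end)
    free = free or DEFAULT_FREE
    start = {f.path: generator.get(f.path) * start_factor for f in free}
    spec = CalibrationSpec(free=free, n_starts=1, max_nfev=max_nfev, seed=seed, x0=start)
    fit = calibrate_reference(problem, spec, base=generator.replace(start))
    return fit, problem


def first_dose_il6_peak_times(
    subject, problem, window_days: float = 2.0
) -> dict[float, float]:
    """Hours to the serum IL6 peak within the first-dose window, per group."""
    out = {}
    for group, regimen in problem.regimens.items():
        traj = simulate(
            subject, regimen, problem.forcings[group], t_end=problem.t_end,
            settings=problem.settings, drug=problem.drug,
        )
        m = traj.time <= window_days
        il6 = traj.il6()[m]
        out[group] = float(traj.time[m][np.argmax(il6)] * 24.0)
    return out


@dataclass
class PopulationWorkflowResult:
    cohort: list[VirtualSubject]
    cohort_summary: dict
    population: VirtualPopulation


def build_nhl_population_workflow(
    seed: int,
    n_cohort: int = 10,
    n_patients: int = 200,
    max_draws: int = 150,
    envelope_margin: float = 2.0,
    study_seed: Optional[int] = None,
) -> PopulationWorkflowResult:
    """Reference cyno -> virtual cohort -> weighted NHL population.

    Desk scale: a 10-member cohort crossed with sampled tumor
    variability into 200 virtual patients (the full-size study uses the
    same path with a larger cohort and 4500 patients).
    """
    generator = reference_cyno()
    dataset, traces = generate_cyno_study(generator, seed=study_seed or seed)
    problem = problem_from_study(dataset, traces)
    envelopes = envelopes_from_study(dataset, margin=envelope_margin)
    cohort, summary = generate_cohort(
        generator, PerturbationSpec(), envelopes, problem.regimens,
        problem.forcings, n_target=n_cohort, max_draws=max_draws, seed=seed,
    )
    targets = generate_nhl_targets(seed=seed)
    regimen = build_regimen("blin_dlbcl_8wk")
    population = build_nhl_population(
        cohort, human_physiology(), TumorVariabilitySpec(), targets, regimen,
        n_out=n_patients, seed=seed,
    )
    return PopulationWorkflowResult(cohort, summary, population)


WEEKLY_WINDOWS_3WK = [(0.0, 7.0), (7.0, 14.0), (14.0, 21.0)]
#: flat-infusion windows: the first-peak window vs everything later
FLAT60_WINDOWS = [(0.0, 2.0), (2.0, 7.0), (7.0, 14.0), (14.0, 21.0)]


def stepup_il6_peak_time(
    population: VirtualPopulation,
) -> tuple[float, list[RegimenMetrics], np.ndarray]:
    """Weighted median time (h) to the global serum IL6 peak under the
    5/15/60 ug/m2/day step-up infusion."""
    regimen = build_regimen("blin_stepup_5_15_60")
    metrics, w, _ = simulate_population(
        population, regimen, t_end=21.0, windows=WEEKLY_WINDOWS_3WK, settings=FAST,
    )
    times = np.array([m.il6_global_peak_time_h for m in metrics])
    median = float(weighted_quantile(times, w, 0.5)[0])
    return median, metrics, w


def flat60_first_peak_ratio(
    population: VirtualPopulation,
) -> tuple[float, list[RegimenMetrics], np.ndarray]:
    """Weighted median ratio of the first IL6 peak to the largest later
    peak under the constant 60 ug/m2/day infusion."""
    regimen = build_regimen("blin_flat_60")
    metrics, w, _ = simulate_population(
        population, regimen, t_end=21.0, windows=FLAT60_WINDOWS, settings=FAST,
    )
    ratios = np.array(
        [m.first_il6_peak / max(m.max_subsequent_il6_peak, 1e-9) for m in metrics]
    )
    median = float(weighted_quantile(ratios, w, 0.5)[0])
    return median, metrics, w


MOSUN_REGIMENS = (
    "nonfractionated_20",
    "flat_6.7x3",
    "double_step_1.6_10_10",
    "single_step_1.6_20",
)


def mosun_regimen_comparison(population: VirtualPopulation, **kw):
    from .metrics import compare_regimens

    regimens = [build_regimen(t) for t in MOSUN_REGIMENS]
    return compare_regimens(population, regimens, **kw)
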