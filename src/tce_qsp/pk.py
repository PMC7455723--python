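"""Drug-concentration forcing functions.

Pharmacokinetics enter the lymphocyte model purely as a forcing: a
plasma-concentration function of time. Two sources are supported,

* :func:`pk_from_samples` — interpolation of measured (or emulated)
  concentration samples, the mode used for preclinical calibration, and
* :class:`TwoCompartmentPKParams` — an analytic linear two-compartment
  model with IV-bolus and zero-order-infusion administration and
  allometric clearance scaling, the mode used for clinical projection.

Concentrations are ng/mL, amounts mg, time days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

DoseUnit = Literal["mg", "mg_per_kg", "ug_per_m2_per_day"]
Route = Literal["bolus", "infusion"]


class DoseEvent(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    time: float  # day
    amount: float  # in `unit`
    unit: DoseUnit = "mg"
    route: Route = "bolus"
    duration: Optional[float] = None  # day, infusions only

    @model_validator(mode="after")
    def _check(self) -> "DoseEvent":
        if self.time < 0:
            raise ValueError("dose time must be >= 0")
        if self.amount <= 0:
            raise ValueError("dose amount must be > 0")
        if self.route == "infusion":
            if self.duration is None or self.duration <= 0:
                raise ValueError("infusions need duration > 0")
        elif self.duration is not None:
            raise ValueError("duration applies to infusions only")
        if self.unit == "ug_per_m2_per_day" and self.route != "infusion":
            raise ValueError("ug/m2/day dosing is an infusion rate")
        return self


class Regimen(BaseModel):
    """An ordered dose schedule plus the body size used to normalize it."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    label: str
    drug: str
    events: tuple[DoseEvent, ...]
    body_weight_kg: float = 70.0
    body_surface_m2: float = 1.8

    @model_validator(mode="after")
    def _check(self) -> "Regimen":
        if self.body_weight_kg <= 0 or self.body_surface_m2 <= 0:
            raise ValueError("body size must be > 0")
        times = [e.time for e in self.events]
        if times != sorted(times):
            raise ValueError("dose events must be time-sorted")
        end = -math.inf
        for e in self.events:
            if e.route == "infusion":
                if e.time < end - 1e-12:
                    raise ValueError("overlapping infusions are not allowed")
                end = e.time + (e.duration or 0.0)
        return self

    @property
    def dose_times(self) -> tuple[float, ...]:
        return tuple(e.time for e in self.events)

    def dose_mg(self, event: DoseEvent) -> float:
        """Total administered amount of an event in mg."""
        if event.unit == "mg":
            return event.amount
        if event.unit == "mg_per_kg":
            return event.amount * self.body_weight_kg
        # ug/m2/day infusion rate -> mg over the infusion
        return event.amount * self.body_surface_m2 * (event.duration or 0.0) / 1000.0

    def infusion_rate_mg_per_day(self, event: DoseEvent) -> float:
        if event.route != "infusion":
            raise ValueError("not an infusion event")
        return self.dose_mg(event) / (event.duration or 1.0)

    def end_time(self) -> float:
        return max(
            (e.time + (e.duration or 0.0) for e in self.events), default=0.0
        )


def allometric_clearance(cl_ref: float, w_ref: float, w: float, exponent: float = 0.75) -> float:
    """Scale a reference clearance to body weight ``w`` by a power law."""
    if w_ref <= 0 or w <= 0:
        raise ValueError("body weights must be > 0")
    return cl_ref * (w / w_ref) ** exponent


class TwoCompartmentPKParams(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    v1: float  # central volume, L
    v2: float  # peripheral volume, L
    cl: float  # clearance, L/day
    q: float  # inter-compartment clearance, L/day
    ref_weight_kg: float = 70.0

    @model_validator(mode="after")
    def _check(self) -> "TwoCompartmentPKParams":
        for f in ("v1", "v2", "cl", "q", "ref_weight_kg"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be > 0")
        return self

    def scaled_to(self, weight_kg: float, cl_exponent: float = 0.75) -> "TwoCompartmentPKParams":
        """Allometric rescaling: CL, Q with exponent 0.75; volumes linearly."""
        r = weight_kg / self.ref_weight_kg
        return TwoCompartmentPKParams(
            v1=self.v1 * r,
            v2=self.v2 * r,
            cl=allometric_clearance(self.cl, self.ref_weight_kg, weight_kg, cl_exponent),
            q=allometric_clearance(self.q, self.ref_weight_kg, weight_kg, cl_exponent),
            ref_weight_kg=weight_kg,
        )

    def hybrid_constants(self) -> tuple[float, float, float]:
        """Macro rate constants (alpha, beta, k21) of the bi-exponential."""
        k10 = self.cl / self.v1
        k12 = self.q / self.v1
        k21 = self.q / self.v2
        s = k10 + k12 + k21
        disc = math.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
        alpha = 0.5 * (s + disc)
        beta = 0.5 * (s - disc)
        return alpha, beta, k21


def _bolus_profile(p: TwoCompartmentPKParams, dose_mg: float, dt: np.ndarray) -> np.ndarray:
    """Central concentration (ng/mL) after an IV bolus, for dt >= 0."""
    alpha, beta, k21 = p.hybrid_constants()
    ca = (alpha - k21) / (alpha - beta)
    cb = (k21 - beta) / (alpha - beta)
    conc_mg_per_l = dose_mg / p.v1 * (ca * np.exp(-alpha * dt) + cb * np.exp(-beta * dt))
    return conc_mg_per_l * 1e3  # mg/L -> ng/mL


def _infusion_profile(
    p: TwoCompartmentPKParams, rate_mg_day: float, duration: float, dt: np.ndarray
) -> np.ndarray:
    """Central concentration (ng/mL) for a zero-order infusion started at dt=0."""
    alpha, beta, k21 = p.hybrid_constants()
    ca = (alpha - k21) / (alpha - beta) / alpha
    cb = (k21 - beta) / (alpha - beta) / beta
    te = np.minimum(dt, duration)  # infusion exposure time
    tp = dt - te  # time since infusion end (0 while running)
    conc_mg_per_l = (
        rate_mg_day
        / p.v1
        * (
            ca * (1.0 - np.exp(-alpha * te)) * np.exp(-alpha * tp)
            + cb * (1.0 - np.exp(-beta * te)) * np.exp(-beta * tp)
        )
    )
    return conc_mg_per_l * 1e3


def two_compartment_concentration(
    params: TwoCompartmentPKParams, regimen: Regimen, t: float | np.ndarray
) -> np.ndarray | float:
    """Superposed central concentration of all regimen events at time(s) t."""
    tt = np.asarray(t, dtype=float)
    out = np.zeros_like(tt)
    for e in regimen.events:
        dt = tt - e.time
        mask = dt >= 0
        if not np.any(mask):
            continue
        if e.route == "bolus":
            out[mask] += _bolus_profile(params, regimen.dose_mg(e), dt[mask])
        else:
            out[mask] += _infusion_profile(
                params, regimen.infusion_rate_mg_per_day(e), float(e.duration), dt[mask]
            )
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SampledPK:
    """Measured concentration samples of one subject."""

    subject_id: str
    times: np.ndarray  # day
    conc: np.ndarray  # ng/mL
    bql: np.ndarray = field(default=None)  # below-quantification flags

    def __post_init__(self):
        t = np.asarray(self.times, float)
        c = np.asarray(self.conc, float)
        if t.ndim != 1 or t.shape != c.shape:
            raise ValueError("times and conc must be 1-D and congruent")
        if np.any(np.diff(t) < 0):
            raise ValueError("sample times must be sorted")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")
        b = np.zeros(t.shape, bool) if self.bql is None else np.asarray(self.bql, bool)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "conc", c)
        object.__setattr__(self, "bql", b)


class PKForcing:
    """Interface consumed by the simulator: conc(t) plus breakpoints.

    Breakpoints are times where the forcing is non-smooth (dose events,
    infusion ends, sample knots); the integrator restarts there.
    """

    breakpoints: tuple[float, ...] = ()

    def conc(self, t: float) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def conc_array(self, t: np.ndarray) -> np.ndarray:
        return np.array([self.conc(x) for x in np.asarray(t, float)])


class ZeroForcing(PKForcing):
    """No drug (placebo / drug-free runs)."""

    def conc(self, t: float) -> float:
        return 0.0

    def conc_array(self, t: np.ndarray) -> np.ndarray:
        return np.zeros_like(np.asarray(t, float))


class TwoCompartmentForcing(PKForcing):
    def __init__(self, params: TwoCompartmentPKParams, regimen: Regimen):
        self.params = params
        self.regimen = regimen
        bp = set()
        for e in regimen.events:
            bp.add(e.time)
            if e.route == "infusion":
                bp.add(e.time + float(e.duration))
        self.breakpoints = tuple(sorted(bp))

    def conc(self, t: float) -> float:
        return float(two_compartment_concentration(self.params, self.regimen, t))

    def conc_array(self, t: np.ndarray) -> np.ndarray:
        return np.asarray(two_compartment_concentration(self.params, self.regimen, t))


class InterpolatedForcing(PKForcing):
    """Piecewise log-linear interpolation of measured PK samples.

    Positive neighbouring samples are interpolated log-linearly (mono-
    exponential segments); segments touching a zero are linear. Before
    the first sample the first value is held; after the last sample the
    profile is extrapolated log-linearly with the terminal slope of the
    last two positive samples (flat if that slope is nonnegative or
    undefined).
    """

    def __init__(self, samples: SampledPK):
        if samples.times.size < 2:
            raise ValueError("need at least 2 PK samples")
        self.samples = samples
        self.breakpoints = tuple(np.unique(samples.times))
        t, c = samples.times, samples.conc
        pos = c > 0
        self._term_slope = 0.0
        if pos.sum() >= 2:
            ip = np.where(pos)[0][-2:]
            # only use as terminal slope when they are the last two samples
            if ip[1] == t.size - 1 and t[ip[1]] > t[ip[0]]:
                sl = (math.log(c[ip[1]]) - math.log(c[ip[0]])) / (t[ip[1]] - t[ip[0]])
                self._term_slope = min(sl, 0.0)

    def conc(self, t: float) -> float:
        return float(self.conc_array(np.array([t]))[0])

    def conc_array(self, t: np.ndarray) -> np.ndarray:
        tt = np.asarray(t, float)
        ts, cs = self.samples.times, self.samples.conc
        out = np.empty_like(tt)
        for i, x in enumerate(tt.ravel()):
            if x <= ts[0]:
                out.flat[i] = cs[0]
            elif x >= ts[-1]:
                out.flat[i] = cs[-1] * math.exp(self._term_slope * (x - ts[-1]))
            else:
                j = int(np.searchsorted(ts, x, side="right")) - 1
                j = min(j, ts.size - 2)
                t0, t1, c0, c1 = ts[j], ts[j + 1], cs[j], cs[j + 1]
                if t1 == t0:
                    out.flat[i] = c1
                elif c0 > 0 and c1 > 0:
                    w = (x - t0) / (t1 - t0)
                    out.flat[i] = math.exp((1 - w) * math.log(c0) + w * math.log(c1))
                else:
                    out.flat[i] = c0 + (c1 - c0) * (x - t0) / (t1 - t0)
        return out


def pk_from_samples(samples: SampledPK) -> InterpolatedForcing:
    """Build the measured-PK forcing function used for calibration."""
    return InterpolatedForcing(samples)


# --- regimen templates -------------------------------------------------

MOSUN_MAINTENANCE_MG = 20.0
_CYCLE = 21.0


def _mosun_cycle1(doses: Sequence[tuple[float, float]], n_cycles: int = 4) -> list[DoseEvent]:
    events = [DoseEvent(time=t, amount=a, unit="mg", route="bolus") for t, a in doses]
    for c in range(1, n_cycles):
        events.append(
            DoseEvent(time=c * _CYCLE, amount=MOSUN_MAINTENANCE_MG, unit="mg", route="bolus")
        )
    return events


def build_regimen(
    template: str,
    body_weight_kg: float = 70.0,
    body_surface_m2: float = 1.8,
    dose_mg_per_kg: Optional[float] = None,
) -> Regimen:
    """Named clinical/preclinical schedules.

    Mosunetuzumab regimens span 4 cycles of 21 days with 20 mg from
    Cycle 2 on; blinatumomab cytokine regimens are 3-week continuous
    infusions; ``cyno_weeklyx4`` takes the per-dose level in mg/kg.
    """
    kw = dict(body_weight_kg=body_weight_kg, body_surface_m2=body_surface_m2)
    if template == "nonfractionated_20":
        ev = _mosun_cycle1([(0.0, 20.0)])
    elif template == "flat_6.7x3":
        ev = _mosun_cycle1([(0.0, 6.7), (7.0, 6.7), (14.0, 6.7)])
    elif template == "double_step_1.6_10_10":
        ev = _mosun_cycle1([(0.0, 1.6), (7.0, 10.0), (14.0, 10.0)])
    elif template == "single_step_1.6_20":
        ev = _mosun_cycle1([(0.0, 1.6), (7.0, 20.0)])
    elif template == "blin_stepup_5_15_60":
        ev = [
            DoseEvent(time=0.0, amount=5.0, unit="ug_per_m2_per_day", route="infusion", duration=7.0),
            DoseEvent(time=7.0, amount=15.0, unit="ug_per_m2_per_day", route="infusion", duration=7.0),
            DoseEvent(time=14.0, amount=60.0, unit="ug_per_m2_per_day", route="infusion", duration=7.0),
        ]
    elif template == "blin_flat_60":
        ev = [
            DoseEvent(time=0.0, amount=60.0, unit="ug_per_m2_per_day", route="infusion", duration=21.0),
        ]
    elif template == "blin_dlbcl_8wk":
        # 8-week continuous step-up infusion used as the DLBCL efficacy
        # reference; dose levels are a configurable package default.
        ev = [
            DoseEvent(time=0.0, amount=9.0, unit="ug_per_m2_per_day", route="infusion", duration=7.0),
            DoseEvent(time=7.0, amount=28.0, unit="ug_per_m2_per_day", route="infusion", duration=7.0),
            DoseEvent(time=14.0, amount=112.0, unit="ug_per_m2_per_day", route="infusion", duration=42.0),
        ]
    elif template == "cyno_weeklyx4":
        if dose_mg_per_kg is None:
            raise ValueError("cyno_weeklyx4 needs dose_mg_per_kg")
        ev = [
            DoseEvent(time=7.0 * i, amount=dose_mg_per_kg, unit="mg_per_kg", route="bolus")
            for i in range(4)
        ]
    else:
        known = (
            "nonfractionated_20, flat_6.7x3, double_step_1.6_10_10, single_step_1.6_20, "
            "blin_stepup_5_15_60, blin_flat_60, blin_dlbcl_8wk, cyno_weeklyx4"
        )
        raise ValueError(f"unknown regimen template {template!r}; options: {known}")
    drug = "blinatumomab" if template.startswith("blin") else "mosunetuzumab"
    return Regimen(label=template, drug=drug, events=tuple(ev), **kw)
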