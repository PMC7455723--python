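"""Compartmental ODE model of bispecific T-cell-engager pharmacodynamics.

State per compartment (PB, spleen, lymph node, bone marrow, optional
tumor): resting/activated/post-activated CD8+ T cells and CD19+CD20+ B
cells; additionally CD19+CD20- pro-B cells in the BM, tumor B cells in
the tumor, and one serum IL6 state. Drug concentration is an external
forcing (see :mod:`tce_qsp.pk`); tissue levels follow the plasma level
through fixed partition coefficients.

Mechanisms:

* drug- and B:T-ratio-dependent T-cell activation (Michaelis–Menten in
  concentration, Vmax saturating in the local target-B:T ratio);
* proliferation of activated cells into activated and post-activated
  progeny; deactivation; post-activated conversion to resting;
  activation-related apoptosis;
* subset-specific PB<->tissue trafficking, with PB exit transiently
  amplified after every administration (injection stress) and faster
  exit / stronger tissue partitioning for activated cells;
* deficit-gated homeostatic fluxes: thymic generation of resting PB T
  cells, excess apoptosis of resting T cells, BM->PB B migration,
  PB->tissue B replenishment, and normal-tissue B proliferation — all
  exactly zero at baseline;
* BM B-lineage production (pro-B generation, maturation, homeostatic
  apoptosis) and constitutive exponential tumor growth;
* killing of target B cells by activated T cells, and IL6 production
  proportional to the activation signal times activated-cell numbers,
  with tissue-derived IL6 down-weighted by ``f_tiss``.

Every mechanism can be switched off individually (``disabled=...``),
which the test suite uses to check each flux against closed forms.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import BM, PB, TU, DrugParams, SubjectParameters
from .pk import PKForcing, Regimen, ZeroForcing

MECHANISMS = frozenset(
    {
        "activation",
        "reactivation",
        "proliferation",
        "deactivation",
        "post_to_rest",
        "act_apoptosis",
        "thymus",
        "excess_apoptosis",
        "t_trafficking",
        "b_production",
        "b_migration",
        "b_replenish",
        "b_deficit_prolif",
        "killing",
        "tumor_growth",
        "il6_production",
        "stress",
    }
)


class ConfigurationError(ValueError):
    """Raised when subject parameters admit no nonnegative equilibrium."""


class SimulationError(RuntimeError):
    """Raised when integration fails or produces invalid states."""


def activation_signal(
    conc: float, target_b: float, total_t: float, drug: DrugParams
) -> float:
    """T-cell activation rate (1/day) from drug level and cell context.

    ``Vmax(r) * conc / (EC50 + conc)`` with ``r = target_B / total_T``
    and ``Vmax(r) = Vmax_max * r / (K_BT + r)``. Zero without drug or
    without target cells; saturates at ``Vmax_max`` when target cells
    are present but T cells are vanishingly few (r -> inf).
    """
    if conc < 0 or target_b < 0 or total_t < 0:
        raise ValueError("activation_signal inputs must be >= 0")
    if conc == 0.0 or target_b == 0.0:
        return 0.0
    if total_t == 0.0:
        vmax = drug.vmax_max  # r -> infinity: saturated
    else:
        r = target_b / total_t
        vmax = drug.vmax_max * r / (drug.k_bt + r)
    return vmax * conc / (drug.ec50_act + conc)


def killing_rate(
    conc: float, ta: float, targets: float, vol: float, drug: DrugParams
) -> float:
    """Target-cell kill flux (cells/day) by activated T cells.

    Per-capita kill scales with the activated-T concentration (Ta/vol)
    so potency is independent of compartment size.
    """
    if min(conc, ta, targets) < 0 or vol <= 0:
        raise ValueError("killing_rate needs nonnegative inputs and vol > 0")
    if conc == 0.0 or ta == 0.0 or targets == 0.0:
        return 0.0
    return drug.k_kill * conc / (drug.ec50_kill + conc) * (ta / vol) * targets


@dataclass(frozen=True)
class SolverSettings:
    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-3  # cells
    base_dt: float = 0.25  # day, coarse output spacing
    dense_dt: float = 1.0 / 48.0  # 0.5 h spacing after each dose
    dense_window: float = 2.0  # days of dense output per dose
    neg_tol: float = 1e-9  # relative nonnegativity tolerance


class StateLayout:
    """Index bookkeeping for the flat state vector."""

    def __init__(self, subject: SubjectParameters):
        phys = subject.physiology
        self.comps: tuple[str, ...] = phys.compartments
        self.n = len(self.comps)
        self.idx = {c: i for i, c in enumerate(self.comps)}
        base = 4 * self.n
        self.i_prob = base if BM in self.idx else None
        base += 1 if self.i_prob is not None else 0
        self.i_tum = base if TU in self.idx else None
        base += 1 if self.i_tum is not None else 0
        self.i_il6 = base
        self.size = base + 1

    def tr(self, y: np.ndarray) -> np.ndarray:
        return y[0 : self.n]

    def ta(self, y: np.ndarray) -> np.ndarray:
        return y[self.n : 2 * self.n]

    def tp(self, y: np.ndarray) -> np.ndarray:
        return y[2 * self.n : 3 * self.n]

    def b(self, y: np.ndarray) -> np.ndarray:
        return y[3 * self.n : 4 * self.n]


class Model:
    """Compiled right-hand side for one subject and one drug."""

    def __init__(
        self,
        subject: SubjectParameters,
        drug: str | DrugParams,
        disabled: Iterable[str] = (),
    ):
        self.subject = subject
        self.drug = subject.drugs[drug] if isinstance(drug, str) else drug
        self.disabled = frozenset(disabled)
        unknown = self.disabled - MECHANISMS
        if unknown:
            raise ValueError(f"unknown mechanism switches: {sorted(unknown)}")
        self.layout = StateLayout(subject)
        self._compile()

    def on(self, mech: str) -> bool:
        return mech not in self.disabled

    # --- derived, baseline-consistent quantities ----------------------

    def _compile(self) -> None:
        lay, phys = self.layout, self.subject.physiology
        tc, bc = self.subject.tcell, self.subject.bcell
        cs = lay.comps
        self.vol = np.array([phys.volumes[c] for c in cs])
        self.tr0 = np.array([phys.tbase(c) for c in cs])
        self.b0 = np.array([phys.bbase(c) for c in cs])
        self.i_pb = lay.idx[PB]
        self.i_bm = lay.idx.get(BM)
        self.i_tu = lay.idx.get(TU)
        self.tissue_ix = np.array([i for i, c in enumerate(cs) if c != PB], dtype=int)
        # drug tissue:plasma partition, PB slot = 1
        self.kpart = np.ones(lay.n)
        for i, c in enumerate(cs):
            if c != PB:
                self.kpart[i] = phys.partition.get(c, 1.0)

        # subset partition fractions over the tissues actually present
        def fracs(subset: str) -> np.ndarray:
            raw = tc.partition_frac.get(subset, {})
            v = np.zeros(lay.n)
            for i in self.tissue_ix:
                v[i] = raw.get(cs[i], 0.0)
            s = v.sum()
            return v / s if s > 0 else v

        self.frac = {s: fracs(s) for s in ("resting", "activated", "post")}
        self.k_exit = {s: tc.pb_exit[s] for s in ("resting", "activated", "post")}
        # resting return rates derived from the pre-therapy balance:
        # k_exit_r * f_c * Tr_PB0 = k_ret_c * Tr_c0  (exact equilibrium)
        kr = np.zeros(lay.n)
        out_pb_r = self.k_exit["resting"] * self.tr0[self.i_pb]
        for i in self.tissue_ix:
            inflow = out_pb_r * self.frac["resting"][i]
            if inflow > 0 and self.tr0[i] <= 0:
                raise ConfigurationError(
                    f"resting T cells traffic into {cs[i]} but its baseline is 0: "
                    "no nonnegative equilibrium (resting trafficking balance)"
                )
            kr[i] = inflow / self.tr0[i] if self.tr0[i] > 0 else 0.0
        self.k_ret_resting = kr
        self.k_ret = {
            "activated": tc.tissue_return["activated"],
            "post": tc.tissue_return["post"],
        }
        # full per-compartment return-rate vectors (PB slot = 0)
        self.k_ret_arr = {"resting": kr}
        for s in ("activated", "post"):
            v = np.zeros(lay.n)
            v[self.tissue_ix] = self.k_ret[s]
            self.k_ret_arr[s] = v

        # BM B-lineage production rates, derived unless supplied
        pb0 = phys.prob_baseline
        bbm0 = self.b0[self.i_bm] if self.i_bm is not None else 0.0
        gen = bc.k_maturation * pb0
        if bc.k_gen_prob is not None:
            if not np.isclose(bc.k_gen_prob, gen, rtol=1e-6, atol=1e-9):
                raise ConfigurationError(
                    "pro-B generation vs. maturation balance violated: "
                    f"k_gen_prob={bc.k_gen_prob} but k_maturation*pB0={gen}"
                )
            gen = bc.k_gen_prob
        self.k_gen_prob = gen
        if gen > 0 and (self.i_bm is None or bbm0 <= 0):
            raise ConfigurationError(
                "pro-B maturation feeds BM B cells but BM B baseline is 0: "
                "no nonnegative equilibrium (BM B balance)"
            )
        apop = gen / bbm0 if bbm0 > 0 else 0.0
        if bc.k_bm_apop is not None:
            if not np.isclose(bc.k_bm_apop, apop, rtol=1e-6, atol=1e-12):
                raise ConfigurationError(
                    "BM B apoptosis vs. maturation inflow balance violated: "
                    f"k_bm_apop={bc.k_bm_apop} but required {apop}"
                )
            apop = bc.k_bm_apop
        self.k_bm_apop = apop
        # PB->tissue replenishment shares (spleen/LN only), by baseline size
        w = np.zeros(lay.n)
        for i in self.tissue_ix:
            if cs[i] in ("SP", "LN"):
                w[i] = self.b0[i]
        self.repl_share = w / w.sum() if w.sum() > 0 else w

        self.tum0 = phys.tumor_baseline or 0.0
        dt_tum = bc.tumor_doubling_time
        self.k_tum = np.log(2.0) / dt_tum if dt_tum else 0.0
        self.serum_ml = phys.serum_volume * 1e3

    # --- pieces --------------------------------------------------------

    def activation_targets(self, b: np.ndarray, prob: float, btum: float) -> np.ndarray:
        """Per-compartment target-B pool for the bound drug."""
        tgt = b.copy()
        if self.drug.target == "CD19" and self.i_bm is not None:
            tgt[self.i_bm] += prob
        if self.i_tu is not None:
            tgt[self.i_tu] += btum  # tumor B are CD19+CD20+
        return tgt

    def stress_factor(self, t: float, dose_times: Sequence[float]) -> float:
        if not self.on("stress"):
            return 1.0
        tc = self.subject.tcell
        if tc.stress_amplitude == 0.0:
            return 1.0
        acc = 0.0
        for td in dose_times:
            dt = t - td
            if 0.0 <= dt < 40.0 * tc.stress_tau:
                acc += math.exp(-dt / tc.stress_tau)
        return 1.0 + tc.stress_amplitude * acc

    def baseline_state(self) -> np.ndarray:
        lay = self.layout
        y = np.zeros(lay.size)
        y[0 : lay.n] = self.tr0
        y[3 * lay.n : 4 * lay.n] = self.b0
        if lay.i_prob is not None:
            y[lay.i_prob] = self.subject.physiology.prob_baseline
        if lay.i_tum is not None:
            y[lay.i_tum] = self.tum0
        y[lay.i_il6] = self.subject.cytokine.baseline
        return y

    def il6_production(self, conc: np.ndarray, sig: np.ndarray, ta: np.ndarray) -> float:
        """Whole-body IL6 production rate (pg/day) entering the serum.

        PB production counts fully; tissue production enters the blood
        with fractional contribution f_tiss.
        """
        cy = self.subject.cytokine
        s = sig * ta
        p = s[self.i_pb] + cy.f_tiss * s[self.tissue_ix].sum()
        return cy.k_prod * p

    # --- right-hand side ----------------------------------------------

    def _activation_vec(self, conc: np.ndarray, tgt: np.ndarray, ttot: np.ndarray) -> np.ndarray:
        """Vectorized per-compartment activation signal (see activation_signal)."""
        d = self.drug
        r = tgt / np.maximum(ttot, 1e-30)  # ttot=0 with targets: r huge, Vmax saturates
        vmax = d.vmax_max * r / (d.k_bt + r)
        sig = vmax * conc / (d.ec50_act + conc)
        sig[(conc <= 0.0) | (tgt <= 0.0)] = 0.0
        return sig

    def rhs(self, t: float, y: np.ndarray, forcing: PKForcing, dose_times: Sequence[float]) -> np.ndarray:
        lay = self.layout
        tc, bc, cy = self.subject.tcell, self.subject.bcell, self.subject.cytokine
        yc = np.maximum(y, 0.0)  # clamp for ratio/flux computation only
        tr, ta, tp, b = lay.tr(yc), lay.ta(yc), lay.tp(yc), lay.b(yc)
        prob = yc[lay.i_prob] if lay.i_prob is not None else 0.0
        btum = yc[lay.i_tum] if lay.i_tum is not None else 0.0
        il6 = yc[lay.i_il6]

        conc = self.kpart * max(forcing.conc(t), 0.0)
        ttot = tr + ta + tp
        tgt = self.activation_targets(b, prob, btum)

        dtr = np.zeros(lay.n)
        dta = np.zeros(lay.n)
        dtp = np.zeros(lay.n)
        db = np.zeros(lay.n)
        dprob = 0.0
        dtum = 0.0

        # activation signal per compartment (also drives IL6)
        sig = np.zeros(lay.n)
        if self.on("activation"):
            sig = self._activation_vec(conc, tgt, ttot)
            dtr -= sig * tr
            dta += sig * tr
            if tc.reactivation and self.on("reactivation"):
                dtp -= sig * tp
                dta += sig * tp

        if self.on("proliferation"):
            dta += tc.k_prol * tc.phi * ta
            dtp += tc.k_prol * (1.0 - tc.phi) * ta
        if self.on("deactivation"):
            dta -= (tc.k_deact_rest + tc.k_deact_post) * ta
            dtr += tc.k_deact_rest * ta
            dtp += tc.k_deact_post * ta
        if self.on("post_to_rest"):
            dtp -= tc.k_post_to_rest * tp
            dtr += tc.k_post_to_rest * tp
        if self.on("act_apoptosis"):
            dta -= tc.k_adeath_act * ta
            dtp -= tc.k_adeath_post * tp

        if self.on("thymus"):
            t0 = self.tr0[self.i_pb]
            if t0 > 0:
                deficit = max(0.0, 1.0 - tr[self.i_pb] / t0)
                dtr[self.i_pb] += tc.k_thymus * deficit
        if self.on("excess_apoptosis") and tc.k_excess_apop > 0:
            excess = np.where(
                self.tr0 > 0,
                np.maximum(tr / np.maximum(self.tr0, 1e-300) - 1.0, 0.0),
                1.0,
            )
            dtr -= tc.k_excess_apop * tr * excess

        if self.on("t_trafficking"):
            stress = self.stress_factor(t, dose_times)
            for subset, pool, dpool in (
                ("resting", tr, dtr),
                ("activated", ta, dta),
                ("post", tp, dtp),
            ):
                out = self.k_exit[subset] * stress * pool[self.i_pb]
                dpool[self.i_pb] -= out
                dpool += out * self.frac[subset]
                ret = self.k_ret_arr[subset] * pool
                dpool -= ret
                dpool[self.i_pb] += ret.sum()

        # --- B lineage ---
        if self.on("b_production") and lay.i_prob is not None:
            dprob += self.k_gen_prob - bc.k_maturation * prob
            db[self.i_bm] += bc.k_maturation * prob - self.k_bm_apop * b[self.i_bm]
        if self.on("b_migration") and self.i_bm is not None:
            b0pb = self.b0[self.i_pb]
            if b0pb > 0:
                mig = bc.k_bm_to_pb * b[self.i_bm] * max(0.0, 1.0 - b[self.i_pb] / b0pb)
                db[self.i_bm] -= mig
                db[self.i_pb] += mig
        b_deficit = np.where(
            self.b0 > 0, np.maximum(1.0 - b / np.maximum(self.b0, 1e-300), 0.0), 0.0
        )
        if self.on("b_replenish") and bc.k_pb_to_tissue > 0:
            fl = bc.k_pb_to_tissue * b[self.i_pb] * self.repl_share * b_deficit
            db += fl
            db[self.i_pb] -= fl.sum()
        if self.on("b_deficit_prolif") and bc.k_deficit_prolif > 0:
            db += bc.k_deficit_prolif * b * b_deficit

        if self.on("tumor_growth") and lay.i_tum is not None:
            dtum += self.k_tum * btum

        if self.on("killing"):
            d = self.drug
            kfac = d.k_kill * conc / (d.ec50_kill + conc) * (ta / self.vol)
            db -= kfac * b
            if d.target == "CD19" and lay.i_prob is not None:
                dprob -= kfac[self.i_bm] * prob
            if lay.i_tum is not None:
                dtum -= kfac[self.i_tu] * btum

        dil6 = 0.0
        if self.on("il6_production"):
            p = self.il6_production(conc, sig, ta)
            dil6 += p / self.serum_ml
        dil6 += cy.k_el * (cy.baseline - il6)

        dy = np.empty(lay.size)
        dy[0 : lay.n] = dtr
        dy[lay.n : 2 * lay.n] = dta
        dy[2 * lay.n : 3 * lay.n] = dtp
        dy[3 * lay.n : 4 * lay.n] = db
        if lay.i_prob is not None:
            dy[lay.i_prob] = dprob
        if lay.i_tum is not None:
            dy[lay.i_tum] = dtum
        dy[lay.i_il6] = dil6
        return dy


def initialize_baseline(subject: SubjectParameters, drug: Optional[str] = None) -> np.ndarray:
    """Homeostatic (pre-therapy) state vector.

    By construction every restoring flux is zero at baseline, so this
    state is an exact drug-free equilibrium of every normal pool; only
    the tumor (when present) departs from it, growing exponentially.
    Raises :class:`ConfigurationError` when the parameters admit no
    nonnegative equilibrium.
    """
    drug = drug or next(iter(subject.drugs))
    return Model(subject, drug).baseline_state()


@dataclass
class Trajectory:
    """Solved time courses plus derived observables."""

    time: np.ndarray  # day
    states: np.ndarray  # (n_t, n_states)
    subject: SubjectParameters
    drug: str
    regimen_label: str
    dose_times: tuple[float, ...]
    layout: StateLayout = field(repr=False, default=None)

    def __post_init__(self):
        if self.layout is None:
            self.layout = StateLayout(self.subject)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("trajectory time grid must be strictly increasing")

    # -- derived observables (all recomputable from states + physiology) --

    def _pb(self, block) -> np.ndarray:
        return block[:, self.layout.idx[PB]]

    @property
    def pb_ul(self) -> float:
        return self.subject.physiology.volumes[PB] * 1e6  # L -> uL

    @property
    def tr(self) -> np.ndarray:
        n = self.layout.n
        return self.states[:, 0:n]

    @property
    def ta(self) -> np.ndarray:
        n = self.layout.n
        return self.states[:, n : 2 * n]

    @property
    def tp(self) -> np.ndarray:
        n = self.layout.n
        return self.states[:, 2 * n : 3 * n]

    @property
    def b(self) -> np.ndarray:
        n = self.layout.n
        return self.states[:, 3 * n : 4 * n]

    def pb_cd8_per_ul(self) -> np.ndarray:
        tot = self._pb(self.tr) + self._pb(self.ta) + self._pb(self.tp)
        return tot / self.pb_ul

    def pct_cd69(self) -> np.ndarray:
        tot = self._pb(self.tr) + self._pb(self.ta) + self._pb(self.tp)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(tot > 0, 100.0 * self._pb(self.ta) / tot, 0.0)
        return out

    def pb_b_per_ul(self) -> np.ndarray:
        return self._pb(self.b) / self.pb_ul

    def il6(self) -> np.ndarray:
        return self.states[:, self.layout.i_il6]

    def tumor_cells(self) -> np.ndarray:
        if self.layout.i_tum is None:
            raise ValueError("no tumor compartment in this subject")
        return self.states[:, self.layout.i_tum]

    def tumor_pct_change(self) -> np.ndarray:
        tum = self.tumor_cells()
        return 100.0 * (tum - tum[0]) / tum[0]

    def tissue_bt_ratio(self, comp: str) -> np.ndarray:
        i = self.layout.idx[comp]
        t = self.tr[:, i] + self.ta[:, i] + self.tp[:, i]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(t > 0, self.b[:, i] / t, np.inf)

    def value_at(self, series: np.ndarray, t: float) -> float:
        return float(np.interp(t, self.time, series))

    def observable(self, analyte: str) -> np.ndarray:
        table = {
            "CD8_count": self.pb_cd8_per_ul,
            "pct_CD69": self.pct_cd69,
            "B_count": self.pb_b_per_ul,
            "IL6": self.il6,
        }
        if analyte not in table:
            raise KeyError(f"unknown analyte {analyte!r}")
        return table[analyte]()

    def to_frame(self) -> pd.DataFrame:
        """Long-format export (time_day, compartment, variable, value, units)."""
        rows = []
        lay = self.layout
        for j, c in enumerate(lay.comps):
            for name, block, unit in (
                ("T_resting", self.tr, "cells"),
                ("T_activated", self.ta, "cells"),
                ("T_post", self.tp, "cells"),
                ("B", self.b, "cells"),
            ):
                rows.append(
                    pd.DataFrame(
                        {
                            "time_day": self.time,
                            "compartment": c,
                            "variable": name,
                            "value": block[:, j],
                            "units": unit,
                        }
                    )
                )
        if lay.i_prob is not None:
            rows.append(
                pd.DataFrame(
                    {
                        "time_day": self.time,
                        "compartment": BM,
                        "variable": "proB",
                        "value": self.states[:, lay.i_prob],
                        "units": "cells",
                    }
                )
            )
        if lay.i_tum is not None:
            rows.append(
                pd.DataFrame(
                    {
                        "time_day": self.time,
                        "compartment": TU,
                        "variable": "B_tumor",
                        "value": self.states[:, lay.i_tum],
                        "units": "cells",
                    }
                )
            )
        rows.append(
            pd.DataFrame(
                {
                    "time_day": self.time,
                    "compartment": "serum",
                    "variable": "IL6",
                    "value": self.il6(),
                    "units": "pg/mL",
                }
            )
        )
        return pd.concat(rows, ignore_index=True)

    def metadata(self) -> dict:
        return {
            "subject_id": self.subject.subject_id,
            "drug": self.drug,
            "regimen": self.regimen_label,
            "dose_times": list(self.dose_times),
        }

    def export(self, csv_path, meta_path=None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if meta_path is not None:
            with open(meta_path, "w") as fh:
                json.dump(self.metadata(), fh, indent=2)


def _output_grid(
    t_end: float, dose_times: Sequence[float], settings: SolverSettings
) -> np.ndarray:
    pts = [np.arange(0.0, t_end + 1e-12, settings.base_dt)]
    for td in dose_times:
        hi = min(td + settings.dense_window, t_end)
        pts.append(np.arange(td, hi + 1e-12, settings.dense_dt))
    grid = np.unique(np.concatenate(pts + [np.array([t_end])]))
    return grid[(grid >= 0) & (grid <= t_end + 1e-12)]


def simulate(
    subject: SubjectParameters,
    regimen: Optional[Regimen],
    forcing: Optional[PKForcing] = None,
    t_end: float = None,
    settings: SolverSettings = SolverSettings(),
    disabled: Iterable[str] = (),
    drug: Optional[str] = None,
    extra_times: Sequence[float] = (),
) -> Trajectory:
    """Integrate the model under a regimen and PK forcing.

    ``regimen`` provides the dose times (integration restart points and
    injection-stress triggers); ``forcing`` provides the plasma drug
    concentration (defaults to zero — placebo). The output grid has
    0.5-h resolution for 48 h after every dose so IL6 peaks are
    resolved, plus any ``extra_times``.
    """
    if regimen is None and drug is None:
        drug = next(iter(subject.drugs))
    drug = drug or regimen.drug
    forcing = forcing or ZeroForcing()
    dose_times = regimen.dose_times if regimen is not None else ()
    if t_end is None:
        t_end = (max(dose_times) + 21.0) if dose_times else 21.0
    for td in dose_times:
        if td > t_end:
            raise ValueError("regimen events must lie within [0, t_end]")

    model = Model(subject, drug, disabled=disabled)
    y0 = model.baseline_state()
    grid = _output_grid(t_end, dose_times, settings)
    grid = np.unique(np.concatenate([grid, np.asarray(extra_times, float)]))
    grid = grid[(grid >= 0) & (grid <= t_end + 1e-9)]

    # integration segments: dose times and forcing breakpoints restart
    breaks = {0.0, float(t_end)}
    breaks.update(float(td) for td in dose_times)
    breaks.update(float(x) for x in forcing.breakpoints if 0.0 < x < t_end)
    seg = sorted(breaks)

    times_out = [np.array([grid[0]])] if grid[0] == 0.0 else []
    states_out = [y0[None, :]] if grid[0] == 0.0 else []
    y = y0.copy()
    for a, b in zip(seg[:-1], seg[1:]):
        if b - a <= 1e-12:
            continue
        t_eval = np.unique(np.concatenate([grid[(grid > a) & (grid < b)], [b]]))
        sol = None
        for method in (settings.method, "BDF", "Radau"):
            sol = solve_ivp(
                model.rhs,
                (a, b),
                y,
                method=method,
                rtol=settings.rtol,
                atol=settings.atol,
                t_eval=t_eval if t_eval.size else None,
                args=(forcing, dose_times),
                dense_output=False,
            )
            if sol.success:
                break
        if not sol.success:
            raise SimulationError(
                f"solver failed in [{a}, {b}] at t={sol.t[-1] if sol.t.size else a}: "
                f"{sol.message}"
            )
        if t_eval.size:
            times_out.append(sol.t)
            states_out.append(sol.y.T)
        y = sol.y[:, -1] if sol.y.size else y

    time = np.concatenate(times_out)
    states = np.concatenate(states_out, axis=0)
    # de-duplicate any repeated boundary points
    keep = np.concatenate([[True], np.diff(time) > 1e-12])
    time, states = time[keep], states[keep]

    scale = max(y0.max(), 1.0)
    worst = states.min()
    if worst < -settings.neg_tol * scale:
        i, j = np.unravel_index(np.argmin(states), states.shape)
        raise SimulationError(
            f"negative state {states[i, j]:.3g} (state {j}) at t={time[i]:.3f} d "
            "exceeds the nonnegativity tolerance"
        )
    states = np.maximum(states, 0.0)

    return Trajectory(
        time=time,
        states=states,
        subject=subject,
        drug=drug,
        regimen_label=regimen.label if regimen is not None else "none",
        dose_times=tuple(dose_times),
        layout=model.layout,
    )
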