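"""Typed parameter containers for virtual subjects.

A virtual subject (cyno or patient) is fully described by a
:class:`SubjectParameters` object: physiology (compartment volumes and
baseline cell numbers), T-cell kinetics, B-cell kinetics, the IL6 module,
and one :class:`DrugParams` block per drug the subject can receive.

Units used throughout the package:

* time — days
* cell pools — absolute cell counts per compartment
* cell observables — cells/uL (converted with the blood volume)
* drug concentration — ng/mL
* IL6 — pg/mL
* volumes — L
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

# Canonical compartment labels: peripheral blood, spleen, lymph node,
# bone marrow, and the optional lymphoid-tissue-embedded tumor.
PB, SP, LN, BM, TU = "PB", "SP", "LN", "BM", "TU"
COMPARTMENTS = (PB, SP, LN, BM, TU)
TISSUES = (SP, LN, BM, TU)  # everything reachable from PB

TargetSelector = Literal["CD20", "CD19"]
Subset = Literal["resting", "activated", "post"]


class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class Physiology(_Frozen):
    """Compartment volumes and pre-therapy baseline cell numbers.

    ``volumes[PB]`` is the whole-blood volume used to convert absolute PB
    counts to cells/uL; ``serum_volume`` is the distribution volume of
    serum IL6. Baselines define the homeostatic set points every
    restoring flux is gated on.
    """

    species: str = "cyno"
    volumes: dict[str, float]
    serum_volume: float
    t_baseline: dict[str, float]  # resting CD8+ per compartment
    b_baseline: dict[str, float]  # CD19+CD20+ B per compartment
    prob_baseline: float = 0.0  # CD19+CD20- pro-B, BM only
    tumor_baseline: Optional[float] = None  # tumor B, TU only
    partition: dict[str, float] = Field(default_factory=dict)  # tissue:plasma drug ratio

    @property
    def compartments(self) -> tuple[str, ...]:
        return tuple(c for c in COMPARTMENTS if c in self.volumes)

    @property
    def has_tumor(self) -> bool:
        return TU in self.volumes

    @model_validator(mode="after")
    def _check(self) -> "Physiology":
        if PB not in self.volumes:
            raise ValueError("physiology must define a PB compartment")
        for c, v in self.volumes.items():
            if c not in COMPARTMENTS:
                raise ValueError(f"unknown compartment {c!r}")
            if v <= 0:
                raise ValueError(f"volume of {c} must be > 0")
        if self.serum_volume <= 0:
            raise ValueError("serum volume must be > 0")
        for name, d in (("t_baseline", self.t_baseline), ("b_baseline", self.b_baseline)):
            for c, x in d.items():
                if c not in self.volumes:
                    raise ValueError(f"{name}[{c}] refers to an absent compartment")
                if x < 0:
                    raise ValueError(f"{name}[{c}] must be >= 0")
        if self.prob_baseline < 0:
            raise ValueError("pro-B baseline must be >= 0")
        if self.prob_baseline > 0 and BM not in self.volumes:
            raise ValueError("pro-B baseline requires a BM compartment")
        if self.tumor_baseline is not None and TU not in self.volumes:
            raise ValueError("tumor baseline requires a TU compartment")
        if TU in self.volumes and self.tumor_baseline is None:
            raise ValueError("TU compartment present but tumor baseline missing")
        for c, k in self.partition.items():
            if c == PB:
                raise ValueError("partition coefficient is defined for non-PB compartments")
            if not 0 < k <= 1:
                raise ValueError(f"partition[{c}] must be in (0, 1]")
        return self

    def tbase(self, c: str) -> float:
        return self.t_baseline.get(c, 0.0)

    def bbase(self, c: str) -> float:
        return self.b_baseline.get(c, 0.0)


class DrugParams(_Frozen):
    """Drug-specific potency of the bispecific.

    ``target`` selects which B-cell pools the drug can engage: "CD20"
    (mature B and CD20+ tumor B only — the CD20/CD3 full-length
    antibody) or "CD19" (additionally the CD20- pro-B pool — the
    CD19/CD3 BiTE). Activation follows Michaelis–Menten kinetics in drug
    concentration, with Vmax itself a saturating function of the local
    B:T ratio (half-saturation ``k_bt``).
    """

    name: str
    target: TargetSelector
    ec50_act: float  # ng/mL
    vmax_max: float  # 1/day
    k_bt: float  # dimensionless B:T ratio
    ec50_kill: float  # ng/mL
    k_kill: float  # L/(cell*day): per-capita kill per activated-T concentration

    @model_validator(mode="after")
    def _check(self) -> "DrugParams":
        for f in ("ec50_act", "vmax_max", "k_bt", "ec50_kill", "k_kill"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be > 0")
        return self


class TCellKinetics(_Frozen):
    """CD8+ T-cell population dynamics and trafficking.

    Restoring fluxes are deficit/excess gated: thymic generation is
    proportional to max(0, 1 - Tr_PB/baseline), homeostatic apoptosis of
    resting cells to max(0, Tr/baseline - 1). PB exit of every subset is
    transiently amplified after each administration (injection stress)
    by a factor 1 + s*exp(-dt/tau).
    """

    k_thymus: float = 0.0  # cells/day at full deficit (PB only)
    k_excess_apop: float = 0.0  # 1/day on resting excess
    k_prol: float = 0.0  # 1/day, activated only
    phi: float = 0.5  # fraction of progeny staying activated
    k_deact_rest: float = 0.0  # activated -> resting, 1/day
    k_deact_post: float = 0.0  # activated -> post-activated, 1/day
    k_post_to_rest: float = 0.0  # post-activated -> resting, 1/day
    reactivation: bool = True  # post-activated cells can be reactivated
    k_adeath_act: float = 0.0  # activation-related apoptosis, 1/day
    k_adeath_post: float = 0.0
    pb_exit: dict[str, float]  # per subset, 1/day
    tissue_return: dict[str, float]  # per subset, 1/day (resting: derived, see model)
    partition_frac: dict[str, dict[str, float]]  # subset -> tissue -> fraction
    stress_amplitude: float = 0.0  # s, dimensionless
    stress_tau: float = 0.25  # day

    @model_validator(mode="after")
    def _check(self) -> "TCellKinetics":
        for f in (
            "k_thymus", "k_excess_apop", "k_prol", "k_deact_rest", "k_deact_post",
            "k_post_to_rest", "k_adeath_act", "k_adeath_post", "stress_amplitude",
        ):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if not 0 <= self.phi <= 1:
            raise ValueError("phi must be in [0, 1]")
        if self.stress_tau <= 0:
            raise ValueError("stress_tau must be > 0")
        for d in (self.pb_exit, self.tissue_return):
            for s in ("resting", "activated", "post"):
                if s not in d:
                    raise ValueError(f"missing subset {s!r}")
                if d[s] < 0:
                    raise ValueError("trafficking rates must be >= 0")
        if self.pb_exit["activated"] < self.pb_exit["resting"]:
            raise ValueError("activated PB-exit rate must be >= resting rate")
        # tissue:PB distribution ratio (exit/return) must be at least as
        # large for activated as for resting cells ("greater tissue
        # partitioning of activated T-cells")
        act_ratio = self.pb_exit["activated"] / max(self.tissue_return["activated"], 1e-300)
        rest_ratio = self.pb_exit["resting"] / max(self.tissue_return["resting"], 1e-300)
        if act_ratio < rest_ratio * (1 - 1e-12):
            raise ValueError("activated tissue partitioning must be >= resting")
        for s, fr in self.partition_frac.items():
            tot = sum(fr.values())
            if fr and abs(tot - 1.0) > 1e-6:
                raise ValueError(f"partition fractions for {s!r} must sum to 1 (got {tot})")
            for c, x in fr.items():
                if c == PB or x < 0:
                    raise ValueError("partition fractions are nonnegative and tissue-only")
        return self


class BCellKinetics(_Frozen):
    """B-lineage population dynamics.

    Pro-B cells are generated in the BM from stem-cell precursors and
    mature into CD20+ B cells; mature BM B cells undergo homeostatic
    apoptosis and migrate to PB when the PB pool is diminished; PB B
    cells replenish spleen/LN when those are diminished; normal-tissue B
    cells proliferate only in deficit; tumor B cells proliferate
    constitutively with doubling time ``tumor_doubling_time``.

    ``k_gen_prob`` (cells/day) and ``k_bm_apop`` (1/day) may be left
    unset, in which case they are derived from the baselines so the
    drug-free system is exactly at equilibrium.
    """

    k_maturation: float  # pro-B -> B, 1/day
    k_gen_prob: Optional[float] = None  # cells/day; derived if None
    k_bm_apop: Optional[float] = None  # 1/day; derived if None
    k_bm_to_pb: float = 0.0  # 1/day, gated on PB deficit
    k_pb_to_tissue: float = 0.0  # 1/day, gated on tissue deficit
    k_deficit_prolif: float = 0.0  # 1/day at full deficit
    tumor_doubling_time: Optional[float] = None  # day

    @model_validator(mode="after")
    def _check(self) -> "BCellKinetics":
        for f in ("k_maturation", "k_bm_to_pb", "k_pb_to_tissue", "k_deficit_prolif"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        for f in ("k_gen_prob", "k_bm_apop"):
            v = getattr(self, f)
            if v is not None and v < 0:
                raise ValueError(f"{f} must be >= 0")
        if self.tumor_doubling_time is not None and self.tumor_doubling_time <= 0:
            raise ValueError("tumor doubling time must be > 0")
        return self


class CytokineParams(_Frozen):
    """Serum IL6 module.

    Production is proportional to the local activation signal times the
    number of activated T cells, summed over compartments with tissue
    terms down-weighted by ``f_tiss`` < 1 (only a fraction of
    tissue-produced IL6 reaches the blood). Elimination is first order;
    the baseline is maintained by a constant basal production term.
    """

    k_prod: float  # pg/day per (activation-signal * cell)
    f_tiss: float = 0.1
    k_el: float = 8.3  # 1/day (~2 h half-life)
    baseline: float = 1.0  # pg/mL

    @model_validator(mode="after")
    def _check(self) -> "CytokineParams":
        if not 0 <= self.f_tiss < 1:
            raise ValueError("f_tiss must be in [0, 1)")
        if self.k_prod <= 0 or self.k_el <= 0:
            raise ValueError("k_prod and k_el must be > 0")
        if self.baseline < 0:
            raise ValueError("IL6 baseline must be >= 0")
        return self


class SubjectParameters(_Frozen):
    """One virtual subject: physiology + kinetics + drug bindings."""

    subject_id: str
    physiology: Physiology
    tcell: TCellKinetics
    bcell: BCellKinetics
    cytokine: CytokineParams
    drugs: dict[str, DrugParams]

    @model_validator(mode="after")
    def _check(self) -> "SubjectParameters":
        if not self.drugs:
            raise ValueError("at least one drug binding is required")
        for label, d in self.drugs.items():
            if d.name != label:
                raise ValueError(f"drug key {label!r} must match DrugParams.name {d.name!r}")
        if self.physiology.has_tumor and self.bcell.tumor_doubling_time is None:
            raise ValueError("tumor compartment present but tumor doubling time missing")
        return self

    # --- dotted-path access, used by calibration and population sampling ---

    def get(self, path: str) -> float:
        """Return a scalar parameter by dotted path.

        Dict hops use the key as a path element, e.g.
        ``"drugs.mosunetuzumab.vmax_max"`` or ``"tcell.pb_exit.activated"``.
        """
        obj = self
        for part in path.split("."):
            obj = obj[part] if isinstance(obj, dict) else getattr(obj, part)
        if not isinstance(obj, (int, float)) or isinstance(obj, bool):
            raise TypeError(f"{path!r} is not a scalar parameter")
        return float(obj)

    def replace(self, updates: dict[str, float]) -> "SubjectParameters":
        """Return a copy with dotted-path scalar parameters replaced."""
        data = self.model_dump()
        for path, value in updates.items():
            node = data
            parts = path.split(".")
            for part in parts[:-1]:
                node = node[part]
            if parts[-1] not in node:
                raise KeyError(f"unknown parameter path {path!r}")
            node[parts[-1]] = float(value)
        return SubjectParameters.model_validate(data)

    def with_id(self, subject_id: str) -> "SubjectParameters":
        return self.model_copy(update={"subject_id": subject_id})
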