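"""Default parameterizations: reference virtual cyno, human presets, PK.

The reference virtual cyno is the single parameter set that reproduces
the qualitative preclinical study conditions the package emulates:
weekly IV dosing at 0.01–1 mg/kg causing >95% peripheral B-cell
depletion within a day, a transient margination dip then rebound of
circulating CD8+ T cells, a dose-dependent spike of %CD69+, and serum
IL6 peaking 2–6 h after the first dose with much smaller peaks after
later doses. Rate constants are package defaults refined by the
calibration module; they are not measurements.
"""

from __future__ import annotations

from .params import (
    BCellKinetics,
    CytokineParams,
    DrugParams,
    Physiology,
    SubjectParameters,
    TCellKinetics,
)
from .pk import TwoCompartmentPKParams

CYNO_WEIGHT_KG = 3.5
CYNO_BSA_M2 = 0.25
HUMAN_WEIGHT_KG = 70.0
HUMAN_BSA_M2 = 1.8


def mosunetuzumab_params() -> DrugParams:
    """CD20/CD3 full-length bispecific: CD20+ targets only."""
    return DrugParams(
        name="mosunetuzumab",
        target="CD20",
        ec50_act=5000.0,  # ng/mL: C1D1 doses (1.6-20 mg) stay sub-saturating
        vmax_max=100.0,  # 1/day
        k_bt=0.5,
        ec50_kill=20.0,
        k_kill=6e-8,  # L/(cell*day)
    )


def blinatumomab_params() -> DrugParams:
    """CD19/CD3 BiTE: also engages CD20- pro-B cells; sub-ng/mL potency."""
    return DrugParams(
        name="blinatumomab",
        target="CD19",
        ec50_act=1.0,  # ng/mL: infusion steady states (0.2-2.4 ng/mL) sub-saturating
        vmax_max=100.0,
        k_bt=0.5,
        ec50_kill=0.2,
        k_kill=6e-8,
    )


def cyno_physiology() -> Physiology:
    """Healthy cynomolgus monkey (~3.5 kg).

    PB counts correspond to ~1000 CD8+/uL and ~1500 B/uL in ~0.28 L of
    blood; the large majority of lymphocytes reside in spleen, lymph
    nodes, and bone marrow.
    """
    return Physiology(
        species="cyno",
        volumes={"PB": 0.28, "SP": 0.01, "LN": 0.012, "BM": 0.08},
        serum_volume=0.15,
        t_baseline={"PB": 2.8e8, "SP": 1.5e9, "LN": 2.2e9, "BM": 7.0e8},
        b_baseline={"PB": 4.2e8, "SP": 3.0e9, "LN": 4.0e9, "BM": 1.2e9},
        prob_baseline=6.0e8,
        partition={"SP": 0.35, "LN": 0.35, "BM": 0.2},
    )


def human_physiology() -> Physiology:
    """Healthy adult human (~70 kg), no tumor compartment."""
    return Physiology(
        species="human",
        volumes={"PB": 5.0, "SP": 0.2, "LN": 0.3, "BM": 1.7},
        serum_volume=3.0,
        t_baseline={"PB": 2.5e9, "SP": 1.5e10, "LN": 2.2e10, "BM": 7.0e9},
        b_baseline={"PB": 1.25e9, "SP": 2.0e10, "LN": 3.0e10, "BM": 8.0e9},
        prob_baseline=4.0e9,
        partition={"SP": 0.35, "LN": 0.35, "BM": 0.2},
    )


def nhl_physiology(
    tumor_cells: float = 1e10,
    tumor_bt_ratio: float = 1e4,
    cells_per_liter: float = 1e12,
) -> Physiology:
    """NHL patient: human physiology plus a B-cell-dense nodal tumor.

    The tumor compartment volume follows from the burden via a packing
    density (default 1e12 cells/L ~ 1e9 cells/mL); its baseline T-cell
    content is set by the tumor B:T ratio (>> 1: B-cell dense mass).
    """
    base = human_physiology()
    vol = dict(base.volumes)
    vol["TU"] = max(tumor_cells / cells_per_liter, 1e-4)
    t_base = dict(base.t_baseline)
    t_base["TU"] = tumor_cells / tumor_bt_ratio
    b_base = dict(base.b_baseline)
    b_base["TU"] = 0.0  # normal B absent; tumor B tracked separately
    part = dict(base.partition)
    part["TU"] = 0.35
    return Physiology(
        species="human_nhl",
        volumes=vol,
        serum_volume=base.serum_volume,
        t_baseline=t_base,
        b_baseline=b_base,
        prob_baseline=base.prob_baseline,
        tumor_baseline=tumor_cells,
        partition=part,
    )


def reference_tcell() -> TCellKinetics:
    return TCellKinetics(
        k_thymus=2.0e7,  # cells/day at full PB deficit
        k_excess_apop=0.3,
        k_prol=1.6,
        phi=0.55,
        k_deact_rest=0.3,
        k_deact_post=0.3,
        k_post_to_rest=0.05,
        reactivation=True,
        k_adeath_act=0.9,
        k_adeath_post=0.1,
        pb_exit={"resting": 0.3, "activated": 3.0, "post": 0.6},
        tissue_return={"resting": 0.3, "activated": 0.5, "post": 0.3},
        partition_frac={
            "resting": {"SP": 0.3, "LN": 0.45, "BM": 0.25},
            "activated": {"SP": 0.3, "LN": 0.45, "BM": 0.25},
            "post": {"SP": 0.3, "LN": 0.45, "BM": 0.25},
        },
        stress_amplitude=2.5,
        stress_tau=0.25,
    )


def reference_bcell() -> BCellKinetics:
    return BCellKinetics(
        k_maturation=0.1,
        k_bm_to_pb=0.3,
        k_pb_to_tissue=0.5,
        k_deficit_prolif=0.25,
    )


def reference_cytokine() -> CytokineParams:
    return CytokineParams(k_prod=1.2e-4, f_tiss=0.05, k_el=8.3, baseline=1.0)


def reference_cyno(subject_id: str = "reference_cyno") -> SubjectParameters:
    """The calibrated reference virtual cyno."""
    return SubjectParameters(
        subject_id=subject_id,
        physiology=cyno_physiology(),
        tcell=reference_tcell(),
        bcell=reference_bcell(),
        cytokine=reference_cytokine(),
        drugs={
            "mosunetuzumab": mosunetuzumab_params(),
            "blinatumomab": blinatumomab_params(),
        },
    )


# --- PK defaults -------------------------------------------------------

def mosunetuzumab_pk_human() -> TwoCompartmentPKParams:
    """Antibody-like kinetics: multi-day half-life."""
    return TwoCompartmentPKParams(v1=3.5, v2=2.5, cl=0.8, q=0.6, ref_weight_kg=70.0)


def mosunetuzumab_pk_cyno() -> TwoCompartmentPKParams:
    return mosunetuzumab_pk_human().scaled_to(CYNO_WEIGHT_KG)


def blinatumomab_pk_human() -> TwoCompartmentPKParams:
    """BiTE kinetics: ~2 h effective half-life, high clearance."""
    return TwoCompartmentPKParams(v1=4.3, v2=1.5, cl=45.0, q=2.0, ref_weight_kg=70.0)


def blinatumomab_pk_cyno() -> TwoCompartmentPKParams:
    return blinatumomab_pk_human().scaled_to(CYNO_WEIGHT_KG)


def pk_defaults(drug: str, species: str = "human") -> TwoCompartmentPKParams:
    table = {
        ("mosunetuzumab", "human"): mosunetuzumab_pk_human,
        ("mosunetuzumab", "cyno"): mosunetuzumab_pk_cyno,
        ("blinatumomab", "human"): blinatumomab_pk_human,
        ("blinatumomab", "cyno"): blinatumomab_pk_cyno,
    }
    key = (drug, "cyno" if species.startswith("cyno") else "human")
    if key not in table:
        raise KeyError(f"no PK defaults for {key}")
    return table[key]()
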