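"""Curated thrombin / histamine / VEGF -> myosin-light-chain network.

The model integrates the three mediator cascades that converge on MLC
phosphorylation in endothelial cells:

* thrombin -> PAR-1 -> Gq (PLCbeta / IP3 / Ca2+) and G12/13 (RhoGEF ->
  Rho GTPase -> ROCK opening and activation);
* histamine -> H1 GPCR -> Gq (shared PLC/IP3/Ca2+ route) and eNOS priming
  (NO -> sGC -> cGMP -> PKG), with no G12/13 branch, so ROCK stays folded
  under histamine alone;
* VEGF -> VEGFR2 -> PLCgamma (Ca2+), eNOS priming, and the Ras-Raf-MEK-ERK
  cascade whose doubly-phosphorylated ERK converts MLCK to a
  higher-activity phosphorylated form.

MLC sits at the bottom as a three-state chain MLC -> pMLC -> ppMLC,
phosphorylated by active MLCK (Ca4CaM-bound), phospho-MLCK (ERK route) and
active ROCK, and dephosphorylated by the myosin phosphatase MYCP.  MYCP is
inhibited two ways: ROCK phosphorylates its targeting subunit (MYPT1), and
PKC-phosphorylated CPI-17 binds it stoichiometrically.  PKG acts only on
the *open* (Rho-GTP bound) ROCK conformation, which is the structural basis
of thrombin+histamine and thrombin+VEGF synergy: one mediator supplies
Rho-GTP to open ROCK, the other supplies PKG to activate it.

Concentrations are uM, time is seconds.  Mediators are ordinary depleting
species; cytosolic Ca2+ exchanges with a finite internal store and with a
clamped extracellular reservoir, so sustained IP3 cannot sustain a high
Ca2+ plateau (store depletion terminates the transient).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .network import (
    MASS_ACTION_IRREVERSIBLE,
    MASS_ACTION_REVERSIBLE,
    NetworkError,
    RateLaw,
    Reaction,
    ReactionNetwork,
    Species,
)
from .params import load_params

__all__ = [
    "CASCADE_LABELS",
    "EXPRESSION_COMPONENTS",
    "StimulusConfig",
    "BaselineConcentrations",
    "build_model",
    "build_thrombin_receptor_block",
    "build_histamine_receptor_block",
    "build_calcium_block",
    "build_mlck_cam_block",
    "build_rho_rock_block",
    "build_myocp_cpi17_block",
    "build_vegf_erk_block",
    "build_no_pkg_block",
    "baseline_species",
]

#: cascade vocabulary used by switch-off (ablation) experiments
CASCADE_LABELS = (
    "ca_dependent",
    "rock_dependent",
    "cpi17_dependent",
    "no_dependent",
    "ras_erk",
)

#: pools that over-expression multipliers act on
EXPRESSION_COMPONENTS = {
    "PAR1": "PAR1",
    "RhoGTPase": "RhoGDP",
    "ROCK": "ROCKf",
    "VEGF": None,  # scales the VEGF dose, not a pool
    "VEGFR2": "VEGFR2",
    "CPI17": "CPI17",
}


@dataclass
class StimulusConfig:
    """One in-silico experiment: doses, expression levels, switches.

    Doses are in uM.  ``expression_multipliers`` scale the corresponding
    baseline pools (positive factors, default 1).  ``cascade_switches``
    turn whole cascades off (all rate constants of tagged reactions set to
    zero).  ``overrides`` set individual species initial concentrations
    after equilibration of the resting cell.
    """

    thrombin: float = 0.0
    histamine: float = 0.0
    vegf: float = 0.0
    expression_multipliers: dict[str, float] = field(default_factory=dict)
    cascade_switches: dict[str, bool] = field(default_factory=dict)
    overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name, dose in (
            ("thrombin", self.thrombin),
            ("histamine", self.histamine),
            ("vegf", self.vegf),
        ):
            if dose < 0:
                raise NetworkError(f"{name} dose must be >= 0")
        for comp, mult in self.expression_multipliers.items():
            if comp not in EXPRESSION_COMPONENTS:
                raise NetworkError(f"unknown expression component {comp!r}")
            if mult <= 0:
                raise NetworkError(f"multiplier for {comp!r} must be > 0")
        for label in self.cascade_switches:
            if label not in CASCADE_LABELS:
                raise NetworkError(f"unknown cascade label {label!r}")

    def to_dict(self) -> dict:
        return {
            "thrombin": self.thrombin,
            "histamine": self.histamine,
            "vegf": self.vegf,
            "expression_multipliers": dict(self.expression_multipliers),
            "cascade_switches": dict(self.cascade_switches),
            "overrides": dict(self.overrides),
        }

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    def same_except_doses(self, other: "StimulusConfig") -> bool:
        a, b = self.to_dict(), other.to_dict()
        for key in ("thrombin", "histamine", "vegf"):
            a.pop(key), b.pop(key)
        return a == b

    def with_doses(self, thrombin=None, histamine=None, vegf=None):
        d = self.to_dict()
        if thrombin is not None:
            d["thrombin"] = thrombin
        if histamine is not None:
            d["histamine"] = histamine
        if vegf is not None:
            d["vegf"] = vegf
        return StimulusConfig(**d)


@dataclass
class BaselineConcentrations:
    """Resting pool sizes (uM) for the curated network.

    Receptor defaults sit inside their stated physiological ranges:
    PAR-1 0.002-0.02, ROCK 0.06-0.3, VEGFR2 0.012-0.072; CPI-17 defaults
    to 0.08.
    """

    pools: dict[str, float] = field(default_factory=lambda: dict(_BASELINE))

    def __post_init__(self):
        for sp, value in self.pools.items():
            if value < 0:
                raise NetworkError(f"baseline for {sp!r} must be >= 0")


_BASELINE = {
    # receptors
    "PAR1": 0.01,
    "H1R": 0.01,
    "VEGFR2": 0.012,
    # G proteins and exchange factors
    "Gq": 0.5,
    "G12": 0.2,
    "GEF": 0.1,
    # Rho / ROCK
    "RhoGDP": 0.2,
    "ROCKf": 0.15,
    # phospholipases
    "PLCb": 0.1,
    "PLCg": 0.1,
    # calcium handling
    "Ca_i": 0.05,
    "Ca_s": 1.5,
    # calmodulin / MLCK
    "CaM": 5.0,
    "MLCK": 1.0,
    # MLC pool (fractions are reported, absolute scale is arbitrary)
    "MLC": 1.0,
    # phosphatase axis
    "MYCP": 0.06,
    "PKC": 0.5,
    "CPI17": 0.08,
    # NO / PKG cascade
    "eNOS": 0.1,
    "sGC": 0.1,
    "PKG": 0.5,
    # Ras / ERK cascade
    "RasGDP": 0.2,
    "Raf": 0.2,
    "MEK": 0.5,
    "ERK": 0.5,
}

#: species that exist only in stimulated / intermediate states
_DERIVED_SPECIES = [
    "Thr", "His", "VEGF",
    "PAR1a", "PAR1i", "H1Ra", "H1Ri", "VR2a",
    "Gqa", "G12a", "GEFa",
    "RhoGTP", "ROCKo", "ROCKa",
    "PLCba", "PLCga", "IP3", "DAG",
    "Ca2CaM", "Ca4CaM", "MLCKa", "MLCKp",
    "pMLC", "ppMLC",
    "MYCPi", "MYCP_CPI", "PKCa", "pCPI17",
    "eNOSp", "eNOSa", "NO", "sGCa", "cGMP", "PKGa",
    "RasGTP", "Rafa", "MEKp", "MEKpp", "ERKp", "ERKpp",
]

_DISPLAY = {
    "Thr": "thrombin", "His": "histamine", "VEGF": "VEGF",
    "Ca_i": "cytosolic Ca2+", "Ca_s": "stored Ca2+",
    "ppMLC": "di-phospho MLC", "pMLC": "mono-phospho MLC",
    "MYCP": "myosin phosphatase", "EXT": "extracellular reservoir",
}


def baseline_species(baseline: BaselineConcentrations) -> list[Species]:
    species = [
        Species("EXT", _DISPLAY["EXT"], 1.0, is_boundary=True),
    ]
    for sp, conc in baseline.pools.items():
        species.append(Species(sp, _DISPLAY.get(sp, sp), conc))
    for sp in _DERIVED_SPECIES:
        species.append(Species(sp, _DISPLAY.get(sp, sp), 0.0))
    return species


def _r(P, rid, reactants, products, kf, kb=None, tags=()):
    """Build one mass-action reaction; ``kf``/``kb`` are parameter *names*
    resolved against the table ``P`` and recorded on the reaction."""
    form = MASS_ACTION_REVERSIBLE if kb is not None else MASS_ACTION_IRREVERSIBLE
    names = {"kf": kf} if kb is None else {"kf": kf, "kb": kb}
    return Reaction(
        id=rid,
        reactants=reactants,
        products=products,
        rate_law=RateLaw(form=form, kf=P[kf], kb=0.0 if kb is None else P[kb]),
        tags=frozenset(tags),
        param_names=names,
    )


def build_thrombin_receptor_block(P) -> list[Reaction]:
    """Thrombin engages PAR-1 as a tight, near-irreversible complex (the
    cleaved receptor cannot revert); the active complex is internalized
    first-order, with slow recycling of resensitized receptor, so
    receptor-level signalling is transient and the thrombin dose sets the
    size of the activated pool (receptor-limited at high dose,
    ligand-limited at low dose).  Active PAR-1 drives the Gq branch
    (-> PLCbeta) and the G12/13 branch (-> RhoGEF -> Rho)."""
    return [
        _r(P, "par1_bind", [("Thr", 1), ("PAR1", 1)], [("PAR1a", 1)],
           "k_par1_bind", "k_par1_unbind"),
        _r(P, "thr_clear", [("Thr", 1)], [], "k_thr_clear"),
        _r(P, "par1_des", [("PAR1a", 1)], [("PAR1i", 1)], "k_par1_des"),
        _r(P, "par1_rec", [("PAR1i", 1)], [("PAR1", 1)], "k_par1_rec"),
        _r(P, "gq_act_thr", [("PAR1a", 1), ("Gq", 1)],
           [("PAR1a", 1), ("Gqa", 1)], "k_gq_act"),
        _r(P, "g12_act", [("PAR1a", 1), ("G12", 1)],
           [("PAR1a", 1), ("G12a", 1)], "k_g12_act"),
        _r(P, "g12_deact", [("G12a", 1)], [("G12", 1)], "k_g12_deact"),
        _r(P, "gef_act", [("G12a", 1), ("GEF", 1)],
           [("G12a", 1), ("GEFa", 1)], "k_gef_act"),
        _r(P, "gef_deact", [("GEFa", 1)], [("GEF", 1)], "k_gef_deact"),
    ]


def build_histamine_receptor_block(P) -> list[Reaction]:
    """H1-receptor branch: reversible histamine binding, slow receptor
    desensitization, Gq coupling (shared PLCbeta route) and eNOS priming.
    There is no G12/13 coupling, so histamine alone never loads Rho."""
    return [
        _r(P, "h1_bind", [("His", 1), ("H1R", 1)], [("H1Ra", 1)],
           "k_h1_bind", "k_h1_unbind"),
        _r(P, "h1_des", [("H1Ra", 1)], [("H1Ri", 1)], "k_h1_des"),
        _r(P, "gq_act_his", [("H1Ra", 1), ("Gq", 1)],
           [("H1Ra", 1), ("Gqa", 1)], "k_gq_act_his"),
        _r(P, "enos_act_his", [("H1Ra", 1), ("eNOS", 1)],
           [("H1Ra", 1), ("eNOSp", 1)], "k_enos_act_his",
           tags=("no_dependent",)),
    ]


def build_calcium_block(P) -> list[Reaction]:
    """PLCbeta (Gq) and PLCgamma (VEGFR2) produce IP3 and DAG; IP3 gates
    Ca2+ release from a finite internal store; SERCA-type re-uptake plus
    plasma-membrane extrusion against a clamped extracellular reservoir
    make the cytosolic Ca2+ rise a sharp transient even under sustained
    IP3 (store depletion)."""
    return [
        _r(P, "gq_deact", [("Gqa", 1)], [("Gq", 1)], "k_gq_deact"),
        _r(P, "plcb_act", [("Gqa", 1), ("PLCb", 1)],
           [("Gqa", 1), ("PLCba", 1)], "k_plcb_act"),
        _r(P, "plcb_deact", [("PLCba", 1)], [("PLCb", 1)], "k_plcb_deact"),
        _r(P, "ip3_prod_b", [("PLCba", 1)], [("PLCba", 1), ("IP3", 1)],
           "k_ip3_prod"),
        _r(P, "dag_prod_b", [("PLCba", 1)], [("PLCba", 1), ("DAG", 1)],
           "k_dag_prod"),
        _r(P, "ip3_deg", [("IP3", 1)], [], "k_ip3_deg"),
        _r(P, "dag_deg", [("DAG", 1)], [], "k_dag_deg"),
        _r(P, "ca_release", [("IP3", 1), ("Ca_s", 1)],
           [("IP3", 1), ("Ca_i", 1)], "k_ca_rel"),
        _r(P, "ca_leak", [("Ca_s", 1)], [("Ca_i", 1)], "k_ca_leak"),
        _r(P, "ca_pump", [("Ca_i", 1)], [("Ca_s", 1)], "k_ca_pump"),
        _r(P, "ca_in", [("EXT", 1)], [("EXT", 1), ("Ca_i", 1)], "k_ca_in"),
        # receptor-operated Ca2+ entry: sustained Gq signalling holds a
        # small influx open, giving a mild cytosolic plateau above rest
        _r(P, "ca_in_rcpt", [("EXT", 1), ("Gqa", 1)],
           [("EXT", 1), ("Gqa", 1), ("Ca_i", 1)], "k_ca_in_rcpt"),
        _r(P, "ca_out", [("Ca_i", 1)], [], "k_ca_out"),
    ]


def build_mlck_cam_block(P) -> list[Reaction]:
    """Cooperative Ca2+-calmodulin loading (4 Ca2+ per CaM, lumped into two
    sequential 2-Ca2+ steps); Ca4CaM-MLCK is the active kinase.  ERK
    phosphorylates MLCK into a higher-activity form that works at resting
    Ca2+ (the VEGF route)."""
    return [
        _r(P, "cam_bind1", [("Ca_i", 2), ("CaM", 1)], [("Ca2CaM", 1)],
           "k_cam1_f", "k_cam1_b"),
        _r(P, "cam_bind2", [("Ca_i", 2), ("Ca2CaM", 1)], [("Ca4CaM", 1)],
           "k_cam2_f", "k_cam2_b"),
        _r(P, "mlck_bind", [("Ca4CaM", 1), ("MLCK", 1)], [("MLCKa", 1)],
           "k_mlck_bind", "k_mlck_unbind"),
        _r(P, "mlck_phos", [("ERKpp", 1), ("MLCK", 1)],
           [("ERKpp", 1), ("MLCKp", 1)], "k_mlck_phos",
           tags=("ras_erk",)),
        _r(P, "mlckp_dephos", [("MLCKp", 1)], [("MLCK", 1)],
           "k_mlckp_dephos"),
        _r(P, "mlc_phos1", [("MLCKa", 1), ("MLC", 1)],
           [("MLCKa", 1), ("pMLC", 1)], "k_mlck_cat",
           tags=("ca_dependent",)),
        _r(P, "mlc_phos2", [("MLCKa", 1), ("pMLC", 1)],
           [("MLCKa", 1), ("ppMLC", 1)], "k_mlck_cat2",
           tags=("ca_dependent",)),
        _r(P, "mlc_phos1p", [("MLCKp", 1), ("MLC", 1)],
           [("MLCKp", 1), ("pMLC", 1)], "k_mlckp_cat",
           tags=("ras_erk",)),
        _r(P, "mlc_phos2p", [("MLCKp", 1), ("pMLC", 1)],
           [("MLCKp", 1), ("ppMLC", 1)], "k_mlckp_cat2",
           tags=("ras_erk",)),
    ]


def build_rho_rock_block(P) -> list[Reaction]:
    """Rho GDP/GTP cycle (GEF loading, GAP hydrolysis).  ROCK is folded
    (auto-inhibited) until Rho-GTP binds and opens it; the open
    conformation is then activated by Rho GTPase or, independently, by PKG
    phosphorylation.  Active ROCK phosphorylates MLC directly and inhibits
    the phosphatase by phosphorylating MYPT1."""
    return [
        _r(P, "rho_act", [("GEFa", 1), ("RhoGDP", 1)],
           [("GEFa", 1), ("RhoGTP", 1)], "k_rho_act"),
        _r(P, "rho_gap", [("RhoGTP", 1)], [("RhoGDP", 1)], "k_rho_gap"),
        # Rho-GTP opens ROCK catalytically (binding/unbinding is fast on
        # the timescale of interest, so the open state does not sequester
        # Rho; this keeps the ROCK over-expression response monotone)
        _r(P, "rock_open", [("RhoGTP", 1), ("ROCKf", 1)],
           [("RhoGTP", 1), ("ROCKo", 1)], "k_rock_open"),
        _r(P, "rock_close", [("ROCKo", 1)], [("ROCKf", 1)],
           "k_rock_close"),
        _r(P, "rock_act_rho", [("RhoGTP", 1), ("ROCKo", 1)],
           [("RhoGTP", 1), ("ROCKa", 1)], "k_rock_act_rho"),
        _r(P, "rock_act_pkg", [("PKGa", 1), ("ROCKo", 1)],
           [("PKGa", 1), ("ROCKa", 1)], "k_rock_act_pkg",
           tags=("no_dependent",)),
        _r(P, "rock_deact", [("ROCKa", 1)], [("ROCKo", 1)], "k_rock_deact"),
        _r(P, "mlc_phos1r", [("ROCKa", 1), ("MLC", 1)],
           [("ROCKa", 1), ("pMLC", 1)], "k_rock_cat",
           tags=("rock_dependent",)),
        _r(P, "mlc_phos2r", [("ROCKa", 1), ("pMLC", 1)],
           [("ROCKa", 1), ("ppMLC", 1)], "k_rock_cat2",
           tags=("rock_dependent",)),
        _r(P, "mypt_phos", [("ROCKa", 1), ("MYCP", 1)],
           [("ROCKa", 1), ("MYCPi", 1)], "k_mypt_phos",
           tags=("rock_dependent",)),
        _r(P, "mypt_dephos", [("MYCPi", 1)], [("MYCP", 1)],
           "k_mypt_dephos"),
    ]


def build_myocp_cpi17_block(P) -> list[Reaction]:
    """Myosin phosphatase core and its CPI-17 brake: MYCP dephosphorylates
    pMLC/ppMLC; DAG-activated PKC phosphorylates CPI-17, and phospho-CPI-17
    binds MYCP stoichiometrically as an inhibited complex."""
    return [
        _r(P, "pkc_act", [("DAG", 1), ("PKC", 1)], [("DAG", 1), ("PKCa", 1)],
           "k_pkc_act"),
        _r(P, "pkc_deact", [("PKCa", 1)], [("PKC", 1)], "k_pkc_deact"),
        _r(P, "cpi_phos", [("PKCa", 1), ("CPI17", 1)],
           [("PKCa", 1), ("pCPI17", 1)], "k_cpi_phos",
           tags=("cpi17_dependent",)),
        _r(P, "cpi_dephos", [("pCPI17", 1)], [("CPI17", 1)], "k_cpi_dephos"),
        _r(P, "cpi_bind", [("pCPI17", 1), ("MYCP", 1)], [("MYCP_CPI", 1)],
           "k_cpi_bind", "k_cpi_unbind", tags=("cpi17_dependent",)),
        _r(P, "mlc_dephos1", [("MYCP", 1), ("pMLC", 1)],
           [("MYCP", 1), ("MLC", 1)], "k_mycp_cat"),
        _r(P, "mlc_dephos2", [("MYCP", 1), ("ppMLC", 1)],
           [("MYCP", 1), ("pMLC", 1)], "k_mycp_cat2"),
    ]


def build_vegf_erk_block(P) -> list[Reaction]:
    """VEGF binds VEGFR2 (active complex, internalized first-order); the
    active receptor drives PLCgamma (shared IP3/DAG route), eNOS priming,
    and the Ras -> Raf -> MEK -> ERK cascade with double phosphorylation
    at the MEK and ERK levels."""
    return [
        _r(P, "vegf_bind", [("VEGF", 1), ("VEGFR2", 1)], [("VR2a", 1)],
           "k_vegf_bind", "k_vegf_unbind"),
        _r(P, "vr2_int", [("VR2a", 1)], [], "k_vr2_int"),
        _r(P, "plcg_act", [("VR2a", 1), ("PLCg", 1)],
           [("VR2a", 1), ("PLCga", 1)], "k_plcg_act"),
        _r(P, "plcg_deact", [("PLCga", 1)], [("PLCg", 1)], "k_plcg_deact"),
        _r(P, "ip3_prod_g", [("PLCga", 1)], [("PLCga", 1), ("IP3", 1)],
           "k_ip3_prod_g"),
        _r(P, "dag_prod_g", [("PLCga", 1)], [("PLCga", 1), ("DAG", 1)],
           "k_dag_prod_g"),
        _r(P, "enos_act_vegf", [("VR2a", 1), ("eNOS", 1)],
           [("VR2a", 1), ("eNOSp", 1)], "k_enos_act_vegf",
           tags=("no_dependent",)),
        _r(P, "ras_act", [("VR2a", 1), ("RasGDP", 1)],
           [("VR2a", 1), ("RasGTP", 1)], "k_ras_act", tags=("ras_erk",)),
        _r(P, "ras_gap", [("RasGTP", 1)], [("RasGDP", 1)], "k_ras_gap",
           tags=("ras_erk",)),
        _r(P, "raf_act", [("RasGTP", 1), ("Raf", 1)],
           [("RasGTP", 1), ("Rafa", 1)], "k_raf_act", tags=("ras_erk",)),
        _r(P, "raf_act_pkg", [("PKGa", 1), ("Raf", 1)],
           [("PKGa", 1), ("Rafa", 1)], "k_raf_act_pkg",
           tags=("no_dependent",)),
        _r(P, "raf_deact", [("Rafa", 1)], [("Raf", 1)], "k_raf_deact",
           tags=("ras_erk",)),
        _r(P, "mek_phos1", [("Rafa", 1), ("MEK", 1)],
           [("Rafa", 1), ("MEKp", 1)], "k_mek_phos", tags=("ras_erk",)),
        _r(P, "mek_phos2", [("Rafa", 1), ("MEKp", 1)],
           [("Rafa", 1), ("MEKpp", 1)], "k_mek_phos", tags=("ras_erk",)),
        _r(P, "mek_dephos2", [("MEKpp", 1)], [("MEKp", 1)], "k_mek_dephos",
           tags=("ras_erk",)),
        _r(P, "mek_dephos1", [("MEKp", 1)], [("MEK", 1)], "k_mek_dephos",
           tags=("ras_erk",)),
        _r(P, "erk_phos1", [("MEKpp", 1), ("ERK", 1)],
           [("MEKpp", 1), ("ERKp", 1)], "k_erk_phos", tags=("ras_erk",)),
        _r(P, "erk_phos2", [("MEKpp", 1), ("ERKp", 1)],
           [("MEKpp", 1), ("ERKpp", 1)], "k_erk_phos", tags=("ras_erk",)),
        _r(P, "erk_dephos2", [("ERKpp", 1)], [("ERKp", 1)], "k_erk_dephos",
           tags=("ras_erk",)),
        _r(P, "erk_dephos1", [("ERKp", 1)], [("ERK", 1)], "k_erk_dephos",
           tags=("ras_erk",)),
    ]


def build_no_pkg_block(P) -> list[Reaction]:
    """Ca2+-CaM-dependent eNOS -> NO -> sGC -> cGMP -> PKG.  eNOS must be
    receptor-primed (histamine or VEGF) *and* Ca4CaM-bound to produce NO;
    PKG then feeds Raf (weak ERK link) and open ROCK (the synergy route,
    defined in the Rho/ROCK and VEGF blocks)."""
    tags = ("no_dependent",)
    return [
        _r(P, "enosp_deact", [("eNOSp", 1)], [("eNOS", 1)],
           "k_enosp_deact", tags=tags),
        _r(P, "enos_bind", [("Ca4CaM", 1), ("eNOSp", 1)], [("eNOSa", 1)],
           "k_enos_bind", "k_enos_unbind", tags=tags),
        _r(P, "no_prod", [("eNOSa", 1)], [("eNOSa", 1), ("NO", 1)],
           "k_no_prod", tags=tags),
        _r(P, "no_deg", [("NO", 1)], [], "k_no_deg", tags=tags),
        _r(P, "sgc_act", [("NO", 1), ("sGC", 1)], [("NO", 1), ("sGCa", 1)],
           "k_sgc_act", tags=tags),
        _r(P, "sgc_deact", [("sGCa", 1)], [("sGC", 1)], "k_sgc_deact",
           tags=tags),
        _r(P, "cgmp_prod", [("sGCa", 1)], [("sGCa", 1), ("cGMP", 1)],
           "k_cgmp_prod", tags=tags),
        _r(P, "cgmp_deg", [("cGMP", 1)], [], "k_cgmp_deg", tags=tags),
        _r(P, "pkg_act", [("cGMP", 1), ("PKG", 1)],
           [("cGMP", 1), ("PKGa", 1)], "k_pkg_act", tags=tags),
        _r(P, "pkg_deact", [("PKGa", 1)], [("PKG", 1)], "k_pkg_deact",
           tags=tags),
    ]


_BLOCKS = (
    build_thrombin_receptor_block,
    build_histamine_receptor_block,
    build_calcium_block,
    build_mlck_cam_block,
    build_rho_rock_block,
    build_myocp_cpi17_block,
    build_vegf_erk_block,
    build_no_pkg_block,
)

_EQ_CACHE: dict[str, np.ndarray] = {}


def build_model(
    cfg: StimulusConfig | None = None,
    baseline: BaselineConcentrations | None = None,
    params: dict | None = None,
    equilibrate: bool = True,
) -> ReactionNetwork:
    """Assemble the full network for one stimulus configuration.

    The resting cell (all mediators zero) is first relaxed to its steady
    state so that an unstimulated run is a fixed point; mediator doses are
    then added as initial concentrations.  Expression multipliers scale
    pools before equilibration; cascade switches are applied before
    equilibration as well.
    """
    if cfg is None:
        cfg = StimulusConfig()
    if baseline is None:
        baseline = BaselineConcentrations()
    P = load_params()
    if params:
        unknown = set(params) - set(P)
        if unknown:
            raise NetworkError(f"unknown parameters: {sorted(unknown)}")
        P = {**P, **params}

    pools = dict(baseline.pools)
    vegf_dose_scale = 1.0
    for comp, mult in cfg.expression_multipliers.items():
        target = EXPRESSION_COMPONENTS[comp]
        if target is None:
            vegf_dose_scale *= mult
        else:
            pools[target] *= mult

    base = BaselineConcentrations(pools)
    species = baseline_species(base)
    reactions = [r for block in _BLOCKS for r in block(P)]
    net = ReactionNetwork(species, reactions)
    if cfg.cascade_switches:
        net = net.apply_switch(cfg.cascade_switches)

    if equilibrate:
        key = json.dumps(
            [sorted(P.items()), sorted(pools.items()),
             sorted(cfg.cascade_switches.items()),
             sorted(cfg.overrides.items())],
            default=float,
        )
        key = hashlib.sha1(key.encode()).hexdigest()
        if key not in _EQ_CACHE:
            y0 = net.initial_state()
            sol = solve_ivp(
                net.rhs, (0.0, 3.0e5), y0, method="LSODA",
                rtol=1e-10, atol=1e-12,
            )
            if not sol.success:
                raise NetworkError(
                    f"baseline equilibration failed: {sol.message}"
                )
            _EQ_CACHE[key] = np.clip(sol.y[:, -1], 0.0, None)
        y_eq = _EQ_CACHE[key].copy()
        for i, sp in enumerate(net.species):
            sp.initial_concentration = float(y_eq[i])

    for sp_id, value in cfg.overrides.items():
        net.species[net.species_index(sp_id)].initial_concentration = float(
            value
        )
    net.species[net.species_index("Thr")].initial_concentration = cfg.thrombin
    net.species[net.species_index("His")].initial_concentration = cfg.histamine
    net.species[net.species_index("VEGF")].initial_concentration = (
        cfg.vegf * vegf_dose_scale
    )
    return net
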