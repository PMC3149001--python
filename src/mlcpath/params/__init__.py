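"""Kinetic parameter table: seed values, provenance, calibrated set.

Every rate constant has a provenance class mirroring how pathway models
are usually parameterized:

* ``published_model`` — order-of-magnitude values carried over from prior
  ODE models of the constituent cascades (Ca2+/CaM/MLCK, IP3/Ca2+ release,
  Ras-Raf-MEK-ERK, NO/cGMP);
* ``analogous_pair`` — values seeded from a kinetically analogous protein
  pair (e.g. the Rho GDP/GTP cycle seeded from the Ras cycle);
* ``fitted`` — the minority of constants estimated by trust-region least
  squares against the printed validation features (see ``calibrate``).

``load_params()`` returns the calibrated table shipped with the package
(``calibrated.yaml``); ``seed_params()`` returns the pre-calibration seed.
Units: first-order constants 1/s, second-order 1/(uM s), bimolecular with
stoichiometry 2 in 1/(uM^2 s).
"""

from __future__ import annotations

import functools
from importlib import resources

import yaml

__all__ = ["SEED", "seed_params", "load_params", "provenance", "PROVENANCE_CLASSES"]

PROVENANCE_CLASSES = ("published_model", "analogous_pair", "fitted")

#: name -> (seed value, provenance class)
SEED: dict[str, tuple[float, str]] = {
    # --- thrombin receptor block
    "k_par1_bind": (20.0, "published_model"),  # thrombin-PAR-1 engagement, 1/(uM s)
    "k_par1_unbind": (1e-4, "published_model"),
    "k_thr_clear": (1e-4, "published_model"),
    "k_par1_des": (6e-4, "fitted"),
    "k_par1_rec": (1e-4, "published_model"),
    "k_gq_act": (20.0, "published_model"),
    "k_gq_deact": (0.1, "published_model"),
    "k_g12_act": (2.0, "analogous_pair"),
    "k_g12_deact": (0.01, "analogous_pair"),
    "k_gef_act": (0.04, "analogous_pair"),
    "k_gef_deact": (0.01, "analogous_pair"),
    # --- histamine receptor block
    "k_h1_bind": (20.0, "analogous_pair"),
    "k_h1_unbind": (0.005, "analogous_pair"),
    "k_h1_des": (4e-4, "fitted"),
    "k_gq_act_his": (20.0, "analogous_pair"),
    "k_enos_act_his": (10.0, "fitted"),
    # --- calcium block
    "k_plcb_act": (2.0, "published_model"),
    "k_plcb_deact": (0.1, "published_model"),
    "k_ip3_prod": (0.15, "published_model"),
    "k_dag_prod": (0.1, "published_model"),
    "k_ip3_deg": (0.03, "published_model"),
    "k_dag_deg": (0.01, "published_model"),
    "k_ca_rel": (0.6, "published_model"),
    "k_ca_leak": (1.67e-3, "published_model"),
    "k_ca_pump": (0.05, "published_model"),
    "k_ca_in": (6e-3, "published_model"),  # vs EXT = 1 uM, so uM/s
    "k_ca_in_rcpt": (0.012, "fitted"),     # receptor-operated entry
    "k_ca_out": (0.12, "published_model"),
    # --- CaM / MLCK block
    "k_cam1_f": (5.0, "published_model"),
    "k_cam1_b": (10.0, "published_model"),
    "k_cam2_f": (5.0, "published_model"),
    "k_cam2_b": (10.0, "published_model"),
    "k_mlck_bind": (10.0, "published_model"),
    "k_mlck_unbind": (1.0, "published_model"),
    "k_mlck_phos": (0.02, "fitted"),
    "k_mlckp_dephos": (5e-3, "fitted"),
    "k_mlck_cat": (0.05, "fitted"),
    "k_mlck_cat2": (0.05, "fitted"),
    "k_mlckp_cat": (8e-3, "fitted"),
    "k_mlckp_cat2": (8e-3, "fitted"),
    # --- Rho / ROCK block
    "k_rho_act": (0.05, "analogous_pair"),
    "k_rho_gap": (5e-3, "analogous_pair"),
    "k_rock_open": (0.15, "fitted"),
    "k_rock_close": (0.01, "fitted"),
    "k_rock_act_rho": (0.1, "fitted"),
    "k_rock_act_pkg": (0.045, "fitted"),
    "k_rock_deact": (3e-3, "fitted"),
    "k_rock_cat": (0.0136, "fitted"),
    "k_rock_cat2": (0.0136, "fitted"),
    "k_mypt_phos": (0.02, "fitted"),
    "k_mypt_dephos": (1e-3, "published_model"),
    # --- MYCP / CPI-17 block
    "k_pkc_act": (0.02, "published_model"),
    "k_pkc_deact": (0.005, "published_model"),
    "k_cpi_phos": (8e-3, "fitted"),
    "k_cpi_dephos": (1e-3, "fitted"),
    "k_cpi_bind": (50.0, "published_model"),
    "k_cpi_unbind": (0.04, "published_model"),
    "k_mycp_cat": (0.1, "fitted"),
    "k_mycp_cat2": (0.1, "fitted"),
    # --- VEGF / ERK block
    "k_vegf_bind": (20.0, "published_model"),
    "k_vegf_unbind": (1e-3, "published_model"),
    "k_vr2_int": (4e-3, "fitted"),
    "k_plcg_act": (2.0, "published_model"),
    "k_plcg_deact": (0.1, "published_model"),
    "k_ip3_prod_g": (0.05, "analogous_pair"),
    "k_dag_prod_g": (0.1, "analogous_pair"),
    "k_enos_act_vegf": (10.0, "fitted"),
    "k_ras_act": (0.3, "published_model"),
    "k_ras_gap": (0.01, "published_model"),
    "k_raf_act": (0.05, "published_model"),
    "k_raf_act_pkg": (0.002, "fitted"),
    "k_raf_deact": (0.01, "published_model"),
    "k_mek_phos": (0.1, "published_model"),
    "k_mek_dephos": (0.01, "published_model"),
    "k_erk_phos": (0.1, "published_model"),
    "k_erk_dephos": (0.01, "published_model"),
    # --- NO / PKG block
    "k_enosp_deact": (2e-3, "published_model"),
    "k_enos_bind": (10.0, "published_model"),
    "k_enos_unbind": (0.01, "published_model"),
    "k_no_prod": (1.0, "published_model"),
    "k_no_deg": (0.1, "published_model"),
    "k_sgc_act": (10.0, "published_model"),
    "k_sgc_deact": (0.02, "published_model"),
    "k_cgmp_prod": (0.01, "published_model"),
    "k_cgmp_deg": (5e-4, "fitted"),
    "k_pkg_act": (5e-4, "published_model"),
    "k_pkg_deact": (8e-4, "fitted"),
}


def seed_params() -> dict[str, float]:
    """Pre-calibration seed values."""
    return {name: value for name, (value, _) in SEED.items()}


def provenance() -> dict[str, str]:
    """Provenance class per parameter."""
    return {name: cls for name, (_, cls) in SEED.items()}


@functools.lru_cache(maxsize=1)
def _calibrated() -> dict[str, float]:
    ref = resources.files(__package__) / "calibrated.yaml"
    if ref.is_file():
        data = yaml.safe_load(ref.read_text())
        table = seed_params()
        unknown = set(data) - set(table)
        if unknown:
            raise KeyError(f"calibrated.yaml has unknown parameters: {unknown}")
        table.update({k: float(v) for k, v in data.items()})
        return table
    return seed_params()


def load_params() -> dict[str, float]:
    """Calibrated parameter table (falls back to the seed if absent)."""
    return dict(_calibrated())
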