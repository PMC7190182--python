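"""Bundled example data for a two-group bilateral canal study.

Group-by-side summary statistics (cell means and SDs for the nine canal
parameters), a nine-parameter set of nominal interaction p-values, and
scoliosis curve records with Cobb angles, representative of an AIS-versus-
control semicircular-canal morphometry study. These serve as defaults for
the cohort simulator and as worked-example inputs for the statistics stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .parameters import PARAMETERS

__all__ = [
    "reference_cell_means",
    "reference_cell_sds",
    "reference_pvalues",
    "curve_records",
    "symmetric_means",
    "default_covariances",
]

# (group, side) -> mean, per parameter. Groups: AIS (scoliosis) vs control.
_CELLS = {
    # parameter: (AIS L, AIS R, control L, control R), (sd AIS L, ...)
    "angle_lateral_superior": ((88.72, 89.72, 92.06, 92.04), (6.85, 4.52, 5.90, 6.97)),
    "angle_superior_posterior": ((87.47, 87.00, 88.02, 86.74), (3.44, 3.73, 4.54, 5.23)),
    "lateral_inclination": ((1.46, 5.03, 5.21, 4.72), (3.42, 2.15, 3.03, 3.88)),
    "midline_distance_lateral": ((42.74, 43.20, 44.12, 43.86), (2.12, 1.89, 1.89, 1.94)),
    "min_csa_superior": ((1.27, 1.20, 1.31, 1.21), (0.74, 0.68, 0.72, 0.51)),
    "min_csa_lateral": ((1.50, 1.51, 1.26, 1.41), (0.85, 0.80, 0.61, 0.64)),
    "min_csa_posterior": ((1.87, 1.43, 1.30, 1.39), (0.97, 0.64, 0.55, 0.47)),
    "angle_lateral_posterior": ((91.07, 89.30, 85.71, 87.65), (4.70, 4.81, 4.68, 5.28)),
    "midline_distance_posterior": ((40.80, 41.20, 41.86, 41.89), (2.11, 2.16, 2.31, 2.13)),
}

#: Nominal group-by-side interaction p-values for the nine parameters.
_PVALUES = {
    "angle_lateral_superior": 0.6573,
    "angle_superior_posterior": 0.6669,
    "lateral_inclination": 0.0012,
    "midline_distance_lateral": 0.3652,
    "min_csa_superior": 0.8941,
    "min_csa_lateral": 0.4356,
    "min_csa_posterior": 0.0604,
    "angle_lateral_posterior": 0.0548,
    "midline_distance_posterior": 0.5124,
}

# patient_id, curve_type, cobb angles (biphasic curves have two)
_CURVES = [
    (1, "R. Thoracic", (47,)), (2, "R. Thoracic", (39,)), (3, "R. Thoracic", (56,)),
    (4, "Biphasic", (42, 46)), (5, "Biphasic", (50, 50)), (6, "R. Lumbar", (50,)),
    (7, "R. Thoracic", (42,)), (8, "Biphasic", (34, 35)), (9, "Biphasic", (54, 52)),
    (10, "Biphasic", (26, 29)), (11, "R. Thoracic", (52,)), (12, "R. Thoracic", (40,)),
    (13, "R. Thoracic", (42,)), (14, "Biphasic", (42, 38)), (15, "Biphasic", (58, 54)),
    (16, "R. Thoracic", (56,)), (17, "Biphasic", (52, 48)), (18, "R. Thoracic", (40,)),
    (19, "L. Lumbar", (60,)), (20, "R. Thoracic", (70,)),
]

# Within-subject R/L correlation implied by the reference control summaries:
# with side SDs 3.88 / 3.03 and an R-L difference SD of 3.25,
# rho = (var_R + var_L - var_diff) / (2 sd_R sd_L) ~= 0.58.
DEFAULT_SIDE_CORRELATION = 0.58


def reference_cell_means() -> dict[str, dict[tuple[str, str], float]]:
    """Group-by-side cell means per parameter."""
    out = {}
    for p, ((al, ar, cl, cr), _) in _CELLS.items():
        out[p] = {("AIS", "L"): al, ("AIS", "R"): ar,
                  ("control", "L"): cl, ("control", "R"): cr}
    return out


def reference_cell_sds() -> dict[str, dict[tuple[str, str], float]]:
    """Group-by-side cell sample SDs per parameter."""
    out = {}
    for p, (_, (al, ar, cl, cr)) in _CELLS.items():
        out[p] = {("AIS", "L"): al, ("AIS", "R"): ar,
                  ("control", "L"): cl, ("control", "R"): cr}
    return out


def reference_pvalues() -> dict[str, float]:
    """Nominal interaction p-values for the nine parameters."""
    return dict(_PVALUES)


def curve_records() -> pd.DataFrame:
    """Scoliosis curve-pattern records: patient_id, curve_type, cobb1[, cobb2]."""
    rows = []
    for pid, ctype, angles in _CURVES:
        rows.append({
            "patient_id": f"AIS{pid:03d}",
            "curve_type": ctype,
            "cobb1": float(angles[0]),
            "cobb2": float(angles[1]) if len(angles) > 1 else np.nan,
        })
    return pd.DataFrame(rows)


def symmetric_means() -> dict[str, dict[tuple[str, str], float]]:
    """Side- and group-symmetric null means: the control side-average of
    each parameter in every cell. Used as the simulator default so that any
    group-by-side interaction comes only from ``interaction_delta``."""
    out = {}
    for p, ((_, _, cl, cr), _) in _CELLS.items():
        m = 0.5 * (cl + cr)
        out[p] = {(g, s): m for g in ("AIS", "control") for s in ("R", "L")}
    return out


def default_covariances(
    rho: float = DEFAULT_SIDE_CORRELATION,
) -> dict[str, tuple[float, float, float]]:
    """Per-parameter (var_R, var_L, cov_RL) pooled over groups from the
    reference SDs, with within-subject side correlation ``rho``."""
    out = {}
    for p, (_, (sal, sar, scl, scr)) in _CELLS.items():
        sd_l = float(np.sqrt(0.5 * (sal**2 + scl**2)))
        sd_r = float(np.sqrt(0.5 * (sar**2 + scr**2)))
        out[p] = (sd_r**2, sd_l**2, rho * sd_r * sd_l)
    return out


def parameter_names() -> tuple[str, ...]:
    return PARAMETERS
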