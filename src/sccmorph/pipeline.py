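"""End-to-end drivers: phantom cohorts through segmentation, morphometry
and statistics, plus the file-based pipeline used by the command line.

The phantom-cohort simulator is the package's in-silico study: two groups
of subjects, each with a bilateral labyrinth whose geometry varies
realistically between subjects and sides, a controllable group-by-side
effect on the lateral-canal inclination, and every measurement produced by
actually segmenting and measuring synthetic image volumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import morphometry as mm
from . import phantom as ph
from . import segment as sg
from .parameters import PARAMETERS

log = logging.getLogger(__name__)

__all__ = [
    "PhantomCohortConfig",
    "simulate_phantom_subject",
    "simulate_phantom_cohort",
    "run_pipeline",
]

_DEF_NORMALS_R = {
    "lateral": np.array([0.0, 0.0, 1.0]),
    "superior": np.array([1.0, 1.0, 0.0]) / np.sqrt(2),
    "posterior": np.array([1.0, -1.0, 0.0]) / np.sqrt(2),
}


@dataclass
class PhantomCohortConfig:
    """Study conditions of the in-silico cohort.

    Geometry means follow adult labyrinth scale (canal ring radius ~3 mm,
    lumen radius ~0.8 mm, lateral-most extent ~43 mm from the midline);
    between-subject and between-side variability put the per-side
    inclination SD near 2.7 deg with a strong bilateral correlation, since
    both labyrinths of one head develop symmetrically. The grid is a
    0.5 mm working resolution so that a full two-group study (39 subjects,
    both sides) segments and measures in seconds per replicate.
    """

    voxel_spacing_mm: float = 0.5
    ring_radius_mm: float = 3.0
    ring_radius_sd: float = 0.10  # between subjects
    tube_radius_mm: float = 0.8
    tube_radius_sd: float = 0.03  # between subjects
    tube_radius_side_sd: float = 0.03  # between sides within a subject
    noise_sd: float = 5.0  # intensity units; lumen-background contrast is 90
    pad_mm: float = 1.2
    center_x_mm: float = 39.5  # labyrinth centre offset from the midline
    center_x_subject_sd: float = 1.2
    center_x_side_sd: float = 0.8
    center_yz_sd: float = 1.0
    base_inclination_deg: float = 4.5
    inclination_subject_sd: float = 2.5  # shared by both sides
    inclination_side_sd: float = 1.0  # independent per side
    normal_jitter_deg: float = 1.5  # superior/posterior plane jitter
    division_spacing: float = 0.7
    refine_iterations: int = 0
    supersample: int = 1
    min_component_voxels: int = 40
    approx_path_points: int = 25

    def morph_config(self) -> mm.MorphometryConfig:
        return mm.MorphometryConfig(
            division_spacing=self.division_spacing,
            refine_iterations=self.refine_iterations,
        )


def _jitter_normal(n: np.ndarray, sd_deg: float, rng: np.random.Generator) -> np.ndarray:
    n = n + rng.normal(0.0, np.radians(sd_deg), 3)
    return n / np.linalg.norm(n)


def simulate_phantom_subject(
    subject_rng: np.random.Generator,
    inclination_by_side: dict[str, float],
    config: PhantomCohortConfig | None = None,
    noise_seed: int = 0,
    keep_artifacts: dict | None = None,
) -> tuple[dict[str, float], dict[str, float], dict[str, dict[str, float]]]:
    """Build, segment and measure one subject's bilateral phantoms.

    Returns ``(values_R, values_L, truth_values)`` where each values dict
    maps parameter name to the measured (or NaN) value and ``truth_values``
    holds the per-side analytic truth for the same subject. If a dict is
    passed as ``keep_artifacts`` it is filled with the per-side labyrinth,
    image, mesh and mask (for QC and debugging).
    """
    cfg = config or PhantomCohortConfig()
    ring = cfg.ring_radius_mm + subject_rng.normal(0.0, cfg.ring_radius_sd)
    tube_subj = cfg.tube_radius_mm + subject_rng.normal(0.0, cfg.tube_radius_sd)
    dx_subj = subject_rng.normal(0.0, cfg.center_x_subject_sd)
    mcfg = cfg.morph_config()

    measured: dict[str, dict[str, float]] = {}
    truth_vals: dict[str, dict[str, float]] = {}
    for k, side in enumerate(("R", "L")):
        sgn = 1.0 if side == "R" else -1.0
        th = np.radians(inclination_by_side[side])
        # the side's inclination is a whole-labyrinth roll about +x: it
        # changes the lateral inclination by exactly th while leaving
        # inter-canal angles, midline extents (x is preserved) and lumen
        # areas untouched
        c, s = np.cos(th), np.sin(th)
        roll = np.array([[1.0, 0, 0], [0, c, -s], [0, s, c]])
        normals = {
            "lateral": roll @ np.array([0.0, 0.0, 1.0]),
            "superior": roll @ _jitter_normal(
                _DEF_NORMALS_R["superior"] * np.array([sgn, 1, 1]),
                cfg.normal_jitter_deg, subject_rng),
            "posterior": roll @ _jitter_normal(
                _DEF_NORMALS_R["posterior"] * np.array([sgn, 1, 1]),
                cfg.normal_jitter_deg, subject_rng),
        }
        center = np.array([
            sgn * (cfg.center_x_mm + dx_subj
                   + subject_rng.normal(0.0, cfg.center_x_side_sd)),
            subject_rng.normal(0.0, cfg.center_yz_sd),
            subject_rng.normal(0.0, cfg.center_yz_sd),
        ])
        tube = tube_subj + subject_rng.normal(0.0, cfg.tube_radius_side_sd)
        tube = float(np.clip(tube, 0.4, 0.45 * ring))
        lab = ph.make_labyrinth(side, center, ring, tube, normals=normals)
        spec = ph.PhantomSpec(
            {side: lab}, voxel_spacing_mm=cfg.voxel_spacing_mm,
            noise_sd=cfg.noise_sd, seed=noise_seed + k, pad_mm=cfg.pad_mm,
        )
        img, truth = ph.generate_intensity_phantom(spec)
        tr = ph.truth_report(truth)
        truth_vals[side] = dict(zip(tr["parameter"], tr["value"]))
        paths = {
            name: geom.points(np.linspace(0, 1, cfg.approx_path_points))
            for name, geom in lab.canals.items()
        }
        try:
            mesh, mask = sg.two_pass_surface(
                img, min_component_voxels=cfg.min_component_voxels,
                supersample=cfg.supersample, return_mask=True,
            )
            vals, segments = mm.measure_side(
                mesh, paths, side, mask=mask, intensity=img, config=mcfg
            )
            if keep_artifacts is not None:
                keep_artifacts[side] = {
                    "labyrinth": lab, "image": img, "mesh": mesh,
                    "mask": mask, "paths": paths, "segments": segments,
                }
        except ValueError as exc:
            log.warning("phantom subject side %s failed: %s", side, exc)
            vals = {p: float("nan") for p in PARAMETERS}
        measured[side] = vals
    return measured["R"], measured["L"], truth_vals


def simulate_phantom_cohort(
    n_per_group: tuple[int, int] = (20, 19),
    lateral_delta_deg: float = 4.1,
    seed: int = 0,
    config: PhantomCohortConfig | None = None,
    groups: tuple[str, str] = ("AIS", "control"),
) -> pd.DataFrame:
    """Simulate a two-group bilateral cohort end to end.

    Every subject's left and right labyrinth is generated as an intensity
    phantom, segmented with two-pass GrowCut, and measured; the AIS group's
    left lateral canal is tilted ``lateral_delta_deg`` degrees more
    horizontal (population group-by-side interaction = +delta on R-L).
    Returns the long-format measurement table. Deterministic given the seed.
    """
    cfg = config or PhantomCohortConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for g_i, (group, n) in enumerate(zip(groups, n_per_group)):
        for s_i in range(n):
            sid = f"{group}{s_i + 1:03d}"
            # independent child stream per subject (replayable)
            subject_seed = int(rng.integers(0, 2**31 - 2))
            srng = np.random.default_rng(subject_seed)
            base = cfg.base_inclination_deg + srng.normal(
                0.0, cfg.inclination_subject_sd)
            incl = {
                "R": base + srng.normal(0.0, cfg.inclination_side_sd),
                "L": base + srng.normal(0.0, cfg.inclination_side_sd)
                - (lateral_delta_deg if g_i == 0 else 0.0),
            }
            vr, vl, _ = simulate_phantom_subject(srng, incl, cfg, subject_seed)
            for side, vals in (("R", vr), ("L", vl)):
                for p in PARAMETERS:
                    rows.append({
                        "subject_id": sid, "group": group, "side": side,
                        "parameter": p, "value": vals[p],
                    })
    return pd.DataFrame(rows)


def run_pipeline(config) -> dict[str, str]:
    """Run the configured stages, writing artifacts under ``out_dir``.

    Artifacts: the per-subject measurement CSV, a group-by-side summary
    table, the FDR-adjusted model report (CSV + JSON), optional curve-type
    summaries, and a run log recording the full configuration and seed.
    Reruns with the same configuration are byte-identical for the
    deterministic stages.

    Returns a mapping of artifact names to file paths.
    """
    import json
    from pathlib import Path

    from . import io as sio
    from . import stats as st

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("sccmorph")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        log.info("pipeline configuration:\n%s", config.to_yaml())
        artifacts["log"] = str(log_path)

        if config.phantom is not None:
            p = config.phantom
            cohort_cfg = PhantomCohortConfig(
                voxel_spacing_mm=p.voxel_spacing_mm,
                noise_sd=p.noise_sd,
                division_spacing=p.division_spacing,
                refine_iterations=p.refine_iterations,
                supersample=p.supersample,
            )
            table = simulate_phantom_cohort(
                n_per_group=tuple(p.n_per_group),
                lateral_delta_deg=p.lateral_delta_deg,
                seed=config.seed,
                config=cohort_cfg,
            )
            cohort_path = out / "measurements.csv"
            sio.write_cohort_csv(table, cohort_path)
            artifacts["measurements"] = str(cohort_path)
            log.info("phantom cohort: %d rows -> %s", len(table), cohort_path)
        elif config.cohort_csv is not None:
            table = sio.read_cohort_csv(config.cohort_csv)
            log.info("cohort loaded from %s (%d rows)", config.cohort_csv, len(table))
        else:
            raise ValueError("config provides neither a phantom stage nor a cohort_csv")

        if config.run_stats:
            can_model = all(
                table[table["parameter"] == p_]["group"].nunique() == 2
                and min(table[table["parameter"] == p_]
                        .groupby("group")["subject_id"].nunique()) >= 2
                for p_ in table["parameter"].unique()
            )
            summary = st.summarize_groups(table)
            summary_path = out / "group_summary.csv"
            summary.to_csv(summary_path, index=False)
            artifacts["group_summary"] = str(summary_path)
            if can_model:
                results, fdr = st.run_all_parameters(table, q=config.stats.q)
                fdr_path = out / "fdr_report.csv"
                fdr.to_frame().to_csv(fdr_path, index=False)
                artifacts["fdr_report"] = str(fdr_path)
                report = {
                    name: {
                        "interaction": r.interaction,
                        "interaction_ci": list(r.interaction_ci),
                        "p_value": r.p_value,
                        "group_diffs": {g: list(v) for g, v in r.group_diffs.items()},
                        "n_per_group": list(r.n_per_group),
                        "df": r.df,
                        "method": r.method,
                    }
                    for name, r in results.items()
                }
                model_path = out / "model_report.json"
                model_path.write_text(json.dumps(report, indent=2))
                artifacts["model_report"] = str(model_path)
                log.info("models fit for %d parameters (q=%g)", len(results), config.stats.q)
            else:
                log.warning("fewer than 2 subjects per group: skipping models")
            if config.stats.curves_csv:
                curves = sio.read_curves_csv(config.stats.curves_csv)
                strat = st.summarize_by_curve_type(table, curves)
                cobb = st.summarize_cobb(curves)
                strat_path = out / "curve_type_summary.csv"
                cobb_path = out / "cobb_summary.csv"
                strat.to_csv(strat_path, index=False)
                cobb.to_csv(cobb_path, index=False)
                artifacts["curve_type_summary"] = str(strat_path)
                artifacts["cobb_summary"] = str(cobb_path)
        return artifacts
    finally:
        root.removeHandler(handler)
        handler.close()
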