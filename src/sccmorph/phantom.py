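"""Synthetic labyrinth phantoms and measurement-cohort simulation.

Every downstream stage (segmentation, morphometry, statistics) is validated
against phantoms with analytically known geometry. A phantom labyrinth is
three planar circular arcs (roughly 270 deg of a torus each) meeting a
spherical vestibule blob, with the superior and posterior arcs additionally
sharing a common-crus blob — the simplest geometry carrying all measurable
features: canal planes, lumen cross-sections, junction endpoints, and
lateral-most extent from the midline.

The cohort simulator emulates a two-group (AIS vs control) bilateral
measurement table with a controllable group-by-side interaction on the
lateral-canal inclination and an unstructured within-subject right/left
covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .parameters import CANALS, PARAMETERS
from .planes import lateral_inclination, orient_normal, plane_angle
from .volume import LabeledVolume

__all__ = [
    "GeometryError",
    "CanalGeometry",
    "LabyrinthGeometry",
    "PhantomSpec",
    "PhantomTruth",
    "CohortSimSpec",
    "make_labyrinth",
    "generate_canal_phantom",
    "generate_intensity_phantom",
    "intensity_from_labels",
    "truth_report",
    "generate_measurement_table",
]

LUMEN_INTENSITY = 100.0
BACKGROUND_INTENSITY = 10.0

# label offsets: right side 1..5, left side 11..15
_CANAL_LABEL = {"lateral": 1, "superior": 2, "posterior": 3}
_VESTIBULE_LABEL = 4
_CRUS_LABEL = 5
_SIDE_OFFSET = {"R": 0, "L": 10}

_DEFAULT_NORMALS_R = {
    "lateral": np.array([0.0, 0.0, 1.0]),
    "superior": np.array([1.0, 1.0, 0.0]) / np.sqrt(2),
    "posterior": np.array([1.0, -1.0, 0.0]) / np.sqrt(2),
}


class GeometryError(ValueError):
    """Raised when a phantom specification yields overlapping canals."""


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero vector")
    return v / n


def _as_profile(tube_radius: float | Callable[[np.ndarray], np.ndarray]):
    if callable(tube_radius):
        return tube_radius
    r = float(tube_radius)
    return lambda t: np.full_like(np.asarray(t, dtype=float), r)


@dataclass
class CanalGeometry:
    """One canal: a planar circular arc with a tube-radius profile.

    The arc is parameterized by t in [0, 1], angle = arc_start + t*arc_span
    in the in-plane (u, v) basis with u x v = plane_normal.
    """

    plane_normal: np.ndarray
    ring_center: np.ndarray
    ring_radius_mm: float
    u: np.ndarray
    v: np.ndarray
    arc_start: float
    arc_span: float
    tube_radius: float | Callable[[np.ndarray], np.ndarray]

    def __post_init__(self) -> None:
        self.plane_normal = _unit(self.plane_normal)
        self.ring_center = np.asarray(self.ring_center, dtype=float).reshape(3)
        self.u = _unit(self.u)
        self.v = _unit(self.v)
        if self.ring_radius_mm <= 0:
            raise ValueError("ring radius must be > 0")
        if self.max_tube_radius() <= 0 or self.max_tube_radius() >= self.ring_radius_mm:
            raise ValueError("require ring_radius > max tube_radius > 0")

    def radius_at(self, t: np.ndarray) -> np.ndarray:
        return _as_profile(self.tube_radius)(np.asarray(t, dtype=float))

    def max_tube_radius(self) -> float:
        return float(np.max(self.radius_at(np.linspace(0, 1, 513))))

    def points(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        phi = self.arc_start + t * self.arc_span
        return (
            self.ring_center
            + self.ring_radius_mm
            * (np.cos(phi)[..., None] * self.u + np.sin(phi)[..., None] * self.v)
        )

    def arc_length(self) -> float:
        return self.ring_radius_mm * self.arc_span

    def distance_to_arc(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Distance from points to the arc and the arc parameter t of the
        nearest arc point (ends clamp)."""
        rel = np.asarray(pts, dtype=float) - self.ring_center
        a = rel @ self.u
        b = rel @ self.v
        phi = np.arctan2(b, a)
        delta = np.mod(phi - self.arc_start, 2 * np.pi)
        t = delta / self.arc_span
        outside = delta > self.arc_span
        # clamp to the nearer end by angular distance
        to_end = delta - self.arc_span
        to_start = 2 * np.pi - delta
        t = np.where(outside, np.where(to_end < to_start, 1.0, 0.0), t)
        nearest = self.points(t)
        dist = np.linalg.norm(pts - nearest, axis=-1)
        return dist, t


@dataclass
class LabyrinthGeometry:
    """Three canals of one side plus the vestibule and common-crus blobs."""

    side: str
    canals: dict[str, CanalGeometry]
    vestibule_center: np.ndarray
    vestibule_radius: float
    crus_center: np.ndarray
    crus_radius: float

    def __post_init__(self) -> None:
        if self.side not in ("R", "L"):
            raise ValueError("side must be 'R' or 'L'")
        self.vestibule_center = np.asarray(self.vestibule_center, dtype=float)
        self.crus_center = np.asarray(self.crus_center, dtype=float)


@dataclass
class PhantomSpec:
    """Full phantom: one or two labyrinths on a common voxel grid."""

    sides: dict[str, LabyrinthGeometry]
    voxel_spacing_mm: float = 0.28
    noise_sd: float = 0.05 * LUMEN_INTENSITY
    seed: int = 0
    pad_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.voxel_spacing_mm <= 0:
            raise ValueError("voxel_spacing_mm must be > 0")
        if not self.sides:
            raise ValueError("at least one side required")


@dataclass
class CanalTruth:
    """Analytic ground truth for one canal of one side."""

    normal: np.ndarray
    centerline: np.ndarray  # interior arc samples, (N, 3) world mm
    min_csa_mm2: float
    max_abs_x_mm: float
    junction_points: np.ndarray  # (2, 3): arc points at blob-surface crossings
    label: int


@dataclass
class PhantomTruth:
    canals: dict[tuple[str, str], CanalTruth]  # (side, canal) -> truth
    junctions: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)


def make_labyrinth(
    side: str,
    center_mm: np.ndarray,
    ring_radius_mm: float | Mapping[str, float] = 3.2,
    tube_radius: float | Callable | Mapping[str, float | Callable] = 0.6,
    vestibule_radius: float | None = None,
    crus_radius: float | None = None,
    lateral_inclination_deg: float = 0.0,
    normals: Mapping[str, np.ndarray] | None = None,
    crus_height_factor: float = 0.9,
) -> LabyrinthGeometry:
    """Construct a labyrinth of one side with known plane orientations.

    The vestibule sits at ``center_mm``; the common crus lies along the
    intersection line of the superior and posterior canal planes, at
    ``crus_height_factor * superior ring radius`` above the vestibule.
    Canal plane normals default to an orthogonal triad (lateral axial,
    superior/posterior vertical at +-45 deg to the sagittal plane, mirrored
    for the left side); ``lateral_inclination_deg`` tilts the lateral plane
    about the +x axis (positive = anterior edge up).
    """
    center_mm = np.asarray(center_mm, dtype=float).reshape(3)
    sgn = 1.0 if side == "R" else -1.0

    rings = dict(ring_radius_mm) if isinstance(ring_radius_mm, Mapping) else {
        c: float(ring_radius_mm) for c in CANALS
    }
    tubes = dict(tube_radius) if isinstance(tube_radius, Mapping) else {
        c: tube_radius for c in CANALS
    }
    max_tube = max(
        _as_profile(tubes[c])(np.linspace(0, 1, 257)).max() for c in CANALS
    )
    r_vest = 3.0 * max_tube if vestibule_radius is None else float(vestibule_radius)
    r_crus = 2.5 * max_tube if crus_radius is None else float(crus_radius)

    if normals is None:
        th = np.radians(lateral_inclination_deg)
        normals = {
            "lateral": np.array([0.0, -np.sin(th), np.cos(th)]),
            "superior": _DEFAULT_NORMALS_R["superior"] * np.array([sgn, 1, 1]),
            "posterior": _DEFAULT_NORMALS_R["posterior"] * np.array([sgn, 1, 1]),
        }
    n_lat = _unit(normals["lateral"])
    n_sup = _unit(normals["superior"])
    n_post = _unit(normals["posterior"])

    vest = center_mm
    crus_dir = _unit(np.cross(n_sup, n_post))
    if crus_dir[2] < 0:
        crus_dir = -crus_dir
    cc = vest + crus_height_factor * rings["superior"] * crus_dir

    canals: dict[str, CanalGeometry] = {}

    # -- lateral: ring through the vestibule, bulging laterally/posteriorly
    R = rings["lateral"]
    bulge = np.array([sgn, -1.0, 0.0]) / np.sqrt(2)
    bulge = _unit(bulge - (bulge @ n_lat) * n_lat)
    c_lat = vest + R * bulge
    u = _unit(vest - c_lat)
    v = np.cross(n_lat, u)
    phi_v = 0.0  # vestibule at angle 0 in this basis
    d_end = 0.8 * r_vest
    alpha = 2.0 * np.arcsin(min(1.0, d_end / (2 * R)))
    canals["lateral"] = CanalGeometry(
        n_lat, c_lat, R, u, v, phi_v + alpha, 2 * np.pi - 2 * alpha, tubes["lateral"]
    )

    # -- superior and posterior: rings through both the vestibule and the
    #    common crus, taking the major arc between them
    for name, n_c, bulge_pref in (
        ("superior", n_sup, np.array([0.0, 1.0, 0.0])),
        ("posterior", n_post, np.array([0.0, -1.0, 0.0])),
    ):
        R = rings[name]
        chord = cc - vest
        L = np.linalg.norm(chord)
        if L > 1.995 * R:
            raise GeometryError(f"{name} ring radius too small for crus height")
        mid = 0.5 * (vest + cc)
        dhat = _unit(np.cross(n_c, chord))
        if dhat @ bulge_pref < 0:
            dhat = -dhat
        q = np.sqrt(R * R - 0.25 * L * L)
        c_ring = mid + q * dhat
        u = _unit(vest - c_ring)
        v = np.cross(n_c, u)
        rel_cc = cc - c_ring
        phi_cc = np.arctan2(rel_cc @ v, rel_cc @ u)  # phi_v == 0
        delta = np.mod(phi_cc, 2 * np.pi)
        if delta < np.pi:
            start, span = phi_cc, 2 * np.pi - delta
        else:
            start, span = 0.0, delta
        canals[name] = CanalGeometry(n_c, c_ring, R, u, v, start, span, tubes[name])

    return LabyrinthGeometry(side, canals, vest, r_vest, cc, r_crus)


def _grid_world_coords(shape, affine):
    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    pts = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
    return pts @ affine[:3, :3].T + affine[:3, 3]


def _phantom_bounds(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    lo = np.full(3, np.inf)
    hi = np.full(3, -np.inf)
    t = np.linspace(0, 1, 721)
    for lab in spec.sides.values():
        for g in lab.canals.values():
            pts = g.points(t)
            r = g.max_tube_radius()
            lo = np.minimum(lo, pts.min(axis=0) - r)
            hi = np.maximum(hi, pts.max(axis=0) + r)
        for c, r in ((lab.vestibule_center, lab.vestibule_radius),
                     (lab.crus_center, lab.crus_radius)):
            lo = np.minimum(lo, c - r)
            hi = np.maximum(hi, c + r)
    return lo - spec.pad_mm, hi + spec.pad_mm


def _rasterize(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, PhantomTruth]:
    """Shared rasterizer: integer labels, analytic partial-volume occupancy
    (fraction of each voxel inside the lumen, linearized over one voxel),
    the affine, and the ground truth."""
    lo, hi = _phantom_bounds(spec)
    h = spec.voxel_spacing_mm
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / h)) + 1 for i in range(3))
    affine = np.eye(4)
    affine[:3, :3] *= h
    affine[:3, 3] = lo
    world = _grid_world_coords(shape, affine)

    labels = np.zeros(len(world), dtype=np.int16)
    occupancy = np.zeros(len(world), dtype=np.float32)
    claims = np.zeros(len(world), dtype=np.int8)
    truth = PhantomTruth(canals={})

    for side, lab in spec.sides.items():
        off = _SIDE_OFFSET[side]
        blob_centers = np.array([lab.vestibule_center, lab.crus_center])
        blob_radii = np.array([lab.vestibule_radius, lab.crus_radius])
        near_junction = np.zeros(len(world), dtype=bool)
        for c, r in zip(blob_centers, blob_radii):
            near_junction |= np.linalg.norm(world - c, axis=1) <= 1.6 * r

        for name, geom in lab.canals.items():
            # restrict to the arc's bounding box for speed
            t = np.linspace(0, 1, 721)
            pts = geom.points(t)
            rmax = geom.max_tube_radius()
            sel = np.all(
                (world >= pts.min(axis=0) - rmax - 2 * h)
                & (world <= pts.max(axis=0) + rmax + 2 * h),
                axis=1,
            )
            idx = np.nonzero(sel)[0]
            dist, tt = geom.distance_to_arc(world[idx])
            occ = np.clip((geom.radius_at(tt) - dist) / h + 0.5, 0.0, 1.0)
            np.maximum.at(occupancy, idx, occ.astype(np.float32))
            inside = dist <= geom.radius_at(tt)
            vox = idx[inside]
            overlap = vox[(claims[vox] > 0) & ~near_junction[vox]]
            if overlap.size:
                raise GeometryError(
                    f"canals overlap away from junctions on side {side} "
                    f"({name}, {overlap.size} voxels)"
                )
            claims[vox] += 1
            labels[vox] = off + _CANAL_LABEL[name]
            truth.canals[(side, name)] = _canal_truth(
                geom, lab, off + _CANAL_LABEL[name], side, name
            )

        for blob_c, blob_r, blob_l in (
            (lab.vestibule_center, lab.vestibule_radius, _VESTIBULE_LABEL),
            (lab.crus_center, lab.crus_radius, _CRUS_LABEL),
        ):
            d = np.linalg.norm(world - blob_c, axis=1)
            occ = np.clip((blob_r - d) / h + 0.5, 0.0, 1.0).astype(np.float32)
            occupancy = np.maximum(occupancy, occ)
            labels[(d <= blob_r) & (labels == 0)] = off + blob_l
        truth.junctions[side] = {
            "vestibule": lab.vestibule_center.copy(),
            "common_crus": lab.crus_center.copy(),
        }
    return labels.reshape(shape), occupancy.reshape(shape), affine, truth


def generate_canal_phantom(spec: PhantomSpec) -> tuple[LabeledVolume, PhantomTruth]:
    """Voxelize a phantom into a label volume with analytic ground truth.

    Each canal's lumen voxels carry a distinct integer label (vestibule and
    common-crus blobs have their own labels). Deterministic given the spec.

    Raises
    ------
    GeometryError
        If two canal lumens overlap away from the junction blobs.
    """
    labels, _, affine, truth = _rasterize(spec)
    return LabeledVolume(labels, affine), truth


def generate_intensity_phantom(
    spec: PhantomSpec,
) -> tuple[LabeledVolume, PhantomTruth]:
    """T2-like intensity phantom with analytic partial volume.

    Voxel intensity is background plus contrast times the fraction of the
    voxel inside the fluid lumen (linearized over one voxel width), plus
    Gaussian noise of ``spec.noise_sd`` — emulating how MRI integrates
    sub-voxel anatomy rather than binarizing it. Deterministic given the
    spec's seed.
    """
    _, occ, affine, truth = _rasterize(spec)
    img = BACKGROUND_INTENSITY + (LUMEN_INTENSITY - BACKGROUND_INTENSITY) * occ.astype(float)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return LabeledVolume(img, affine), truth


def _canal_truth(
    geom: CanalGeometry, lab: LabyrinthGeometry, label: int, side: str, name: str
) -> CanalTruth:
    """Analytic truth for one canal, restricted to the interior arc
    (between the blob-surface crossings)."""
    t = np.linspace(0, 1, 8001)
    pts = geom.points(t)
    d_vest = np.linalg.norm(pts - lab.vestibule_center, axis=1)
    d_crus = np.linalg.norm(pts - lab.crus_center, axis=1)
    interior = (d_vest > lab.vestibule_radius) & (d_crus > lab.crus_radius)
    if not interior.any():
        raise GeometryError(f"{side} {name}: arc entirely inside junction blobs")
    i0, i1 = np.nonzero(interior)[0][[0, -1]]
    ti = t[i0 : i1 + 1]
    centerline = pts[i0 : i1 + 1]
    junctions = np.array([pts[i0], pts[i1]])

    r = geom.radius_at(ti)
    min_csa = float(np.pi * np.min(r) ** 2)

    # lateral-most extent: surface point x = p_x + r * (cos f * radial_x
    # + sin f * n_x); extremize over the tube angle f analytically
    radial = (centerline - geom.ring_center) / geom.ring_radius_mm
    amp = r * np.sqrt(radial[:, 0] ** 2 + geom.plane_normal[0] ** 2)
    max_abs_x = float(np.max(np.abs(centerline[:, 0]) + amp))

    return CanalTruth(
        normal=geom.plane_normal.copy(),
        centerline=centerline,
        min_csa_mm2=min_csa,
        max_abs_x_mm=max_abs_x,
        junction_points=junctions,
        label=label,
    )


def intensity_from_labels(
    label_vol: LabeledVolume,
    noise_sd: float = 0.05 * LUMEN_INTENSITY,
    seed: int = 0,
    psf_sigma_vox: float = 0.6,
) -> LabeledVolume:
    """T2-like intensity phantom: bright fluid lumen, dark bone, Gaussian
    noise, and a slight Gaussian point-spread blur for partial-volume
    realism. Deterministic given the seed."""
    rng = np.random.default_rng(seed)
    fluid = (label_vol.voxels > 0).astype(float)
    if psf_sigma_vox > 0:
        fluid = ndimage.gaussian_filter(fluid, psf_sigma_vox)
    img = BACKGROUND_INTENSITY + (LUMEN_INTENSITY - BACKGROUND_INTENSITY) * fluid
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return LabeledVolume(img, label_vol.affine.copy())


def truth_report(truth: PhantomTruth, subject_id: str = "phantom") -> pd.DataFrame:
    """The nine canal parameters computed analytically from phantom truth.

    Returns a long-format table (subject_id, side, parameter, value) using
    the same orientation and sign conventions as the measurement pipeline.
    """
    rows = []
    sides = sorted({s for s, _ in truth.canals})
    for side in sides:
        n = {
            c: orient_normal(truth.canals[(side, c)].normal, c, side) for c in CANALS
        }
        vals = {
            "angle_lateral_superior": plane_angle(n["lateral"], n["superior"]),
            "angle_superior_posterior": plane_angle(n["superior"], n["posterior"]),
            "angle_lateral_posterior": plane_angle(n["lateral"], n["posterior"]),
            "lateral_inclination": lateral_inclination(n["lateral"]),
            "midline_distance_lateral": truth.canals[(side, "lateral")].max_abs_x_mm,
            "midline_distance_posterior": truth.canals[(side, "posterior")].max_abs_x_mm,
            "min_csa_lateral": truth.canals[(side, "lateral")].min_csa_mm2,
            "min_csa_superior": truth.canals[(side, "superior")].min_csa_mm2,
            "min_csa_posterior": truth.canals[(side, "posterior")].min_csa_mm2,
        }
        for p in PARAMETERS:
            rows.append(
                {"subject_id": subject_id, "side": side, "parameter": p,
                 "value": float(vals[p])}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class CohortSimSpec:
    """Two-group bilateral cohort with unstructured R/L covariance.

    ``means`` maps parameter -> {(group, side): population mean}; when
    omitted, side- and group-symmetric defaults matching published control
    summaries are used (see :mod:`sccmorph.datasets`). ``covariances`` maps
    parameter -> (var_R, var_L, cov_RL). ``interaction_delta`` (degrees) is
    the population group-by-side contrast on the lateral inclination,
    applied as +delta/2 to the AIS right side and -delta/2 to the AIS left
    side.
    """

    n_per_group: tuple[int, int] = (20, 19)
    means: Mapping[str, Mapping[tuple[str, str], float]] | None = None
    covariances: Mapping[str, tuple[float, float, float]] | None = None
    interaction_delta: float = 0.0
    seed: int = 0
    groups: tuple[str, str] = ("AIS", "control")

    def __post_init__(self) -> None:
        if min(self.n_per_group) < 2:
            raise ValueError("need >= 2 subjects per group")


def _check_pd(cov: tuple[float, float, float], param: str) -> np.ndarray:
    vr, vl, c = cov
    S = np.array([[vr, c], [c, vl]], dtype=float)
    if vr <= 0 or vl <= 0 or np.linalg.det(S) <= 0:
        raise ValueError(f"covariance for {param!r} is not positive definite")
    return S


def generate_measurement_table(spec: CohortSimSpec) -> pd.DataFrame:
    """Simulate a long-format measurement table (one row per
    subject x side x parameter). Deterministic given the seed."""
    from . import datasets

    means = spec.means if spec.means is not None else datasets.symmetric_means()
    covs = (
        spec.covariances
        if spec.covariances is not None
        else datasets.default_covariances()
    )
    rng = np.random.default_rng(spec.seed)
    frames = []
    for g_i, (group, n) in enumerate(zip(spec.groups, spec.n_per_group)):
        sids = [f"{group}{i + 1:03d}" for i in range(n)]
        for param in PARAMETERS:
            mu = np.array([means[param][(group, "R")], means[param][(group, "L")]])
            if param == "lateral_inclination" and g_i == 0:
                mu = mu + np.array([0.5, -0.5]) * spec.interaction_delta
            S = _check_pd(covs[param], param)
            y = rng.multivariate_normal(mu, S, size=n)  # (n, 2): R, L
            frames.append(pd.DataFrame({
                "subject_id": sids * 2,
                "group": group,
                "side": ["R"] * n + ["L"] * n,
                "parameter": param,
                "value": np.concatenate([y[:, 0], y[:, 1]]),
            }))
    return pd.concat(frames, ignore_index=True)
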