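"""Canal morphometry: divisions, centroid spline, plane fits, nine parameters.

Pipeline per side: the labyrinth surface is resliced perpendicular to an
approximate centerline into divisions every 0.25 mm; each division's
cross-sectional area and centre of mass feed a cubic centroid spline, which
is refined by re-slicing perpendicular to itself. Canals are truncated at
the vestibule and common-crus junctions, detected as the first division
(walking outward from mid-canal) whose area exceeds k times the canal's
median area. The canal plane is then fit to the canal's volumetric point
cloud with weights inverse to the squared local cross-sectional area, and
the nine shape parameters follow from the oriented plane normals, the
division areas and the lateral-most extent from the sagittal midline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh
from scipy import interpolate
from scipy.spatial import cKDTree

from .parameters import CANALS, PARAMETERS
from .planes import (
    FitPlane,
    fit_weighted_plane_points,
    lateral_inclination,
    orient_normal,
    plane_angle,
)
from .volume import LabeledVolume

log = logging.getLogger(__name__)

__all__ = [
    "MorphometryConfig",
    "CrossSection",
    "Centerline",
    "CanalSegment",
    "reslice_divisions",
    "centroid_spline",
    "split_canals",
    "min_csa",
    "fit_weighted_plane",
    "midline_distance",
    "segment_midline_distance",
    "measure_side",
    "measure_subject",
]


@dataclass
class MorphometryConfig:
    """Tunable measurement parameters (all lengths in mm)."""

    division_spacing: float = 0.25  # distance between cross-sectional slices
    endpoint_k: float = 2.5  # junction threshold: k x median division area
    refine_iterations: int = 2  # centroid-spline re-slicing passes
    max_center_dist: float = 2.5  # reject loops whose centroid is farther
    min_loop_area: float = 0.05  # reject sliver loops (tangent cuts), mm^2
    cloud_radius_factor: float = 1.3  # canal point assignment, x local r + 1 voxel
    min_sections: int = 4
    max_skipped_fraction: float = 0.2


@dataclass
class CrossSection:
    """One canal division: plane centre, normal, area, optional boundary."""

    center_mm: np.ndarray
    normal: np.ndarray
    area_mm2: float
    polygon: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.area_mm2 <= 0:
            raise ValueError("cross-sectional area must be > 0")


@dataclass
class Centerline:
    """Arc-length resampled centroid path."""

    samples: np.ndarray  # (N, 3), consecutive spacing == `spacing`
    tangents: np.ndarray  # (N, 3) unit
    spacing: float

    @property
    def length(self) -> float:
        return self.spacing * (len(self.samples) - 1)


@dataclass
class CanalSegment:
    """One canal truncated at the vestibule / common-crus junctions."""

    canal: str
    side: str
    centerline: Centerline
    cross_sections: list[CrossSection]
    endpoints: tuple[np.ndarray, np.ndarray]
    plane: FitPlane | None = None
    mesh: trimesh.Trimesh | None = field(default=None, repr=False)

    def areas(self) -> np.ndarray:
        return np.array([s.area_mm2 for s in self.cross_sections])


def _resample_path(points: np.ndarray, spacing: float):
    """Cubic spline through path points, resampled at uniform arc length.

    Returns (samples, unit tangents)."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("path needs at least 2 points")
    # drop consecutive duplicates
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9
    pts = pts[keep]
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    k = min(3, len(pts) - 1)
    spl = interpolate.make_interp_spline(chord, pts, k=k)
    # reparameterize by arc length on a dense sampling
    dense_t = np.linspace(0, chord[-1], max(8 * len(pts), 200))
    dense = spl(dense_t)
    seglen = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arclen[-1]
    s_targets = np.arange(0.0, total + 1e-9, spacing)
    t_of_s = np.interp(s_targets, arclen, dense_t)
    samples = spl(t_of_s)
    tang = spl.derivative()(t_of_s)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    return samples, tang


def _nearest_loop(loops, point, max_dist, min_area):
    best, best_d = None, np.inf
    for lp in loops:
        if lp.area < min_area:  # sliver from a near-tangent cut
            continue
        d = np.linalg.norm(lp.centroid - point)
        if d < best_d:
            best, best_d = lp, d
    if best is None or best_d > max_dist:
        return None
    return best


def reslice_divisions(
    mesh: trimesh.Trimesh,
    approx_path: np.ndarray,
    spacing: float = 0.25,
    max_center_dist: float = 2.5,
    max_skipped_fraction: float = 0.2,
    return_polygons: bool = False,
    min_loop_area: float = 0.05,
) -> list[CrossSection]:
    """Cut the mesh perpendicular to a path at uniform divisions.

    At each arc-length division the mesh-plane intersection loop whose
    centroid lies nearest the path point becomes the division's
    cross-section. Divisions where the plane misses the mesh (or the nearest
    loop is farther than ``max_center_dist``) are skipped with a warning;
    more than ``max_skipped_fraction`` skipped is an error.
    """
    from .sections import slice_loops

    samples, tangents = _resample_path(approx_path, spacing)
    # only faces near the path can contribute relevant loops
    centroids = mesh.triangles_center
    margin = max_center_dist + 2.0
    lo = samples.min(axis=0) - margin
    hi = samples.max(axis=0) + margin
    near = np.all((centroids >= lo) & (centroids <= hi), axis=1)
    faces = np.asarray(mesh.faces)[near]
    vertices = np.asarray(mesh.vertices)
    out: list[CrossSection] = []
    skipped = 0
    for p, t in zip(samples, tangents):
        loops = slice_loops(vertices, faces, p, t, return_polygons)
        best = _nearest_loop(loops, p, max_center_dist, min_loop_area)
        if best is None:
            skipped += 1
            continue
        out.append(CrossSection(best.centroid, best.normal, best.area, best.points))
    if skipped:
        log.warning("reslice_divisions: skipped %d of %d divisions", skipped, len(samples))
    if skipped > max_skipped_fraction * len(samples):
        raise ValueError(
            f"{skipped}/{len(samples)} divisions missed the mesh; "
            "approximate path is too far from the lumen"
        )
    return out


def _check_simple(samples: np.ndarray, spacing: float) -> None:
    """Reject self-intersecting centroid paths: distant-in-arc samples must
    not come closer than half a division spacing."""
    n = len(samples)
    if n < 8:
        return
    sep = max(4, int(np.ceil(2.0 / spacing)))  # ignore neighbours within ~2 mm
    tree = cKDTree(samples)
    pairs = tree.query_pairs(r=max(0.5 * spacing, 0.1), output_type="ndarray")
    if pairs.size and np.any(np.abs(pairs[:, 0] - pairs[:, 1]) > sep):
        raise ValueError("centroid path self-intersects")


def centroid_spline(
    sections: list[CrossSection],
    spacing: float = 0.25,
    mesh: trimesh.Trimesh | None = None,
    refine: int = 2,
    max_center_dist: float = 2.5,
    min_loop_area: float = 0.05,
) -> tuple[Centerline, list[CrossSection]]:
    """Cubic spline through division centres, resampled at 0.25 mm arc length.

    When a mesh is given, the spline is refined: the mesh is re-sliced
    perpendicular to the current spline, centroids are recomputed and the
    spline is refit (``refine`` passes). Returns the centerline and the
    divisions consistent with it.
    """
    if len(sections) < 4:
        raise ValueError("need at least 4 cross-sections for a centroid spline")
    centers = np.array([s.center_mm for s in sections])
    samples, tangents = _resample_path(centers, spacing)
    _check_simple(samples, spacing)
    if mesh is not None:
        # once a centroid path exists the true centre is nearby, so the
        # loop-acceptance radius can tighten to the local tube scale
        areas0 = np.array([s.area_mm2 for s in sections])
        r_med = float(np.sqrt(np.median(areas0) / np.pi))
        refine_dist = min(max_center_dist, max(1.5 * spacing, 0.75 * r_med))
        # pin roughly one tube radius at each end: near the junctions the
        # merged lumen drags re-sliced centroids off the canal axis, which
        # would extend and fold the spline on every pass
        k_pin = max(1, int(round(r_med / spacing)))
        pinned = refine > 0 and len(sections) > 2 * k_pin + 2
        if pinned:
            for _ in range(max(0, refine)):
                mid = reslice_divisions(
                    mesh, samples[k_pin:-k_pin], spacing,
                    max_center_dist=refine_dist, min_loop_area=min_loop_area,
                )
                if len(mid) < 2:
                    break
                sections = sections[:k_pin] + mid + sections[-k_pin:]
                centers = np.array([s.center_mm for s in sections])
                samples, tangents = _resample_path(centers, spacing)
                _check_simple(samples, spacing)
            # the pins only anchored the extent; the final path keeps the
            # freshly measured divisions (pinned originals can kink the ends)
            sections = sections[k_pin:-k_pin]
            centers = np.array([s.center_mm for s in sections])
            samples, tangents = _resample_path(centers, spacing)
            _check_simple(samples, spacing)
    return Centerline(samples, tangents, spacing), sections


def _junction_trim(
    areas: np.ndarray, k: float, centers: np.ndarray | None = None,
    jump_tol: float | None = None,
) -> tuple[int, int]:
    """Indices (lo, hi) of the interior division range: walking outward from
    mid-canal, stop before the first division whose area exceeds k x median
    or whose centre jumps discontinuously (the slicing plane has latched
    onto a neighbouring structure near the junction).

    Raises if neither end blows up (no junction found)."""
    med = np.median(areas)
    n = len(areas)
    mid = n // 2

    def discontinuous(i, j):
        if centers is None or jump_tol is None:
            return False
        return np.linalg.norm(centers[i] - centers[j]) > jump_tol

    hit_lo = hit_hi = -1
    for i in range(mid, -1, -1):
        if areas[i] > k * med or (i < mid and discontinuous(i, i + 1)):
            hit_lo = i
            break
    for i in range(mid, n):
        if areas[i] > k * med or (i > mid and discontinuous(i, i - 1)):
            hit_hi = i
            break
    if hit_lo < 0 and hit_hi < 0:
        raise ValueError(
            "no junction found: no division area exceeds "
            f"{k} x median along the path"
        )
    lo = hit_lo + 1 if hit_lo >= 0 else 0
    hi = hit_hi - 1 if hit_hi >= 0 else n - 1
    # strip tangent-cut slivers from the segment ends: near the junctions
    # the cutting plane can graze the lumen, producing a tiny loop whose
    # centroid is off-axis and would warp the centroid spline
    while lo < hi and areas[lo] < 0.35 * med:
        lo += 1
    while hi > lo and areas[hi] < 0.35 * med:
        hi -= 1
    if hi - lo + 1 < 4:
        raise ValueError("fewer than 4 interior divisions after junction trim")
    return lo, hi


def split_canals(
    mesh: trimesh.Trimesh,
    approx_paths: dict[str, np.ndarray],
    side: str,
    config: MorphometryConfig | None = None,
) -> dict[str, CanalSegment]:
    """Separate the three canals, truncated at vestibule and common crus.

    ``approx_paths`` maps canal name -> rough centerline polyline (world mm)
    that extends past the junctions so that the area blow-up is visible.
    """
    cfg = config or MorphometryConfig()
    segments: dict[str, CanalSegment] = {}
    for canal, path in approx_paths.items():
        sections = reslice_divisions(
            mesh, path, cfg.division_spacing, cfg.max_center_dist,
            cfg.max_skipped_fraction, min_loop_area=cfg.min_loop_area,
        )
        if len(sections) < cfg.min_sections:
            raise ValueError(f"{canal}: only {len(sections)} usable divisions")
        areas = np.array([s.area_mm2 for s in sections])
        centers = np.array([s.center_mm for s in sections])
        r_med = float(np.sqrt(np.median(areas) / np.pi))
        jump_tol = max(3 * cfg.division_spacing, 2 * r_med)
        lo, hi = _junction_trim(areas, cfg.endpoint_k, centers, jump_tol)
        interior = sections[lo : hi + 1]
        # endpoints: step half a division beyond the last interior centroid
        # along the local axis (the junction division's own centroid is
        # dragged toward the merged vestibule mass and would overshoot)
        def _extrapolate(c0, c1):
            d = c0.center_mm - c1.center_mm
            n = np.linalg.norm(d)
            if n < 1e-9:
                return c0.center_mm
            return c0.center_mm + 0.5 * cfg.division_spacing * d / n

        end_lo = (_extrapolate(interior[0], interior[1]) if lo > 0
                  else interior[0].center_mm)
        end_hi = (_extrapolate(interior[-1], interior[-2]) if hi + 1 < len(sections)
                  else interior[-1].center_mm)
        centerline, refined = centroid_spline(
            interior, cfg.division_spacing, mesh=mesh,
            refine=cfg.refine_iterations, max_center_dist=cfg.max_center_dist,
            min_loop_area=cfg.min_loop_area,
        )
        segments[canal] = CanalSegment(
            canal, side, centerline, refined, (end_lo, end_hi), mesh=mesh
        )
    _snap_common_crus(segments)
    return segments


def _snap_common_crus(segments: dict[str, CanalSegment]) -> None:
    """Identify the single common intersection point of the superior and
    posterior canals: their mutually nearest junction-side endpoints are
    replaced by the shared midpoint."""
    if "superior" not in segments or "posterior" not in segments:
        return
    es = segments["superior"].endpoints
    ep = segments["posterior"].endpoints
    d = np.array([[np.linalg.norm(a - b) for b in ep] for a in es])
    i, j = np.unravel_index(np.argmin(d), d.shape)
    if d[i, j] > 4.0:  # canals do not meet: leave endpoints alone
        return
    shared = 0.5 * (es[i] + ep[j])
    segments["superior"].endpoints = (
        (shared, es[1]) if i == 0 else (es[0], shared))
    segments["posterior"].endpoints = (
        (shared, ep[1]) if j == 0 else (ep[0], shared))


def min_csa(segment: CanalSegment, smooth_mm: float = 1.25) -> float:
    """Minimum division area (mm^2) strictly between the canal endpoints.

    The division-area profile of a meshed voxel surface carries wiggle that
    biases a plain minimum low; a 3-division running median (outliers)
    followed by a ~``smooth_mm`` running mean (wiggle) is applied first.
    ``smooth_mm=0`` disables smoothing. The window is short relative to
    anatomical area variation, so genuine minima are preserved.
    """
    areas = segment.areas()
    if len(areas) < 4:
        raise ValueError("too few divisions for a minimum area")
    if smooth_mm > 0:
        from scipy.ndimage import median_filter, uniform_filter1d

        areas = median_filter(areas, size=3, mode="nearest")
        n = int(round(smooth_mm / segment.centerline.spacing))
        n = max(3, n | 1)
        areas = uniform_filter1d(areas, n, mode="nearest")
    return float(np.min(areas))


def _segment_sample_areas(segment: CanalSegment) -> np.ndarray:
    """Division areas mapped onto the centerline samples, conditioned for
    use as fit weights: a 3-division running median removes isolated
    mis-measured divisions (a tangent-cut sliver would otherwise receive a
    divergent 1/A^2 weight and hijack the plane fit), and the profile is
    clamped to [0.3, 3] x the canal median."""
    from scipy.ndimage import median_filter

    centers = np.array([s.center_mm for s in segment.cross_sections])
    areas = median_filter(segment.areas(), size=3, mode="nearest")
    med = np.median(areas)
    areas = np.clip(areas, 0.3 * med, 3.0 * med)
    tree = cKDTree(centers)
    _, idx = tree.query(segment.centerline.samples)
    return areas[idx]


def fit_weighted_plane(
    cloud: np.ndarray,
    centerline: Centerline,
    areas: np.ndarray,
    point_mass: np.ndarray | None = None,
) -> FitPlane:
    """Area-weighted total-least-squares canal plane.

    Each cloud point is weighted by the inverse squared cross-sectional
    area of its nearest division (``areas`` aligned with
    ``centerline.samples``); residuals are centred at the weighted centroid
    so the canal's ring extent dominates the in-plane variance.

    ``point_mass`` (optional, >= 0) multiplies each point's contribution to
    the second-moment matrix — used for partial-volume weighting, where a
    boundary voxel counts in proportion to how much lumen it contains. On
    thin canals this suppresses the voxel-grid aliasing that a binary
    in/out cloud imposes on the fitted normal.
    """
    cloud = np.atleast_2d(np.asarray(cloud, dtype=float))
    areas = np.asarray(areas, dtype=float).reshape(-1)
    if len(areas) != len(centerline.samples):
        raise ValueError("areas must align with centerline samples")
    tree = cKDTree(centerline.samples)
    _, idx = tree.query(cloud)
    w = 1.0 / areas[idx] ** 2
    if point_mass is not None:
        w = w * np.sqrt(np.maximum(np.asarray(point_mass, dtype=float), 0.0))
    return fit_weighted_plane_points(cloud, w)


def midline_distance(points: np.ndarray) -> float:
    """Horizontal distance (mm) from the sagittal midline (plane x = 0) to
    the lateral-most aspect of a canal: max |x| over its surface points."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    return float(np.max(np.abs(points[:, 0])))


def segment_midline_distance(segment: CanalSegment) -> float:
    """Midline distance of a canal from its divisions: at each division the
    tube surface extends ``r_i * sqrt(1 - t_x^2)`` beyond the centre in x
    (t = local tangent), so the lateral-most aspect is the maximum of
    ``|x_centre| + r_i sqrt(1 - t_x^2)`` over interior divisions. Using the
    divisions rather than raw mesh vertices keeps junction (vestibule)
    surface out of the estimate."""
    line = segment.centerline
    areas = _segment_sample_areas(segment)
    r = np.sqrt(areas / np.pi)
    # junction-adjacent divisions can be inflated by merged vestibule mass;
    # cap the local radius near the canal's own calibre
    r = np.minimum(r, 1.25 * np.median(r))
    tx = np.clip(line.tangents[:, 0], -1.0, 1.0)
    extent = np.abs(line.samples[:, 0]) + r * np.sqrt(1.0 - tx**2)
    best = float(np.max(extent))
    # the canal continues to its junction endpoints; include them with the
    # median calibre so truncation jitter does not clip the extent
    r_med = float(np.median(r))
    for end, tan in ((segment.endpoints[0], line.tangents[0]),
                     (segment.endpoints[1], line.tangents[-1])):
        ex = abs(end[0]) + r_med * np.sqrt(1.0 - np.clip(tan[0], -1, 1) ** 2)
        best = max(best, float(ex))
    return best


def _assign_points(
    points: np.ndarray,
    segments: dict[str, CanalSegment],
    radius_factor: float,
    pad: float = 0.0,
) -> dict[str, np.ndarray]:
    """Assign points to canals by nearest interior centerline sample, within
    ``radius_factor x local division radius + pad`` (pad ~ one voxel covers
    the partial-volume shell). The gate keeps junction (vestibule/crus) mass
    out of the per-canal clouds."""
    names = list(segments)
    dists = np.full((len(points), len(names)), np.inf)
    idxs = np.zeros((len(points), len(names)), dtype=int)
    for j, name in enumerate(names):
        tree = cKDTree(segments[name].centerline.samples)
        dists[:, j], idxs[:, j] = tree.query(points)
    owner = np.argmin(dists, axis=1)
    out: dict[str, np.ndarray] = {}
    for j, name in enumerate(names):
        seg = segments[name]
        local_r = np.sqrt(_segment_sample_areas(seg) / np.pi)
        # cap: junction-adjacent divisions are inflated by merged blob mass
        local_r = np.minimum(local_r, 1.25 * np.median(local_r))
        mine = owner == j
        lim = radius_factor * local_r[idxs[mine, j]] + pad
        sel = np.nonzero(mine)[0][dists[mine, j] <= lim]
        out[name] = sel
    return out


def cloud_from_mask(mask: LabeledVolume) -> np.ndarray:
    """World-mm coordinates of foreground voxel centres."""
    vox = np.argwhere(mask.voxels > 0)
    return mask.voxel_to_world(vox)


def measure_side(
    mesh: trimesh.Trimesh,
    approx_paths: dict[str, np.ndarray],
    side: str,
    mask: LabeledVolume | None = None,
    intensity: LabeledVolume | None = None,
    config: MorphometryConfig | None = None,
) -> tuple[dict[str, float], dict[str, CanalSegment]]:
    """All nine parameters for one side.

    The plane-fit point cloud is the volumetric model of each canal: the
    segmentation mask's voxel centres when ``mask`` is given, otherwise the
    mesh voxelized at the division spacing. When the source ``intensity``
    volume is also given, cloud points carry a partial-volume mass
    ``max(I - background, 0)`` so boundary voxels count fractionally, which
    removes the grid aliasing a binary cloud imposes on thin canals. Canals
    that fail to split or fit yield missing (NaN) parameters rather than
    aborting the subject.
    """
    from scipy import ndimage

    cfg = config or MorphometryConfig()
    values: dict[str, float] = {p: float("nan") for p in PARAMETERS}

    try:
        segments = split_canals(mesh, approx_paths, side, cfg)
    except ValueError as exc:
        log.warning("side %s: canal splitting failed: %s", side, exc)
        return values, {}

    mass = None
    if mask is not None and intensity is not None:
        fg = mask.voxels > 0
        near = ndimage.binary_dilation(fg, iterations=1)
        shell = ndimage.binary_dilation(near, iterations=1)
        bg_level = float(np.median(intensity.voxels[~near]))
        cloud = mask.voxel_to_world(np.argwhere(shell))
        mass = np.maximum(intensity.voxels[shell] - bg_level, 0.0)
    elif mask is not None:
        cloud = cloud_from_mask(mask)
    else:
        pitch = max(cfg.division_spacing, 0.25)
        vg = mesh.voxelized(pitch).fill()
        cloud = np.asarray(vg.points)

    voxel_pad = float(np.max(mask.spacing_mm)) if mask is not None else cfg.division_spacing
    assigned = _assign_points(cloud, segments, cfg.cloud_radius_factor, pad=voxel_pad)

    planes: dict[str, FitPlane] = {}
    for canal, seg in segments.items():
        try:
            pts = cloud[assigned[canal]]
            areas = _segment_sample_areas(seg)
            pm = mass[assigned[canal]] if mass is not None else None
            plane = fit_weighted_plane(pts, seg.centerline, areas, point_mass=pm)
            n = orient_normal(plane.normal, canal, side)
            plane = FitPlane(n, plane.offset, plane.weighted_residual)
            seg.plane = plane
            planes[canal] = plane
            values[f"min_csa_{canal}"] = min_csa(seg)
        except ValueError as exc:
            log.warning("side %s %s: plane fit failed: %s", side, canal, exc)

    for canal in ("lateral", "posterior"):
        if canal in segments:
            values[f"midline_distance_{canal}"] = segment_midline_distance(
                segments[canal])

    if "lateral" in planes:
        values["lateral_inclination"] = lateral_inclination(planes["lateral"])
    for a, b in (("lateral", "superior"), ("superior", "posterior"),
                 ("lateral", "posterior")):
        if a in planes and b in planes:
            key = f"angle_{a}_{b}"
            values[key] = plane_angle(planes[a], planes[b])
    return values, segments


def measure_subject(
    meshes: dict[str, trimesh.Trimesh],
    approx_paths: dict[str, dict[str, np.ndarray]],
    subject_id: str = "subject",
    masks: dict[str, LabeledVolume] | None = None,
    intensities: dict[str, LabeledVolume] | None = None,
    config: MorphometryConfig | None = None,
) -> pd.DataFrame:
    """Measure both sides of a subject; long-format table of the nine
    parameters per side. Deterministic given inputs and config."""
    rows = []
    for side in ("R", "L"):
        if side not in meshes:
            raise ValueError(f"side {side} missing")
        mask = masks.get(side) if masks else None
        inten = intensities.get(side) if intensities else None
        values, _ = measure_side(
            meshes[side], approx_paths[side], side, mask, inten, config
        )
        for p in PARAMETERS:
            rows.append({"subject_id": subject_id, "side": side,
                         "parameter": p, "value": values[p]})
    return pd.DataFrame(rows)
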