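"""Vestibular-system segmentation: ROI crop, GrowCut, two-pass surface.

GrowCut is a competitive region-growing cellular automaton: every voxel
carries a label and a strength in [0, 1]; at each synchronous iteration a
neighbour q attacks voxel p with strength ``g(|I_p - I_q|) * strength_q``
where g decreases linearly from 1 to 0 over the image intensity range, and
p adopts q's label when the attack exceeds p's current strength. Seeds start
at strength 1 and are therefore never overwritten. Because the result
depends on the initial conditions, the surface is extracted in two passes:
the first segmentation, eroded, re-seeds a second run whose boundary is
allowed to re-compete before meshing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from numba import njit
from scipy import ndimage
from skimage import measure

from .volume import LabeledVolume

__all__ = [
    "SeedLabels",
    "extract_roi",
    "systematic_seeds",
    "growcut",
    "two_pass_surface",
    "mask_to_mesh",
    "intensity_isosurface",
]

FOREGROUND = 1
BACKGROUND = 2


@dataclass
class SeedLabels:
    """Sparse voxel -> label map (labels: 1 foreground, 2 background)."""

    coords: np.ndarray  # (N, 3) integer voxel indices
    labels: np.ndarray  # (N,) integers > 0

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=np.int64))
        self.labels = np.asarray(self.labels, dtype=np.int8).reshape(-1)
        if len(self.coords) != len(self.labels):
            raise ValueError("coords and labels length mismatch")
        if len(self.coords) == 0:
            raise ValueError("empty seed set")

    def validate(self, shape: tuple[int, int, int]) -> None:
        if np.any(self.coords < 0) or np.any(self.coords >= np.array(shape)):
            raise ValueError("seed voxels outside volume")
        present = set(np.unique(self.labels))
        if FOREGROUND not in present or BACKGROUND not in present:
            raise ValueError("need at least one foreground and one background seed")


def extract_roi(
    vol: LabeledVolume,
    side: str,
    size_mm: np.ndarray,
    center_mm: np.ndarray | None = None,
) -> LabeledVolume:
    """Crop a cubic ROI around one side's vestibular system.

    Under RAS, x < 0 is the left side and x > 0 the right. When no centre is
    given, the ROI is centred on the requested half of the volume's world
    bounding box. The affine is updated so every retained voxel keeps its
    world coordinates exactly. Requires a near-axis-aligned volume (as after
    AC-PC regridding).

    Raises
    ------
    ValueError
        If the requested ROI lies outside the volume.
    """
    if side not in ("L", "R"):
        raise ValueError("side must be 'L' or 'R'")
    size_mm = np.broadcast_to(np.asarray(size_mm, dtype=float), (3,))
    R = vol.affine[:3, :3]
    off_diag = np.abs(R) - np.diag(np.abs(np.diag(R)))
    if np.max(np.abs(off_diag)) > 1e-6 * np.max(np.abs(R)):
        raise ValueError("extract_roi requires an axis-aligned volume; regrid first")

    corners = vol.voxel_to_world(
        np.array([[i, j, k] for i in (0, vol.shape[0] - 1)
                  for j in (0, vol.shape[1] - 1) for k in (0, vol.shape[2] - 1)])
    )
    lo_w, hi_w = corners.min(axis=0), corners.max(axis=0)
    if center_mm is None:
        center_mm = 0.5 * (lo_w + hi_w)
        half_x = (0.25 if side == "R" else -0.25) * (hi_w[0] - lo_w[0])
        center_mm = center_mm + np.array([half_x, 0.0, 0.0])
    center_mm = np.asarray(center_mm, dtype=float).reshape(3)

    lo = vol.world_to_voxel(center_mm - size_mm / 2)[0]
    hi = vol.world_to_voxel(center_mm + size_mm / 2)[0]
    lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)
    i0 = np.floor(lo).astype(int)
    i1 = np.ceil(hi).astype(int) + 1
    if np.any(i1 <= 0) or np.any(i0 >= np.array(vol.shape)):
        raise ValueError("ROI lies outside the volume")
    i0 = np.clip(i0, 0, np.array(vol.shape) - 1)
    i1 = np.clip(i1, 1, np.array(vol.shape))
    sub = vol.voxels[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
    new_affine = vol.affine.copy()
    new_affine[:3, 3] = vol.voxel_to_world(i0.astype(float))[0]
    return LabeledVolume(sub.copy(), new_affine)


def systematic_seeds(
    vol: LabeledVolume, foreground_percentile: float = 99.5, border: int = 1
) -> SeedLabels:
    """Reproducible seeding without operator clicks: foreground = voxels
    above the given intensity percentile (T2 fluid is the brightest tissue),
    background = the ROI border shell."""
    img = vol.voxels
    thr = np.percentile(img, foreground_percentile)
    if thr <= img.min():
        raise ValueError("image has no intensity contrast to seed from")
    shell = np.ones(vol.shape, dtype=bool)
    shell[border:-border, border:-border, border:-border] = False
    fg = np.argwhere((img >= thr) & ~shell)  # >=: noise-free images tie at max
    if len(fg) == 0:
        raise ValueError("no voxels above the foreground percentile")
    bg = np.argwhere(shell)
    coords = np.vstack([fg, bg])
    labels = np.concatenate(
        [np.full(len(fg), FOREGROUND, np.int8), np.full(len(bg), BACKGROUND, np.int8)]
    )
    return SeedLabels(coords, labels)


@njit(cache=True)
def _growcut_sweep(intensity, labels, strength, new_labels, new_strength, inv_range):
    nx, ny, nz = intensity.shape
    changed = 0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                best_l = labels[i, j, k]
                best_s = strength[i, j, k]
                ip = intensity[i, j, k]
                for di in range(-1, 2):
                    qi = i + di
                    if qi < 0 or qi >= nx:
                        continue
                    for dj in range(-1, 2):
                        qj = j + dj
                        if qj < 0 or qj >= ny:
                            continue
                        for dk in range(-1, 2):
                            if di == 0 and dj == 0 and dk == 0:
                                continue
                            qk = k + dk
                            if qk < 0 or qk >= nz:
                                continue
                            lq = labels[qi, qj, qk]
                            if lq == 0:
                                continue
                            g = 1.0 - abs(ip - intensity[qi, qj, qk]) * inv_range
                            attack = g * strength[qi, qj, qk]
                            if attack > best_s:
                                best_s = attack
                                best_l = lq
                new_labels[i, j, k] = best_l
                new_strength[i, j, k] = best_s
                if best_l != labels[i, j, k]:
                    changed += 1
    return changed


def growcut(
    vol: LabeledVolume,
    seeds: SeedLabels,
    max_iter: int = 200,
    tol: int = 0,
) -> LabeledVolume:
    """Competitive region growing from seed labels (26-neighbourhood).

    Runs the synchronous cellular automaton until at most ``tol`` voxels
    change label in a sweep (or ``max_iter`` sweeps). Every voxel reachable
    from a seed ends up labelled; seed strengths are 1 and are never
    overwritten.
    """
    if vol.is_label:
        raise ValueError("growcut expects an intensity volume")
    seeds.validate(vol.shape)

    intensity = np.ascontiguousarray(vol.voxels, dtype=np.float64)
    labels = np.zeros(vol.shape, dtype=np.int8)
    strength = np.zeros(vol.shape, dtype=np.float64)
    labels[tuple(seeds.coords.T)] = seeds.labels
    strength[tuple(seeds.coords.T)] = 1.0

    rng = float(np.ptp(intensity))
    inv_range = 1.0 / rng if rng > 0 else 0.0
    new_labels = np.empty_like(labels)
    new_strength = np.empty_like(strength)
    for _ in range(max_iter):
        changed = _growcut_sweep(
            intensity, labels, strength, new_labels, new_strength, inv_range
        )
        labels, new_labels = new_labels, labels
        strength, new_strength = new_strength, strength
        if changed <= tol:
            break
    return LabeledVolume(labels.copy(), vol.affine.copy())


def mask_to_mesh(
    mask: np.ndarray,
    affine: np.ndarray,
    min_component_voxels: int = 100,
    supersample: int = 2,
) -> trimesh.Trimesh:
    """Marching cubes (iso-level 0.5) on a binary mask, in world mm.

    Connected components smaller than ``min_component_voxels`` are dropped
    first; the mask is zero-padded so the surface is closed at the borders.
    ``supersample > 1`` linearly upsamples the indicator before contouring,
    which halves the voxelization wiggle of cross-section areas on thin
    tubes at modest cost (set to 1 for speed in large batch runs).
    """
    mask = np.asarray(mask).astype(bool)
    if min_component_voxels > 1:
        lab, n = ndimage.label(mask)
        if n > 0:
            counts = np.bincount(lab.ravel())
            keep = np.nonzero(counts >= min_component_voxels)[0]
            keep = keep[keep > 0]
            mask = np.isin(lab, keep)
    if not mask.any():
        raise ValueError("empty mask: nothing to mesh")
    field = mask.astype(np.float32)
    f = max(1, int(supersample))
    if f > 1:
        field = ndimage.zoom(field, f, order=1)
    padded = np.pad(field, 1)
    verts, faces, _, _ = measure.marching_cubes(padded, 0.5)
    verts = (verts - 1.0) / f  # undo padding and upsampling
    verts = verts @ affine[:3, :3].T + affine[:3, 3]
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def intensity_isosurface(
    vol: LabeledVolume,
    mask: np.ndarray,
    pre_sigma_vox: float = 0.6,
    dilate_voxels: int = 2,
) -> trimesh.Trimesh:
    """Surface of a segmented structure at the half-intensity iso-level.

    The image carries sub-voxel boundary information through partial-volume
    averaging, so contouring the (lightly smoothed) intensity at the
    midpoint between the structure's and the background's median levels
    places the surface far more accurately than contouring the binary mask.
    The mask selects the structure: intensities outside its dilation are
    clamped to background so neighbouring anatomy is not meshed.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask: nothing to mesh")
    field = vol.voxels.astype(np.float32)
    if pre_sigma_vox > 0:
        field = ndimage.gaussian_filter(field, pre_sigma_vox)
    near = ndimage.binary_dilation(mask, iterations=max(dilate_voxels, 1))
    fg_level = float(np.median(field[mask]))
    bg_level = float(np.median(field[~near]))
    if not fg_level > bg_level:
        raise ValueError("foreground is not brighter than background")
    iso = 0.5 * (fg_level + bg_level)
    field = np.where(near, field, bg_level)
    padded = np.pad(field, 1, constant_values=bg_level)
    verts, faces, _, _ = measure.marching_cubes(padded, iso)
    verts = (verts - 1.0) @ vol.affine[:3, :3].T + vol.affine[:3, 3]
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def two_pass_surface(
    vol: LabeledVolume,
    seeds: SeedLabels | None = None,
    max_iter: int = 200,
    min_component_voxels: int = 100,
    erosion_voxels: int = 1,
    supersample: int = 2,
    surface_from: str = "intensity",
    return_mask: bool = False,
):
    """GrowCut twice, then extract the lumen surface.

    Pass 1 segments from the initial seeds. Pass 2 re-seeds from the eroded
    pass-1 foreground (confident core) and the eroded pass-1 background
    (complement of the dilated foreground), letting the boundary re-compete.
    The final surface is the half-intensity iso-contour of the image within
    the pass-2 mask (``surface_from="intensity"``, sub-voxel accurate), or
    marching cubes at 0.5 on the binary mask (``surface_from="mask"``).
    With ``return_mask=True`` also returns the pass-2 mask volume.

    Raises
    ------
    ValueError
        If pass 1 produces an empty foreground.
    """
    if seeds is None:
        seeds = systematic_seeds(vol)
    pass1 = growcut(vol, seeds, max_iter=max_iter)
    fg = pass1.voxels == FOREGROUND
    if not fg.any():
        raise ValueError("empty foreground after GrowCut pass 1")

    core = ndimage.binary_erosion(fg, iterations=erosion_voxels) if erosion_voxels else fg
    if not core.any():
        core = fg
    bg_seed = ~ndimage.binary_dilation(fg, iterations=max(erosion_voxels, 1))
    if not bg_seed.any():
        bg_seed = pass1.voxels == BACKGROUND
    coords = np.vstack([np.argwhere(core), np.argwhere(bg_seed)])
    labels2 = np.concatenate([
        np.full(core.sum(), FOREGROUND, np.int8),
        np.full(bg_seed.sum(), BACKGROUND, np.int8),
    ])
    pass2 = growcut(vol, SeedLabels(coords, labels2), max_iter=max_iter)
    mask2 = pass2.voxels == FOREGROUND
    if min_component_voxels > 1:
        lab, n = ndimage.label(mask2)
        if n > 0:
            counts = np.bincount(lab.ravel())
            keep = np.nonzero(counts >= min_component_voxels)[0]
            mask2 = np.isin(lab, keep[keep > 0])
    if surface_from == "intensity":
        mesh = intensity_isosurface(vol, mask2)
    else:
        mesh = mask_to_mesh(mask2, vol.affine, 1, supersample)
    if return_mask:
        return mesh, LabeledVolume(mask2.astype(np.uint8), vol.affine.copy())
    return mesh
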