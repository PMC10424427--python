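"""Mesh- and principal-component-based shape features.

Volume and surface area come from a triangulated iso-surface of the mask at
its physical spacing (marching cubes at level 0.5 on the zero-padded
indicator).  Axis features come from the eigenvalues of the covariance of the
foreground voxel centre coordinates in mm.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull
from skimage import measure

from ..imaging import BinaryMask
from .registry import SHAPE_FEATURES


def _mesh(mask: BinaryMask, smooth_iterations: int = 30) -> tuple[np.ndarray, np.ndarray]:
    """Triangulated iso-surface of the mask, Taubin-smoothed.

    Marching cubes on a binary indicator produces a staircase surface whose
    area overestimates smooth anatomy by ~10%; Taubin λ/μ smoothing relaxes
    the staircase while preserving enclosed volume (unlike Laplacian
    smoothing, which shrinks the mesh).
    """
    padded = np.pad(mask.values.astype(float), 1)
    verts, faces, _, _ = measure.marching_cubes(
        padded, level=0.5, spacing=mask.spacing
    )
    if smooth_iterations > 0:
        import trimesh

        tm = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        trimesh.smoothing.filter_taubin(tm, iterations=smooth_iterations)
        verts, faces = np.asarray(tm.vertices), np.asarray(tm.faces)
    return verts, faces


def mesh_volume_and_area(mask: BinaryMask) -> tuple[float, float]:
    """Volume (mm³) and surface area (mm²) of the triangulated mask surface.

    The volume is the signed-tetrahedron sum over mesh faces (divergence
    theorem); the area is the summed triangle areas.
    """
    if mask.is_empty:
        raise ValueError("mask is empty")
    verts, faces = _mesh(mask)
    tri = verts[faces]  # (n_faces, 3, 3)
    v = np.abs(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum()) / 6.0
    a = float(measure.mesh_surface_area(verts, faces))
    return float(v), a


def sphericity(volume: float, area: float) -> float:
    """Sphericity ∛(36·π·V²)/A — 1 for a sphere, → 0 for flat shapes."""
    if volume <= 0 or area <= 0:
        raise ValueError("volume and area must be > 0")
    return float((36.0 * np.pi * volume**2) ** (1.0 / 3.0) / area)


def _coords_mm(mask: BinaryMask) -> np.ndarray:
    idx = np.argwhere(mask.values).astype(float)
    return idx * np.asarray(mask.spacing)


def _axis_eigenvalues(mask: BinaryMask) -> np.ndarray:
    """Eigenvalues (mm², descending) of the voxel-coordinate covariance."""
    coords = _coords_mm(mask)
    if coords.shape[0] < 2:
        raise ValueError("need >= 2 foreground voxels for axis features")
    cov = np.cov(coords, rowvar=False)
    eig = np.linalg.eigvalsh(cov)[::-1]
    return np.clip(eig, 0.0, None)


def flatness(mask: BinaryMask) -> float:
    """√(λ_least / λ_major) of the principal components; 1 for isotropic shapes."""
    eig = _axis_eigenvalues(mask)
    if eig[0] <= 0:
        raise ValueError("degenerate covariance: no spatial extent")
    return float(np.sqrt(eig[2] / eig[0]))


def _max_pairwise_distance(points: np.ndarray) -> float:
    if points.shape[0] < 2:
        return 0.0
    if points.shape[0] > 10:
        try:
            hull = ConvexHull(points)
            points = points[hull.vertices]
        except Exception:  # degenerate (coplanar/collinear) point sets
            pass
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def _border_coords_mm(mask: BinaryMask) -> np.ndarray:
    from scipy import ndimage

    eroded = ndimage.binary_erosion(mask.values)
    border = mask.values & ~eroded
    if not border.any():
        border = mask.values
    return np.argwhere(border).astype(float) * np.asarray(mask.spacing)


def shape_features(mask: BinaryMask) -> dict[str, float]:
    """All 14 shape features of the default registry for one region."""
    v, a = mesh_volume_and_area(mask)
    coords = _border_coords_mm(mask)
    eig = _axis_eigenvalues(mask)
    major, minor, least = (4.0 * np.sqrt(e) for e in eig)

    # maximum 2D diameters: largest in-plane pairwise distance, per plane family
    def _planar(drop_axis: int) -> float:
        keep = [i for i in range(3) if i != drop_axis]
        best = 0.0
        vals = coords[:, drop_axis]
        for u in np.unique(vals):
            pts = coords[vals == u][:, keep]
            best = max(best, _max_pairwise_distance(pts))
        return best

    feats = {
        "MeshVolume": v,
        "VoxelVolume": mask.voxel_count() * float(np.prod(mask.spacing)),
        "SurfaceArea": a,
        "SurfaceVolumeRatio": a / v,
        "Sphericity": sphericity(v, a),
        "Maximum3DDiameter": _max_pairwise_distance(coords),
        "Maximum2DDiameterSlice": _planar(2),   # axial plane (x, y)
        "Maximum2DDiameterColumn": _planar(1),  # coronal plane (x, z)
        "Maximum2DDiameterRow": _planar(0),     # sagittal plane (y, z)
        "MajorAxisLength": float(major),
        "MinorAxisLength": float(minor),
        "LeastAxisLength": float(least),
        "Elongation": float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0,
        "Flatness": float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0,
    }
    assert set(feats) == set(SHAPE_FEATURES)
    return feats
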