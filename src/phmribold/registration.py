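"""Affine atlas registration and group composite maps.

Each subject's anatomy is aligned to a segmented template with a
nine-parameter affine transform (three translations, three rotations,
three per-axis scales) — the transform ``T_j`` for subject *j*. Group
composite percent-change maps are then built in atlas space by mapping
every atlas voxel through the inverse transform ``T_j^-1`` and sampling
each subject's activation map with trilinear interpolation, so that the
full composite volume is populated with subject contributions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize

__all__ = [
    "AffineTransform",
    "register_affine",
    "smooth_gaussian",
    "trilinear_sample",
    "resample_to_grid",
    "CompositeMap",
    "build_composite",
]

# FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# Affine transforms
# ---------------------------------------------------------------------------

def _rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """Rotation about x, then y, then z (radians), right-handed."""
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


@dataclass(frozen=True)
class AffineTransform:
    """Rigid-plus-scale spatial mapping between subject and atlas space.

    ``matrix`` is a 4x4 homogeneous transform acting on physical (mm)
    coordinates, mapping subject space to atlas space. When built from
    parameters the mapping is

        x_atlas = c + t + R(rotation) @ diag(scale) @ (x_subj - c)

    with ``c`` the rotation/scaling centre in mm.
    """

    matrix: np.ndarray
    translation: tuple[float, float, float] | None = None
    rotation: tuple[float, float, float] | None = None
    scale: tuple[float, float, float] | None = None
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    _inverse: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"expected a 4x4 matrix, got shape {m.shape}")
        if abs(np.linalg.det(m[:3, :3])) < 1e-12:
            raise ValueError("transform matrix is singular")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "_inverse", np.linalg.inv(m))

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls.from_params((0, 0, 0), (0, 0, 0), (1, 1, 1))

    @classmethod
    def from_params(
        cls,
        translation: Sequence[float],
        rotation: Sequence[float],
        scale: Sequence[float],
        center: Sequence[float] = (0.0, 0.0, 0.0),
    ) -> "AffineTransform":
        """Build the transform from 3 translations (mm), 3 rotations (rad)
        and 3 per-axis scale factors, applied about ``center`` (mm)."""
        t = np.asarray(translation, dtype=float)
        r = np.asarray(rotation, dtype=float)
        s = np.asarray(scale, dtype=float)
        c = np.asarray(center, dtype=float)
        if np.any(s == 0):
            raise ValueError("zero scale factor gives a degenerate transform")
        A = _rotation_matrix(*r) @ np.diag(s)
        m = np.eye(4)
        m[:3, :3] = A
        m[:3, 3] = c + t - A @ c
        return cls(
            matrix=m,
            translation=tuple(t),
            rotation=tuple(r),
            scale=tuple(s),
            center=tuple(c),
        )

    @property
    def inverse_matrix(self) -> np.ndarray:
        return self._inverse

    def inverse(self) -> "AffineTransform":
        return AffineTransform(matrix=self._inverse.copy())

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        """Map points (..., 3) from subject mm to atlas mm."""
        p = np.asarray(points_mm, dtype=float)
        return p @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def apply_inverse(self, points_mm: np.ndarray) -> np.ndarray:
        """Map points (..., 3) from atlas mm back to subject mm."""
        p = np.asarray(points_mm, dtype=float)
        return p @ self._inverse[:3, :3].T + self._inverse[:3, 3]

    # -- serialisation ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({"matrix_mm_row_major": self.matrix.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "AffineTransform":
        obj = json.loads(text)
        return cls(matrix=np.asarray(obj["matrix_mm_row_major"], dtype=float))


# ---------------------------------------------------------------------------
# Smoothing and interpolation primitives
# ---------------------------------------------------------------------------

def smooth_gaussian(
    volume: np.ndarray,
    fwhm_mm: float,
    voxel_size: Sequence[float],
) -> np.ndarray:
    """Separable Gaussian smoothing specified by its FWHM in mm.

    ``fwhm_mm = 0`` returns the input unchanged.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    if fwhm_mm == 0:
        return np.asarray(volume, dtype=float).copy()
    vs = np.asarray(voxel_size, dtype=float)
    sigma_vox = fwhm_mm * _FWHM_TO_SIGMA / vs
    return ndimage.gaussian_filter(np.asarray(volume, dtype=float), sigma=sigma_vox)


def trilinear_sample(volume: np.ndarray, points_vox: np.ndarray) -> np.ndarray:
    """Sample ``volume`` at continuous voxel coordinates (..., 3).

    Each sample is the weighted mean of the 8 surrounding voxel values,
    weights given by the fractional coordinates. Points outside the valid
    grid ``[0, n-1]`` on any axis yield NaN (a designated missing value,
    not zero), so callers can exclude them from averages.
    """
    vol = np.asarray(volume, dtype=float)
    pts_in = np.asarray(points_vox, dtype=float)
    batch_shape = pts_in.shape[:-1]
    pts = pts_in.reshape(-1, 3)
    n = np.asarray(vol.shape)

    inside = np.all((pts >= 0) & (pts <= n - 1), axis=-1)
    out = np.full(pts.shape[0], np.nan)
    if np.any(inside):
        p = pts[inside]
        i0 = np.floor(p).astype(int)
        # keep the upper corner in-grid for points exactly on the far face
        i0 = np.clip(i0, 0, n - 2)
        f = p - i0

        acc = np.zeros(p.shape[0])
        for dx in (0, 1):
            wx = f[:, 0] if dx else 1.0 - f[:, 0]
            for dy in (0, 1):
                wy = f[:, 1] if dy else 1.0 - f[:, 1]
                for dz in (0, 1):
                    wz = f[:, 2] if dz else 1.0 - f[:, 2]
                    acc += wx * wy * wz * vol[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
        out[inside] = acc
    if pts_in.ndim == 1:
        return float(out[0])
    return out.reshape(batch_shape)


def _grid_points_mm(shape: Sequence[int], voxel_size: Sequence[float]) -> np.ndarray:
    """Physical coordinates (mm) of all voxel centres, shape (N, 3).

    Voxel centres sit at index * voxel_size (0-based indices)."""
    idx = np.indices(shape).reshape(3, -1).T
    return idx * np.asarray(voxel_size, dtype=float)


def resample_to_grid(
    volume: np.ndarray,
    transform: AffineTransform,
    out_shape: Sequence[int],
    out_voxel_size: Sequence[float],
    in_voxel_size: Sequence[float],
    fill: float = np.nan,
    order: str = "trilinear",
) -> np.ndarray:
    """Resample a subject-space volume onto an atlas-space grid.

    Every output (atlas) voxel centre is mapped through ``transform``'s
    inverse to subject mm, converted to subject voxel coordinates, and
    sampled trilinearly (or nearest-neighbour for label volumes). Points
    falling outside the subject grid receive ``fill``.
    """
    pts_atlas = _grid_points_mm(out_shape, out_voxel_size)
    pts_subj = transform.apply_inverse(pts_atlas) / np.asarray(in_voxel_size, float)
    if order == "nearest":
        n = np.asarray(volume.shape)
        idx = np.round(pts_subj).astype(int)
        inside = np.all((idx >= 0) & (idx <= n - 1), axis=1)
        vals = np.full(pts_subj.shape[0], fill, dtype=float)
        ii = idx[inside]
        vals[inside] = np.asarray(volume, dtype=float)[ii[:, 0], ii[:, 1], ii[:, 2]]
    else:
        vals = trilinear_sample(volume, pts_subj)
        if not np.isnan(fill):
            vals = np.where(np.isnan(vals), fill, vals)
    return vals.reshape(tuple(out_shape))


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------

def _sample_points(
    template: np.ndarray,
    voxel_size: np.ndarray,
    separation_mm: float,
    quality: float,
) -> np.ndarray:
    """Template foreground voxel centres subsampled at the stated
    separation; ``quality`` sets the fraction of candidates retained."""
    stride = np.maximum(1, np.round(separation_mm / voxel_size).astype(int))
    mask = template > template.mean()
    sub = np.zeros_like(mask)
    sub[:: stride[0], :: stride[1], :: stride[2]] = True
    idx = np.argwhere(mask & sub)
    if idx.shape[0] == 0:
        raise ValueError("no foreground sample points in template")
    n_keep = max(8, int(np.ceil(quality * idx.shape[0])))
    keep = np.unique(np.linspace(0, idx.shape[0] - 1, n_keep).astype(int))
    return idx[keep].astype(float)


class RegistrationError(RuntimeError):
    """Raised when the similarity optimisation cannot find overlap."""


def register_affine(
    subject_anat: np.ndarray,
    template: np.ndarray,
    voxel_size: Sequence[float],
    template_voxel_size: Sequence[float] | None = None,
    quality: float = 0.97,
    smoothing_mm: float = 0.35,
    separation_mm: float = 0.50,
    init: AffineTransform | None = None,
) -> AffineTransform:
    """Estimate the nine-parameter affine mapping subject to atlas space.

    The transform (translation, rotation and per-axis scaling, in all
    three dimensions) maximises the normalised cross-correlation between
    the subject volume, warped into atlas space, and the template.  Both
    volumes are pre-smoothed (``smoothing_mm`` FWHM) and similarity is
    evaluated at foreground template voxels subsampled at
    ``separation_mm``; ``quality`` sets the fraction of those sample
    points used. A coarse level (double smoothing and separation) seeds
    a fine level at the stated settings; both use Powell's
    derivative-free method. Deterministic for fixed inputs.
    """
    vs_s = np.asarray(voxel_size, dtype=float)
    vs_t = np.asarray(
        template_voxel_size if template_voxel_size is not None else voxel_size,
        dtype=float,
    )
    template = np.asarray(template, dtype=float)
    subject_anat = np.asarray(subject_anat, dtype=float)

    # rotation/scaling centre: template foreground centroid, in mm
    fg = template > template.mean()
    center = np.argwhere(fg).mean(axis=0) * vs_t

    # parameter scaling so Powell's unit steps are comparable across
    # translation (mm), rotation (rad) and log-scale dimensions
    p_scale = np.array([1.0, 1.0, 1.0, 0.02, 0.02, 0.02, 0.01, 0.01, 0.01])

    def build(u: np.ndarray) -> AffineTransform:
        v = u * p_scale
        return AffineTransform.from_params(
            translation=v[0:3],
            rotation=v[3:6],
            scale=np.exp(v[6:9]),
            center=center,
        )

    def params_to_u(t: AffineTransform) -> np.ndarray:
        v = np.concatenate([t.translation, t.rotation, np.log(t.scale)])
        return v / p_scale

    u0 = np.zeros(9)
    if init is not None:
        if init.translation is None:
            raise ValueError("init transform must carry explicit parameters")
        u0 = params_to_u(init)

    levels = [
        (2.0 * smoothing_mm + vs_t.min(), 2.0 * separation_mm, 1e-3, 1e-10),
        (smoothing_mm, separation_mm, 1e-8, 1e-14),
    ]
    u = u0
    n_subj = np.asarray(subject_anat.shape)
    for fwhm, sep, xtol, ftol in levels:
        t_sm = smooth_gaussian(template, fwhm, vs_t)
        s_sm = smooth_gaussian(subject_anat, fwhm, vs_s)
        # cubic B-spline representation of the subject: interpolation in
        # the similarity measure must not attenuate structure the way a
        # trilinear kernel would, or the optimum drifts off the true pose
        s_coeffs = ndimage.spline_filter(s_sm, order=3)
        pts_vox = _sample_points(t_sm, vs_t, sep, quality)
        pts_mm = pts_vox * vs_t
        t_vals = t_sm[
            pts_vox[:, 0].astype(int), pts_vox[:, 1].astype(int), pts_vox[:, 2].astype(int)
        ]

        def cost(uu: np.ndarray) -> float:
            tr = build(uu)
            subj_vox = tr.apply_inverse(pts_mm) / vs_s
            inb = np.all((subj_vox >= 0) & (subj_vox <= n_subj - 1), axis=1)
            frac = inb.mean()
            if frac < 0.25:
                return 2.0 + (0.25 - frac)  # push back toward overlap
            s_vals = ndimage.map_coordinates(
                s_coeffs, subj_vox[inb].T, order=3, prefilter=False
            )
            a = t_vals[inb]
            if a.std() == 0 or s_vals.std() == 0:
                return 2.0
            ncc = np.corrcoef(a, s_vals)[0, 1]
            # mild penalty for shrinking overlap so the optimiser cannot
            # cheat by sliding the subject off the sampled field of view
            return -ncc + 0.1 * (1.0 - frac)

        res = optimize.minimize(
            cost, u, method="Powell",
            options={"xtol": xtol, "ftol": ftol, "maxiter": 500},
        )
        u = res.x
        if res.fun >= 1.9:
            raise RegistrationError(
                "registration failed: no usable overlap between subject and "
                f"template (cost {res.fun:.3f}); check initial alignment"
            )
    return build(u)


# ---------------------------------------------------------------------------
# Group composites
# ---------------------------------------------------------------------------

@dataclass
class CompositeMap:
    """Group-average percent-change map in atlas space.

    Positive and negative activation components are averaged separately;
    ``n_contributing`` counts, per voxel, the subjects whose grid covered
    that atlas location (out-of-bounds samples are excluded)."""

    group: str
    positive: np.ndarray
    negative: np.ndarray
    n_contributing: np.ndarray
    voxel_size: tuple[float, float, float]


def build_composite(
    subject_maps,
    transforms: Sequence[AffineTransform],
    atlas,
    group: str = "",
    include_zeros: bool = True,
    smooth_fwhm_mm: float = 0.0,
) -> CompositeMap:
    """Average subject activation maps into one atlas-space composite.

    Every atlas voxel centre is mapped through each subject's inverse
    transform ``T_j^-1`` and the subject's positive and negative retained
    percent-change maps are sampled trilinearly at that location; the
    voxel's composite value is the mean of the contributions. With
    ``include_zeros`` (default) all in-bounds subjects contribute,
    non-retained voxels counting as zeros; otherwise the mean runs over
    nonzero contributions only. ``smooth_fwhm_mm`` optionally smooths
    each subject map before compositing.
    """
    maps = list(subject_maps)
    transforms = list(transforms)
    if len(maps) != len(transforms):
        missing = abs(len(maps) - len(transforms))
        raise ValueError(f"{missing} subject(s) lack a transform")
    shape = atlas.labels.shape
    vs_atlas = np.asarray(atlas.voxel_size, dtype=float)
    pts_mm = _grid_points_mm(shape, vs_atlas)

    out = {}
    counts = np.zeros(pts_mm.shape[0])
    for sign in ("positive", "negative"):
        total = np.zeros(pts_mm.shape[0])
        n = np.zeros(pts_mm.shape[0])
        for amap, tr in zip(maps, transforms):
            vol = getattr(amap, sign)
            if smooth_fwhm_mm > 0:
                vol = smooth_gaussian(vol, smooth_fwhm_mm, amap.voxel_size)
            pts_vox = tr.apply_inverse(pts_mm) / np.asarray(amap.voxel_size, float)
            vals = trilinear_sample(vol, pts_vox)
            valid = np.isfinite(vals)
            if not include_zeros:
                valid &= vals != 0
            total[valid] += vals[valid]
            n[valid] += 1
        with np.errstate(invalid="ignore"):
            mean = np.where(n > 0, total / np.maximum(n, 1), 0.0)
        out[sign] = mean.reshape(shape)
        counts = np.maximum(counts, n)

    return CompositeMap(
        group=group,
        positive=out["positive"],
        negative=out["negative"],
        n_contributing=counts.reshape(shape).astype(int),
        voxel_size=tuple(vs_atlas),
    )
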