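"""Synthetic awake-mouse phMRI cohorts with known ground truth.

Generates everything the downstream pipeline consumes — a labelled
ellipsoidal "brain" atlas, per-subject affine transforms, 4D BOLD series
with injected dose-dependent percent-change effects, and motion traces —
so every stage can be validated against a recorded truth (responder
masks, transforms, labels) without any scanner data.

The default acquisition geometry mirrors the emulated protocol: a
96x96 in-plane matrix over 18 slices (0.1875 x 0.1875 x 0.75 mm voxels),
150 acquisitions of which the first 50 form the pre-injection control
window, and a whole-brain mask of roughly 15 000 voxels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np

from .registration import AffineTransform

__all__ = [
    "LabeledAtlas",
    "AnalyticAnatomy",
    "BoldSeries",
    "MotionTrace",
    "RegionEffect",
    "EffectSpec",
    "SubjectTruth",
    "make_atlas",
    "intensity_field",
    "make_subject_transform",
    "simulate_bold",
    "simulate_motion",
    "make_cohort",
    "load_cohort_manifest",
]

#: default voxel edge lengths, mm (in-plane resolution 187.5 um, 0.75 mm slices)
DEFAULT_VOXEL_SIZE = (0.1875, 0.1875, 0.75)
#: full-scale acquisition grid and windows
FULL_SHAPE = (96, 96, 18)
N_BASELINE = 50
N_STIM = 100
#: ellipsoid semi-axes as fractions of the grid, chosen so the full-scale
#: brain mask holds ~15 000 voxels
_BRAIN_SEMIAXES_FRAC = (0.235, 0.235, 0.39)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class LabeledAtlas:
    """Segmented reference volume: integer labels (0 = background), a
    region id -> name table, and physical voxel size in mm."""

    labels: np.ndarray
    names: dict[int, str]
    voxel_size: tuple[float, float, float]

    @property
    def region_ids(self) -> list[int]:
        return sorted(self.names)

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    def region_mask(self, region_id: int) -> np.ndarray:
        if region_id not in self.names:
            raise KeyError(f"unknown region id {region_id}")
        return self.labels == region_id

    def region_sizes(self) -> dict[int, int]:
        counts = np.bincount(self.labels.ravel(), minlength=max(self.names) + 1)
        return {rid: int(counts[rid]) for rid in self.region_ids}


@dataclass
class SubjectTruth:
    """Ground truth recorded at simulation time for validation."""

    labels: np.ndarray            # atlas labels resampled into subject space
    positive_mask: np.ndarray     # voxels given a positive effect
    negative_mask: np.ndarray     # voxels given a negative effect
    transform: AffineTransform    # subject -> atlas, the generating T_j
    anatomy: np.ndarray           # noiseless subject-space intensity field


@dataclass
class BoldSeries:
    """One subject's 4D functional acquisition plus timing metadata."""

    data: np.ndarray              # (x, y, z, t)
    n_baseline: int
    n_stim: int
    voxel_size: tuple[float, float, float]
    subject_id: str = ""
    group: str = ""
    truth: SubjectTruth | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4D (x, y, z, t)")
        if self.data.shape[3] != self.n_baseline + self.n_stim:
            raise ValueError(
                f"time axis {self.data.shape[3]} != n_baseline + n_stim "
                f"({self.n_baseline} + {self.n_stim})"
            )

    @property
    def baseline(self) -> np.ndarray:
        return self.data[..., : self.n_baseline]

    @property
    def stim(self) -> np.ndarray:
        return self.data[..., self.n_baseline :]


@dataclass
class MotionTrace:
    """Per-acquisition head displacement in micrometres, relative to the
    first (reference) acquisition."""

    displacement_um: np.ndarray   # (t, 3): x, y, z
    subject_id: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.displacement_um, dtype=float)
        if d.ndim != 2 or d.shape[1] != 3:
            raise ValueError("displacement must have shape (n_acquisitions, 3)")
        if not np.all(np.isfinite(d)):
            raise ValueError("displacement contains non-finite values")
        self.displacement_um = d


@dataclass(frozen=True)
class RegionEffect:
    """A BOLD response injected into one region at one dose.

    ``amplitude_pct`` is the signed percent change from baseline (positive
    effects > 0, negative < 0), ``fraction`` the proportion of the region's
    voxels that respond, ``onset`` the acquisition index at which the
    response begins (never before the control window ends), and ``shape``
    either an instantaneous ``step`` or a linear ``ramp`` reaching full
    amplitude ``ramp_len`` acquisitions after onset.
    """

    region_id: int
    amplitude_pct: float
    fraction: float = 1.0
    onset: int = N_BASELINE
    shape: str = "step"
    ramp_len: int = 5

    def __post_init__(self) -> None:
        if self.amplitude_pct == 0:
            raise ValueError("effect amplitude must be nonzero")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("responding fraction must lie in [0, 1]")
        if self.shape not in ("step", "ramp"):
            raise ValueError(f"unknown response shape {self.shape!r}")

    def time_profile(self, n_acq: int) -> np.ndarray:
        """Response multiplier g(t) in [0, 1] over the whole acquisition."""
        g = np.zeros(n_acq)
        g[self.onset :] = 1.0
        if self.shape == "ramp" and self.ramp_len > 0:
            ramp_end = min(self.onset + self.ramp_len, n_acq)
            g[self.onset : ramp_end] = (
                np.arange(1, ramp_end - self.onset + 1) / self.ramp_len
            ).clip(max=1.0)
        return g


#: Effect library keyed by dose label ("vehicle", "1.0", "3.3", "10") —
#: each dose maps to the region effects present at that dose.
EffectSpec = Mapping[str, Sequence[RegionEffect]]


# ---------------------------------------------------------------------------
# Atlas and anatomy
# ---------------------------------------------------------------------------

def make_atlas(
    n_regions: int,
    shape: Sequence[int] = FULL_SHAPE,
    voxel_size: Sequence[float] = DEFAULT_VOXEL_SIZE,
    seed: int = 0,
) -> LabeledAtlas:
    """Build a labelled ellipsoidal brain with ``n_regions`` contiguous
    parcels.

    The brain mask is an axis-aligned ellipsoid whose semi-axes are fixed
    fractions of the grid (~15 000 voxels at the full 96x96x18 scale);
    parcels are the Voronoi cells of seeded interior points, so each is
    convex — hence spatially connected — and nonempty. Deterministic for
    a fixed seed.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    shape = tuple(int(s) for s in shape)
    rng = np.random.default_rng(seed)

    center = (np.asarray(shape) - 1) / 2.0
    semi = np.asarray(_BRAIN_SEMIAXES_FRAC) * np.asarray(shape)
    idx = np.indices(shape).reshape(3, -1).T
    r2 = (((idx - center) / semi) ** 2).sum(axis=1)
    mask_flat = r2 <= 1.0
    n_mask = int(mask_flat.sum())
    if n_mask < n_regions:
        raise ValueError(
            f"shape {shape} yields a brain mask of {n_mask} voxels, "
            f"too small for {n_regions} regions"
        )

    mask_idx = idx[mask_flat]
    seeds = mask_idx[rng.choice(n_mask, size=n_regions, replace=False)]
    # nearest seed in physical units -> convex Voronoi parcels
    vs = np.asarray(voxel_size, dtype=float)
    d2 = (
        ((mask_idx[:, None, :] - seeds[None, :, :]) * vs) ** 2
    ).sum(axis=2)
    assign = d2.argmin(axis=1) + 1

    labels = np.zeros(shape, dtype=np.int32)
    labels[tuple(mask_idx.T)] = assign
    names = {i: f"region_{i:03d}" for i in range(1, n_regions + 1)}
    return LabeledAtlas(labels=labels, names=names, voxel_size=tuple(vs))


@dataclass
class AnalyticAnatomy:
    """Continuous anatomical intensity field, evaluable at any mm point.

    The field is a smooth ellipsoidal brain envelope modulated by
    region-scale Gaussian bumps (one per atlas region, at its centroid —
    the smooth analogue of per-region mean intensity) and finer Gaussian
    texture blobs. Because it is analytic, a subject volume can be
    rendered in any frame by exact evaluation rather than by resampling
    a grid — so registration recovery tests see no interpolation bias in
    their ground truth.
    """

    center_mm: np.ndarray
    semi_mm: np.ndarray
    envelope_width: float
    blob_centers: np.ndarray     # (n, 3) mm
    blob_sigmas: np.ndarray      # (n,) mm
    blob_amps: np.ndarray        # (n,) relative amplitude
    base: float = 900.0
    background: float = 100.0

    @classmethod
    def from_atlas(
        cls, atlas: LabeledAtlas, seed: int = 0, n_texture: int = 60
    ) -> "AnalyticAnatomy":
        rng = np.random.default_rng(seed)
        shape = np.asarray(atlas.labels.shape)
        vs = np.asarray(atlas.voxel_size, dtype=float)
        center_mm = (shape - 1) / 2.0 * vs
        semi_mm = np.asarray(_BRAIN_SEMIAXES_FRAC) * shape * vs

        # one bump per region at its centroid, width ~ region radius
        r_centers, r_sigmas = [], []
        for rid in atlas.region_ids:
            vox = np.argwhere(atlas.labels == rid)
            r_centers.append(vox.mean(axis=0) * vs)
            radius_mm = (vox.shape[0] * np.prod(vs) * 3.0 / (4.0 * np.pi)) ** (1 / 3)
            r_sigmas.append(max(radius_mm, vs.max()))
        r_amps = rng.uniform(-0.2, 0.2, len(r_centers))

        t_centers = rng.uniform(-0.8, 0.8, (n_texture, 3)) * semi_mm + center_mm
        t_sigmas = rng.uniform(1.0, 2.5, n_texture)
        t_amps = rng.uniform(-0.35, 0.35, n_texture)

        return cls(
            center_mm=center_mm,
            semi_mm=semi_mm,
            envelope_width=0.06,
            blob_centers=np.vstack([np.asarray(r_centers), t_centers]),
            blob_sigmas=np.concatenate([np.asarray(r_sigmas), t_sigmas]),
            blob_amps=np.concatenate([r_amps, t_amps]),
        )

    def evaluate(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.asarray(points_mm, dtype=float)
        rho = np.sqrt((((pts - self.center_mm) / self.semi_mm) ** 2).sum(axis=-1))
        envelope = 1.0 / (1.0 + np.exp((rho - 1.0) / self.envelope_width))
        structure = np.ones(pts.shape[:-1])
        for c, sg, a in zip(self.blob_centers, self.blob_sigmas, self.blob_amps):
            structure = structure + a * np.exp(
                -((pts - c) ** 2).sum(axis=-1) / (2.0 * sg * sg)
            )
        return np.clip(self.background + self.base * envelope * structure, 1.0, None)

    def on_grid(
        self, shape: Sequence[int], voxel_size: Sequence[float]
    ) -> np.ndarray:
        idx = np.indices(tuple(shape)).reshape(3, -1).T
        vals = self.evaluate(idx * np.asarray(voxel_size, dtype=float))
        return vals.reshape(tuple(shape))


def intensity_field(atlas: LabeledAtlas, seed: int = 0) -> np.ndarray:
    """Atlas-space anatomical template: the analytic anatomy field of
    :class:`AnalyticAnatomy` rendered on the atlas grid."""
    return AnalyticAnatomy.from_atlas(atlas, seed=seed).on_grid(
        atlas.labels.shape, atlas.voxel_size
    )


def make_subject_transform(
    scale_jitter: float = 0.03,
    rotation_jitter: float = 0.05,
    translation_jitter: float = 0.4,
    seed: int = 0,
    center: Sequence[float] = (0.0, 0.0, 0.0),
) -> AffineTransform:
    """Draw a random subject-to-atlas transform (translation mm, rotation
    rad, per-axis scale) with jitters uniform in ±the stated magnitude.

    Zero jitters give the identity. The generating parameters are kept on
    the returned transform so registration recovery can be scored.
    """
    if scale_jitter >= 1.0:
        raise ValueError("scale jitter must be < 1 (zero scale is degenerate)")
    rng = np.random.default_rng(seed)
    t = rng.uniform(-translation_jitter, translation_jitter, 3)
    r = rng.uniform(-rotation_jitter, rotation_jitter, 3)
    s = 1.0 + rng.uniform(-scale_jitter, scale_jitter, 3)
    return AffineTransform.from_params(t, r, s, center=center)


# ---------------------------------------------------------------------------
# BOLD simulation
# ---------------------------------------------------------------------------

def _subject_space(atlas: LabeledAtlas, transform: AffineTransform,
                   anatomy: "AnalyticAnatomy | np.ndarray"):
    """Render the anatomy and labels in subject space.

    Subject voxel centres are mapped forward through ``transform`` (subject
    -> atlas) and the atlas-space fields are taken there: the analytic
    anatomy is evaluated exactly (a grid template falls back to trilinear
    sampling), labels are looked up nearest-neighbour."""
    shape = atlas.labels.shape
    vs = np.asarray(atlas.voxel_size, dtype=float)
    idx = np.indices(shape).reshape(3, -1).T
    pts_atlas_mm = transform.apply(idx * vs)
    pts_atlas_vox = pts_atlas_mm / vs

    if isinstance(anatomy, AnalyticAnatomy):
        anat = anatomy.evaluate(pts_atlas_mm).reshape(shape)
    else:
        from .registration import trilinear_sample  # deferred, avoids import cycle

        anat = trilinear_sample(np.asarray(anatomy, dtype=float), pts_atlas_vox)
        anat = np.where(np.isfinite(anat), anat, 100.0).reshape(shape)

    n = np.asarray(shape)
    nn = np.round(pts_atlas_vox).astype(int)
    inside = np.all((nn >= 0) & (nn <= n - 1), axis=1)
    labels = np.zeros(idx.shape[0], dtype=np.int32)
    ii = nn[inside]
    labels[inside] = atlas.labels[ii[:, 0], ii[:, 1], ii[:, 2]]
    return anat, labels.reshape(shape)


def simulate_bold(
    atlas: LabeledAtlas,
    transform: AffineTransform,
    effects: Sequence[RegionEffect] = (),
    noise_sd: float = 2.0,
    drift_slope: float = 0.005,
    seed: int = 0,
    n_baseline: int = N_BASELINE,
    n_stim: int = N_STIM,
    anatomy: "AnalyticAnatomy | np.ndarray | None" = None,
    subject_id: str = "",
    group: str = "",
) -> BoldSeries:
    """Simulate one subject's 4D BOLD series with known ground truth.

    The subject's anatomy is the atlas intensity field carried into the
    subject's own frame by ``transform``. Responding voxels (a seeded
    ``fraction`` of each effect's region, in subject space) shift by the
    signed ``amplitude_pct`` after onset; every voxel additionally carries
    independent Gaussian noise (``noise_sd``, % of baseline) and a global
    linear drift (``drift_slope``, % per acquisition). The returned series
    carries a :class:`SubjectTruth` with responder masks, subject-space
    labels and the generating transform.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    if anatomy is None:
        anatomy = AnalyticAnatomy.from_atlas(atlas, seed=0)
    anat, labels = _subject_space(atlas, transform, anatomy)
    shape = anat.shape
    n_acq = n_baseline + n_stim

    pos_mask = np.zeros(shape, dtype=bool)
    neg_mask = np.zeros(shape, dtype=bool)
    pc = np.zeros(shape + (n_acq,), dtype=np.float32)  # injected % change
    taken = np.zeros(shape, dtype=bool)
    for eff in effects:
        if eff.region_id not in atlas.names:
            raise KeyError(f"effect references unknown region id {eff.region_id}")
        if eff.onset < n_baseline:
            raise ValueError(
                f"effect onset {eff.onset} precedes end of control window ({n_baseline})"
            )
        region_vox = np.argwhere((labels == eff.region_id) & ~taken)
        n_resp = int(round(eff.fraction * region_vox.shape[0]))
        if n_resp == 0:
            continue
        chosen = region_vox[rng.choice(region_vox.shape[0], n_resp, replace=False)]
        sel = tuple(chosen.T)
        taken[sel] = True
        (pos_mask if eff.amplitude_pct > 0 else neg_mask)[sel] = True
        g = eff.time_profile(n_acq).astype(np.float32)
        pc[sel] += eff.amplitude_pct * g

    t = np.arange(n_acq, dtype=np.float32)
    factor = 1.0 + pc / 100.0 + (drift_slope / 100.0) * t
    if noise_sd > 0:
        factor = factor + (noise_sd / 100.0) * rng.standard_normal(
            shape + (n_acq,)
        ).astype(np.float32)
    data = anat[..., None].astype(np.float32) * factor

    truth = SubjectTruth(
        labels=labels,
        positive_mask=pos_mask,
        negative_mask=neg_mask,
        transform=transform,
        anatomy=anat,
    )
    return BoldSeries(
        data=data,
        n_baseline=n_baseline,
        n_stim=n_stim,
        voxel_size=atlas.voxel_size,
        subject_id=subject_id,
        group=group,
        truth=truth,
    )


def simulate_motion(
    n_acq: int = N_BASELINE + N_STIM,
    walk_sd_um: float = 10.0,
    seed: int = 0,
    spike_um: float | None = None,
    spike_at: int | None = None,
    subject_id: str = "",
) -> MotionTrace:
    """Zero-mean random-walk head motion, in micrometres.

    ``walk_sd_um`` is the RMS displacement reached by the end of the run
    (per axis); an optional spike inserts a single large in-plane
    excursion to exercise the exclusion rule.
    """
    rng = np.random.default_rng(seed)
    step_sd = walk_sd_um / np.sqrt(max(n_acq - 1, 1))
    steps = rng.normal(0.0, step_sd, size=(n_acq, 3))
    steps[0] = 0.0  # reference acquisition
    disp = np.cumsum(steps, axis=0)
    if spike_um is not None:
        at = spike_at if spike_at is not None else n_acq // 2
        disp[at, 0] += spike_um
    return MotionTrace(displacement_um=disp, subject_id=subject_id)


# ---------------------------------------------------------------------------
# Cohorts on disk
# ---------------------------------------------------------------------------

def _nifti(volume: np.ndarray, voxel_size: Sequence[float]) -> nib.Nifti1Image:
    affine = np.diag(list(voxel_size) + [1.0])  # RAS+, mm
    return nib.Nifti1Image(np.asarray(volume), affine)


def default_effect_library(atlas: LabeledAtlas) -> dict[str, list[RegionEffect]]:
    """Dose -> effects library emulating the reported dose profiles:
    a descending positive response (largest at 1.0 mg/kg), a U-shaped
    positive response (smallest at 3.3), and a negative response maximal
    at the low dose. Uses the first three region ids."""
    rids = atlas.region_ids
    r_desc, r_u, r_neg = rids[0], rids[1 % len(rids)], rids[2 % len(rids)]
    return {
        "vehicle": [],
        "1.0": [
            RegionEffect(r_desc, +5.0, fraction=0.8),
            RegionEffect(r_u, +4.0, fraction=0.6),
            RegionEffect(r_neg, -4.0, fraction=0.6),
        ],
        "3.3": [
            RegionEffect(r_desc, +3.5, fraction=0.6),
            RegionEffect(r_u, +2.5, fraction=0.3),
            RegionEffect(r_neg, -3.0, fraction=0.4),
        ],
        "10": [
            RegionEffect(r_desc, +2.5, fraction=0.3),
            RegionEffect(r_u, +4.0, fraction=0.5),
            RegionEffect(r_neg, -2.5, fraction=0.3),
        ],
    }


def make_cohort(config: Mapping, out_dir: str | Path) -> dict:
    """Write a complete synthetic cohort to ``out_dir`` and return the
    manifest (also saved as ``manifest.json``).

    ``config`` keys (all optional except ``groups``):
      groups: mapping group label -> number of subjects
      n_regions, shape, voxel_size, n_baseline, n_stim,
      noise_sd, drift_slope, walk_sd_um,
      scale_jitter / rotation_jitter / translation_jitter,
      effects: dose -> list of RegionEffect (or dicts), default library,
      seed: root seed expanded deterministically per subject.

    Per subject: anatomical + functional NIfTI, motion TSV, truth masks
    and labels as NIfTI, transform as JSON (4x4 row-major, mm).
    Rerunning with an identical config and seed reproduces every file.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create cohort directory {out}: {exc}") from exc

    groups: Mapping[str, int] = config["groups"]
    n_regions = int(config.get("n_regions", 134))
    shape = tuple(config.get("shape", FULL_SHAPE))
    voxel_size = tuple(config.get("voxel_size", DEFAULT_VOXEL_SIZE))
    n_baseline = int(config.get("n_baseline", N_BASELINE))
    n_stim = int(config.get("n_stim", N_STIM))
    noise_sd = float(config.get("noise_sd", 2.0))
    drift_slope = float(config.get("drift_slope", 0.005))
    walk_sd_um = float(config.get("walk_sd_um", 10.0))
    seed = int(config.get("seed", 0))

    atlas = make_atlas(n_regions, shape=shape, voxel_size=voxel_size, seed=seed)
    anatomy = AnalyticAnatomy.from_atlas(atlas, seed=seed)
    template = anatomy.on_grid(shape, voxel_size)
    effects = config.get("effects")
    if effects is None:
        effects = default_effect_library(atlas)
    else:
        effects = {
            dose: [e if isinstance(e, RegionEffect) else RegionEffect(**e) for e in lst]
            for dose, lst in effects.items()
        }

    center_mm = (np.asarray(shape) - 1) / 2.0 * np.asarray(voxel_size)
    nib.save(_nifti(atlas.labels, voxel_size), out / "atlas_labels.nii")
    nib.save(_nifti(template, voxel_size), out / "atlas_template.nii")
    with open(out / "atlas_regions.tsv", "w") as fh:
        fh.write("region_id\tname\n")
        for rid in atlas.region_ids:
            fh.write(f"{rid}\t{atlas.names[rid]}\n")

    ss = np.random.SeedSequence(seed)
    subjects = []
    subj_seeds = iter(ss.spawn(sum(groups.values()) * 3))
    i = 0
    for grp, size in groups.items():
        for k in range(size):
            sid = f"{grp.replace('.', 'p')}_s{k:02d}"
            s_tr, s_bold, s_mot = (
                int(next(subj_seeds).generate_state(1)[0] % (2**31)) for _ in range(3)
            )
            tr = make_subject_transform(
                scale_jitter=float(config.get("scale_jitter", 0.02)),
                rotation_jitter=float(config.get("rotation_jitter", 0.03)),
                translation_jitter=float(config.get("translation_jitter", 0.3)),
                seed=s_tr,
                center=center_mm,
            )
            series = simulate_bold(
                atlas, tr, effects.get(grp, ()), noise_sd=noise_sd,
                drift_slope=drift_slope, seed=s_bold, n_baseline=n_baseline,
                n_stim=n_stim, anatomy=anatomy, subject_id=sid, group=grp,
            )
            motion = simulate_motion(
                n_acq=n_baseline + n_stim, walk_sd_um=walk_sd_um,
                seed=s_mot, subject_id=sid,
            )

            paths = {
                "anat": f"{sid}_anat.nii",
                "func": f"{sid}_func.nii",
                "motion": f"{sid}_motion.tsv",
                "labels": f"{sid}_labels.nii",
                "truth_pos": f"{sid}_truth_pos.nii",
                "truth_neg": f"{sid}_truth_neg.nii",
                "transform": f"{sid}_transform.json",
            }
            truth = series.truth
            nib.save(_nifti(truth.anatomy, voxel_size), out / paths["anat"])
            nib.save(_nifti(series.data, voxel_size), out / paths["func"])
            nib.save(_nifti(truth.labels, voxel_size), out / paths["labels"])
            nib.save(_nifti(truth.positive_mask.astype(np.uint8), voxel_size),
                     out / paths["truth_pos"])
            nib.save(_nifti(truth.negative_mask.astype(np.uint8), voxel_size),
                     out / paths["truth_neg"])
            with open(out / paths["motion"], "w") as fh:
                fh.write("acquisition_index\tx_um\ty_um\tz_um\n")
                for j, (x, y, z) in enumerate(motion.displacement_um):
                    fh.write(f"{j}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")
            with open(out / paths["transform"], "w") as fh:
                fh.write(tr.to_json())
            subjects.append({"subject_id": sid, "group": grp, "seed": s_bold, **paths})
            i += 1

    manifest = {
        "n_regions": n_regions,
        "shape": list(shape),
        "voxel_size": list(voxel_size),
        "n_baseline": n_baseline,
        "n_stim": n_stim,
        "noise_sd": noise_sd,
        "seed": seed,
        "groups": {g: int(n) for g, n in groups.items()},
        "atlas_labels": "atlas_labels.nii",
        "atlas_template": "atlas_template.nii",
        "atlas_regions": "atlas_regions.tsv",
        "subjects": subjects,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def load_cohort_manifest(cohort_dir: str | Path) -> dict:
    with open(Path(cohort_dir) / "manifest.json") as fh:
        return json.load(fh)
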