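"""End-to-end orchestration: simulate -> QC -> activation -> registration
-> composites -> regional tables -> time series.

A single YAML config drives every stage; one root seed is expanded
deterministically per subject and stage, so a rerun with an identical
config is bit-identical for the deterministic stages. Every output file
is stamped with the config hash (a ``# config_hash=`` header on TSVs,
JSON fields elsewhere) for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Mapping

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import activation as act
from . import motion as mqc
from . import regional as reg
from . import registration as regi
from . import synthetic as syn
from . import timeseries as tss

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]

log = logging.getLogger("phmribold")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name (and subject, if any)."""

    def __init__(self, stage: str, message: str, subject: str | None = None):
        self.stage = stage
        self.subject = subject
        where = f"stage {stage!r}" + (f", subject {subject!r}" if subject else "")
        super().__init__(f"{where}: {message}")


@dataclass
class PipelineConfig:
    """Validated configuration for a full pipeline run.

    Defaults follow the emulated protocol: 50-acquisition control window
    followed by 100 post-injection acquisitions; step-up filter q = 0.2,
    cV = 1 with a 2% magnitude threshold; registration quality 0.97,
    pre-smoothing 0.35 mm, sampling separation 0.50 mm and composite
    smoothing FWHM 0.8 mm; 93.75 um half-voxel motion exclusion."""

    output_dir: str = "phmri_output"
    cohort: dict | None = None          # synthetic cohort config, if simulating
    cohort_dir: str | None = None       # existing cohort, if not
    n_baseline: int = 50
    n_stim: int = 100
    q: float = 0.2
    c_v: float = 1.0
    threshold_pct: float = 2.0
    quality: float = 0.97
    smoothing_mm: float = 0.35
    separation_mm: float = 0.50
    composite_fwhm_mm: float = 0.8
    use_truth_transforms: bool = False
    half_voxel_um: float = 93.75
    region_sets: dict = dc_field(default_factory=dict)  # name -> [region ids]
    anova_pairs: list = dc_field(default_factory=lambda: [["1.0", "vehicle"]])
    anova_bins: int | None = 10
    seed: int = 0

    def validate(self) -> None:
        act.FilterParams(q=self.q, c_v=self.c_v, threshold_pct=self.threshold_pct)
        if self.n_baseline < 2 or self.n_stim < 2:
            raise ValueError("both windows need at least 2 acquisitions")
        if self.half_voxel_um <= 0:
            raise ValueError("half_voxel_um must be positive")
        if not 0 < self.quality <= 1:
            raise ValueError("registration quality must lie in (0, 1]")
        if min(self.smoothing_mm, self.separation_mm, self.composite_fwhm_mm) < 0:
            raise ValueError("registration lengths must be non-negative")
        if self.cohort is None and self.cohort_dir is None:
            raise ValueError("either a cohort config or a cohort_dir is required")

    def config_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def _load_series(cohort: Path, sub: Mapping[str, Any], cfg: PipelineConfig) -> syn.BoldSeries:
    img = nib.load(cohort / sub["func"])
    data = np.asarray(img.dataobj, dtype=np.float32)
    vs = tuple(float(z) for z in img.header.get_zooms()[:3])
    return syn.BoldSeries(
        data=data,
        n_baseline=cfg.n_baseline,
        n_stim=cfg.n_stim,
        voxel_size=vs,
        subject_id=sub["subject_id"],
        group=sub["group"],
    )


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute every stage and return a summary dict of output paths.

    Stage failures raise :class:`PipelineError` naming the stage and
    subject; outputs written before the failure are preserved."""
    config.validate()
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    fh = logging.FileHandler(out / "pipeline.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    timings: dict[str, float] = {}
    summary: dict[str, Any] = {"config_hash": chash, "output_dir": str(out)}

    def stage(name: str):
        log.info("stage %s: start", name)
        timings[name] = time.perf_counter()

    def done(name: str):
        timings[name] = time.perf_counter() - timings[name]
        log.info("stage %s: done in %.1f s", name, timings[name])

    try:
        # -- simulate -----------------------------------------------------
        if config.cohort is not None:
            stage("simulate")
            cohort_dir = out / "cohort"
            cohort_cfg = dict(config.cohort)
            cohort_cfg.setdefault("seed", config.seed)
            cohort_cfg.setdefault("n_baseline", config.n_baseline)
            cohort_cfg.setdefault("n_stim", config.n_stim)
            try:
                manifest = syn.make_cohort(cohort_cfg, cohort_dir)
            except Exception as exc:
                raise PipelineError("simulate", str(exc)) from exc
            done("simulate")
        else:
            cohort_dir = Path(config.cohort_dir)
            manifest = syn.load_cohort_manifest(cohort_dir)
        summary["cohort_dir"] = str(cohort_dir)

        atlas_img = nib.load(cohort_dir / manifest["atlas_labels"])
        names = (
            pd.read_csv(cohort_dir / manifest["atlas_regions"], sep="\t")
            .set_index("region_id")["name"]
            .to_dict()
        )
        vs = tuple(float(z) for z in atlas_img.header.get_zooms()[:3])
        atlas = syn.LabeledAtlas(
            labels=np.asarray(atlas_img.dataobj).astype(np.int32),
            names={int(k): v for k, v in names.items()},
            voxel_size=vs,
        )
        template = np.asarray(nib.load(cohort_dir / manifest["atlas_template"]).dataobj)

        # -- motion QC ----------------------------------------------------
        stage("qc")
        summaries = []
        retained_subjects = []
        for sub in manifest["subjects"]:
            try:
                trace = mqc.read_motion_tsv(cohort_dir / sub["motion"], sub["subject_id"])
                s = mqc.apply_exclusion(
                    mqc.summarize_motion(trace), config.half_voxel_um
                )
            except Exception as exc:
                raise PipelineError("qc", str(exc), sub["subject_id"]) from exc
            summaries.append(s)
            if s.excluded:
                log.info("excluded %s: %s", sub["subject_id"], s.reason)
            else:
                retained_subjects.append(sub)
        qc_df = mqc.write_motion_summaries(summaries, out / "qc_report.tsv")
        summary["n_excluded"] = int(qc_df["excluded"].sum())
        done("qc")

        # -- per-subject activation --------------------------------------
        stage("activate")
        params = act.FilterParams(config.q, config.c_v, config.threshold_pct)
        maps: dict[str, act.ActivationMap] = {}
        count_rows = []
        for sub in retained_subjects:
            try:
                series = _load_series(cohort_dir, sub, config)
                labels = np.asarray(
                    nib.load(cohort_dir / sub["labels"]).dataobj
                ).astype(np.int32)
                amap = act.compute_activation(series, mask=labels > 0, params=params)
                amap.save(out / "activation", sub["subject_id"])
            except Exception as exc:
                raise PipelineError("activate", str(exc), sub["subject_id"]) from exc
            maps[sub["subject_id"]] = amap
            count_rows.append(
                {
                    "subject_id": sub["subject_id"],
                    "group": sub["group"],
                    "n_positive": amap.n_positive,
                    "n_negative": amap.n_negative,
                }
            )
        _write_tsv(pd.DataFrame(count_rows), out / "voxel_counts.tsv", chash)
        done("activate")

        # -- registration -------------------------------------------------
        stage("register")
        transforms: dict[str, regi.AffineTransform] = {}
        (out / "transforms").mkdir(exist_ok=True)
        for sub in retained_subjects:
            sid = sub["subject_id"]
            try:
                if config.use_truth_transforms:
                    with open(cohort_dir / sub["transform"]) as f:
                        tr = regi.AffineTransform.from_json(f.read())
                else:
                    anat = np.asarray(nib.load(cohort_dir / sub["anat"]).dataobj)
                    tr = regi.register_affine(
                        anat,
                        template,
                        voxel_size=vs,
                        quality=config.quality,
                        smoothing_mm=config.smoothing_mm,
                        separation_mm=config.separation_mm,
                    )
            except Exception as exc:
                raise PipelineError("register", str(exc), sid) from exc
            transforms[sid] = tr
            with open(out / "transforms" / f"{sid}.json", "w") as f:
                f.write(tr.to_json())
        done("register")

        # -- composites ---------------------------------------------------
        stage("composite")
        groups = sorted({s["group"] for s in retained_subjects})
        affine4 = np.diag(list(atlas.voxel_size) + [1.0])
        for grp in groups:
            sids = [s["subject_id"] for s in retained_subjects if s["group"] == grp]
            comp = regi.build_composite(
                [maps[s] for s in sids],
                [transforms[s] for s in sids],
                atlas,
                group=grp,
                smooth_fwhm_mm=config.composite_fwhm_mm,
            )
            for sign in ("positive", "negative"):
                img = nib.Nifti1Image(
                    getattr(comp, sign).astype(np.float32), affine4
                )
                img.header["descrip"] = f"config_hash={chash}".encode()[:79]
                nib.save(img, out / f"composite_{grp.replace('.', 'p')}_{sign}.nii")
        done("composite")

        # -- regional tables ----------------------------------------------
        stage("regions")
        counts: dict[str, dict] = {"positive": {}, "negative": {}}
        group_of: dict[str, str] = {}
        for sub in retained_subjects:
            sid, grp = sub["subject_id"], sub["group"]
            group_of[sid] = grp
            amap = maps[sid]
            atlas_map = act.ActivationMap(
                positive=regi.resample_to_grid(
                    amap.positive, transforms[sid], atlas.labels.shape,
                    atlas.voxel_size, amap.voxel_size, fill=0.0,
                ),
                negative=regi.resample_to_grid(
                    amap.negative, transforms[sid], atlas.labels.shape,
                    atlas.voxel_size, amap.voxel_size, fill=0.0,
                ),
                voxel_size=atlas.voxel_size,
                subject_id=sid,
            )
            per_region = reg.count_activated(atlas_map, atlas)
            for sign in ("positive", "negative"):
                for rid, c in per_region[sign].items():
                    counts[sign].setdefault(rid, {}).setdefault(grp, []).append(c)
        tables = {}
        for sign in ("positive", "negative"):
            table = reg.regional_table(
                counts[sign], q=config.q, c_v=config.c_v, atlas=atlas
            )
            _write_tsv(table, out / f"regional_table_{sign}.tsv", chash)
            tables[sign] = table
        summary["regional_tables"] = {
            s: str(out / f"regional_table_{s}.tsv") for s in tables
        }
        done("regions")

        # -- time series --------------------------------------------------
        stage("timeseries")
        tc_rows = []
        anova_rows = []
        for set_name, rids in (config.region_sets or {}).items():
            for sign in ("positive", "negative"):
                courses: dict[str, list[np.ndarray]] = {}
                for sub in retained_subjects:
                    sid = sub["subject_id"]
                    series = _load_series(cohort_dir, sub, config)
                    labels = np.asarray(
                        nib.load(cohort_dir / sub["labels"]).dataobj
                    ).astype(np.int32)
                    try:
                        tc = tss.region_timecourse(
                            series, labels, rids, set_name, sign,
                            activation=maps[sid], voxels="retained",
                        )
                    except ValueError:
                        tc = tss.region_timecourse(
                            series, labels, rids, set_name, sign, voxels="all"
                        )
                    courses.setdefault(sub["group"], []).append(tc.values)
                    for t, v in enumerate(tc.values):
                        tc_rows.append(
                            {
                                "subject_id": sid,
                                "group": sub["group"],
                                "region_set": set_name,
                                "sign": sign,
                                "acquisition": t,
                                "percent_change": v,
                            }
                        )
                for pair in config.anova_pairs:
                    a, b = pair
                    if a not in courses or b not in courses:
                        continue
                    post = slice(config.n_baseline, None)
                    try:
                        res = tss.two_way_anova(
                            {
                                a: np.stack(courses[a])[:, post],
                                b: np.stack(courses[b])[:, post],
                            },
                            n_bins=config.anova_bins,
                        )
                    except ValueError as exc:
                        log.warning("ANOVA skipped (%s/%s %s): %s", set_name, sign, pair, exc)
                        continue
                    anova_rows.append(
                        {
                            "region_set": set_name,
                            "sign": sign,
                            "treatment": a,
                            "control": b,
                            "F": res.f_statistic,
                            "df_num": res.df_num,
                            "df_den": res.df_den,
                            "p": res.p_value,
                            "direction": res.direction,
                        }
                    )
        if tc_rows:
            _write_tsv(pd.DataFrame(tc_rows), out / "timecourses.tsv", chash)
        if anova_rows:
            _write_tsv(pd.DataFrame(anova_rows), out / "anova_results.tsv", chash)
        done("timeseries")

        with open(out / "provenance.json", "w") as f:
            json.dump(
                {
                    "config_hash": chash,
                    "seed": config.seed,
                    "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
                    "config": {k: v for k, v in config.__dict__.items()},
                },
                f,
                indent=1,
                default=str,
            )
        summary["tables"] = tables
        return summary
    finally:
        log.removeHandler(fh)
        fh.close()
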