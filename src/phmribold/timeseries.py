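"""Region-set BOLD time courses and treatment-by-time ANOVA.

For a named set of regions (e.g. a hippocampal complex of CA1, CA3,
dentate gyrus and subiculum), each subject contributes one percent-change
time course: the per-acquisition mean over the set's voxels — by default
only those retained in the subject's activation map of the requested
sign, optionally all set voxels. Drug and vehicle groups are then
compared over the post-injection window with a two-factor fixed-effects
ANOVA (treatment x time), reporting the treatment main effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .activation import ActivationMap, percent_change_series
from .synthetic import BoldSeries

__all__ = ["TimeCourse", "AnovaResult", "region_timecourse", "two_way_anova"]


@dataclass
class TimeCourse:
    """One subject's mean percent-change series over a region set."""

    subject_id: str
    group: str
    region_set: str
    sign: str
    values: np.ndarray          # (n_acquisitions,) mean % change
    n_voxels: int


def region_timecourse(
    series: BoldSeries,
    labels: np.ndarray,
    region_ids: Sequence[int],
    region_set: str = "",
    sign: str = "positive",
    activation: ActivationMap | None = None,
    voxels: str = "retained",
) -> TimeCourse:
    """Mean percent change per acquisition over a region set's voxels.

    ``labels`` is the label volume in the subject's own space. With
    ``voxels='retained'`` (default) the average runs over the set's
    voxels retained in ``activation``'s component of the given sign;
    ``voxels='all'`` uses every voxel of the set.
    """
    region_ids = list(region_ids)
    set_mask = np.isin(labels, region_ids)
    if not np.any(set_mask):
        raise ValueError(
            f"region set {region_set or region_ids!r} is empty in the label volume"
        )
    if voxels == "retained":
        if activation is None:
            raise ValueError("voxels='retained' requires an activation map")
        comp = activation.positive if sign == "positive" else activation.negative
        sel = set_mask & (comp != 0)
    elif voxels == "all":
        sel = set_mask
    else:
        raise ValueError("voxels must be 'retained' or 'all'")
    if not np.any(sel):
        raise ValueError(
            f"no {voxels} voxels of sign {sign!r} in region set "
            f"{region_set or region_ids!r}"
        )
    pc, valid = percent_change_series(series, mask=sel)
    sel &= valid
    vals = pc[sel].mean(axis=0)
    return TimeCourse(
        subject_id=series.subject_id,
        group=series.group,
        region_set=region_set or ",".join(map(str, region_ids)),
        sign=sign,
        values=vals,
        n_voxels=int(sel.sum()),
    )


@dataclass(frozen=True)
class AnovaResult:
    """Treatment main effect of the two-factor (treatment x time) ANOVA."""

    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    direction: str              # e.g. "drug > vehicle"
    treatment_means: dict


def _bin_time(values: np.ndarray, n_bins: int | None) -> np.ndarray:
    """Average the time axis of (n_subjects, n_time) into ``n_bins``."""
    if n_bins is None or n_bins >= values.shape[1]:
        return values
    edges = np.linspace(0, values.shape[1], n_bins + 1).astype(int)
    return np.stack(
        [values[:, a:b].mean(axis=1) for a, b in zip(edges[:-1], edges[1:])], axis=1
    )


def two_way_anova(
    groups: Mapping[str, np.ndarray],
    n_bins: int | None = None,
) -> AnovaResult:
    """Two-factor fixed-effects ANOVA on treatment x time cell data.

    ``groups`` maps the two treatment labels to arrays of shape
    (n_subjects, n_time) holding post-injection percent-change values
    (the baseline window is not part of the comparison). Subjects are
    the replicates within each treatment x time cell; ``n_bins``
    optionally averages the time axis into coarser bins first. Returns
    the treatment main-effect F, its degrees of freedom, p-value and the
    direction of the marginal treatment means.
    """
    if len(groups) != 2:
        raise ValueError("exactly two treatment levels are required")
    labels = list(groups)
    arrays = {}
    n_time = None
    for lab in labels:
        arr = np.atleast_2d(np.asarray(groups[lab], dtype=float))
        if arr.shape[0] < 2:
            raise ValueError(
                f"treatment group {lab!r} has a single subject; "
                "within-cell variance is undefined"
            )
        if n_time is not None and arr.shape[1] != n_time:
            raise ValueError("treatment groups are on different time grids")
        n_time = arr.shape[1]
        arrays[lab] = _bin_time(arr, n_bins)

    frames = []
    for lab, arr in arrays.items():
        n_subj, n_t = arr.shape
        frames.append(
            pd.DataFrame(
                {
                    "value": arr.ravel(),
                    "treatment": lab,
                    "time": np.tile(np.arange(n_t), n_subj),
                    "subject": np.repeat(np.arange(n_subj), n_t),
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)

    model = smf.ols("value ~ C(treatment) * C(time)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    row = table.loc["C(treatment)"]
    resid = table.loc["Residual"]
    f = float(row["F"])
    p = float(row["PR(>F)"])
    if np.isnan(f):
        # zero residual variance: a perfect separation gives F -> inf,
        # identical groups (SS_treatment = 0) give F = 0
        if float(row["sum_sq"]) <= 1e-12 * max(float(table["sum_sq"].sum()), 1e-300):
            f, p = 0.0, 1.0
        else:
            f, p = np.inf, 0.0
    elif np.isinf(f):
        p = 0.0
    means = {lab: float(arr.mean()) for lab, arr in arrays.items()}
    hi, lo = max(means, key=means.get), min(means, key=means.get)
    direction = "equal" if means[hi] == means[lo] else f"{hi} > {lo}"
    return AnovaResult(
        f_statistic=f,
        df_num=int(row["df"]),
        df_den=int(resid["df"]),
        p_value=p,
        direction=direction,
        treatment_means=means,
    )
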