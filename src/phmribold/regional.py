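"""Region-level dose-response statistics on volumes of activation.

Per subject and atlas region, the "volume of activation" is the number
of retained voxels in each sign component. Regions are compared across
treatment groups (vehicle and three doses) with a Kruskal-Wallis rank
test, Wilcoxon rank-sum post hocs at p <= .05, and a rank-based
effect size; the resulting region list is ranked by omnibus p-value and
cut with the same step-up rule used at the voxel level, so the printed
cutoff equals (i*/V) * (q/cV) for i* retained regions out of V analysed.

A dose-profile classifier labels each region's median response across
doses (descending, ascending, U-shaped, single-dose-max, or flat), the
vocabulary used to describe regional sensitivity to low vs high doses.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .activation import ActivationMap, fdr_filter, step_up_cutoff
from .synthetic import LabeledAtlas

__all__ = [
    "count_activated",
    "kruskal_wallis",
    "wilcoxon_ranksum",
    "effect_size",
    "rank_and_cut",
    "classify_profile",
    "DoseProfile",
    "regional_table",
    "most_effective_dose_tally",
    "load_reference_voa",
]

#: canonical group labels, in dose order
DOSE_ORDER = ("vehicle", "1.0", "3.3", "10")


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def count_activated(
    amap: ActivationMap, atlas: LabeledAtlas
) -> dict[str, dict[int, int]]:
    """Number of retained voxels per region, separately per sign.

    ``amap`` must be in atlas space (same grid as ``atlas.labels``)."""
    if amap.positive.shape != atlas.labels.shape:
        raise ValueError(
            f"activation map grid {amap.positive.shape} does not match "
            f"atlas grid {atlas.labels.shape}"
        )
    n_lab = max(atlas.names) + 1
    out: dict[str, dict[int, int]] = {}
    for sign, vol in (("positive", amap.positive), ("negative", amap.negative)):
        hits = np.bincount(
            atlas.labels.ravel()[vol.ravel() != 0], minlength=n_lab
        )
        out[sign] = {rid: int(hits[rid]) for rid in atlas.region_ids}
    return out


# ---------------------------------------------------------------------------
# Nonparametric tests
# ---------------------------------------------------------------------------

def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H on mid-ranks with tie correction; p from the
    chi-square approximation with k-1 degrees of freedom.

    All values identical across all groups gives H = 0, p = 1."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need at least two nonempty groups")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def wilcoxon_ranksum(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when both samples have n <= 8 and there are no
    ties; otherwise the normal approximation with tie correction."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def effect_size(h: float, n_total: int, k_groups: int) -> float:
    """Rank-based effect size for a Kruskal-Wallis comparison.

    Uses the chance-corrected estimator (H - k + 1) / (n - k), clipped to
    [0, 1]; under the null expectation E[H] = k - 1 it is exactly 0. The
    uncorrected H / (n - 1) variant is available via
    ``effect_size_uncorrected``."""
    if n_total <= k_groups:
        raise ValueError("effect size undefined for n <= k")
    return float(np.clip((h - k_groups + 1) / (n_total - k_groups), 0.0, 1.0))


def effect_size_uncorrected(h: float, n_total: int) -> float:
    """The H / (n - 1) rank epsilon-squared variant."""
    if n_total < 2:
        raise ValueError("need n >= 2")
    return float(np.clip(h / (n_total - 1), 0.0, 1.0))


# ---------------------------------------------------------------------------
# Ranked tables and the region-list cutoff
# ---------------------------------------------------------------------------

def rank_and_cut(
    table: pd.DataFrame,
    v_regions: int | None = None,
    q: float = 0.2,
    c_v: float = 1.0,
    p_column: str = "p",
) -> pd.DataFrame:
    """Sort regions by ascending omnibus p and apply the step-up rule.

    ``v_regions`` is the total number of regions analysed (defaults to
    the table length). Adds ``rank`` (1-based, ascending p) and
    ``significant`` columns; the implied significance level
    (i*/V) * (q/cV) is stored in ``result.attrs['cutoff']`` (None when
    nothing is retained)."""
    v = int(v_regions) if v_regions is not None else len(table)
    out = table.sort_values(p_column, kind="stable").reset_index(drop=True)
    p = out[p_column].to_numpy(float)
    # rank within the full V-region list: the table may be a head of it
    retained = fdr_filter(
        np.concatenate([p, np.ones(max(v - len(p), 0))]), q=q, c_v=c_v
    )[: len(p)]
    out["rank"] = np.arange(1, len(out) + 1)
    out["significant"] = retained
    n_ret = int(retained.sum())
    out.attrs["cutoff"] = step_up_cutoff(n_ret, v, q=q, c_v=c_v) if n_ret else None
    out.attrs["n_retained"] = n_ret
    out.attrs["v_regions"] = v
    return out


@dataclass(frozen=True)
class DoseProfile:
    """Categorical shape of a region's median response across doses."""

    label: str                    # descending | ascending | U-shaped |
                                  # single-dose-max | flat
    max_dose: str | None          # dose with the largest median, if unique


def classify_profile(
    medians: Sequence[float],
    doses: Sequence[str] = DOSE_ORDER,
    tol: float = 0.0,
) -> DoseProfile:
    """Classify the dose-response shape of four group medians
    (vehicle, low, mid, high).

    Rules, in precedence order over the three drug doses (m1, m2, m3):
    all four medians within ``tol`` of each other -> flat; strictly
    monotone beyond ``tol`` -> descending / ascending; mid dose strictly
    smallest with both ends larger -> U-shaped; a unique strict maximum
    -> single-dose-max; anything else -> flat. Ties fall through to
    flat."""
    m = np.asarray(medians, dtype=float)
    if m.size != 4:
        raise ValueError("expected four medians (vehicle + three doses)")
    m1, m2, m3 = m[1], m[2], m[3]
    drug_doses = list(doses[1:])

    if m.max() - m.min() <= tol:
        return DoseProfile("flat", None)
    max_idx = int(np.argmax(m[1:]))
    # a strict maximum must clear the runners-up by more than the tolerance
    unique_max = np.sum(m[1:] >= m[1:].max() - tol) == 1
    max_dose = drug_doses[max_idx] if unique_max else None
    if m1 > m2 + tol and m2 > m3 + tol:
        return DoseProfile("descending", max_dose)
    if m3 > m2 + tol and m2 > m1 + tol:
        return DoseProfile("ascending", max_dose)
    if m2 + tol < m1 and m2 + tol < m3:
        return DoseProfile("U-shaped", max_dose)
    if unique_max:
        return DoseProfile("single-dose-max", max_dose)
    return DoseProfile("flat", None)


def most_effective_dose_tally(
    table: pd.DataFrame,
    dose_columns: Sequence[str] = ("mg_1_0", "mg_3_3", "mg_10"),
) -> dict[str, int]:
    """Count, per drug dose, the regions whose median count has its
    strict maximum at that dose (ties and all-zero rows count for no
    dose)."""
    tally = {c: 0 for c in dose_columns}
    vals = table[list(dose_columns)].to_numpy(float)
    for row in vals:
        if np.all(row == 0):
            continue
        top = row.max()
        winners = np.nonzero(row == top)[0]
        if winners.size == 1:
            tally[dose_columns[winners[0]]] += 1
    return tally


def load_reference_voa(sign: str) -> pd.DataFrame:
    """Packaged reference table of published median volumes of activation
    per region and dose (positive or negative BOLD), with omnibus p and
    effect size columns."""
    if sign not in ("positive", "negative"):
        raise ValueError("sign must be 'positive' or 'negative'")
    ref = importlib.resources.files("phmribold.data") / f"voa_{sign}.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Full regional table
# ---------------------------------------------------------------------------

def regional_table(
    counts: Mapping[str, Mapping[str, Sequence[int]]],
    q: float = 0.2,
    c_v: float = 1.0,
    posthoc_alpha: float = 0.05,
    profile_tol: float = 0.0,
    atlas: LabeledAtlas | None = None,
) -> pd.DataFrame:
    """Build the ranked region table for one sign component.

    ``counts`` maps region key -> group label -> per-subject voxel
    counts. Emits one row per region with the group medians, the
    Kruskal-Wallis H and p, the rank effect size, pairwise Wilcoxon
    post-hoc p-values (reported only when the omnibus p <= posthoc
    alpha), the dose-profile label, and the step-up significance flag
    with the implied cutoff in ``.attrs['cutoff']``."""
    rows = []
    for region, by_group in counts.items():
        labels = [g for g in DOSE_ORDER if g in by_group] or list(by_group)
        groups = [np.asarray(by_group[g], dtype=float) for g in labels]
        n_total = sum(len(g) for g in groups)
        h, p = kruskal_wallis(groups)
        row: dict = {"region": region}
        if atlas is not None and isinstance(region, (int, np.integer)):
            row["region_name"] = atlas.names.get(int(region), str(region))
        medians = [float(np.median(g)) for g in groups]
        for g, med in zip(labels, medians):
            row[f"median_{g}"] = med
        row["H"] = h
        row["p"] = p
        row["omega_sq"] = effect_size(h, n_total, len(groups))
        if p <= posthoc_alpha:
            for (i, gi), (j, gj) in combinations(enumerate(labels), 2):
                row[f"wilcoxon_{gi}_vs_{gj}"] = wilcoxon_ranksum(groups[i], groups[j])
        if len(labels) == 4:
            prof = classify_profile(medians, doses=labels, tol=profile_tol)
            row["profile"] = prof.label
            row["max_dose"] = prof.max_dose
        rows.append(row)
    df = pd.DataFrame(rows)
    return rank_and_cut(df, v_regions=len(df), q=q, c_v=c_v)
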