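"""Ordered-trend tests across clinical stages and APOE e4 dosage, per sex,
and detection of genes with significantly opposite trends between sexes.

The Jonckheere-Terpstra statistic counts concordant cross-group pairs over
ordered groups (ties count 1/2). Small samples (total n <= 10) can be tested
exactly by enumerating every assignment of the observed values to the group
sizes; otherwise a tie-corrected normal approximation with continuity
correction is used. The companion spline trend test regresses expression on
a smooth basis of the ordinal level (quadratic polynomial for up to four
levels, natural cubic basis with three degrees of freedom beyond) and
F-tests the basis against an intercept-only model, capturing non-monotone
trends the rank test misses.

A differentially trended gene (DTG) is significant in BOTH sexes for the
same axis with opposite nonzero linear directions; genes opposite in at
least ``min_traits`` clinical traits form the TDTA set, genes opposite along
the APOE-dosage axis form the ADTA set.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import FrozenSet, List, Mapping, NamedTuple, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "JTResult",
    "jonckheere_test",
    "spline_trend_test",
    "trend_table",
    "apoe_trend",
    "trait_trends",
    "DTGSet",
    "opposite_trend_genes",
    "CLINICAL_TRAITS",
    "APOE_AXIS",
]

CLINICAL_TRAITS = ("braak", "cdr", "cerad", "plaque_density")
APOE_AXIS = "apoe"
EXACT_MAX_N = 10


class JTResult(NamedTuple):
    jt: float
    p: float
    direction: int


def _jt_statistic(groups: Sequence[np.ndarray]) -> float:
    jt = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a = groups[i][:, None]
            b = groups[j][None, :]
            jt += float((b > a).sum()) + 0.5 * float((b == a).sum())
    return jt


def _jt_moments(pooled: np.ndarray,
                sizes: Sequence[int]) -> Tuple[float, float]:
    """Null mean and tie-corrected variance of the JT statistic."""
    n = np.asarray(sizes, dtype=float)
    N = n.sum()
    _, tie_counts = np.unique(pooled, return_counts=True)
    t = tie_counts.astype(float)
    mean = (N * N - (n * n).sum()) / 4.0
    a = (N * (N - 1) * (2 * N + 5)
         - (n * (n - 1) * (2 * n + 5)).sum()
         - (t * (t - 1) * (2 * t + 5)).sum())
    b = (n * (n - 1) * (n - 2)).sum() * (t * (t - 1) * (t - 2)).sum()
    c = (n * (n - 1)).sum() * (t * (t - 1)).sum()
    var = a / 72.0
    if N > 2:
        var += b / (36.0 * N * (N - 1) * (N - 2))
    var += c / (8.0 * N * (N - 1))
    return mean, var


def _index_assignments(indices: Tuple[int, ...], sizes: Sequence[int]):
    """All distinct ways to split ``indices`` into consecutive groups of the
    given sizes (order within a group is irrelevant for JT)."""
    if not sizes:
        yield ()
        return
    k = sizes[0]
    for combo in itertools.combinations(indices, k):
        rest = tuple(i for i in indices if i not in combo)
        for tail in _index_assignments(rest, sizes[1:]):
            yield (combo,) + tail


def _exact_null(pooled: np.ndarray, sizes: Sequence[int]) -> np.ndarray:
    stats_ = []
    for assignment in _index_assignments(tuple(range(pooled.size)), sizes):
        groups = [pooled[list(g)] for g in assignment]
        stats_.append(_jt_statistic(groups))
    return np.asarray(stats_)


def jonckheere_test(
    groups: Sequence[Sequence[float]],
    alternative: str = "two-sided",
    mode: str = "auto",
) -> JTResult:
    """Jonckheere-Terpstra test for an ordered trend across ``groups``.

    ``groups`` are the per-level value collections in their natural order;
    ``alternative`` is ``increasing``, ``decreasing`` or ``two-sided``;
    ``mode`` is ``exact`` (total n <= 10), ``normal``, or ``auto`` (exact
    when feasible). Returns the statistic, the p-value, and the sign of
    ``JT - E[JT]`` as the linear trend direction.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(arrays) < 2:
        raise ValueError("need >= 2 non-empty ordered groups")
    if alternative not in ("increasing", "decreasing", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate(arrays)
    sizes = [a.size for a in arrays]
    N = pooled.size
    jt = _jt_statistic(arrays)
    mean, var = _jt_moments(pooled, sizes)
    direction = int(np.sign(jt - mean)) if var > 0 else 0

    if mode == "auto":
        mode = "exact" if N <= EXACT_MAX_N else "normal"
    if mode == "exact":
        if N > EXACT_MAX_N:
            raise ValueError(f"exact mode infeasible for n={N} (> "
                             f"{EXACT_MAX_N}); use mode='normal'")
        null = _exact_null(pooled, sizes)
        eps = 1e-9
        p_inc = float((null >= jt - eps).mean())
        p_dec = float((null <= jt + eps).mean())
    elif mode == "normal":
        if var <= 0:
            return JTResult(jt, 1.0, 0)
        sd = np.sqrt(var)
        p_inc = float(stats.norm.sf((jt - mean - 0.5) / sd))
        p_dec = float(stats.norm.sf((mean - jt - 0.5) / sd))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if var <= 0:
        return JTResult(jt, 1.0, 0)
    if alternative == "increasing":
        p = p_inc
    elif alternative == "decreasing":
        p = p_dec
    else:
        p = min(1.0, 2.0 * min(p_inc, p_dec))
    return JTResult(jt, p, direction)


def _natural_cubic_basis(x: np.ndarray, df: int = 3) -> np.ndarray:
    """Natural cubic spline basis (df columns, no intercept), knots at
    quantiles of the distinct values."""
    uniq = np.unique(x)
    knots = np.quantile(uniq, np.linspace(0, 1, df + 1))
    knots = np.unique(knots)
    if knots.size < 3:
        raise ValueError("too few distinct levels for a cubic basis")
    K = knots.size

    def d(k_idx):
        num = (np.maximum(x - knots[k_idx], 0) ** 3
               - np.maximum(x - knots[-1], 0) ** 3)
        return num / (knots[-1] - knots[k_idx])

    cols = [x]
    d_last = d(K - 2)
    for j in range(K - 2):
        cols.append(d(j) - d_last)
    return np.column_stack(cols)


def _trend_basis(levels: np.ndarray, df: int | None = None) -> np.ndarray:
    uniq = np.unique(levels)
    if uniq.size < 2:
        raise ValueError("need >= 2 distinct levels")
    x = (levels - levels.mean()) / max(levels.std(), 1e-12)
    if df is None:
        if uniq.size <= 4:
            degree = min(2, uniq.size - 1)
            return np.column_stack([x ** k for k in range(1, degree + 1)])
        return _natural_cubic_basis(x, df=3)
    if uniq.size < df + 1:
        raise ValueError(f"{uniq.size} distinct levels cannot support "
                         f"df={df}")
    if df <= 2:
        return np.column_stack([x ** k for k in range(1, df + 1)])
    return _natural_cubic_basis(x, df=df)


def _spline_f_test(Y: np.ndarray, levels: np.ndarray,
                   df: int | None = None) -> np.ndarray:
    """Vectorized F-test of a spline-of-level model vs intercept for every
    row of ``Y`` (genes x samples)."""
    basis = _trend_basis(levels, df=df)
    n = levels.size
    Bc = basis - basis.mean(axis=0, keepdims=True)
    Q, R = np.linalg.qr(Bc)
    keep = np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(np.diag(R)).max())
    Q = Q[:, keep]
    q = Q.shape[1]
    if q == 0:
        return np.ones(Y.shape[0])
    p_full = q + 1
    if n < p_full + 1:
        raise ValueError("too few samples for the spline basis")
    Yc = Y - Y.mean(axis=1, keepdims=True)
    rss0 = (Yc ** 2).sum(axis=1)
    proj = Yc @ Q
    rss1 = np.maximum(rss0 - (proj ** 2).sum(axis=1), 0.0)
    dfe = n - p_full
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss1) / q) / (rss1 / dfe)
    p = stats.f.sf(F, q, dfe)
    p = np.where(rss1 <= 1e-12 * np.maximum(rss0, 1.0),
                 np.where(rss0 > 1e-12, 0.0, 1.0), p)
    return p


def spline_trend_test(values: Sequence[float], levels: Sequence[int],
                      df: int | None = None) -> float:
    """F-test p-value of a smooth trend of ``values`` over ordinal
    ``levels`` (basis chosen as described in the module docstring)."""
    y = np.asarray(values, dtype=float)[None, :]
    lv = np.asarray(levels, dtype=float)
    if y.shape[1] != lv.size:
        raise ValueError("values and levels differ in length")
    return float(_spline_f_test(y, lv, df=df)[0])


def trend_table(
    matrix: pd.DataFrame,
    ordered_groups: Sequence[Sequence[str]],
    trait: str,
    sex: str,
) -> pd.DataFrame:
    """Per-gene Jonckheere (normal mode) + spline trend tests over ordered
    sample groups. Returns a tidy frame with one row per gene."""
    groups = [list(g) for g in ordered_groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError(f"trend on {trait}/{sex}: fewer than 2 non-empty "
                         "ordered groups")
    mats = [matrix[g].to_numpy(dtype=float) for g in groups]
    n_genes = matrix.shape[0]
    sizes = [m.shape[1] for m in mats]

    jt = np.zeros(n_genes)
    for i in range(len(mats)):
        for j in range(i + 1, len(mats)):
            A = mats[i][:, :, None]
            B = mats[j][:, None, :]
            jt += (B > A).sum(axis=(1, 2)) + 0.5 * (B == A).sum(axis=(1, 2))

    pooled = np.concatenate(mats, axis=1)
    p_lin = np.ones(n_genes)
    direction = np.zeros(n_genes, dtype=int)
    for g in range(n_genes):
        mean, var = _jt_moments(pooled[g], sizes)
        if var <= 0:
            continue
        sd = np.sqrt(var)
        p_inc = stats.norm.sf((jt[g] - mean - 0.5) / sd)
        p_dec = stats.norm.sf((mean - jt[g] - 0.5) / sd)
        p_lin[g] = min(1.0, 2.0 * min(p_inc, p_dec))
        direction[g] = int(np.sign(jt[g] - mean))

    levels = np.concatenate([np.full(s, k) for k, s in enumerate(sizes)])
    p_spl = _spline_f_test(pooled, levels.astype(float))

    return pd.DataFrame({
        "gene_id": matrix.index,
        "trait": trait,
        "sex": sex,
        "jt_stat": jt,
        "direction": direction,
        "p_linear": p_lin,
        "p_spline": p_spl,
    })


def _sex_samples(meta: pd.DataFrame, sex: str) -> pd.DataFrame:
    sub = meta.loc[meta["sex"] == sex]
    if sub.empty:
        raise ValueError(f"no samples with sex={sex!r}")
    return sub


def apoe_trend(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    sex: str,
    genotype_order: Sequence[str] = ("e23", "e33", "e34", "e44"),
) -> pd.DataFrame:
    """Trend tests over the ordered APOE genotype axis within one sex."""
    sub = _sex_samples(meta, sex)
    groups = []
    for gt in genotype_order:
        g = sub.index[sub["apoe"] == gt].intersection(matrix.columns)
        if len(g) == 0:
            if gt != "e44":
                logger.info("apoe_trend(%s): genotype %s absent", sex, gt)
            continue
        groups.append(list(g))
    return trend_table(matrix, groups, APOE_AXIS, sex)


def trait_trends(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    sex: str,
    groupings: Mapping[str, pd.Series],
    include_apoe: bool = True,
) -> pd.DataFrame:
    """All per-gene trend tests for one sex: the four clinical-trait axes
    (stage groupings in their ordinal order) plus, optionally, the APOE
    axis. BH adjustment is applied per axis across genes."""
    sub = _sex_samples(meta, sex)
    frames: List[pd.DataFrame] = []
    for trait in CLINICAL_TRAITS:
        if trait not in groupings:
            continue
        grouping = groupings[trait]
        idx = grouping.index.intersection(sub.index).intersection(
            matrix.columns)
        grouping = grouping.loc[idx]
        ordered = [list(grouping.index[grouping == lvl])
                   for lvl in grouping.cat.categories]
        ordered = [g for g in ordered if g]
        if len(ordered) < 2:
            logger.info("trait_trends(%s, %s): <2 stage groups; skipped",
                        trait, sex)
            continue
        frames.append(trend_table(matrix, ordered, trait, sex))
    if include_apoe:
        frames.append(apoe_trend(matrix, meta.loc[sub.index], sex))
    out = pd.concat(frames, ignore_index=True)
    out["q_linear"] = np.nan
    out["q_spline"] = np.nan
    for trait in out["trait"].unique():
        mask = out["trait"] == trait
        out.loc[mask, "q_linear"] = bh_adjust(out.loc[mask, "p_linear"])
        out.loc[mask, "q_spline"] = bh_adjust(out.loc[mask, "p_spline"])
    return out


@dataclass
class DTGSet:
    """Differentially trended genes with their per-axis evidence."""

    tdta: FrozenSet[str]
    adta: FrozenSet[str]
    evidence: pd.DataFrame  # gene_id, trait, dir_F, dir_M, opposite

    @property
    def genes(self) -> FrozenSet[str]:
        return self.tdta | self.adta


def opposite_trend_genes(
    female: pd.DataFrame,
    male: pd.DataFrame,
    min_traits: int = 2,
    alpha: float = 0.05,
    rule: str = "either",
) -> DTGSet:
    """Genes whose trends are significant in both sexes with opposite
    nonzero directions; ``rule`` picks which test must be significant
    (``linear``, ``spline`` or ``either``)."""
    if set(female["gene_id"]) != set(male["gene_id"]):
        raise ValueError("female and male trend tables cover different "
                         "gene universes")

    def significant(df: pd.DataFrame) -> pd.Series:
        if rule == "linear":
            return df["q_linear"] < alpha
        if rule == "spline":
            return df["q_spline"] < alpha
        if rule == "either":
            return (df["q_linear"] < alpha) | (df["q_spline"] < alpha)
        raise ValueError(f"unknown significance rule {rule!r}")

    f = female.assign(sig=significant(female))
    m = male.assign(sig=significant(male))
    merged = f.merge(m, on=["gene_id", "trait"], suffixes=("_F", "_M"))
    merged["opposite"] = (merged["sig_F"] & merged["sig_M"]
                          & (merged["direction_F"] * merged["direction_M"]
                             == -1))
    evidence = merged[["gene_id", "trait", "direction_F", "direction_M",
                       "opposite"]].copy()
    clinical = evidence[evidence["trait"] != APOE_AXIS]
    counts = clinical.groupby("gene_id")["opposite"].sum()
    tdta = frozenset(counts.index[counts >= min_traits])
    apoe_rows = evidence[(evidence["trait"] == APOE_AXIS)
                         & evidence["opposite"]]
    adta = frozenset(apoe_rows["gene_id"])
    return DTGSet(tdta=tdta, adta=adta, evidence=evidence)
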