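"""Module-level statistics: eigengene summaries, trait correlation,
Fisher-exact enrichment, the sum of -log10(p) ranking, and cell-type
assignment.

A module is summarized by the sign-aligned first principal component of its
member submatrix (the eigengene convention), correlated with each ordinal
clinical trait by Spearman rank correlation, and tested for enrichment of
gene signatures by one-sided Fisher exact tests over a declared background
universe. The combined module score sums -log10 of every p-value slot
(floored at 1e-300), and modules are ranked by descending score with
deterministic id tie-breaking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, NamedTuple, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "P_FLOOR",
    "module_summary",
    "module_trait_correlation",
    "enrichment_fet",
    "FETResult",
    "ModuleScore",
    "combined_score",
    "rank_modules",
    "assign_cell_types",
]

P_FLOOR = 1e-300


def module_summary(matrix: pd.DataFrame,
                   members: Iterable[str]) -> pd.Series:
    """Sign-aligned first principal component scores of the member
    submatrix (one value per sample).

    The sign is fixed so the summary correlates positively with the mean
    member expression, making it a stable "eigengene".
    """
    members = sorted(members)
    missing = [g for g in members if g not in matrix.index]
    if missing:
        raise KeyError(f"module members missing from matrix: {missing[:5]}")
    if len(members) < 2:
        raise ValueError("module summary needs >= 2 members")
    sub = matrix.loc[members].to_numpy(dtype=float)
    centered = sub - sub.mean(axis=1, keepdims=True)
    # PC1 of genes x samples: leading right singular vector scores samples
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    summary = s[0] * vt[0]
    mean_expr = centered.mean(axis=0)
    if np.dot(summary, mean_expr) < 0:
        summary = -summary
    return pd.Series(summary, index=matrix.columns, name="summary")


def module_trait_correlation(summary: pd.Series,
                             trait: pd.Series) -> Tuple[float, float]:
    """Two-sided Spearman correlation of a module summary with a trait.

    Pairs with a missing value are dropped; a constant input returns
    (rho=0, p=1) by convention (flagged in the log).
    """
    joined = pd.concat([summary, trait], axis=1, join="inner").dropna()
    if len(joined) < 5:
        raise ValueError("need >= 5 paired non-missing observations")
    x, y = joined.iloc[:, 0], joined.iloc[:, 1]
    if x.nunique() < 2 or y.nunique() < 2:
        logger.info("module_trait_correlation: constant input; rho=0, p=1")
        return 0.0, 1.0
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


class FETResult(NamedTuple):
    overlap: int
    fold_enrichment: float
    p: float


def enrichment_fet(set_a: Iterable[str], set_b: Iterable[str],
                   background: int) -> FETResult:
    """One-sided (enrichment) Fisher exact test of two gene sets over a
    background universe of ``background`` genes.

    Fold enrichment is ``(overlap/|A|) / (|B|/background)``; the p-value is
    the hypergeometric upper tail P(X >= overlap).
    """
    a, b = set(set_a), set(set_b)
    if not a:
        raise ValueError("enrichment_fet: empty query set")
    if background < len(a | b):
        raise ValueError("background smaller than the union of the sets")
    overlap = len(a & b)
    if not b:
        return FETResult(0, 0.0, 1.0)
    fe = (overlap / len(a)) / (len(b) / background)
    p = float(stats.hypergeom.sf(overlap - 1, background, len(b), len(a)))
    return FETResult(overlap, fe, min(p, 1.0))


@dataclass
class ModuleScore:
    """Per-module evidence: trait correlations and signature enrichments,
    combined as S = sum_i -log10(p_i)."""

    module_id: str
    trait_rho: Dict[str, float] = field(default_factory=dict)
    trait_p: Dict[str, float] = field(default_factory=dict)
    enrich_fe: Dict[str, float] = field(default_factory=dict)
    enrich_p: Dict[str, float] = field(default_factory=dict)

    @property
    def pvalues(self) -> List[float]:
        return list(self.trait_p.values()) + list(self.enrich_p.values())

    @property
    def S(self) -> float:
        return combined_score(self.pvalues)


def combined_score(pvalues: Sequence[float]) -> float:
    """Sum of -log10(p) with missing values treated as 1 and a floor of
    1e-300 keeping the total finite."""
    total = 0.0
    for p in pvalues:
        if p is None or np.isnan(p):
            p = 1.0
        total += -np.log10(max(float(p), P_FLOOR))
    return total


def rank_modules(scores: Sequence[ModuleScore]) -> pd.DataFrame:
    """Modules ordered by descending combined score S (ties by module id).

    Returns a frame with columns ``module_id, S, rank`` (rank 1 = best);
    permutation-invariant to the input order.
    """
    rows = sorted(((m.module_id, m.S) for m in scores),
                  key=lambda t: (-t[1], t[0]))
    return pd.DataFrame(
        [(mid, s, i + 1) for i, (mid, s) in enumerate(rows)],
        columns=["module_id", "S", "rank"],
    )


def assign_cell_types(
    modules: Mapping[str, Iterable[str]],
    marker_sets: Mapping[str, Iterable[str]],
    background: int,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Best-enriched cell type per module via a BH-adjusted FET grid.

    A module is assigned the marker set with the largest fold enrichment
    among those with q < ``fdr_max`` and FE > 1, else ``unassigned``.
    """
    records = []
    for mod_id, members in modules.items():
        for cell_type, markers in marker_sets.items():
            res = enrichment_fet(members, markers, background)
            records.append((mod_id, cell_type, res.overlap,
                            res.fold_enrichment, res.p))
    grid = pd.DataFrame(records, columns=["module_id", "cell_type",
                                          "overlap", "FE", "p"])
    grid["q"] = bh_adjust(grid["p"])
    assignments = []
    for mod_id, sub in grid.groupby("module_id", sort=True):
        hits = sub[(sub["q"] < fdr_max) & (sub["FE"] > 1.0)]
        if hits.empty:
            assignments.append((mod_id, "unassigned", np.nan, np.nan))
        else:
            best = hits.sort_values(["FE", "cell_type"],
                                    ascending=[False, True]).iloc[0]
            assignments.append((mod_id, best["cell_type"],
                                best["FE"], best["q"]))
    return pd.DataFrame(assignments,
                        columns=["module_id", "cell_type", "FE", "q"])
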