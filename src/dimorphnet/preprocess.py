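"""Gene filtering, covariate residualization and disease-stage grouping.

The abundance filter keeps genes detected above a minimum value in enough
samples (a count, or a fraction applied with a ceiling so "at least 10% of
samples" is never satisfied by fewer). Covariate correction is per-gene
ordinary-least-squares residualization against an intercept-plus-covariates
design (categoricals one-hot-expanded, reference level dropped), with the
gene's grand mean added back so the output stays on the input scale. Stage
groups follow the clinical conventions: Braak normal (<=2) / medium
(2-4] / severe (>4); CDR normal (=0) / MCI (=0.5) / AD (>0.5); plaque
density low (<=6) / medium (6-12] / high (>12); CERAD groups come from a
configurable ordered category list.
"""

from __future__ import annotations

import logging
import math
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "filter_genes",
    "residualize_covariates",
    "assign_stage_groups",
    "drop_excluded_samples",
    "STAGE_GROUPS",
]

#: Ordered group labels per trait, mirroring the clinical cutoffs.
STAGE_GROUPS = {
    "braak": ("normal", "medium", "severe"),
    "cdr": ("normal", "MCI", "AD"),
    "plaque_density": ("low", "medium", "high"),
}


def filter_genes(
    matrix: pd.DataFrame,
    min_value: float,
    min_count: int | None = None,
    min_fraction: float | None = None,
) -> pd.DataFrame:
    """Keep genes with ``value >= min_value`` in enough samples.

    Exactly one of ``min_count`` (">= k samples") or ``min_fraction``
    (">= ceil(f * n_samples) samples") must be given. Gene order and the
    sample axis are preserved.
    """
    if (min_count is None) == (min_fraction is None):
        raise ValueError("give exactly one of min_count / min_fraction")
    n = matrix.shape[1]
    if min_fraction is not None:
        if not 0 < min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")
        k = max(1, math.ceil(min_fraction * n))
        rule = f">= {min_value} in >= {min_fraction:.0%} of samples (k={k})"
    else:
        k = int(min_count)
        if k < 1:
            raise ValueError("min_count must be >= 1")
        rule = f">= {min_value} in >= {k} samples"
    keep = (matrix.to_numpy() >= min_value).sum(axis=1) >= k
    if not keep.any():
        raise ValueError(f"no gene passes the abundance filter ({rule})")
    out = matrix.loc[keep]
    logger.info("filter_genes: %d/%d genes pass rule %s",
                out.shape[0], matrix.shape[0], rule)
    return out


def _design_matrix(meta: pd.DataFrame,
                   covariate_names: Sequence[str]) -> pd.DataFrame:
    cols: Dict[str, np.ndarray] = {"(intercept)": np.ones(len(meta))}
    for name in covariate_names:
        if name not in meta.columns:
            raise KeyError(f"covariate {name!r} not in metadata")
        col = meta[name]
        if pd.api.types.is_numeric_dtype(col):
            if col.nunique() <= 1:
                # absorbed by the intercept: residualization is a no-op
                logger.info("covariate %r is constant; ignored", name)
                continue
            cols[name] = col.to_numpy(dtype=float)
        else:
            dummies = pd.get_dummies(col.astype("category"), drop_first=True)
            for level in dummies.columns:
                cols[f"{name}[{level}]"] = dummies[level].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=meta.index)


def residualize_covariates(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    covariate_names: Sequence[str],
) -> pd.DataFrame:
    """Per-gene OLS residuals against the covariates, plus the grand mean.

    The returned matrix is orthogonal to every covariate column (within
    numerical tolerance) and idempotent under re-application. A rank-
    deficient design raises with the offending columns listed.
    """
    missing = [s for s in matrix.columns if s not in meta.index]
    if missing:
        raise KeyError(f"samples absent from metadata: {missing[:5]}")
    design = _design_matrix(meta.loc[matrix.columns], covariate_names)
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns whose removal restores full rank
        collinear: List[str] = []
        for j, name in enumerate(design.columns):
            reduced = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                collinear.append(name)
        raise ValueError(f"rank-deficient design; collinear columns: "
                         f"{collinear}")
    Y = matrix.to_numpy(dtype=float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = resid.T + matrix.to_numpy().mean(axis=1, keepdims=True)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def drop_excluded_samples(meta: pd.DataFrame) -> pd.DataFrame:
    """Drop samples whose diagnosis is neither control nor AD (e.g. possible
    or probable disease calls excluded from the case/control contrasts)."""
    keep = meta["diagnosis"].isin(["control", "AD"])
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropping %d samples with excluded diagnosis", n_drop)
    return meta.loc[keep]


def assign_stage_groups(
    meta: pd.DataFrame,
    trait: str,
    cerad_bins: Sequence[tuple] | None = None,
) -> pd.Series:
    """Ordinal stage group per sample for one clinical trait.

    Returns an ordered categorical Series; samples with a missing trait value
    are excluded (their count is logged). ``trait`` is one of ``braak``,
    ``cdr``, ``plaque_density``, or ``cerad`` with ``cerad_bins`` supplying
    ``(label, ordered value list)`` pairs since CERAD categories carry no
    universal numeric cutoffs.
    """
    if trait == "cerad":
        if cerad_bins is None:
            cerad_bins = [("normal", [1.0]), ("possible", [2.0]),
                          ("probable", [3.0]), ("definite", [4.0])]
        values = meta[trait]
        mapping = {v: label for label, vals in cerad_bins for v in vals}
        groups = values.map(mapping)
        order = [label for label, _ in cerad_bins]
    elif trait in STAGE_GROUPS:
        values = meta[trait]
        order = list(STAGE_GROUPS[trait])
        if trait == "braak":
            groups = pd.cut(values, [-np.inf, 2, 4, np.inf], labels=order)
        elif trait == "cdr":
            conds = [values == 0, values == 0.5, values > 0.5]
            groups = pd.Series(np.select(conds, order, default=None),
                               index=meta.index)
        else:  # plaque_density
            groups = pd.cut(values, [-np.inf, 6, 12, np.inf], labels=order)
    else:
        raise ValueError(f"no stage rule for trait {trait!r}")
    groups = pd.Series(groups, index=meta.index, name=f"{trait}_group")
    n_missing = int(groups.isna().sum() + values.isna().sum()
                    - (groups.isna() & values.isna()).sum())
    if n_missing:
        logger.info("assign_stage_groups(%s): %d samples without a group",
                    trait, n_missing)
    groups = groups.dropna()
    return groups.astype(pd.CategoricalDtype(order, ordered=True))
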