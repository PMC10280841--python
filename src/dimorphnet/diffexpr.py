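"""Two-group differential expression, BH adjustment and signature extraction.

Expression is assumed to be on the log2 scale already, so the log2 fold
change of a gene is the difference of its group means and the test is the
ordinary pooled-variance two-sample t (df = nA + nB - 2) with a small
variance floor guarding genes that are constant within both groups. A
signature keeps the genes passing both an FDR cutoff (BH-adjusted p) and a
natural-scale fold-change cutoff, split by direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "Signature",
    "bh_adjust",
    "differential_expression",
    "extract_signature",
    "tcg_signatures",
    "TCG_COMPARISONS",
    "signatures_to_gmt",
]

VAR_FLOOR = 1e-8


@dataclass(frozen=True)
class Signature:
    """A named, signed gene set with its tested background size."""

    name: str
    up: FrozenSet[str]
    down: FrozenSet[str]
    background: int
    provenance: str = ""

    def __post_init__(self):
        if self.up & self.down:
            raise ValueError(f"signature {self.name}: up/down overlap")

    @property
    def genes(self) -> FrozenSet[str]:
        return self.up | self.down

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaNs propagate as NaN and are excluded from the ranking. Output is capped
    at 1 and monotone non-decreasing in the order of the sorted p-values.
    """
    p = np.asarray(pvals, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.sum() == 0:
        return q
    q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def differential_expression(
    matrix: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> pd.DataFrame:
    """Per-gene pooled-variance t-test of group A vs group B.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (mean_A -
    mean_B), ``t``, ``p``, ``q`` and ``var_floored`` (True where the pooled
    variance hit the floor).
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    A = matrix[group_a].to_numpy(dtype=float)
    B = matrix[group_b].to_numpy(dtype=float)
    na, nb = A.shape[1], B.shape[1]
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    ssa = ((A - mean_a[:, None]) ** 2).sum(axis=1)
    ssb = ((B - mean_b[:, None]) ** 2).sum(axis=1)
    df = na + nb - 2
    pooled = (ssa + ssb) / df
    floored = pooled < VAR_FLOOR
    pooled = np.maximum(pooled, VAR_FLOOR)
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    log2fc = mean_a - mean_b
    t = log2fc / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame(
        {"log2fc": log2fc, "t": t, "p": p, "q": bh_adjust(p),
         "var_floored": floored},
        index=matrix.index,
    )


def extract_signature(
    de: pd.DataFrame,
    fdr_max: float = 0.05,
    fc_min: float = 1.2,
    name: str = "signature",
    provenance: str = "",
) -> Signature:
    """Genes with ``q < fdr_max`` and natural-scale fold change beyond
    ``fc_min`` in either direction (up: FC > fc_min; down: 1/FC > fc_min)."""
    if fdr_max <= 0 or fc_min <= 0:
        raise ValueError("thresholds must be > 0")
    log_fc_min = np.log2(fc_min)
    sig = de["q"] < fdr_max
    up = frozenset(de.index[sig & (de["log2fc"] > log_fc_min)])
    down = frozenset(de.index[sig & (de["log2fc"] < -log_fc_min)])
    return Signature(name=name, up=up, down=down, background=len(de),
                     provenance=provenance)


#: The eight trait-stage contrasts used as trait-associated-gene (TCG)
#: signatures: (label, trait, group A, group B).
TCG_COMPARISONS: Tuple[Tuple[str, str, str, str], ...] = (
    ("braak_medium_vs_severe", "braak", "medium", "severe"),
    ("braak_normal_vs_severe", "braak", "normal", "severe"),
    ("cdr_mci_vs_ad", "cdr", "MCI", "AD"),
    ("cdr_normal_vs_ad", "cdr", "normal", "AD"),
    ("cerad_definite_vs_normal", "cerad", "definite", "normal"),
    ("cerad_definite_vs_possible", "cerad", "definite", "possible"),
    ("plaque_high_vs_low", "plaque_density", "high", "low"),
    ("plaque_medium_vs_low", "plaque_density", "medium", "low"),
)


def tcg_signatures(
    matrix: pd.DataFrame,
    groupings: Mapping[str, pd.Series],
    fdr_max: float = 0.05,
    fc_min: float = 1.2,
    label_prefix: str = "",
) -> Dict[str, Signature]:
    """The eight stage-contrast signatures for one stratum (typically one
    sex), given per-trait stage groupings from ``assign_stage_groups``.

    A contrast whose groups have fewer than two samples each is skipped with
    a logged reason. Grouping series may cover only a subset of the matrix
    columns (e.g. one sex); the intersection is used.
    """
    out: Dict[str, Signature] = {}
    for label, trait, a, b in TCG_COMPARISONS:
        if trait not in groupings:
            logger.info("tcg_signatures: no grouping for %s; skipped", trait)
            continue
        grouping = groupings[trait]
        samples = grouping.index.intersection(matrix.columns)
        grouping = grouping.loc[samples]
        ga = list(grouping.index[grouping == a])
        gb = list(grouping.index[grouping == b])
        if len(ga) < 2 or len(gb) < 2:
            logger.info("tcg_signatures: %s skipped (%d vs %d samples)",
                        label, len(ga), len(gb))
            continue
        de = differential_expression(matrix, ga, gb)
        out[label] = extract_signature(
            de, fdr_max=fdr_max, fc_min=fc_min,
            name=label_prefix + label,
            provenance=f"{trait}: {a} vs {b}")
    return out


def signatures_to_gmt(signatures: Iterable[Signature]) -> Dict[str, List[str]]:
    """Flatten signatures to GMT-ready ``{name_up/down: genes}`` entries."""
    sets: Dict[str, List[str]] = {}
    for sig in signatures:
        sets[f"{sig.name}_up"] = sorted(sig.up)
        sets[f"{sig.name}_down"] = sorted(sig.down)
    return sets
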