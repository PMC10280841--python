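"""Modular differential connectivity (MDC) between two condition-specific
networks, with dual permutation false-discovery rates.

A module's connectivity under one condition is the mean |Spearman rho| over
its unordered gene pairs computed on that condition's samples (the full
correlation structure, not the sparse planar backbone, so small modules do
not degenerate). MDC is the ratio of that mean between conditions: > 1 is a
gain of connectivity (GOC), < 1 a loss (LOC). Significance is assessed
against two nulls — shuffling sample-to-condition labels and replacing the
module with random gene sets of equal size — using |log MDC| as the
statistic with add-one smoothing; the per-module empirical p-values are
BH-adjusted across modules and the larger of the two FDRs is the final one.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "mean_module_connectivity",
    "mdc",
    "mdc_fdr",
]


def _abs_corr(values: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(values, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
    return np.abs(np.nan_to_num(rho, nan=0.0))


def _mean_offdiag(abs_rho: np.ndarray, idx: np.ndarray) -> float:
    sub = abs_rho[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(sub[iu].mean())


def mean_module_connectivity(matrix: pd.DataFrame,
                             genes: Iterable[str]) -> float:
    """Mean |Spearman rho| over unordered pairs of ``genes`` computed on
    the samples of ``matrix``."""
    genes = sorted(set(genes))
    missing = [g for g in genes if g not in matrix.index]
    if missing:
        raise KeyError(f"genes missing from matrix: {missing[:5]}")
    if len(genes) < 2:
        raise ValueError("need >= 2 genes for module connectivity")
    abs_rho = _abs_corr(matrix.loc[genes].to_numpy(dtype=float))
    return _mean_offdiag(abs_rho, np.arange(len(genes)))


def mdc(matrix_a: pd.DataFrame, matrix_b: pd.DataFrame,
        genes: Iterable[str]) -> float:
    """Modular differential connectivity: connectivity(A) / connectivity(B)
    for the same gene set under each condition's samples."""
    num = mean_module_connectivity(matrix_a, genes)
    den = mean_module_connectivity(matrix_b, genes)
    if den == 0:
        raise ZeroDivisionError("module has zero connectivity in the "
                                "denominator network")
    return num / den


def mdc_fdr(
    matrix_a: pd.DataFrame,
    matrix_b: pd.DataFrame,
    modules: Mapping[str, Iterable[str]],
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """MDC per module with sample- and gene-permutation FDRs and GOC/LOC
    calls.

    Returns a frame with columns ``module_id, mdc, fdr_sample, fdr_gene,
    fdr_final, call``; ``fdr_final = max(fdr_sample, fdr_gene)`` and a call
    of GOC (mdc > 1) or LOC (mdc < 1) requires ``fdr_final < alpha``.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    mods = {mid: sorted(set(genes)) for mid, genes in modules.items()}
    if not mods:
        raise ValueError("no modules given")
    shared = matrix_a.index.intersection(matrix_b.index)
    for mid, genes in mods.items():
        missing = [g for g in genes if g not in shared]
        if missing:
            raise KeyError(f"module {mid}: genes missing from a condition "
                           f"matrix: {missing[:5]}")
    universe = list(shared)
    gene_pos = {g: i for i, g in enumerate(universe)}
    A = matrix_a.loc[universe].to_numpy(dtype=float)
    B = matrix_b.loc[universe].to_numpy(dtype=float)
    na, nb = A.shape[1], B.shape[1]
    if na < 3 or nb < 3:
        raise ValueError("need >= 3 samples per condition to permute")

    abs_a, abs_b = _abs_corr(A), _abs_corr(B)

    def module_mdc(ca: np.ndarray, cb: np.ndarray, idx: np.ndarray) -> float:
        den = _mean_offdiag(cb, idx)
        num = _mean_offdiag(ca, idx)
        if den <= 0:
            return np.inf if num > 0 else 1.0
        return num / den

    observed = {}
    for mid, genes in mods.items():
        idx = np.array([gene_pos[g] for g in genes])
        observed[mid] = module_mdc(abs_a, abs_b, idx)

    rng = np.random.default_rng(seed)
    pooled = np.concatenate([A, B], axis=1)
    obs_stat = {mid: abs(np.log(max(v, 1e-12)))
                for mid, v in observed.items()}

    # --- sample-label permutation null ------------------------------------
    exceed_sample = {mid: 0 for mid in mods}
    for _ in range(n_perm):
        perm = rng.permutation(na + nb)
        pa, pb = pooled[:, perm[:na]], pooled[:, perm[na:]]
        ca, cb = _abs_corr(pa), _abs_corr(pb)
        for mid, genes in mods.items():
            idx = np.array([gene_pos[g] for g in genes])
            stat = abs(np.log(max(module_mdc(ca, cb, idx), 1e-12)))
            if stat >= obs_stat[mid]:
                exceed_sample[mid] += 1

    # --- random gene-set null --------------------------------------------
    exceed_gene = {mid: 0 for mid in mods}
    for _ in range(n_perm):
        for mid, genes in mods.items():
            idx = rng.choice(len(universe), size=len(genes), replace=False)
            stat = abs(np.log(max(module_mdc(abs_a, abs_b, idx), 1e-12)))
            if stat >= obs_stat[mid]:
                exceed_gene[mid] += 1

    mids = sorted(mods)
    p_sample = np.array([(exceed_sample[m] + 1) / (n_perm + 1) for m in mids])
    p_gene = np.array([(exceed_gene[m] + 1) / (n_perm + 1) for m in mids])
    fdr_sample = bh_adjust(p_sample)
    fdr_gene = bh_adjust(p_gene)
    fdr_final = np.maximum(fdr_sample, fdr_gene)

    rows = []
    for i, mid in enumerate(mids):
        value = observed[mid]
        call = "none"
        if fdr_final[i] < alpha:
            if value > 1.0:
                call = "GOC"
            elif value < 1.0:
                call = "LOC"
        rows.append((mid, value, fdr_sample[i], fdr_gene[i],
                     fdr_final[i], call))
    return pd.DataFrame(rows, columns=["module_id", "mdc", "fdr_sample",
                                       "fdr_gene", "fdr_final", "call"])
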