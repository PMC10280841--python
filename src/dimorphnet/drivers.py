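"""Sex-specific key-driver candidate selection, scoring and validation.

A candidate sex-specific driver must be a key network driver (hub) of a
disease-associated module in that sex's co-expression network and satisfy at
least one of three criteria: (1) differential expression both between
case and control within the sex and between female and male cases; (2)
significantly opposite expression trends between sexes in at least two
clinical traits; (3) significantly opposite trends across the ordered APOE
genotype axis. Candidates are then rank-ordered by the strength of their
association with disease: the -log10 p-values of their module's four trait
correlations plus the enrichment of the three case/control and
between-sex DEG signatures in the candidate's L-layer network neighborhood
are summed, and the ascending rank of that sum divided by the candidate
count yields a 0-1 score (the top candidate scores 1.0).
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, Mapping, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .coexnet import l_layer_neighborhood
from .diffexpr import Signature, bh_adjust
from .modstats import combined_score, enrichment_fet
from .trend import DTGSet

logger = logging.getLogger(__name__)

__all__ = [
    "CRITERION_SIGNATURES",
    "apply_criteria",
    "select_candidates",
    "candidate_score",
    "validate_targets",
]

#: Signature keys consumed by criterion 1 and the neighborhood scoring for a
#: given sex: within-sex case/control plus the between-sex case contrast.
CRITERION_SIGNATURES = {
    "F": ("F_AD_vs_Ctrl", "F_AD_vs_M_AD"),
    "M": ("M_AD_vs_Ctrl", "F_AD_vs_M_AD"),
}
SCORING_SIGNATURES = ("F_AD_vs_Ctrl", "M_AD_vs_Ctrl", "F_AD_vs_M_AD")


def apply_criteria(
    gene: str,
    sex: str,
    signatures: Mapping[str, Signature],
    dtg: DTGSet,
) -> Tuple[bool, bool, bool]:
    """The three sex-specific driver criteria for one gene.

    Criterion 1: member of both the within-sex case/control signature and
    the female-case vs male-case signature; criterion 2: in the
    trait-based differentially trended set (TDTA); criterion 3: in the
    APOE-based set (ADTA). The caller guarantees the gene is a hub of a
    disease-associated module.
    """
    own_key, contrast_key = CRITERION_SIGNATURES[sex]
    c1 = (gene in signatures[own_key].genes
          and gene in signatures[contrast_key].genes)
    c2 = gene in dtg.tdta
    c3 = gene in dtg.adta
    return c1, c2, c3


def select_candidates(
    knds_by_module: Mapping[str, Iterable[str]],
    ad_modules: Iterable[str],
    signatures: Mapping[str, Signature],
    dtg: DTGSet,
    sex: str,
) -> pd.DataFrame:
    """Hubs of disease-associated modules that pass >= 1 criterion.

    ``knds_by_module`` maps module id to its nominated hub genes;
    ``ad_modules`` is the disease-associated subset of module ids. Returns a
    frame with columns ``gene, sex, module_id, criterion1..3`` (one row per
    gene; a gene hubbing several qualifying modules is attributed to the
    lexicographically first)."""
    ad_modules = set(ad_modules)
    rows = []
    seen: Set[str] = set()
    for mod_id in sorted(ad_modules):
        for gene in sorted(knds_by_module.get(mod_id, ())):
            if gene in seen:
                continue
            c1, c2, c3 = apply_criteria(gene, sex, signatures, dtg)
            if c1 or c2 or c3:
                rows.append((gene, sex, mod_id, c1, c2, c3))
                seen.add(gene)
    return pd.DataFrame(rows, columns=["gene", "sex", "module_id",
                                       "criterion1", "criterion2",
                                       "criterion3"])


def candidate_score(
    candidates: pd.DataFrame,
    network: nx.Graph,
    signatures: Mapping[str, Signature],
    module_trait_p: Mapping[str, Mapping[str, float]],
    background: int,
    L: int = 3,
) -> pd.DataFrame:
    """Evidence score and 0-1 rank score per candidate.

    Per candidate the evidence p-values are its module's trait-correlation
    p-values plus the Fisher-exact p of each scoring signature's overlap
    with the candidate's L-layer neighborhood (neighborhood excludes the
    candidate); S sums their -log10. The score is ascending-rank(S)/n with
    ties broken lexicographically on the gene id, so scores form
    {1/n, ..., 1} and the strongest candidate scores 1.0.
    """
    if candidates.empty:
        return candidates.assign(S=pd.Series(dtype=float),
                                 score=pd.Series(dtype=float))
    records = []
    for row in candidates.itertuples(index=False):
        if row.gene not in network:
            raise KeyError(f"candidate {row.gene} absent from network")
        neighborhood = l_layer_neighborhood(network, row.gene, L)
        pvals: Dict[str, float] = {}
        for trait, p in sorted(module_trait_p.get(row.module_id, {}).items()):
            pvals[f"p_trait_{trait}"] = p
        for key in SCORING_SIGNATURES:
            sig = signatures[key]
            if neighborhood and sig.genes:
                res = enrichment_fet(neighborhood, sig.genes, background)
                pvals[f"p_enrich_{key}"] = res.p
            else:
                pvals[f"p_enrich_{key}"] = 1.0
        S = combined_score(list(pvals.values()))
        records.append({**row._asdict(), **pvals, "S": S})
    out = pd.DataFrame(records)
    order = out.sort_values(["S", "gene"], ascending=[True, True],
                            kind="mergesort").index
    n = len(out)
    ranks = pd.Series(np.arange(1, n + 1), index=order)
    out["score"] = ranks.reindex(out.index) / n
    return out.sort_values("score", ascending=False).reset_index(drop=True)


def validate_targets(
    network: nx.Graph,
    candidate: str,
    targets: Iterable[str],
    background: int,
    L_values: Sequence[int] = (2, 3, 4),
) -> pd.DataFrame:
    """Enrichment of an external target gene set (e.g. the union of
    perturbation-response DEGs) in the candidate's L-layer neighborhoods.

    One Fisher exact test per L, BH-adjusted across the tested L values.
    """
    target_set = set(targets)
    if not target_set:
        raise ValueError("empty target set")
    rows = []
    for L in L_values:
        neighborhood = l_layer_neighborhood(network, candidate, L)
        if neighborhood:
            res = enrichment_fet(neighborhood, target_set, background)
            rows.append((candidate, L, res.overlap, res.fold_enrichment,
                         res.p))
        else:
            rows.append((candidate, L, 0, 0.0, 1.0))
    out = pd.DataFrame(rows, columns=["gene", "L", "overlap", "FE", "p"])
    out["q"] = bh_adjust(out["p"])
    return out
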