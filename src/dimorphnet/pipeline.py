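"""End-to-end orchestration: staging, differential expression, trend tests,
per-sex planar networks, module ranking, differential connectivity and
sex-specific driver scoring, with every intermediate artifact written as
plain text and a deterministic JSON run report.

The flow mirrors the two-step driver discovery design: Step 1 selects hub
genes (key network drivers) of disease-associated modules that satisfy at
least one sex-specificity criterion; Step 2 rank-orders them by combined
module-trait and neighborhood-enrichment evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .coexnet import (build_pmfg, correlation_edges, detect_modules,
                      intramodular_connectivity, nominate_knds)
from .diffconn import mdc_fdr
from .diffexpr import (Signature, differential_expression, extract_signature,
                       signatures_to_gmt, tcg_signatures)
from .drivers import candidate_score, select_candidates
from .modstats import (ModuleScore, enrichment_fet, module_summary,
                       module_trait_correlation, rank_modules)
from .preprocess import (assign_stage_groups, drop_excluded_samples,
                         residualize_covariates)
from .synthetic import CohortConfig, DriverSpec, DTGSpec, generate_cohort
from .trend import opposite_trend_genes, trait_trends

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "make_fixtures", "load_config"]

TRAITS = ("braak", "cdr", "cerad", "plaque_density")


@dataclass
class PipelineConfig:
    """Thresholds, seeds and input description for one pipeline run."""

    simulate: Optional[CohortConfig] = None
    expression_path: Optional[str] = None
    metadata_path: Optional[str] = None
    covariates: Tuple[str, ...] = ("cov1", "cov2")
    fdr_max: float = 0.05
    fc_min: float = 1.2
    trend_alpha: float = 0.05
    trend_rule: str = "either"
    min_traits: int = 2
    edge_fdr: float = 0.05
    min_module_size: int = 10
    max_depth: int = 5
    ad_module_fraction: float = 0.25
    L: int = 3
    mdc_n_perm: int = 100
    mdc_alpha: float = 0.05
    seed: int = 0
    outdir: Optional[str] = None

    def validate(self) -> None:
        if (self.simulate is None) == (self.expression_path is None):
            raise ValueError("give either a simulate block or input paths")
        for name in ("fdr_max", "trend_alpha", "edge_fdr", "mdc_alpha",
                     "ad_module_fraction"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.fc_min <= 0 or self.L < 0 or self.min_module_size < 2:
            raise ValueError("invalid threshold configuration")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML/JSON pipeline config; a ``simulate`` block maps onto the
    cohort generator's configuration (driver/DTG specs as lists of dicts)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    sim = raw.pop("simulate", None)
    if sim is not None:
        sim = dict(sim)
        sim["driver_spec"] = tuple(
            DriverSpec(**d) for d in sim.get("driver_spec", []))
        sim["dtg_spec"] = tuple(
            DTGSpec(**d) for d in sim.get("dtg_spec", []))
        sim["module_sizes"] = tuple(sim.get("module_sizes", (30, 25, 20, 15)))
        de = sim.get("disease_effect", {})
        sim["disease_effect"] = {int(k): dict(v) for k, v in de.items()}
        if "covariate_effects" in sim:
            sim["covariate_effects"] = tuple(sim["covariate_effects"])
        sim = CohortConfig(**sim)
    if "covariates" in raw:
        raw["covariates"] = tuple(raw["covariates"])
    return PipelineConfig(simulate=sim, **raw)


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        return generate_cohort(config.simulate)
    matrix = dio.read_expression(config.expression_path)
    meta = dio.read_metadata(config.metadata_path)
    return matrix, meta, None


def _de_signatures(matrix: pd.DataFrame,
                   meta: pd.DataFrame,
                   config: PipelineConfig) -> Dict[str, Signature]:
    """The three case/control and between-sex signatures."""
    def samples(sex=None, dx=None):
        mask = pd.Series(True, index=meta.index)
        if sex is not None:
            mask &= meta["sex"] == sex
        if dx is not None:
            mask &= meta["diagnosis"] == dx
        return list(meta.index[mask])

    contrasts = {
        "F_AD_vs_Ctrl": (samples("F", "AD"), samples("F", "control")),
        "M_AD_vs_Ctrl": (samples("M", "AD"), samples("M", "control")),
        "F_AD_vs_M_AD": (samples("F", "AD"), samples("M", "AD")),
    }
    out = {}
    for name, (a, b) in contrasts.items():
        de = differential_expression(matrix, a, b)
        out[name] = extract_signature(de, config.fdr_max, config.fc_min,
                                      name=name, provenance=name)
    return out


def _sex_network(matrix: pd.DataFrame, meta: pd.DataFrame, sex: str,
                 config: PipelineConfig):
    """Planar network, module hierarchy, connectivity and hubs for one sex,
    built from that sex's case samples."""
    ad_samples = list(meta.index[(meta["sex"] == sex)
                                 & (meta["diagnosis"] == "AD")])
    sub = matrix[ad_samples]
    edges = correlation_edges(sub, fdr_max=config.edge_fdr)
    network = build_pmfg(edges, matrix.index)
    hierarchy = detect_modules(network, min_size=config.min_module_size,
                               max_depth=config.max_depth, seed=config.seed)
    knds_by_module: Dict[str, frozenset] = {}
    for mod in hierarchy.nonroot():
        profile = intramodular_connectivity(network, mod.members, mod.id)
        knds_by_module[mod.id] = nominate_knds(profile)
    return edges, network, hierarchy, knds_by_module


def _score_modules(matrix: pd.DataFrame, meta: pd.DataFrame, sex: str,
                   hierarchy, tcg_sigs: Mapping[str, Signature],
                   config: PipelineConfig):
    """Rank modules by combined trait-correlation and TCG-enrichment
    evidence; returns (ranked frame, trait-p mapping, AD-associated ids)."""
    sex_samples = list(meta.index[meta["sex"] == sex])
    sub = matrix[sex_samples]
    background = matrix.shape[0]
    scores: List[ModuleScore] = []
    trait_p: Dict[str, Dict[str, float]] = {}
    for mod in hierarchy.nonroot():
        summary = module_summary(sub, mod.members)
        score = ModuleScore(module_id=mod.id)
        for trait in TRAITS:
            rho, p = module_trait_correlation(
                summary, meta.loc[sex_samples, trait])
            score.trait_rho[trait] = rho
            score.trait_p[trait] = p
        for label, sig in tcg_sigs.items():
            if sig.genes:
                res = enrichment_fet(mod.members, sig.genes, background)
                score.enrich_fe[label] = res.fold_enrichment
                score.enrich_p[label] = res.p
            else:
                score.enrich_fe[label] = np.nan
                score.enrich_p[label] = 1.0
        trait_p[mod.id] = dict(score.trait_p)
        scores.append(score)
    if not scores:
        return pd.DataFrame(columns=["module_id", "S", "rank"]), {}, set()
    ranked = rank_modules(scores)
    n_top = max(1, int(np.ceil(config.ad_module_fraction * len(ranked))))
    ad_modules = set(ranked["module_id"].head(n_top))
    return ranked, trait_p, ad_modules


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute every stage and return the run report (also written, with all
    intermediate artifacts, under ``config.outdir`` when set)."""
    config.validate()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    matrix, meta, truth = _load_inputs(config)
    meta = drop_excluded_samples(meta)
    matrix = matrix[meta.index]
    covs = [c for c in config.covariates if c in meta.columns]
    if covs:
        matrix = residualize_covariates(matrix, meta, covs)

    groupings = {t: assign_stage_groups(meta, t) for t in TRAITS}

    signatures = _de_signatures(matrix, meta, config)

    tcg: Dict[str, Dict[str, Signature]] = {}
    for sex in ("F", "M"):
        sex_idx = meta.index[meta["sex"] == sex]
        sex_groupings = {t: g.loc[g.index.intersection(sex_idx)]
                         for t, g in groupings.items()}
        tcg[sex] = tcg_signatures(matrix[list(sex_idx)], sex_groupings,
                                  config.fdr_max, config.fc_min,
                                  label_prefix=f"{sex}_")

    trends = {sex: trait_trends(matrix, meta, sex, groupings)
              for sex in ("F", "M")}
    dtg = opposite_trend_genes(trends["F"], trends["M"],
                               min_traits=config.min_traits,
                               alpha=config.trend_alpha,
                               rule=config.trend_rule)

    report: Dict = {
        "n_genes": int(matrix.shape[0]),
        "n_samples": int(matrix.shape[1]),
        "seed": config.seed,
        "signatures": {name: {"up": len(sig.up), "down": len(sig.down)}
                       for name, sig in signatures.items()},
        "tcg_counts": {sex: {label: len(sig)
                             for label, sig in tcg[sex].items()}
                       for sex in ("F", "M")},
        "dtg": {"tdta": sorted(dtg.tdta), "adta": sorted(dtg.adta)},
        "networks": {},
        "mdc": {},
        "candidates": {},
    }

    nets = {}
    for sex in ("F", "M"):
        edges, network, hierarchy, knds_by_module = _sex_network(
            matrix, meta, sex, config)
        ranked, trait_p, ad_modules = _score_modules(
            matrix, meta, sex, hierarchy, tcg[sex], config)
        nets[sex] = dict(edges=edges, network=network, hierarchy=hierarchy,
                         knds_by_module=knds_by_module, ranked=ranked,
                         trait_p=trait_p, ad_modules=ad_modules)
        all_knds = set().union(*knds_by_module.values()) \
            if knds_by_module else set()
        report["networks"][sex] = {
            "n_nodes": network.number_of_nodes(),
            "n_edges": network.number_of_edges(),
            "n_modules": len(hierarchy.nonroot()),
            "n_knds": len(all_knds),
            "knd_genes": sorted(all_knds),
            "ad_modules": sorted(ad_modules),
        }
        if outdir:
            edges.to_csv(outdir / f"edges_{sex}.tsv", sep="\t", index=False)
            hierarchy.to_frame().to_csv(outdir / f"modules_{sex}.tsv",
                                        sep="\t", index=False)
            ranked.to_csv(outdir / f"module_scores_{sex}.tsv", sep="\t",
                          index=False)

    # modular differential connectivity, each sex's modules vs the other sex
    ad_meta = meta[meta["diagnosis"] == "AD"]
    mat_f = matrix[list(ad_meta.index[ad_meta["sex"] == "F"])]
    mat_m = matrix[list(ad_meta.index[ad_meta["sex"] == "M"])]
    for sex, own, other in (("F", mat_f, mat_m), ("M", mat_m, mat_f)):
        modules = {m.id: m.members
                   for m in nets[sex]["hierarchy"].nonroot()}
        if not modules:
            report["mdc"][sex] = {"n_tested": 0, "n_goc": 0, "n_loc": 0}
            continue
        table = mdc_fdr(own, other, modules, n_perm=config.mdc_n_perm,
                        alpha=config.mdc_alpha, seed=config.seed)
        report["mdc"][sex] = {
            "n_tested": int(len(table)),
            "n_goc": int((table["call"] == "GOC").sum()),
            "n_loc": int((table["call"] == "LOC").sum()),
        }
        if outdir:
            table.to_csv(outdir / f"mdc_{sex}.tsv", sep="\t", index=False)

    for sex in ("F", "M"):
        net = nets[sex]
        cands = select_candidates(net["knds_by_module"], net["ad_modules"],
                                  signatures, dtg, sex)
        scored = candidate_score(cands, net["network"], signatures,
                                 net["trait_p"],
                                 background=matrix.shape[0], L=config.L)
        report["candidates"][sex] = [
            {"gene": r.gene, "module_id": r.module_id,
             "criterion1": bool(r.criterion1),
             "criterion2": bool(r.criterion2),
             "criterion3": bool(r.criterion3),
             "S": round(float(r.S), 6), "score": round(float(r.score), 6)}
            for r in scored.itertuples(index=False)
        ]
        if outdir and not scored.empty:
            scored.to_csv(outdir / f"candidates_{sex}.tsv", sep="\t",
                          index=False)

    if outdir:
        dio.write_expression(matrix, outdir / "expression_corrected.tsv")
        dio.write_metadata(meta, outdir / "metadata_used.tsv")
        dio.write_gmt(signatures_to_gmt(signatures.values()),
                      outdir / "signatures.gmt")
        dio.write_gmt({"TDTA": sorted(dtg.tdta), "ADTA": sorted(dtg.adta)},
                      outdir / "dtg.gmt")
        pd.concat(trends.values()).to_csv(outdir / "trend_tests.tsv",
                                          sep="\t", index=False)
        if truth is not None:
            truth.to_json(outdir / "ground_truth.json")
        dio.write_json(report, outdir / "report.json")
    return report


def make_fixtures(outdir: str | Path, seed: int = 0) -> Dict[str, Path]:
    """Write the small deterministic inputs used by unit tests: a complete
    K5 edge list with distinct weights, a three-group ordered dataset for
    the trend test, and a toy marker GMT."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths: Dict[str, Path] = {}

    nodes = [f"G{i}" for i in range(5)]
    rows = []
    for i in range(5):
        for j in range(i + 1, 5):
            rows.append((nodes[i], nodes[j]))
    weights = rng.permutation(np.linspace(0.1, 0.95, len(rows)))
    k5 = pd.DataFrame(rows, columns=["gene_a", "gene_b"])
    k5["rho"] = weights
    k5["p"] = 0.001
    k5["q"] = 0.001
    k5 = k5.sort_values("rho", ascending=False)
    paths["k5_edges"] = outdir / "k5_edges.tsv"
    k5.to_csv(paths["k5_edges"], sep="\t", index=False)

    paths["jonckheere_groups"] = outdir / "jonckheere_groups.json"
    dio.write_json({"groups": [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]},
                   paths["jonckheere_groups"])

    paths["markers"] = outdir / "markers.gmt"
    dio.write_gmt({"neuron": [f"G{i:04d}" for i in range(0, 10)],
                   "microglia": [f"G{i:04d}" for i in range(10, 20)]},
                  paths["markers"])
    return paths
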