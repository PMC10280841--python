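"""Synthetic two-sex case/control expression cohorts with planted structure.

The generator emulates the statistical skeleton of a postmortem brain
case/control RNA-seq cohort on the log2 scale: correlated gene modules driven
by latent per-sample activities, disease shifts of module activity that may
differ between sexes, ordinal clinical severity traits (CDR, Braak stage,
CERAD category, plaque density) that increase with a per-sample severity
latent, an ordered APOE genotype axis with e4-dosage effects whose sign can
differ between sexes, and hub "driver" genes carrying the largest factor
loading of their module plus their own sex-specific expression effects.

Everything needed to verify downstream stages (module membership, planted
drivers, planted differentially-trended genes, injected covariate effects) is
returned as :class:`GroundTruth`.

The generative model, per sample ``s`` with module ``m``::

    a_m(s) = Normal(0, 1) + disease_effect[m][sex(s)] * 1[AD]
    x_g(s) = mu_g + lambda_g * a_m(s)
             + driver/DTG terms (AD x sex shifts, e4-dosage slopes)
             + c1 * cov1(s) + c2 * cov2(s) + Normal(0, noise_sd)

Background genes omit the factor term (pure unit-variance noise around their
baseline). Clinical traits are monotone quantile discretizations of a noisy
copy of the severity latent, so every stage group is non-empty by
construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as dio

__all__ = [
    "ConfigError",
    "DriverSpec",
    "DTGSpec",
    "CohortConfig",
    "GroundTruth",
    "generate_cohort",
    "counts_from_log2",
    "write_cohort",
    "default_config",
    "null_config",
    "driver_config",
]

SEXES = ("F", "M")
DIAGNOSES = ("control", "AD")
GENOTYPES = ("e23", "e33", "e34")
#: e4 allele dosage per genotype on the ordered axis e23 < e33 < e34 (< e44).
E4_DOSAGE = {"e23": 0, "e33": 0, "e34": 1, "e44": 2}

# Ordinal codes the discretized traits map onto. Braak "severe" is stage > 4,
# CDR 0.5 is MCI, plaque density > 12 is "high", CERAD 4 is definite AD.
TRAIT_LEVELS = {
    "braak": (1.0, 3.0, 5.0),
    "cdr": (0.0, 0.5, 2.0),
    "plaque_density": (3.0, 9.0, 15.0),
    "cerad": (1.0, 2.0, 3.0, 4.0),
}


class ConfigError(ValueError):
    """Raised for an internally inconsistent :class:`CohortConfig`."""


@dataclass(frozen=True)
class DriverSpec:
    """A planted hub driver gene.

    The driver receives ``loading`` as its factor loading (made the largest
    absolute loading in its module), an AD-by-sex expression shift
    ``de_effect`` applied in ``sex`` only, and an e4-dosage slope of
    ``+apoe_effect`` per allele in ``sex`` and ``-apoe_effect`` in the other
    sex (zero disables either effect).
    """

    module: int
    sex: str = "F"
    loading: float = 2.0
    de_effect: float = 2.0
    apoe_effect: float = 2.0


@dataclass(frozen=True)
class DTGSpec:
    """A planted differentially-trended background gene.

    ``axis`` is ``"apoe"`` (slope per e4 allele) or ``"severity"`` (slope per
    standardized severity-latent unit); the slope is ``+effect *
    female_direction`` in females and ``-effect * female_direction`` in males.
    """

    axis: str = "apoe"
    effect: float = 1.5
    female_direction: int = 1


@dataclass(frozen=True)
class CohortConfig:
    n_genes: int = 200
    n_samples_per_cell: int = 20
    module_sizes: Tuple[int, ...] = (30, 25, 20, 15)
    loading_mean: float = 1.0
    loading_sd: float = 0.2
    noise_sd: float = 0.5
    #: per-module, per-sex shift of latent module activity in AD samples
    disease_effect: Mapping[int, Mapping[str, float]] = field(
        default_factory=dict
    )
    trait_noise_sd: float = 0.3
    #: mean shift of the severity latent in AD vs control samples
    severity_gap: float = 2.5
    #: global coefficients of the two injected numeric covariates
    covariate_effects: Tuple[float, float] = (0.7, -0.4)
    driver_spec: Tuple[DriverSpec, ...] = ()
    dtg_spec: Tuple[DTGSpec, ...] = ()
    include_e44: bool = False
    seed: int = 0

    def validate(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ConfigError("sum(module_sizes) exceeds n_genes")
        if any(s < 3 for s in self.module_sizes):
            raise ConfigError("every module needs at least 3 genes")
        for name in ("loading_sd", "noise_sd", "trait_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_samples_per_cell < 1:
            raise ConfigError("n_samples_per_cell must be >= 1")
        n_drivers: Dict[int, int] = {}
        for spec in self.driver_spec:
            if not 0 <= spec.module < len(self.module_sizes):
                raise ConfigError(
                    f"driver module {spec.module} outside configured modules"
                )
            if spec.sex not in SEXES:
                raise ConfigError(f"driver sex {spec.sex!r} not in {SEXES}")
            n_drivers[spec.module] = n_drivers.get(spec.module, 0) + 1
            if n_drivers[spec.module] > self.module_sizes[spec.module]:
                raise ConfigError("more drivers than genes in a module")
        n_background = self.n_genes - sum(self.module_sizes)
        if len(self.dtg_spec) > n_background:
            raise ConfigError("more planted DTGs than background genes")
        for spec in self.dtg_spec:
            if spec.axis not in ("apoe", "severity"):
                raise ConfigError(f"unknown DTG axis {spec.axis!r}")
            if spec.female_direction not in (-1, 1):
                raise ConfigError("female_direction must be +1 or -1")

    @property
    def genotypes(self) -> Tuple[str, ...]:
        return GENOTYPES + ("e44",) if self.include_e44 else GENOTYPES

    @property
    def n_samples(self) -> int:
        return 2 * 2 * len(self.genotypes) * self.n_samples_per_cell


@dataclass
class GroundTruth:
    """What was planted, keyed by the generated gene/sample identifiers."""

    module_membership: Dict[str, str]  # gene -> "M<k>" or "background"
    planted_drivers: List[Tuple[str, str]]  # (gene, sex)
    planted_dtg: List[Tuple[str, str, int, int]]  # (gene, axis, dirF, dirM)
    true_disease_effects: Dict[str, Dict[str, float]]
    loadings: Dict[str, float]
    covariate_effects: Tuple[float, float]
    severity: Dict[str, float]  # sample -> severity latent

    def module_of(self, gene: str) -> str:
        return self.module_membership[gene]

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        dio.write_json(payload, path)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = dio.read_json(path)
        raw["planted_drivers"] = [tuple(t) for t in raw["planted_drivers"]]
        raw["planted_dtg"] = [tuple(t) for t in raw["planted_dtg"]]
        raw["covariate_effects"] = tuple(raw["covariate_effects"])
        return cls(**raw)


def _make_metadata(config: CohortConfig,
                   rng: np.random.Generator) -> Tuple[pd.DataFrame, np.ndarray]:
    """Sample metadata plus the severity latent (returned separately)."""
    rows = []
    for sex in SEXES:
        for dx in DIAGNOSES:
            for gt in config.genotypes:
                for _ in range(config.n_samples_per_cell):
                    rows.append((sex, dx, gt))
    n = len(rows)
    sample_ids = [f"S{i:04d}" for i in range(n)]
    meta = pd.DataFrame(rows, columns=["sex", "diagnosis", "apoe"],
                        index=pd.Index(sample_ids, name="sample_id"))
    is_ad = (meta["diagnosis"] == "AD").to_numpy()

    severity = rng.normal(0.0, 1.0, n) + config.severity_gap * is_ad
    for trait, levels in TRAIT_LEVELS.items():
        noisy = severity + rng.normal(0.0, config.trait_noise_sd, n)
        # fixed quantile thresholds of the (noisy) severity latent: every
        # stage group is non-empty by construction
        qs = np.quantile(noisy, np.linspace(0, 1, len(levels) + 1)[1:-1])
        codes = np.searchsorted(qs, noisy, side="right")
        meta[trait] = np.asarray(levels)[codes]

    meta["cov1"] = rng.normal(0.0, 1.0, n)
    meta["cov2"] = rng.normal(0.0, 1.0, n)
    return meta, severity


def generate_cohort(
    config: CohortConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (expression genes x samples, sample metadata, ground truth).

    Deterministic: the same config (including its ``seed``) always produces
    byte-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    meta, severity = _make_metadata(config, rng)
    n_samples = len(meta)
    sex = meta["sex"].to_numpy()
    is_ad = (meta["diagnosis"] == "AD").to_numpy().astype(float)
    dosage = meta["apoe"].map(E4_DOSAGE).to_numpy().astype(float)
    is_f = (sex == "F").astype(float)
    sex_sign = np.where(sex == "F", 1.0, -1.0)

    gene_ids = [f"G{i:04d}" for i in range(config.n_genes)]
    membership: Dict[str, str] = {g: "background" for g in gene_ids}
    loadings: Dict[str, float] = {}
    baseline = rng.uniform(2.0, 8.0, config.n_genes)

    X = np.zeros((config.n_genes, n_samples))

    # --- module genes -----------------------------------------------------
    gene_cursor = 0
    module_slots: Dict[int, List[int]] = {}
    for m, size in enumerate(config.module_sizes):
        idx = list(range(gene_cursor, gene_cursor + size))
        module_slots[m] = idx
        gene_cursor += size
        eff = config.disease_effect.get(m, {})
        shift = np.where(is_f == 1.0, eff.get("F", 0.0), eff.get("M", 0.0))
        activity = rng.normal(0.0, 1.0, n_samples) + shift * is_ad
        lam = np.abs(rng.normal(config.loading_mean, config.loading_sd, size))
        lam = np.maximum(lam, 0.05)  # keep every gene coupled to its factor
        for j, gi in enumerate(idx):
            membership[gene_ids[gi]] = f"M{m}"
            loadings[gene_ids[gi]] = float(lam[j])
            X[gi] = lam[j] * activity

    # --- planted drivers: overwrite loading, add sex-specific effects -----
    planted_drivers: List[Tuple[str, str]] = []
    planted_dtg: List[Tuple[str, str, int, int]] = []
    taken: Dict[int, int] = {m: 0 for m in module_slots}
    driver_slots = set()
    slot_of_spec = []
    for spec in config.driver_spec:
        slot = module_slots[spec.module][taken[spec.module]]
        taken[spec.module] += 1
        driver_slots.add(slot)
        slot_of_spec.append(slot)
    for spec, slot in zip(config.driver_spec, slot_of_spec):
        gene = gene_ids[slot]
        # drivers carry the largest |loading| of their module (ties allowed
        # between co-planted drivers)
        cap = abs(spec.loading) - 0.05
        for other in module_slots[spec.module]:
            og = gene_ids[other]
            if other not in driver_slots and loadings[og] > cap:
                X[other] *= cap / loadings[og]
                loadings[og] = cap
        old = loadings[gene]
        X[slot] *= spec.loading / old
        loadings[gene] = float(spec.loading)
        in_sex = (sex == spec.sex).astype(float)
        if spec.de_effect:
            X[slot] += spec.de_effect * is_ad * in_sex
        if spec.apoe_effect:
            own_sign = np.where(in_sex == 1.0, 1.0, -1.0)
            X[slot] += spec.apoe_effect * dosage * own_sign
            dir_f = 1 if spec.sex == "F" else -1
            planted_dtg.append((gene, "apoe", dir_f, -dir_f))
        planted_drivers.append((gene, spec.sex))

    # --- planted DTG genes on background slots ----------------------------
    background = [i for i in range(config.n_genes)
                  if membership[gene_ids[i]] == "background"]
    sev_std = (severity - severity.mean()) / max(severity.std(), 1e-12)
    for k, spec in enumerate(config.dtg_spec):
        gi = background[k]
        gene = gene_ids[gi]
        slope = spec.effect * spec.female_direction * sex_sign
        X[gi] += slope * (dosage if spec.axis == "apoe" else sev_std)
        planted_dtg.append((gene, spec.axis,
                            spec.female_direction, -spec.female_direction))

    # --- noise, baselines, injected covariates ----------------------------
    noise_sd = np.full(config.n_genes, config.noise_sd)
    noise_sd[background] = 1.0  # background genes are pure unit noise
    X += rng.normal(0.0, 1.0, X.shape) * noise_sd[:, None]
    X += baseline[:, None]
    c1, c2 = config.covariate_effects
    X += c1 * meta["cov1"].to_numpy()[None, :]
    X += c2 * meta["cov2"].to_numpy()[None, :]

    matrix = pd.DataFrame(X, index=pd.Index(gene_ids, name="gene_id"),
                          columns=meta.index)
    truth = GroundTruth(
        module_membership=membership,
        planted_drivers=planted_drivers,
        planted_dtg=planted_dtg,
        true_disease_effects={
            f"M{m}": {"F": config.disease_effect.get(m, {}).get("F", 0.0),
                      "M": config.disease_effect.get(m, {}).get("M", 0.0)}
            for m in range(len(config.module_sizes))
        },
        loadings=loadings,
        covariate_effects=config.covariate_effects,
        severity=dict(zip(meta.index, severity.tolist())),
    )
    return matrix, meta, truth


def correlated_blocks(
    blocks: Sequence[Tuple[int, float, float]],
    n_samples: int = 100,
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[str, List[str]]]:
    """Two condition matrices with block-equicorrelated modules.

    Each ``(size, corr_a, corr_b)`` block is generated as
    ``x = sqrt(c) * f + sqrt(1 - c) * eps`` per condition, giving pairwise
    within-block correlation ``c`` under that condition and independence
    between blocks. Returns (matrix_A, matrix_B, {block id: genes}) — the
    direct test-bench for differential-connectivity analysis.
    """
    rng = np.random.default_rng(seed)
    mats = {"A": [], "B": []}
    modules: Dict[str, List[str]] = {}
    gene_ids: List[str] = []
    for b, (size, corr_a, corr_b) in enumerate(blocks):
        names = [f"B{b}_{i:03d}" for i in range(size)]
        modules[f"block{b}"] = names
        gene_ids.extend(names)
        for cond, corr in (("A", corr_a), ("B", corr_b)):
            if not 0 <= corr < 1:
                raise ConfigError("block correlations must be in [0, 1)")
            f = rng.normal(0.0, 1.0, n_samples)
            eps = rng.normal(0.0, 1.0, (size, n_samples))
            mats[cond].append(np.sqrt(corr) * f + np.sqrt(1 - corr) * eps)
    index = pd.Index(gene_ids, name="gene_id")
    mat_a = pd.DataFrame(np.vstack(mats["A"]), index=index,
                         columns=[f"A{i:03d}" for i in range(n_samples)])
    mat_b = pd.DataFrame(np.vstack(mats["B"]), index=index,
                         columns=[f"B{i:03d}" for i in range(n_samples)])
    return mat_a, mat_b, modules


def counts_from_log2(matrix: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Optional count emission: Poisson draws around 2**x, for testing the
    abundance filter on count-like data."""
    rng = np.random.default_rng(seed)
    lam = np.power(2.0, matrix.to_numpy())
    return pd.DataFrame(rng.poisson(lam).astype(float),
                        index=matrix.index, columns=matrix.columns)


def write_cohort(config: CohortConfig, outdir: str | Path) -> Dict[str, Path]:
    """Generate and persist expression TSV, metadata TSV and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, meta, truth = generate_cohort(config)
    paths = {
        "expression": outdir / "expression.tsv",
        "metadata": outdir / "metadata.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    dio.write_expression(matrix, paths["expression"])
    dio.write_metadata(meta, paths["metadata"])
    truth.to_json(paths["ground_truth"])
    return paths


# ---------------------------------------------------------------------------
# Canonical study conditions used throughout the test-bench.
# ---------------------------------------------------------------------------

_DEFAULT_DISEASE_EFFECT = {
    0: {"F": 2.0, "M": 0.4},
    1: {"F": 0.4, "M": 2.0},
    2: {"F": 1.2, "M": 1.2},
    3: {"F": 0.0, "M": 0.0},
}


def default_config(seed: int = 0, **overrides) -> CohortConfig:
    """The canonical planted cohort: 200 genes, 240 samples, four modules
    with sex-asymmetric (M0 female-biased, M1 male-biased), sex-neutral (M2)
    and null (M3) disease shifts."""
    kwargs = dict(disease_effect=_DEFAULT_DISEASE_EFFECT, seed=seed)
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


def null_config(seed: int = 0, **overrides) -> CohortConfig:
    """Same cohort geometry with every planted effect removed: modules still
    co-express, but nothing is associated with disease, sex or genotype."""
    kwargs = dict(disease_effect={}, driver_spec=(), dtg_spec=(), seed=seed)
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


def driver_config(seed: int = 0, **overrides) -> CohortConfig:
    """Driver-recovery conditions: modules M0 and M1 carry equally strong
    sex-neutral disease shifts; M0 holds the planted female driver (top hub
    loading, female-AD expression shift, sex-opposite e4-dosage slope) and
    M1 holds its matched male "null twin" — an equally loaded hub of an
    equally disease-associated module with no planted sex effects."""
    kwargs = dict(
        disease_effect={
            0: {"F": 2.0, "M": 2.0},
            1: {"F": 2.0, "M": 2.0},
            2: {"F": 0.8, "M": 0.8},
            3: {"F": 0.0, "M": 0.0},
        },
        driver_spec=(
            DriverSpec(module=0, sex="F", loading=3.0,
                       de_effect=3.0, apoe_effect=1.2),
            DriverSpec(module=1, sex="M", loading=3.0,
                       de_effect=0.0, apoe_effect=0.0),
        ),
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)
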