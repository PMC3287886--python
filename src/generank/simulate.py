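"""Synthetic genotype/phenotype generators.

Two families of data are produced:

* a mini-exome with many genes, a rare-variant-dominated MAF spectrum,
  quantitative endpoints Q1/Q2, a nuisance trait Q4 and a binary affection
  status AFF driven by a liability threshold -- the structure the scoring
  pipeline assumes of a whole-exome association study of unrelated
  individuals;
* a case-control scenario with a block of null genes plus a single causal
  gene whose markers act through a logistic penetrance model with a stated
  per-allele odds ratio, sampled retrospectively (genotype given status by
  exact Bayes enumeration).

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .types import ENDPOINTS, NONSYNONYMOUS, SYNONYMOUS, GenotypeStudy, TruthTable


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


def _default_marker_count_dist() -> dict[int, float]:
    # right-skewed marker counts: most genes small, a tail of large genes
    weights = {k: 1.0 / k for k in range(1, 16)}
    total = sum(weights.values())
    return {k: w / total for k, w in weights.items()}


@dataclass
class ExomeConfig:
    """Configuration of the mini-exome generator.

    The defaults emulate a mini-exome association design of unrelated
    individuals: 697 subjects, genes of 1-15 markers, a variant spectrum
    dominated by rare alleles, nonsynonymous variants in the majority, a
    handful of causal genes per endpoint, and covariates age/sex/smoking.
    The number of genes is kept at a few hundred so that a full multi-method
    scan stays interactive; all sizes are free parameters.
    """

    n_individuals: int = 697
    n_genes: int = 300
    markers_per_gene: dict[int, float] = field(default_factory=_default_marker_count_dist)
    rare_fraction: float = 0.75
    maf_rare_range: tuple[float, float] = (0.0008, 0.01)
    maf_common_range: tuple[float, float] = (0.01, 0.5)
    nonsyn_fraction: float = 0.7
    n_causal_genes: dict[str, int] = field(
        default_factory=lambda: {"Q1": 9, "Q2": 13, "AFF": 15}
    )
    causal_markers_per_gene_max: int = 4
    causal_beta_range: tuple[float, float] = (0.2, 0.8)
    trait_noise_sd: float = 1.0
    prevalence: float = 0.3
    # covariate model (presence matters more than the particular values)
    age_range: tuple[int, int] = (30, 70)
    smoking_prevalence: float = 0.3
    covariate_beta: float = 0.25
    liability_trait_weight: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.markers_per_gene, dict) or not self.markers_per_gene:
            raise ConfigurationError("markers_per_gene must be a non-empty {count: weight} dict")
        if any(k < 1 or w < 0 for k, w in self.markers_per_gene.items()):
            raise ConfigurationError("markers_per_gene keys must be >=1 with weights >=0")
        if not math.isclose(sum(self.markers_per_gene.values()), 1.0, abs_tol=1e-6):
            total = sum(self.markers_per_gene.values())
            if total <= 0:
                raise ConfigurationError("markers_per_gene weights must sum to a positive value")
            self.markers_per_gene = {k: w / total for k, w in self.markers_per_gene.items()}
        for name in ("rare_fraction", "nonsyn_fraction", "prevalence", "smoking_prevalence"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name}={value} outside [0, 1]")
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigurationError("prevalence must lie strictly inside (0, 1)")
        lo_r, hi_r = self.maf_rare_range
        lo_c, hi_c = self.maf_common_range
        if not (0.0 < lo_r <= hi_r <= 0.01):
            raise ConfigurationError("maf_rare_range must lie within (0, 0.01]")
        if not (0.01 <= lo_c <= hi_c <= 0.5):
            raise ConfigurationError("maf_common_range must lie within [0.01, 0.5]")
        if hi_r > lo_c:
            raise ConfigurationError("rare and common MAF ranges must be disjoint and ordered")
        if any(n > self.n_genes for n in self.n_causal_genes.values()):
            raise ConfigurationError("n_causal_genes cannot exceed n_genes")
        if self.trait_noise_sd <= 0:
            raise ConfigurationError("trait_noise_sd must be positive")


def simulate_exome(cfg: ExomeConfig) -> tuple[GenotypeStudy, TruthTable]:
    """Draw a mini-exome genotype study and its causal-marker truth table.

    Genotypes are sampled per marker under Hardy-Weinberg equilibrium at the
    marker's generating MAF.  Causal markers are nonsynonymous only; each
    endpoint gets ``cfg.n_causal_genes[endpoint]`` causal genes with 1 to
    ``cfg.causal_markers_per_gene_max`` causal markers and positive effects
    drawn uniformly from ``cfg.causal_beta_range``.
    """
    rng = np.random.default_rng(cfg.seed)
    counts = np.array(sorted(cfg.markers_per_gene))
    probs = np.array([cfg.markers_per_gene[k] for k in counts], dtype=float)
    gene_sizes = rng.choice(counts, size=cfg.n_genes, p=probs)

    n_markers = int(gene_sizes.sum())
    gene_ids = np.repeat(
        [f"GENE{i:05d}" for i in range(cfg.n_genes)], gene_sizes
    )
    marker_ids = np.array([f"M{i:06d}" for i in range(n_markers)])

    is_rare = rng.random(n_markers) < cfg.rare_fraction
    maf = np.where(
        is_rare,
        rng.uniform(*cfg.maf_rare_range, size=n_markers),
        rng.uniform(*cfg.maf_common_range, size=n_markers),
    )
    is_nonsyn = rng.random(n_markers) < cfg.nonsyn_fraction
    func_class = np.where(is_nonsyn, NONSYNONYMOUS, SYNONYMOUS)

    genotypes = rng.binomial(2, maf, size=(cfg.n_individuals, n_markers)).astype(np.int8)

    markers = pd.DataFrame(
        {
            "marker_id": marker_ids,
            "gene_id": gene_ids,
            "func_class": func_class,
            "maf": maf,
        }
    )
    study = GenotypeStudy(genotypes=genotypes, markers=markers)

    # causal assignment: only genes carrying >=1 nonsynonymous marker qualify
    nonsyn_by_gene = markers[markers["func_class"] == NONSYNONYMOUS].groupby(
        "gene_id", sort=False
    )
    eligible = list(nonsyn_by_gene.groups)
    effects: dict[str, pd.DataFrame] = {}
    for endpoint in ENDPOINTS:
        n_causal = cfg.n_causal_genes.get(endpoint, 0)
        if n_causal > len(eligible):
            raise ConfigurationError(
                f"{endpoint}: requested {n_causal} causal genes but only "
                f"{len(eligible)} genes carry nonsynonymous markers"
            )
        chosen = rng.choice(eligible, size=n_causal, replace=False)
        rows = []
        for gene in chosen:
            gene_markers = nonsyn_by_gene.get_group(gene)["marker_id"].to_numpy()
            k_max = min(cfg.causal_markers_per_gene_max, len(gene_markers))
            k = int(rng.integers(1, k_max + 1))
            picked = rng.choice(gene_markers, size=k, replace=False)
            betas = rng.uniform(*cfg.causal_beta_range, size=k)
            rows.extend(
                {"gene_id": gene, "marker_id": m, "beta": b}
                for m, b in zip(picked, betas)
            )
        effects[endpoint] = pd.DataFrame(rows, columns=["gene_id", "marker_id", "beta"])
    return study, TruthTable(effects=effects)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def simulate_phenotypes(
    study: GenotypeStudy,
    truth: TruthTable,
    cfg: ExomeConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate one phenotype replicate for a fixed genotype study.

    Q1 and Q2 are additive linear traits (genetics + covariates + Gaussian
    noise); Q4 is a covariates-plus-noise nuisance trait with no genetic
    component; AFF is a liability-threshold trait whose latent score adds
    its own causal markers, standardized Q1 and Q2 contributions and noise,
    thresholded at the empirical (1 - prevalence) quantile so the realised
    prevalence matches ``cfg.prevalence``.

    A distinct ``seed`` yields a new phenotype replicate on the same
    genotypes (the replicate design of mini-exome workshops).
    """
    truth.validate_against(study)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = study.n_individuals

    age = rng.integers(cfg.age_range[0], cfg.age_range[1] + 1, size=n)
    sex = rng.integers(0, 2, size=n)
    smoking = (rng.random(n) < cfg.smoking_prevalence).astype(int)
    cov_effect = cfg.covariate_beta * (_zscore(age) + sex + smoking)

    marker_col = {m: j for j, m in enumerate(study.markers["marker_id"])}

    def genetic_component(endpoint: str) -> np.ndarray:
        frame = truth.causal_markers(endpoint)
        if frame.empty:
            return np.zeros(n)
        cols = [marker_col[m] for m in frame["marker_id"]]
        return study.genotypes[:, cols].astype(float) @ frame["beta"].to_numpy()

    noise = cfg.trait_noise_sd
    q1 = genetic_component("Q1") + cov_effect + rng.normal(0.0, noise, size=n)
    q2 = genetic_component("Q2") + cov_effect + rng.normal(0.0, noise, size=n)
    q4 = cov_effect + rng.normal(0.0, noise, size=n)

    w = cfg.liability_trait_weight
    liability = (
        genetic_component("AFF")
        + w * _zscore(q1)
        + w * _zscore(q2)
        + rng.normal(0.0, noise, size=n)
    )
    threshold = np.quantile(liability, 1.0 - cfg.prevalence)
    aff = (liability > threshold).astype(int)

    return pd.DataFrame(
        {
            "Q1": q1,
            "Q2": q2,
            "Q4": q4,
            "AFF": aff,
            "age": age,
            "sex": sex,
            "smoking": smoking,
        }
    )


# ---------------------------------------------------------------------------
# case-control scenario


@dataclass
class CaseControlScenario:
    """One cell of the case-control power grid.

    A block of null genes (each with ``markers_per_null_gene`` markers,
    allele frequencies uniform over ``null_af_range``) plus one causal gene
    of the same width whose first ``n_causal_markers`` markers carry a
    per-allele odds ratio ``odds_ratio`` at frequency ``causal_maf``.
    """

    n_null_genes: int = 2000
    markers_per_null_gene: int = 5
    n_causal_markers: int = 1
    causal_maf: float = 0.1
    odds_ratio: float = 1.5
    n_cases: int = 1000
    n_controls: int | None = None
    n_causal_replicates: int = 1000
    baseline_prevalence: float = 0.01
    null_af_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls is None:
            self.n_controls = self.n_cases
        if self.n_causal_markers > self.markers_per_null_gene:
            raise ConfigurationError(
                "n_causal_markers cannot exceed markers_per_null_gene"
            )
        if self.odds_ratio < 1.0:
            raise ConfigurationError("odds_ratio must be >= 1")
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ConfigurationError("baseline_prevalence must lie in (0, 1)")
        if not 0.0 < self.causal_maf <= 0.5:
            raise ConfigurationError("causal_maf must lie in (0, 0.5]")

    @property
    def n_total(self) -> int:
        return self.n_cases + int(self.n_controls)


def case_control_genotype_distributions(
    maf: float, odds_ratio: float, prevalence: float
) -> tuple[np.ndarray, np.ndarray]:
    """Exact genotype distributions in cases and controls.

    Under HWE genotype probabilities ``P(g)`` for ``g in {0,1,2}`` and a
    logistic penetrance ``P(case | g) = expit(alpha + g*log(OR))`` with the
    intercept solved so the population prevalence equals ``prevalence``,
    returns ``(P(g | case), P(g | control))`` by Bayes' rule.
    """
    p_g = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
    log_or = math.log(odds_ratio)

    def prevalence_at(alpha: float) -> float:
        return float(p_g @ expit(alpha + np.arange(3) * log_or)) - prevalence

    alpha = brentq(prevalence_at, -60.0, 60.0)
    pen = expit(alpha + np.arange(3) * log_or)
    p_case = p_g * pen / prevalence
    p_control = p_g * (1.0 - pen) / (1.0 - prevalence)
    return p_case, p_control


def case_control_status(sc: CaseControlScenario) -> np.ndarray:
    """Status vector: cases first (1), then controls (0)."""
    return np.concatenate(
        [np.ones(sc.n_cases, dtype=np.int8), np.zeros(int(sc.n_controls), dtype=np.int8)]
    )


def simulate_null_genes(sc: CaseControlScenario, seed: int | None = None) -> GenotypeStudy:
    """Genotypes for the scenario's null-gene block, independent of status."""
    rng = np.random.default_rng(sc.seed if seed is None else seed)
    m = sc.markers_per_null_gene
    n_markers = sc.n_null_genes * m
    af = rng.uniform(*sc.null_af_range, size=n_markers)
    genotypes = rng.binomial(2, af, size=(sc.n_total, n_markers)).astype(np.int8)
    markers = pd.DataFrame(
        {
            "marker_id": [f"NM{i:06d}" for i in range(n_markers)],
            "gene_id": np.repeat([f"NULL{i:05d}" for i in range(sc.n_null_genes)], m),
            "func_class": NONSYNONYMOUS,
            "maf": af,
        }
    )
    return GenotypeStudy(genotypes=genotypes, markers=markers)


def simulate_causal_gene(
    sc: CaseControlScenario, seed: int | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """One replicate of the causal gene's genotypes given case/control status.

    Returns the ``(n_total, markers_per_null_gene)`` genotype block (columns
    ordered causal markers first) and the marker metadata frame.  Causal
    markers are sampled from the exact genotype-given-status distributions;
    the remaining markers are null fillers with uniform allele frequencies.
    """
    rng = np.random.default_rng(sc.seed if seed is None else seed)
    m = sc.markers_per_null_gene
    genotypes = np.empty((sc.n_total, m), dtype=np.int8)

    p_case, p_control = case_control_genotype_distributions(
        sc.causal_maf, sc.odds_ratio, sc.baseline_prevalence
    )
    g_levels = np.arange(3)
    n_ctrl = int(sc.n_controls)
    for j in range(sc.n_causal_markers):
        genotypes[: sc.n_cases, j] = rng.choice(g_levels, size=sc.n_cases, p=p_case)
        genotypes[sc.n_cases :, j] = rng.choice(g_levels, size=n_ctrl, p=p_control)

    n_fill = m - sc.n_causal_markers
    maf = np.full(m, sc.causal_maf)
    if n_fill:
        fill_af = rng.uniform(*sc.null_af_range, size=n_fill)
        genotypes[:, sc.n_causal_markers :] = rng.binomial(
            2, fill_af, size=(sc.n_total, n_fill)
        )
        maf[sc.n_causal_markers :] = fill_af

    markers = pd.DataFrame(
        {
            "marker_id": [f"CM{j:03d}" for j in range(m)],
            "gene_id": "CAUSAL",
            "func_class": NONSYNONYMOUS,
            "maf": maf,
        }
    )
    return genotypes, markers


def simulate_case_control(
    sc: CaseControlScenario,
) -> tuple[GenotypeStudy, np.ndarray, TruthTable]:
    """Full scenario draw: null genes + one causal gene + status vector."""
    root = np.random.SeedSequence(sc.seed)
    null_seed, causal_seed = (int(s.generate_state(1)[0] % 2**31) for s in root.spawn(2))
    null_study = simulate_null_genes(sc, seed=null_seed)
    causal_geno, causal_markers = simulate_causal_gene(sc, seed=causal_seed)

    genotypes = np.hstack([null_study.genotypes, causal_geno])
    markers = pd.concat([null_study.markers, causal_markers], ignore_index=True)
    study = GenotypeStudy(genotypes=genotypes, markers=markers)

    beta = math.log(sc.odds_ratio)
    if beta == 0.0:  # degenerate OR=1 scenario carries no causal effect
        effects = pd.DataFrame(columns=["gene_id", "marker_id", "beta"])
    else:
        effects = pd.DataFrame(
            {
                "gene_id": "CAUSAL",
                "marker_id": causal_markers["marker_id"][: sc.n_causal_markers],
                "beta": beta,
            }
        )
    truth = TruthTable(effects={"CC": effects})
    return study, case_control_status(sc), truth
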