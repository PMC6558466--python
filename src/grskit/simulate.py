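"""Synthetic case/control cohorts with the structure the GRS model assumes.

Controls draw genotypes per SNP under Hardy-Weinberg equilibrium at the
catalog risk-allele frequency, ``P(0,1,2) = ((1-f)^2, 2f(1-f), f^2)``, so the
cohort mean GRS converges to 1. Cases draw from the tilted law
``P(g | case) = OR^g P(g) / W`` — the unique per-SNP genotype distribution
consistent with a multiplicative per-allele odds ratio, whose normalizer is
exactly the standardization weight ``W``. SNPs are simulated independently,
matching the pairwise-r² < 0.2 curation the catalogs assume.

One master seed spawns independent child streams for cases, controls, sex
labels and missingness, so enlarging one arm never perturbs the draws of
another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import SNPCatalog, SNPRecord, validate_catalog
from .errors import AnalysisError, CatalogError
from .genotypes import GenotypeMatrix
from .grs import expected_risk_weight


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one simulated case/control study."""

    catalog: SNPCatalog
    n_cases: int
    n_controls: int
    seed: int
    sex_ratio: float = 0.5  # fraction male
    missing_rate: float = 0.0  # uniform genotype missingness

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise AnalysisError("cohort sizes must be non-negative")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise AnalysisError("sex_ratio must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise AnalysisError("missing_rate must be in [0, 1)")


def control_genotype_probs(catalog: SNPCatalog) -> np.ndarray:
    """SNPs × 3 matrix of HWE genotype probabilities ((1-f)^2, 2f(1-f), f^2)."""
    f = catalog.risk_freqs
    return np.column_stack([(1 - f) ** 2, 2 * f * (1 - f), f**2])


def case_genotype_probs(catalog: SNPCatalog) -> np.ndarray:
    """SNPs × 3 matrix of tilted genotype probabilities ``OR^g P(g) / W``."""
    or_ = catalog.odds_ratios[:, None]
    w = expected_risk_weight(catalog.risk_freqs, catalog.odds_ratios)[..., None]
    return control_genotype_probs(catalog) * or_ ** np.arange(3) / w


def _draw_genotypes(
    probs: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n × SNPs dosage draws from per-SNP genotype distributions."""
    cum = probs.cumsum(axis=1)
    u = rng.random((n, probs.shape[0]))
    return (u[:, :, None] > cum[None, :, :2]).sum(axis=2).astype(float)


def _simulate_arm(
    catalog: SNPCatalog,
    n: int,
    rng: np.random.Generator,
    probs: np.ndarray,
    prefix: str,
) -> GenotypeMatrix:
    if n < 0:
        raise AnalysisError("n must be non-negative")
    problems = validate_catalog(catalog, allow_monomorphic=True)
    if problems:
        raise CatalogError("invalid catalog: " + "; ".join(problems))
    width = max(5, len(str(max(n, 1))))
    return GenotypeMatrix(
        subject_ids=tuple(f"{prefix}{i:0{width}d}" for i in range(1, n + 1)),
        snp_ids=catalog.rsids,
        dosages=_draw_genotypes(probs, n, rng),
        oriented=True,
        alleles={r.rsid: (r.risk_allele, r.other_allele) for r in catalog.records},
    )


def simulate_controls(
    catalog: SNPCatalog, n: int, seed: int | np.random.Generator
) -> GenotypeMatrix:
    """Simulate ``n`` population controls under HWE at the catalog frequencies."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _simulate_arm(catalog, n, rng, control_genotype_probs(catalog), "ctrl")


def simulate_cases(
    catalog: SNPCatalog, n: int, seed: int | np.random.Generator
) -> GenotypeMatrix:
    """Simulate ``n`` cases under the tilted (OR-enriched) genotype law."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _simulate_arm(catalog, n, rng, case_genotype_probs(catalog), "case")


def simulate_study(spec: CohortSpec) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate a full case/control study: genotypes plus a phenotype table.

    Returns the concatenated case+control dosage matrix (cases first) and a
    phenotype DataFrame with columns ``subject_id``, ``status`` (case /
    control for the catalog's cancer type) and ``sex`` (male / female drawn
    by ``sex_ratio``). Deterministic for a fixed spec: the same seed yields
    byte-identical outputs.
    """
    children = np.random.SeedSequence(spec.seed).spawn(4)
    cases = simulate_cases(
        spec.catalog, spec.n_cases, np.random.default_rng(children[0])
    )
    controls = simulate_controls(
        spec.catalog, spec.n_controls, np.random.default_rng(children[1])
    )
    dosages = np.vstack([cases.dosages, controls.dosages])
    if spec.missing_rate > 0:
        rng_miss = np.random.default_rng(children[3])
        dosages = np.where(
            rng_miss.random(dosages.shape) < spec.missing_rate, np.nan, dosages
        )
    subject_ids = cases.subject_ids + controls.subject_ids
    matrix = GenotypeMatrix(
        subject_ids=subject_ids,
        snp_ids=spec.catalog.rsids,
        dosages=dosages,
        oriented=True,
        alleles=dict(cases.alleles),
    )
    rng_sex = np.random.default_rng(children[2])
    sex = np.where(
        rng_sex.random(len(subject_ids)) < spec.sex_ratio, "male", "female"
    )
    phenotypes = pd.DataFrame(
        {
            "subject_id": list(subject_ids),
            "status": ["case"] * spec.n_cases + ["control"] * spec.n_controls,
            "sex": sex,
        }
    )
    return matrix, phenotypes


def random_catalog(
    n_snps: int,
    seed: int,
    freq_range: tuple[float, float] = (0.1, 0.9),
    or_range: tuple[float, float] = (1.05, 1.5),
    cancer_type: str = "synthetic",
) -> SNPCatalog:
    """A synthetic risk-SNP panel with frequencies and ORs drawn uniformly.

    Stands in for a published GWAS panel when exercising the pipeline
    without real summary statistics; rsids are ``snp001`` etc.
    """
    if n_snps < 1:
        raise CatalogError("catalog needs at least one SNP")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(*freq_range, n_snps)
    ors = rng.uniform(*or_range, n_snps)
    width = max(3, len(str(n_snps)))
    records = tuple(
        SNPRecord(
            rsid=f"snp{i + 1:0{width}d}",
            chrom="1",
            pos=1000 * (i + 1),
            risk_allele="A",
            other_allele="G",
            odds_ratio=float(ors[i]),
            risk_freq=float(freqs[i]),
        )
        for i in range(n_snps)
    )
    return SNPCatalog(cancer_type, records)
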