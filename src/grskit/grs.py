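"""Population-standardized genetic risk score (GRS).

For a panel of ``n`` independent risk SNPs, an individual's score is the
product of per-allele odds ratios normalized per SNP by its expected risk
effect in the population::

    GRS = prod_i  OR_i^{g_i} / W_i
    W_i = f_i^2 OR_i^2 + 2 f_i (1 - f_i) OR_i + (1 - f_i)^2

where ``g_i`` in {0, 1, 2} counts risk alleles, ``OR_i`` is the external
allelic odds ratio and ``f_i`` the risk-allele frequency in the reference
population. ``W_i`` is exactly the Hardy-Weinberg expectation of
``OR_i^g``, so E[GRS] = 1 in the general population and a score reads as a
relative risk: GRS 1.8 means 1.8-fold the population-average risk.

Products accumulate in log space so catalogs of ~80 SNPs cannot under- or
overflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .catalog import SNPCatalog
from .errors import AnalysisError, GenotypeError
from .genotypes import GenotypeMatrix

MissingPolicy = Literal["skip", "mean_dose"]


@dataclass(frozen=True)
class GRSVector:
    """Per-subject GRS values and the number of SNPs each score used."""

    subject_ids: tuple[str, ...]
    grs: np.ndarray
    n_used: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "grs", np.asarray(self.grs, dtype=float))
        object.__setattr__(self, "n_used", np.asarray(self.n_used, dtype=int))
        if not (len(self.subject_ids) == self.grs.size == self.n_used.size):
            raise AnalysisError("GRSVector fields have inconsistent lengths")
        if (self.grs <= 0).any():
            raise AnalysisError("GRS values must be positive")

    def __len__(self) -> int:
        return self.grs.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": list(self.subject_ids),
                "grs": self.grs,
                "n_used": self.n_used,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_grs_tsv(path: str | Path) -> GRSVector:
    frame = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    return GRSVector(
        tuple(frame["subject_id"]),
        frame["grs"].to_numpy(float),
        frame["n_used"].to_numpy(int),
    )


def expected_risk_weight(risk_freq, odds_ratio):
    """Per-SNP normalizer ``W = f^2 OR^2 + 2 f (1-f) OR + (1-f)^2``.

    Equals ``E[OR^g]`` for a genotype ``g`` drawn under Hardy-Weinberg
    equilibrium at risk-allele frequency ``f``. Accepts scalars or arrays.
    """
    f = np.asarray(risk_freq, dtype=float)
    or_ = np.asarray(odds_ratio, dtype=float)
    if (or_ <= 0).any() or not np.isfinite(or_).all():
        raise AnalysisError("odds_ratio must be finite and > 0")
    if ((f < 0) | (f > 1)).any():
        raise AnalysisError("risk_freq must be in [0, 1]")
    w = f**2 * or_**2 + 2 * f * (1 - f) * or_ + (1 - f) ** 2
    return float(w) if w.ndim == 0 else w


def _log_contributions(
    dosages: np.ndarray, catalog: SNPCatalog, missing_policy: MissingPolicy
) -> tuple[np.ndarray, np.ndarray]:
    """Per-entry log(OR^g / W) terms and the non-missing mask.

    ``dosages`` is subjects × catalog SNPs with NaN for missing. Under the
    ``skip`` policy a missing SNP contributes log 1 = 0 (that SNP's factor is
    its population mean); under ``mean_dose`` the missing dosage is imputed
    as its expectation 2f before exponentiation.
    """
    if missing_policy not in ("skip", "mean_dose"):
        raise AnalysisError(f"unknown missing policy {missing_policy!r}")
    d = np.atleast_2d(np.asarray(dosages, dtype=float))
    finite = d[~np.isnan(d)]
    if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
        raise GenotypeError("dosages must be 0, 1, 2 or missing")
    log_or = np.log(catalog.odds_ratios)
    log_w = np.log(expected_risk_weight(catalog.risk_freqs, catalog.odds_ratios))
    used = ~np.isnan(d)
    if missing_policy == "skip":
        g = np.where(used, d, 0.0)
        terms = g * log_or - np.where(used, log_w, 0.0)
    else:
        g = np.where(used, d, 2.0 * catalog.risk_freqs)
        terms = g * log_or - log_w
    return terms, used


def grs_single(
    dosages: Sequence[float],
    catalog: SNPCatalog,
    missing_policy: MissingPolicy = "skip",
) -> float:
    """GRS for one subject from risk-allele dosages in catalog order.

    Missing dosages are ``NaN`` (or ``None``). With everything missing the
    skip policy returns the empty product 1.0 — the population mean.
    """
    d = np.array([np.nan if g is None else g for g in dosages], dtype=float)
    if d.size != catalog.n_snps:
        raise AnalysisError(
            f"{d.size} dosages for a catalog of {catalog.n_snps} SNPs"
        )
    terms, _ = _log_contributions(d, catalog, missing_policy)
    return float(np.exp(terms.sum()))


def grs_cohort(
    matrix: GenotypeMatrix,
    catalog: SNPCatalog,
    missing_policy: MissingPolicy = "skip",
) -> GRSVector:
    """Vectorized GRS over a cohort.

    The matrix must already be oriented to risk alleles. Catalog SNPs absent
    from the matrix are treated as missing for every subject (reported once
    via a warning); an empty catalog/matrix intersection is fatal.
    """
    import warnings

    if not matrix.oriented:
        raise AnalysisError("genotype matrix must be oriented to risk alleles first")
    present = [r.rsid for r in catalog.records if matrix.has_snp(r.rsid)]
    absent = [r.rsid for r in catalog.records if not matrix.has_snp(r.rsid)]
    if not present:
        raise AnalysisError("no catalog SNP is present in the genotype matrix")
    if absent:
        warnings.warn(
            f"{len(absent)} catalog SNP(s) absent from genotypes, treated as "
            f"missing for all subjects: {absent}",
            stacklevel=2,
        )
    d = np.full((matrix.n_subjects, catalog.n_snps), np.nan)
    for j, rec in enumerate(catalog.records):
        if matrix.has_snp(rec.rsid):
            d[:, j] = matrix.column(rec.rsid)
    terms, used = _log_contributions(d, catalog, missing_policy)
    return GRSVector(
        subject_ids=matrix.subject_ids,
        grs=np.exp(terms.sum(axis=1)),
        n_used=used.sum(axis=1),
    )


def analytic_case_mean_grs(catalog: SNPCatalog) -> float:
    """Expected GRS among cases under the multiplicative allelic-OR model.

    Per SNP the case genotype law is the tilted Hardy-Weinberg distribution
    ``P(g | case) = OR^g P(g) / W``, so the expected per-SNP factor is
    ``E[OR^g / W | case] = (f^2 OR^4 + 2 f (1-f) OR^2 + (1-f)^2) / W^2``
    (the numerator is ``E[OR^{2g}]`` under HWE). SNPs multiply independently.
    Always >= 1, with equality iff every OR is 1.
    """
    f = catalog.risk_freqs
    or_ = catalog.odds_ratios
    w = expected_risk_weight(f, or_)
    numerator = f**2 * or_**4 + 2 * f * (1 - f) * or_**2 + (1 - f) ** 2
    return float(np.prod(numerator / w**2))
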