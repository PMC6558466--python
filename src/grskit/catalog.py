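"""Risk-SNP catalogs: the per-cancer lists of GWAS-established risk variants.

A catalog row carries the two external quantities the genetic risk score
needs for each SNP: the allelic odds ratio ``OR`` from published GWAS and the
risk-allele frequency ``f`` in a reference population (e.g. gnomAD NFE).
Catalogs are exchanged as headered TSV files with exactly the columns of
:class:`SNPRecord`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd

from .errors import CatalogError

if TYPE_CHECKING:  # pragma: no cover
    from .genotypes import GenotypeMatrix

CATALOG_COLUMNS = (
    "rsid",
    "chrom",
    "pos",
    "risk_allele",
    "other_allele",
    "odds_ratio",
    "risk_freq",
)

_NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True)
class SNPRecord:
    """One risk-associated SNP with its external weight and frequency.

    Parameters
    ----------
    rsid : str
        dbSNP identifier; the primary join key against genotype data.
    chrom, pos : str, int
        Advisory 1-based genomic coordinate.
    risk_allele, other_allele : str
        Single nucleotides; the odds ratio is per copy of ``risk_allele``.
    odds_ratio : float
        Allelic odds ratio from the external GWAS, > 0.
    risk_freq : float
        Risk-allele frequency in the standardization population, in [0, 1].
    """

    rsid: str
    chrom: str
    pos: int
    risk_allele: str
    other_allele: str
    odds_ratio: float
    risk_freq: float


@dataclass(frozen=True)
class SNPCatalog:
    """Ordered collection of :class:`SNPRecord` for one cancer type."""

    cancer_type: str
    records: tuple[SNPRecord, ...]

    @property
    def n_snps(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SNPRecord]:
        return iter(self.records)

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(r.rsid for r in self.records)

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.array([r.odds_ratio for r in self.records], dtype=float)

    @property
    def risk_freqs(self) -> np.ndarray:
        return np.array([r.risk_freq for r in self.records], dtype=float)

    def subset(self, rsids: Sequence[str]) -> "SNPCatalog":
        """Catalog restricted to ``rsids``, preserving original order."""
        keep = set(rsids)
        unknown = keep - set(self.rsids)
        if unknown:
            raise CatalogError(f"rsids not in catalog: {sorted(unknown)}")
        return SNPCatalog(
            self.cancer_type, tuple(r for r in self.records if r.rsid in keep)
        )

    def record(self, rsid: str) -> SNPRecord:
        for r in self.records:
            if r.rsid == rsid:
                return r
        raise CatalogError(f"rsid {rsid!r} not in catalog")


def validate_catalog(
    catalog: SNPCatalog, allow_monomorphic: bool = False
) -> list[str]:
    """Check every catalog invariant; return one message per violation.

    Violations are data, not exceptions: an empty list means the catalog is
    valid. Each message names the offending rsid. Monomorphic SNPs
    (``risk_freq`` exactly 0 or 1) make the standardization weight a constant
    and carry no information; they are rejected unless ``allow_monomorphic``.
    """
    violations: list[str] = []
    if catalog.n_snps < 1:
        violations.append("catalog must contain at least one SNP")
    seen: set[str] = set()
    for rec in catalog.records:
        if rec.rsid in seen:
            violations.append(f"{rec.rsid}: duplicate rsid")
        seen.add(rec.rsid)
        if not (np.isfinite(rec.odds_ratio) and rec.odds_ratio > 0):
            violations.append(f"{rec.rsid}: odds_ratio must be > 0")
        if not (np.isfinite(rec.risk_freq) and 0.0 <= rec.risk_freq <= 1.0):
            violations.append(f"{rec.rsid}: risk_freq must be in [0, 1]")
        elif rec.risk_freq in (0.0, 1.0) and not allow_monomorphic:
            violations.append(
                f"{rec.rsid}: risk_freq is monomorphic ({rec.risk_freq:g}); "
                "pass allow_monomorphic to accept"
            )
        for field in ("risk_allele", "other_allele"):
            allele = getattr(rec, field)
            if allele.upper() not in _NUCLEOTIDES:
                violations.append(f"{rec.rsid}: {field} {allele!r} is not a single nucleotide")
        if rec.risk_allele.upper() == rec.other_allele.upper():
            violations.append(f"{rec.rsid}: risk_allele equals other_allele")
        if rec.pos < 1:
            violations.append(f"{rec.rsid}: pos must be a positive 1-based coordinate")
    return violations


def read_catalog(
    path: str | Path,
    cancer_type: str | None = None,
    allow_monomorphic: bool = False,
) -> SNPCatalog:
    """Parse a headered TSV catalog file, preserving row order.

    The header must contain exactly the :data:`CATALOG_COLUMNS` names (extra
    columns are ignored). Parse failures cite the 1-based data row; invariant
    violations raise :class:`~grskit.errors.CatalogError` listing every
    problem at once.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise CatalogError(f"cannot read catalog {path}: {exc}") from exc
    missing = [c for c in CATALOG_COLUMNS if c not in frame.columns]
    if missing:
        raise CatalogError(f"{path}: missing required column(s) {missing}")

    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            records.append(
                SNPRecord(
                    rsid=str(row.rsid).strip(),
                    chrom=str(row.chrom).strip(),
                    pos=int(row.pos),
                    risk_allele=str(row.risk_allele).strip().upper(),
                    other_allele=str(row.other_allele).strip().upper(),
                    odds_ratio=float(row.odds_ratio),
                    risk_freq=float(row.risk_freq),
                )
            )
        except (TypeError, ValueError) as exc:
            raise CatalogError(f"{path}: row {i}: {exc}") from exc

    catalog = SNPCatalog(cancer_type or path.stem, tuple(records))
    problems = validate_catalog(catalog, allow_monomorphic=allow_monomorphic)
    if problems:
        detail = "; ".join(
            f"row {i}" for i, rec in enumerate(records, start=1)
            if any(p.startswith(rec.rsid + ":") for p in problems)
        )
        raise CatalogError(f"{path}: invalid catalog ({detail}): " + "; ".join(problems))
    return catalog


def write_catalog(catalog: SNPCatalog, path: str | Path) -> None:
    """Write a catalog as headered TSV; inverse of :func:`read_catalog`."""
    frame = pd.DataFrame([dataclasses.asdict(r) for r in catalog.records],
                         columns=list(CATALOG_COLUMNS))
    frame.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class PruneResult:
    """Outcome of LD pruning: the retained catalog and the dropped rsids."""

    catalog: SNPCatalog
    removed: tuple[str, ...]


def prune_by_ld(
    catalog: SNPCatalog,
    genotypes: "GenotypeMatrix",
    r2_threshold: float = 0.2,
) -> PruneResult:
    """Greedily drop SNPs until all retained pairs have dosage r² below threshold.

    SNPs are visited in catalog order; a SNP is kept only if its squared
    Pearson correlation with every previously kept SNP is strictly below
    ``r2_threshold`` (earlier-listed SNPs win ties). The composite (dosage)
    r² is used, so phased haplotypes are not required. A SNP whose dosage
    column is constant has undefined r² and is retained.
    """
    from .genotypes import pairwise_r2  # local import to avoid a cycle

    if not (0.0 < r2_threshold <= 1.0):
        raise CatalogError(f"r2_threshold must be in (0, 1], got {r2_threshold}")
    absent = [r.rsid for r in catalog.records if not genotypes.has_snp(r.rsid)]
    if absent:
        raise CatalogError(f"catalog SNPs absent from genotype matrix: {absent}")

    kept: list[str] = []
    removed: list[str] = []
    for rec in catalog.records:
        r2s = (pairwise_r2(genotypes, rec.rsid, other) for other in kept)
        if any(r2 >= r2_threshold for r2 in r2s if not np.isnan(r2)):
            removed.append(rec.rsid)
        else:
            kept.append(rec.rsid)
    return PruneResult(catalog.subset(kept), tuple(removed))
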