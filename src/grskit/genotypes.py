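"""Genotype containers and I/O: VCF extraction, dosage matrices, allele orientation.

Dosages are stored as a subjects × SNPs float matrix where each entry counts
alleles (0, 1 or 2) and ``NaN`` marks a missing genotype. A matrix read from
VCF counts ALT alleles and is *unoriented*; :func:`align_to_risk_alleles`
turns it into risk-allele dosages against a catalog, handling REF/ALT swaps
and strand flips. Dosage TSV files are declared pre-oriented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import SNPCatalog
from .errors import AlignmentError, GenotypeError

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _complement(allele: str) -> str:
    return _COMPLEMENT[allele.upper()]


def is_strand_ambiguous(a1: str, a2: str) -> bool:
    """True for A/T and C/G SNPs, whose strand cannot be told from alleles."""
    return _complement(a1) == a2.upper()


@dataclass(frozen=True)
class GenotypeMatrix:
    """Subjects × SNPs allele-count matrix.

    Attributes
    ----------
    subject_ids, snp_ids : tuple of str
        Row and column labels.
    dosages : ndarray of float
        Counts in {0, 1, 2}; ``NaN`` marks missing genotypes.
    oriented : bool
        True once entries count *risk* alleles (catalog orientation);
        False when they count VCF ALT alleles.
    alleles : dict
        Per-SNP ``(ref, alt)`` pair retained from the source VCF, needed by
        :func:`align_to_risk_alleles`. Empty for pre-oriented dosage files.
    """

    subject_ids: tuple[str, ...]
    snp_ids: tuple[str, ...]
    dosages: np.ndarray
    oriented: bool
    alleles: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.dosages, dtype=float)
        object.__setattr__(self, "dosages", d)
        if d.shape != (len(self.subject_ids), len(self.snp_ids)):
            raise GenotypeError(
                f"dosage shape {d.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.snp_ids)} SNPs"
            )
        finite = d[~np.isnan(d)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))][0]
            raise GenotypeError(f"dosage values must be 0, 1, 2 or missing; found {bad}")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def has_snp(self, rsid: str) -> bool:
        return rsid in self.snp_ids

    def column(self, rsid: str) -> np.ndarray:
        try:
            j = self.snp_ids.index(rsid)
        except ValueError:
            raise GenotypeError(f"SNP {rsid!r} not in genotype matrix") from None
        return self.dosages[:, j]

    def subset_subjects(self, ids: Sequence[str]) -> "GenotypeMatrix":
        """Row subset in the order of ``ids``."""
        index = {s: i for i, s in enumerate(self.subject_ids)}
        try:
            rows = [index[s] for s in ids]
        except KeyError as exc:
            raise GenotypeError(f"unknown subject id {exc.args[0]!r}") from None
        return replace(
            self, subject_ids=tuple(ids), dosages=self.dosages[rows, :]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosages, index=list(self.subject_ids), columns=list(self.snp_ids)
        )


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    """Read a pre-oriented risk-allele dosage matrix.

    Format: headered TSV, first column the subject id, remaining column names
    rsids, cells in {0, 1, 2, NA}. Any other cell raises
    :class:`~grskit.errors.GenotypeError` naming the subject row and SNP column.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    values = frame.to_numpy()
    dosages = np.full(values.shape, np.nan)
    for (i, j), cell in np.ndenumerate(values):
        cell = str(cell).strip()
        if cell in ("NA", "nan", ""):
            continue
        if cell not in ("0", "1", "2"):
            raise GenotypeError(
                f"{path}: invalid dosage {cell!r} at subject "
                f"{frame.index[i]!r}, SNP {frame.columns[j]!r}"
            )
        dosages[i, j] = float(cell)
    return GenotypeMatrix(
        subject_ids=tuple(str(s) for s in frame.index),
        snp_ids=tuple(str(c) for c in frame.columns),
        dosages=dosages,
        oriented=True,
    )


def write_dosage_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the dosage matrix as TSV with NA for missing entries."""
    frame = matrix.to_frame()
    out = frame.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.index.name = "subject_id"
    out.to_csv(path, sep="\t")


def read_genotypes_vcf(
    path: str | Path, wanted: Sequence[str]
) -> tuple[GenotypeMatrix, list[str]]:
    """Extract ALT-allele dosages for ``wanted`` rsids from a VCF.

    Returns the (unoriented) matrix plus the list of wanted rsids absent from
    the file — absence is reported, not fatal, because array content differs
    between cohorts. A wanted site that is multi-allelic raises. ``./.``
    genotypes become missing.
    """
    from cyvcf2 import VCF

    wanted_set = set(wanted)
    path = Path(path)
    if not path.exists():
        raise GenotypeError(f"VCF not found: {path}")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad files
        raise GenotypeError(f"cannot open VCF {path}: {exc}") from exc

    subjects = tuple(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    alleles: dict[str, tuple[str, str]] = {}
    for variant in vcf:
        rsid = variant.ID
        if rsid not in wanted_set or rsid in columns:
            continue
        if len(variant.ALT) != 1:
            raise GenotypeError(
                f"{path}: wanted site {rsid} is not biallelic (ALT={variant.ALT})"
            )
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(variant.gt_types, dtype=float)
        dose = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        columns[rsid] = dose
        alleles[rsid] = (variant.REF.upper(), variant.ALT[0].upper())

    found = [rsid for rsid in wanted if rsid in columns]
    missing = [rsid for rsid in wanted if rsid not in columns]
    dosages = (
        np.column_stack([columns[r] for r in found])
        if found
        else np.empty((len(subjects), 0))
    )
    matrix = GenotypeMatrix(
        subject_ids=subjects,
        snp_ids=tuple(found),
        dosages=dosages,
        oriented=False,
        alleles=alleles,
    )
    return matrix, missing


@dataclass(frozen=True)
class AlignmentResult:
    """Oriented matrix plus the strand-ambiguous rsids that were dropped."""

    matrix: GenotypeMatrix
    excluded: tuple[str, ...]


def align_to_risk_alleles(
    matrix: GenotypeMatrix, catalog: SNPCatalog
) -> AlignmentResult:
    """Re-orient ALT-allele dosages so they count catalog risk alleles.

    For each catalog SNP present in the matrix, in order:

    * risk allele == ALT (other == REF): dosage unchanged;
    * risk allele == REF (other == ALT): dosage reflected, ``g -> 2 - g``;
    * otherwise the catalog alleles are strand-complemented and the same two
      rules applied;
    * a strand-ambiguous SNP (A/T or C/G) that would need the complement is
      excluded and reported — allele labels alone cannot resolve its strand,
      and frequency-based disambiguation is deliberately not attempted;
    * alleles that match neither orientation even after complementing raise
      :class:`~grskit.errors.AlignmentError`.

    The result keeps only the catalog SNPs found in the matrix, carries
    ``oriented=True``, and records per-SNP alleles as (risk, other).
    """
    if matrix.oriented:
        raise AlignmentError("matrix is already oriented to risk alleles")

    kept_ids: list[str] = []
    kept_cols: list[np.ndarray] = []
    new_alleles: dict[str, tuple[str, str]] = {}
    excluded: list[str] = []
    for rec in catalog.records:
        if not matrix.has_snp(rec.rsid):
            continue
        if rec.rsid not in matrix.alleles:
            raise AlignmentError(f"{rec.rsid}: no REF/ALT metadata retained from VCF")
        ref, alt = matrix.alleles[rec.rsid]
        risk, other = rec.risk_allele, rec.other_allele
        column = matrix.column(rec.rsid)
        if (risk, other) == (alt, ref):
            aligned = column
        elif (risk, other) == (ref, alt):
            aligned = 2.0 - column
        elif is_strand_ambiguous(risk, other):
            warnings.warn(
                f"{rec.rsid}: strand-ambiguous ({risk}/{other}) and requires a "
                "strand complement; excluded from alignment",
                stacklevel=2,
            )
            excluded.append(rec.rsid)
            continue
        else:
            crisk, cother = _complement(risk), _complement(other)
            if (crisk, cother) == (alt, ref):
                aligned = column
            elif (crisk, cother) == (ref, alt):
                aligned = 2.0 - column
            else:
                raise AlignmentError(
                    f"{rec.rsid}: catalog alleles {risk}/{other} irreconcilable "
                    f"with VCF {ref}/{alt}"
                )
        kept_ids.append(rec.rsid)
        kept_cols.append(aligned)
        new_alleles[rec.rsid] = (risk, other)

    dosages = (
        np.column_stack(kept_cols)
        if kept_cols
        else np.empty((matrix.n_subjects, 0))
    )
    oriented = GenotypeMatrix(
        subject_ids=matrix.subject_ids,
        snp_ids=tuple(kept_ids),
        dosages=dosages,
        oriented=True,
        alleles=new_alleles,
    )
    return AlignmentResult(oriented, tuple(excluded))


def pairwise_r2(matrix: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    """Composite LD: squared Pearson correlation of two dosage columns.

    Computed over pairwise-complete subjects. Returns ``NaN`` with a warning
    when either column is constant (correlation undefined); symmetric in its
    SNP arguments.
    """
    a, b = matrix.column(snp_a), matrix.column(snp_b)
    keep = ~(np.isnan(a) | np.isnan(b))
    if keep.sum() < 2:
        raise GenotypeError(
            f"fewer than 2 subjects with both {snp_a} and {snp_b} non-missing"
        )
    a, b = a[keep], b[keep]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn(
            f"r2({snp_a}, {snp_b}) undefined: constant dosage column", stacklevel=2
        )
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(min(r * r, 1.0))
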