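"""End-to-end orchestration: catalogs + genotypes + phenotypes -> report tables.

One call produces, per cancer type, a GRS file, a case-vs-control summary
(sample sizes, mean GRS with CI per arm, Wilcoxon p), a stratified
odds-ratio table (low/average/high counts, ORs, CIs, trend p), and across
cancers a risk-category proportion table for the control arm plus the
multi-cancer high/low-risk tallies. A run log records package versions, the
seed, and every policy in effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catalog import SNPCatalog, prune_by_ld, read_catalog
from .errors import AnalysisError, ConfigError, GrsKitError
from .genotypes import (
    GenotypeMatrix,
    align_to_risk_alleles,
    read_dosage_tsv,
    read_genotypes_vcf,
)
from .grs import GRSVector, grs_cohort
from .stats import (
    CATEGORIES,
    SEX_RESTRICTED,
    build_risk_table,
    categorize_risk,
    mean_grs_summary,
    tally_multi_cancer,
    wilcoxon_rank_sum,
)

logger = logging.getLogger("grskit.pipeline")

PHENOTYPE_VALUES = ("case", "control", "unknown")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one analysis run needs, resolvable from a YAML file."""

    catalogs: dict[str, Path]  # cancer type -> catalog TSV
    genotypes: Path
    phenotypes: Path
    out_dir: Path
    genotype_format: str = "dosage"  # "dosage" or "vcf"
    low_cut: float = 0.5
    high_cut: float = 1.5
    missing_policy: str = "skip"
    alpha: float = 0.05
    prune_r2: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.catalogs:
            raise ConfigError("at least one catalog is required")
        if self.genotype_format not in ("dosage", "vcf"):
            raise ConfigError(f"unknown genotype_format {self.genotype_format!r}")
        if not self.low_cut < self.high_cut:
            raise ConfigError("cutpoints must satisfy low_cut < high_cut")
        for label, path in [("genotypes", self.genotypes), ("phenotypes", self.phenotypes)] + [
            (f"catalog {c}", p) for c, p in self.catalogs.items()
        ]:
            if not Path(path).exists():
                raise ConfigError(f"{label} file not found: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a config file; keyword arguments override file values."""
        path = Path(path)
        try:
            raw = yaml.safe_load(path.read_text())
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        try:
            catalogs = {str(c): Path(p) for c, p in dict(raw.pop("catalogs")).items()}
            return cls(
                catalogs=catalogs,
                genotypes=Path(raw.pop("genotypes")),
                phenotypes=Path(raw.pop("phenotypes")),
                out_dir=Path(raw.pop("out_dir")),
                **raw,
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"{path}: invalid config: {exc}") from exc


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read the phenotype table: subject_id, sex, one status column per cancer.

    A single-cancer study may use a generic ``status`` column instead of a
    column named for the cancer type. Status values are case / control /
    unknown; sex values male / female / unknown.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for column in ("subject_id", "sex"):
        if column not in frame.columns:
            raise ConfigError(f"{path}: phenotype file lacks column {column!r}")
    if frame["subject_id"].duplicated().any():
        dup = frame["subject_id"][frame["subject_id"].duplicated()].iloc[0]
        raise ConfigError(f"{path}: duplicate subject_id {dup!r}")
    status_cols = [c for c in frame.columns if c not in ("subject_id", "sex")]
    for column in status_cols:
        bad = ~frame[column].fillna("unknown").isin(PHENOTYPE_VALUES)
        if bad.any():
            raise ConfigError(
                f"{path}: column {column!r} has value "
                f"{frame[column][bad].iloc[0]!r}, expected one of {PHENOTYPE_VALUES}"
            )
    return frame


def _status_column(phenotypes: pd.DataFrame, cancer: str) -> pd.Series:
    if cancer in phenotypes.columns:
        column = phenotypes[cancer]
    elif "status" in phenotypes.columns:
        column = phenotypes["status"]
    else:
        raise ConfigError(f"phenotype file has no status column for {cancer!r}")
    return column.fillna("unknown")


def _arm_ids(phenotypes: pd.DataFrame, cancer: str) -> tuple[list[str], list[str]]:
    """Case and control subject ids for one cancer, honoring sex restriction."""
    status = _status_column(phenotypes, cancer)
    keep = pd.Series(True, index=phenotypes.index)
    required = SEX_RESTRICTED.get(cancer.lower())
    if required is not None:
        keep = phenotypes["sex"] == required
    cases = phenotypes.loc[keep & (status == "case"), "subject_id"].tolist()
    controls = phenotypes.loc[keep & (status == "control"), "subject_id"].tolist()
    return cases, controls


def _load_genotypes(
    config: PipelineConfig, catalogs: Mapping[str, SNPCatalog]
) -> dict[str, GenotypeMatrix]:
    """One oriented matrix per cancer (VCF needs per-catalog alignment)."""
    if config.genotype_format == "dosage":
        matrix = read_dosage_tsv(config.genotypes)
        return {cancer: matrix for cancer in catalogs}
    wanted = sorted({r.rsid for cat in catalogs.values() for r in cat.records})
    raw, absent = read_genotypes_vcf(config.genotypes, wanted)
    if absent:
        logger.info("%d wanted SNP(s) absent from VCF: %s", len(absent), absent)
    oriented = {}
    for cancer, cat in catalogs.items():
        result = align_to_risk_alleles(raw, cat)
        if result.excluded:
            logger.info(
                "%s: excluded strand-ambiguous SNP(s): %s", cancer, result.excluded
            )
        oriented[cancer] = result.matrix
    return oriented


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the full analysis; return the paths of the report bundle.

    Outputs in ``config.out_dir``: ``grs_<cancer>.tsv`` per cancer,
    ``grs_summary.tsv`` (per-arm mean GRS + Wilcoxon p), ``risk_table.tsv``
    (stratified ORs + trend p), ``risk_proportions.tsv`` (control-arm
    category proportions per cancer), ``multi_cancer_tally.tsv`` and
    ``run.log``. Any stage failure removes partial outputs and re-raises
    with the stage name.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    pipe_logger = logging.getLogger("grskit")
    pipe_logger.addHandler(handler)
    pipe_logger.setLevel(logging.INFO)

    stage = "setup"
    try:
        logger.info(
            "grskit %s (numpy %s, pandas %s); seed=%s missing_policy=%s "
            "cutpoints=(%g, %g) alpha=%g prune_r2=%s",
            __version__, np.__version__, pd.__version__, config.seed,
            config.missing_policy, config.low_cut, config.high_cut,
            config.alpha, config.prune_r2,
        )
        stage = "read catalogs"
        catalogs = {
            cancer: read_catalog(path, cancer)
            for cancer, path in config.catalogs.items()
        }
        stage = "read phenotypes"
        phenotypes = read_phenotypes(config.phenotypes)
        sex_map = dict(zip(phenotypes["subject_id"], phenotypes["sex"].fillna("unknown")))
        stage = "read genotypes"
        matrices = _load_genotypes(config, catalogs)

        summary_rows, table_rows, proportion_rows = [], [], []
        control_categories = {}
        for cancer, catalog in catalogs.items():
            stage = f"{cancer}: prune"
            matrix = matrices[cancer]
            if config.prune_r2 is not None:
                pruned = prune_by_ld(catalog, matrix, config.prune_r2)
                if pruned.removed:
                    logger.info(
                        "%s: LD-pruned %d SNP(s): %s",
                        cancer, len(pruned.removed), pruned.removed,
                    )
                catalog = pruned.catalog

            stage = f"{cancer}: GRS"
            case_ids, control_ids = _arm_ids(phenotypes, cancer)
            scored = [s for s in case_ids + control_ids if s in set(matrix.subject_ids)]
            if len(scored) < len(case_ids) + len(control_ids):
                logger.info(
                    "%s: %d phenotyped subject(s) lack genotypes",
                    cancer, len(case_ids) + len(control_ids) - len(scored),
                )
            if not scored:
                raise AnalysisError(f"{cancer}: no phenotyped subject has genotypes")
            grs = grs_cohort(
                matrix.subset_subjects(scored), catalog, config.missing_policy
            )
            logger.info(
                "%s: %d subjects scored on %d SNPs; GRS mean %.4f min %.4f max %.4f",
                cancer, len(grs), catalog.n_snps,
                grs.grs.mean(), grs.grs.min(), grs.grs.max(),
            )
            grs_path = out_dir / f"grs_{cancer}.tsv"
            grs.write_tsv(grs_path)
            written.append(grs_path)

            stage = f"{cancer}: statistics"
            by_id = dict(zip(grs.subject_ids, range(len(grs))))
            case_idx = [by_id[s] for s in case_ids if s in by_id]
            ctrl_idx = [by_id[s] for s in control_ids if s in by_id]
            case_grs = GRSVector(
                tuple(grs.subject_ids[i] for i in case_idx),
                grs.grs[case_idx], grs.n_used[case_idx],
            )
            ctrl_grs = GRSVector(
                tuple(grs.subject_ids[i] for i in ctrl_idx),
                grs.grs[ctrl_idx], grs.n_used[ctrl_idx],
            )
            _, wilcoxon_p = wilcoxon_rank_sum(case_grs.grs, ctrl_grs.grs)
            case_summary = mean_grs_summary(case_grs, "case", config.alpha)
            ctrl_summary = mean_grs_summary(ctrl_grs, "control", config.alpha)
            summary_rows.append(
                {
                    "cancer_type": cancer,
                    "n_snps": catalog.n_snps,
                    "n_cases": case_summary.n,
                    "case_mean_grs": case_summary.mean,
                    "case_ci_low": case_summary.ci_low,
                    "case_ci_high": case_summary.ci_high,
                    "n_controls": ctrl_summary.n,
                    "control_mean_grs": ctrl_summary.mean,
                    "control_ci_low": ctrl_summary.ci_low,
                    "control_ci_high": ctrl_summary.ci_high,
                    "wilcoxon_p": wilcoxon_p,
                }
            )

            case_cats = categorize_risk(case_grs, config.low_cut, config.high_cut)
            ctrl_cats = categorize_risk(ctrl_grs, config.low_cut, config.high_cut)
            control_categories[cancer] = ctrl_cats
            risk = build_risk_table(case_cats, ctrl_cats, alpha=config.alpha)
            frame = risk.to_frame()
            frame.insert(0, "cancer_type", cancer)
            table_rows.append(frame)

            counts = ctrl_cats.counts()
            proportion_rows.append(
                {
                    "cancer_type": cancer,
                    "n": len(ctrl_cats),
                    **{
                        f"{cat}_risk": counts[cat] / len(ctrl_cats)
                        for cat in CATEGORIES
                    },
                }
            )

        stage = "write reports"
        outputs = {"log": log_path}
        summary_path = out_dir / "grs_summary.tsv"
        pd.DataFrame(summary_rows).to_csv(summary_path, sep="\t", index=False)
        written.append(summary_path)
        outputs["grs_summary"] = summary_path

        table_path = out_dir / "risk_table.tsv"
        pd.concat(table_rows, ignore_index=True).to_csv(table_path, sep="\t", index=False)
        written.append(table_path)
        outputs["risk_table"] = table_path

        proportions_path = out_dir / "risk_proportions.tsv"
        pd.DataFrame(proportion_rows).to_csv(proportions_path, sep="\t", index=False)
        written.append(proportions_path)
        outputs["risk_proportions"] = proportions_path

        stage = "multi-cancer tally"
        tally = tally_multi_cancer(control_categories, sex_map)
        tally_path = out_dir / "multi_cancer_tally.tsv"
        tally.to_frame().to_csv(tally_path, sep="\t")
        written.append(tally_path)
        outputs["multi_cancer_tally"] = tally_path

        logger.info("pipeline complete: %d report file(s)", len(written))
        return outputs
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        if isinstance(exc, GrsKitError):
            raise type(exc)(f"[stage: {stage}] {exc}") from exc
        raise GrsKitError(f"[stage: {stage}] {exc}") from exc
    finally:
        pipe_logger.removeHandler(handler)
        handler.close()
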