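"""End-to-end discovery workflow.

Orchestrates phenotype → bulk → presence screen → validation, either on a
simulated population (simulate mode, for testing and power analysis) or on
user-supplied tables (real-input mode).  Every stage writes its output
before the next stage reads it, stage counts are logged to stderr, and the
report carries a provenance block (config hash, seed, version) sufficient
to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import io as lio
from .bulkseg import (
    CandidateGene,
    ExpressionMatrix,
    PhenotypePools,
    compute_rpkm,
    detection_flags,
    pairwise_candidate_filter,
    presence_correlation_screen,
)
from .sim import QPCRDesign, SimConfig, simulate_marker_panel, simulate_panel, \
    simulate_pileups, simulate_qpcr, simulate_volatile_tables, simulate_expression
from .validate import ddct_fold_change, chi_square_ratio, marker_concordance, \
    ssr_allele_association
from .variants import filter_snps, write_vcf
from .volatiles import ProducerStatus, call_producer_status, classify_seasonal_trend, \
    series_from_peaks

__all__ = ["RunConfig", "ReportBundle", "run_discovery", "load_config"]

logger = logging.getLogger("lactomap")

try:
    from importlib.metadata import version as _pkg_version
    VERSION = _pkg_version("lactomap")
except Exception:  # pragma: no cover - not installed
    VERSION = "unknown"


class RunConfig(BaseModel):
    """Schema-validated configuration for a full discovery run.

    Unknown keys are rejected so typos fail before any stage runs.
    """

    model_config = ConfigDict(extra="forbid")

    mode: str = Field(default="simulate", pattern="^(simulate|real-input)$")
    seed: int = 0
    # input paths (real-input mode)
    counts: str | None = None
    genes: str | None = None
    libsizes: str | None = None
    libsizes_from_colsums: bool = False
    peaks: str | None = None
    markers: str | None = None
    ssr: str | None = None
    pileup: str | None = None
    qpcr: str | None = None
    # thresholds
    noise_floor: float | None = None  # simulate mode: defaults to sim baseline
    rel_tol: float = Field(default=0.2, ge=0, lt=1)
    detect_threshold: float = Field(default=1.0, ge=0)
    fold_threshold: float = Field(default=4.0, gt=1)
    pseudocount: float = Field(default=0.1, ge=0)
    min_nonref_frac: float = Field(default=0.95, gt=0, le=1)
    min_depth: int = Field(default=10, ge=1)
    min_genotypes: int = Field(default=2, ge=1)
    expected_segregation: tuple[float, float] = (1.0, 1.0)
    # simulation parameters
    sim: SimConfig = Field(default_factory=SimConfig)
    n_sim_sites: int = Field(default=200, ge=1)

    def config_hash(self) -> str:
        canonical = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON run configuration."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    return RunConfig.model_validate(data or {})


@dataclass
class ReportBundle:
    """Everything a discovery run produced, plus provenance."""

    phenotypes: pd.DataFrame
    candidate_table: pd.DataFrame
    candidate_counts_by_fold: dict[float, int]
    retained: list[CandidateGene]
    marker_summary: dict[str, Any] | None
    ssr_table: pd.DataFrame | None
    segregation: dict[str, Any] | None
    qpcr_summary: dict[str, Any] | None
    n_snp_calls: int | None
    provenance: dict[str, Any] = field(default_factory=dict)

    def summary(self) -> dict[str, Any]:
        out = {
            "n_genotypes": int(len(self.phenotypes)),
            "n_producers": int((self.phenotypes["status"] == "PRODUCER").sum()),
            "n_nonproducers": int((self.phenotypes["status"] == "NONPRODUCER").sum()),
            "candidate_counts_by_fold": {
                str(k): v for k, v in self.candidate_counts_by_fold.items()
            },
            "n_retained_candidates": len(self.retained),
            "retained_candidates": [c.gene_id for c in self.retained],
            "marker": self.marker_summary,
            "segregation": self.segregation,
            "qpcr": self.qpcr_summary,
            "n_snp_calls": self.n_snp_calls,
            "provenance": self.provenance,
        }
        return out


def _candidate_frame(candidates: list[CandidateGene]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "min_pairwise_fold": c.min_pairwise_fold,
                "perfect_correlation": c.perfect_correlation,
                "producer_mean_rpkm": c.producer_mean_rpkm,
                "nonproducer_mean_rpkm": c.nonproducer_mean_rpkm,
                "n_detected_in": len(c.detected_in),
            }
            for c in candidates
        ],
        columns=[
            "gene_id", "min_pairwise_fold", "perfect_correlation",
            "producer_mean_rpkm", "nonproducer_mean_rpkm", "n_detected_in",
        ],
    )


def run_discovery(config: RunConfig, out_dir: str | Path) -> ReportBundle:
    """Run the full workflow and write all tables under ``out_dir``.

    Stage order: acquire inputs (simulate or read) → volatile phenotyping →
    in-silico bulking and candidate filtering → presence screen → marker,
    SSR, segregation and qPCR validation → report.
    """
    out_dir = Path(out_dir)
    (out_dir / "inputs").mkdir(parents=True, exist_ok=True)

    # -- stage 0: inputs ------------------------------------------------------
    if config.mode == "simulate":
        sim_cfg = config.sim.model_copy(update={"seed": config.seed})
        genotypes = simulate_panel(sim_cfg)
        matrix = simulate_expression(genotypes, sim_cfg, stage="ripe")
        peaks = simulate_volatile_tables(genotypes, sim_cfg)
        markers, ssr = simulate_marker_panel(genotypes, seed=sim_cfg.seed)
        pileups = simulate_pileups(config.n_sim_sites, len(genotypes), sim_cfg)
        qpcr = simulate_qpcr(genotypes, sim_cfg, QPCRDesign(fold=sim_cfg.ripening_fold))
        noise_floor = (
            config.noise_floor if config.noise_floor is not None
            else sim_cfg.volatile_baseline
        )
        ins = out_dir / "inputs"
        lio.write_counts(matrix, ins / "counts.tsv", ins / "genes.tsv",
                         ins / "libsizes.tsv")
        lio.write_peaks(peaks, ins / "peaks.csv")
        lio.write_markers(markers, ins / "markers.tsv")
        lio.write_ssr(ssr, ins / "ssr.tsv")
        lio.write_pileups(pileups, ins / "pileup.tsv")
        lio.write_qpcr(qpcr, ins / "qpcr.csv")
        logger.info("simulated %d genotypes, %d genes, %d peak samples",
                    len(genotypes), sim_cfg.n_genes, len(peaks))
    else:
        if config.counts is None or config.genes is None or config.peaks is None:
            raise ValueError("real-input mode requires counts, genes and peaks paths")
        matrix = lio.read_counts(
            config.counts, config.genes, config.libsizes,
            libsizes_from_colsums=config.libsizes_from_colsums,
        )
        peaks = lio.read_peaks(config.peaks)
        markers = lio.read_markers(config.markers) if config.markers else None
        ssr = lio.read_ssr(config.ssr) if config.ssr else None
        pileups = lio.read_pileups(config.pileup) if config.pileup else None
        qpcr = lio.read_qpcr(config.qpcr) if config.qpcr else None
        if config.noise_floor is None:
            raise ValueError("real-input mode requires an explicit noise_floor")
        noise_floor = config.noise_floor

    # -- stage 1: volatile phenotyping ---------------------------------------
    series = series_from_peaks(peaks)
    pheno_rows = []
    for gid, s in series.items():
        status = call_producer_status(s, noise_floor)
        trend = (
            classify_seasonal_trend(s, noise_floor, config.rel_tol)
            if s.n_harvests == 3
            else None
        )
        pheno_rows.append(
            {"genotype_id": gid, "status": status.value,
             "trend_class": trend.value if trend else None}
        )
    phenotypes = pd.DataFrame(pheno_rows).set_index("genotype_id")
    lio.write_phenotypes(phenotypes, out_dir / "phenotypes.tsv")
    logger.info("phenotyped %d genotypes (%d producers, %d non-producers)",
                len(phenotypes),
                int((phenotypes["status"] == "PRODUCER").sum()),
                int((phenotypes["status"] == "NONPRODUCER").sum()))

    # -- stage 2: bulking and candidate filtering ----------------------------
    matrix_ids = set(matrix.genotype_ids)
    overlap = matrix_ids & set(phenotypes.index)
    if not overlap:
        raise ValueError(
            "no genotype overlap between phenotype and expression tables; "
            f"expression ids: {sorted(matrix_ids)[:5]}..., "
            f"phenotype ids: {sorted(phenotypes.index)[:5]}..."
        )
    producers = frozenset(
        g for g in overlap if phenotypes.at[g, "status"] == "PRODUCER"
    )
    nonproducers = frozenset(
        g for g in overlap if phenotypes.at[g, "status"] == "NONPRODUCER"
    )
    pools = PhenotypePools(producers=producers, nonproducers=nonproducers)
    pools.validate_against(matrix.genotype_ids)
    rpkm = compute_rpkm(matrix)
    flags = detection_flags(rpkm, config.detect_threshold)

    counts_by_fold: dict[float, int] = {}
    for f in (2.0, 3.0, 4.0):
        counts_by_fold[f] = len(
            pairwise_candidate_filter(
                rpkm, pools, fold_threshold=f,
                pseudocount=config.pseudocount,
                detect_threshold=config.detect_threshold,
            )
        )
    candidates = pairwise_candidate_filter(
        rpkm, pools,
        fold_threshold=config.fold_threshold,
        pseudocount=config.pseudocount,
        detect_threshold=config.detect_threshold,
    )
    logger.info("pairwise filter at fold %.1f: %d candidate(s) "
                "(counts at 2/3/4-fold: %s)",
                config.fold_threshold, len(candidates),
                {int(k): v for k, v in counts_by_fold.items()})

    # -- stage 3: presence/absence correlation screen ------------------------
    retained = presence_correlation_screen(candidates, flags, pools)
    cand_table = _candidate_frame(candidates)
    cand_table.to_csv(out_dir / "candidates.tsv", sep="\t", index=False)
    logger.info("presence screen retained %d candidate(s): %s",
                len(retained), [c.gene_id for c in retained])

    # -- stage 4: validation --------------------------------------------------
    pheno_map = {g: phenotypes.at[g, "status"] for g in phenotypes.index}
    marker_summary = None
    if markers:
        conc = marker_concordance(markers, pheno_map)
        marker_summary = {
            "concordance": conc.concordance,
            "n": conc.n,
            "discordant": list(conc.discordant),
            "p_value": conc.p_value,
            "p_method": conc.p_method,
        }
        logger.info("marker concordance %.3f over %d genotypes", conc.concordance, conc.n)
    ssr_table = None
    if ssr:
        ssr_table = ssr_allele_association(ssr, pheno_map)
        ssr_table.reset_index().to_csv(out_dir / "ssr_association.tsv", sep="\t", index=False)
    segregation = None
    statuses = phenotypes["status"]
    n_prod = int((statuses == "PRODUCER").sum())
    n_nonp = int((statuses == "NONPRODUCER").sum())
    if n_prod and n_nonp:
        seg = chi_square_ratio([n_prod, n_nonp], config.expected_segregation)
        segregation = {
            "observed": list(seg.observed),
            "expected_ratio": list(seg.expected_ratio),
            "chi_square": seg.chi_square,
            "df": seg.df,
            "p_value": seg.p_value,
        }
    qpcr_summary = None
    if qpcr:
        conditions = {m.condition for m in qpcr}
        if {"blushing", "ripe"} <= conditions:
            fc = ddct_fold_change(qpcr, "ripe", "blushing")
            qpcr_summary = {
                "contrast": "ripe_vs_blushing",
                "fold": fc.fold,
                "ddct": fc.ddct,
                "sd_ct": fc.sd,
                "fold_lo": fc.fold_lo,
                "fold_hi": fc.fold_hi,
            }
            logger.info("qPCR ripening induction: %.1f-fold", fc.fold)
    n_snp_calls = None
    if pileups:
        calls = filter_snps(
            pileups,
            min_nonref_frac=config.min_nonref_frac,
            min_depth=config.min_depth,
            min_genotypes=config.min_genotypes,
        )
        sample_ids = sorted({g for s in pileups for g in s.observations})
        write_vcf(calls, sample_ids, out_dir / "snps.vcf",
                  source=f"lactomap {VERSION}")
        n_snp_calls = len(calls)
        logger.info("SNP filter: %d of %d sites emitted", len(calls), len(pileups))

    bundle = ReportBundle(
        phenotypes=phenotypes,
        candidate_table=cand_table,
        candidate_counts_by_fold=counts_by_fold,
        retained=retained,
        marker_summary=marker_summary,
        ssr_table=ssr_table,
        segregation=segregation,
        qpcr_summary=qpcr_summary,
        n_snp_calls=n_snp_calls,
        provenance={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": VERSION,
            "mode": config.mode,
        },
    )
    (out_dir / "report.json").write_text(
        json.dumps(bundle.summary(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return bundle
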