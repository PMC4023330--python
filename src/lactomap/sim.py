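"""Synthetic segregating populations with a hemizygous deletion locus.

Generates everything the discovery pipeline consumes — genotypes from
Mendelian crosses, negative-binomial expression counts, GC/MS peak tables,
PCR/SSR marker panels, qPCR CT replicates and site pileups — with the
statistical structure the analysis assumes:

* the trait is controlled by one dominant locus present in a single dose
  (simplex) in the producer parent, so an F1 from producer × non-producer
  segregates ~1:1 carrier : non-carrier;
* non-carriers physically lack the causal gene (deletion), so its counts,
  its PCR amplicon, the linked SSR allele and the volatile are absent
  together;
* decoy genes segregate presence/absence independently of the phenotype,
  emulating homoeolog (subgenome) segregation noise in a polyploid cross;
* the causal gene is ripening-induced in carriers and the volatile is
  modulated by harvest environment.

All randomness flows from one master seed through named SeedSequence
substreams, so identical configuration gives byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .bulkseg import ExpressionMatrix
from .validate import HOUSEKEEPING, TARGET, MarkerCall, QPCRMeasurement, SSRGenotype
from .variants import SiteObservation
from .volatiles import PeakSample, TrendClass

__all__ = [
    "LocusModel",
    "SimGenotype",
    "SimConfig",
    "QPCRDesign",
    "simulate_cross",
    "simulate_panel",
    "simulate_expression",
    "simulate_volatile_tables",
    "simulate_marker_panel",
    "simulate_pileups",
    "simulate_qpcr",
    "CROSS_CARRIER_PROB",
    "TREND_WEIGHTS",
    "STAGES",
]

#: Mendelian carrier probability per cross, simplex carrier × null model.
#: BC1 to the producer parent crosses a carrier F1 back to the simplex
#: carrier parent, giving 1 - 0.5*0.5 = 0.75.
CROSS_CARRIER_PROB = {
    "F1": 0.5,
    "BC1_to_nonproducer": 0.5,
    "BC1_to_producer": 0.75,
}

#: Producer trend-class sampling weights (peak : valley : decrease :
#: increase = 8 : 5 : 3 : 1), the observed class proportions in a
#: ~35-progeny season with roughly half non-producers.
TREND_WEIGHTS = {
    TrendClass.PEAK: 8 / 17,
    TrendClass.VALLEY: 5 / 17,
    TrendClass.DECREASE: 3 / 17,
    TrendClass.INCREASE: 1 / 17,
}

#: Canonical three-harvest response shapes per producer trend class,
#: in units of the carrier signal level.
TREND_SHAPES = {
    TrendClass.PEAK: (1.0, 3.0, 1.0),
    TrendClass.VALLEY: (3.0, 1.0, 3.0),
    TrendClass.DECREASE: (3.0, 1.0, 1.0),
    TrendClass.INCREASE: (1.0, 2.0, 4.0),
}

STAGES = ("green", "blushing", "ripe")

#: Baseline CT levels for the qPCR generator (cycles).
_HOUSEKEEPING_CT = 20.0
_TARGET_CT = 25.0

_INTERNAL_STANDARD_AREA = 50_000.0

#: Fixed length (bp) of the planted causal transcript.
CAUSAL_GENE_LENGTH = 1500


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Deterministic per-operation substream of the master seed."""
    key = zlib.crc32(stream.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass(frozen=True)
class LocusModel:
    """Inheritance model of the causal locus.

    ``carrier_parent_id`` is None for a cross between two non-carriers
    (nothing to transmit).  Only single-dose (simplex) dominant inheritance
    is modelled: the observed ~1:1 segregation identifies one functional
    copy in the producer parent.
    """

    inheritance: Literal["dominant_simplex"] = "dominant_simplex"
    carrier_parent_id: str | None = "P_producer"
    description: str = "single dominant deletion locus, simplex in producer parent"


@dataclass(frozen=True)
class SimGenotype:
    id: str
    role: Literal["parent_producer", "parent_nonproducer", "F1", "BC1"]
    carrier: bool
    trend_class: TrendClass = TrendClass.NONPRODUCER

    def __post_init__(self) -> None:
        if not self.carrier and self.trend_class is not TrendClass.NONPRODUCER:
            raise ValueError(f"non-carrier {self.id} cannot have a producer trend class")


class SimConfig(BaseModel):
    """All generator parameters; ``seed`` fully determines every output."""

    model_config = ConfigDict(extra="forbid")

    n_progeny: int = Field(default=14, ge=1)
    n_genes: int = Field(default=2000, ge=2)
    causal_gene_index: int = Field(default=1414, ge=0)
    n_decoy_genes: int = Field(default=50, ge=0)
    #: per-gene background mean counts, drawn log-uniform over this range
    nb_mean_range: tuple[float, float] = (5.0, 500.0)
    nb_dispersion: float = Field(default=0.1, gt=0)
    #: carrier RPKM of the causal gene in ripe fruit
    causal_mean_rpkm: float = Field(default=50.0, gt=0)
    #: lognormal sigma of per-cell expression noise
    detect_noise_sd: float = Field(default=0.2, ge=0)
    gene_length_range: tuple[int, int] = (200, 5000)
    library_size_range: tuple[int, int] = (300_000, 850_000)
    #: ceiling of non-carrier normalized responses (instrument background)
    volatile_baseline: float = Field(default=0.01, gt=0)
    #: carrier normalized response at shape level 1.0
    volatile_signal: float = Field(default=1.0, gt=0)
    #: lognormal sigma of volatile signal noise
    volatile_noise_sd: float = Field(default=0.1, ge=0)
    #: inductive : non-inductive environment fold on the volatile
    env_effect_fold: float = Field(default=11.0, gt=0)
    #: ripe : blushing fold of causal-gene expression
    ripening_fold: float = Field(default=21.0, gt=0)
    n_replicates: int = Field(default=2, ge=1)
    #: fraction of pileup sites planted to pass the SNP criteria
    snp_pass_fraction: float = Field(default=0.3, ge=0, le=1)
    pileup_mean_depth: float = Field(default=30.0, gt=0)
    pileup_error_rate: float = Field(default=0.05, ge=0, le=1)
    ct_noise_sd: float = Field(default=0.05, ge=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if self.causal_gene_index >= self.n_genes:
            raise ValueError("causal_gene_index must be < n_genes")
        if self.n_decoy_genes >= self.n_genes:
            raise ValueError("n_decoy_genes must be < n_genes")
        for name in ("nb_mean_range", "gene_length_range", "library_size_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must satisfy 0 < low <= high")
        return self


def gene_ids(cfg: SimConfig) -> list[str]:
    return [f"gene{i:05d}" for i in range(cfg.n_genes)]


def causal_gene_id(cfg: SimConfig) -> str:
    return f"gene{cfg.causal_gene_index:05d}"


def simulate_cross(
    locus: LocusModel,
    cross: str,
    n: int,
    seed: int,
) -> list[SimGenotype]:
    """Draw ``n`` progeny carrier states for a cross involving the locus.

    Carrier flags are independent Bernoulli draws at the Mendelian
    probability of the cross (F1 and BC1-to-null: 0.5; BC1 to the simplex
    carrier parent: 0.75).  Carriers additionally receive a seasonal trend
    class sampled from the observed class proportions.
    """
    if cross not in CROSS_CARRIER_PROB:
        raise ValueError(
            f"unknown cross type {cross!r}; expected one of {sorted(CROSS_CARRIER_PROB)}"
        )
    if n < 1:
        raise ValueError("n must be >= 1")
    p = 0.0 if locus.carrier_parent_id is None else CROSS_CARRIER_PROB[cross]
    rng = _rng(seed, f"cross:{cross}")
    carriers = rng.random(n) < p
    classes = list(TREND_WEIGHTS)
    weights = np.array([TREND_WEIGHTS[c] for c in classes])
    trend_idx = rng.choice(len(classes), size=n, p=weights)
    role = "F1" if cross == "F1" else "BC1"
    return [
        SimGenotype(
            id=f"{cross}_{i:05d}",
            role=role,
            carrier=bool(carriers[i]),
            trend_class=classes[trend_idx[i]] if carriers[i] else TrendClass.NONPRODUCER,
        )
        for i in range(n)
    ]


def simulate_panel(
    cfg: SimConfig,
    n_producers: int = 11,
    n_nonproducers: int = 5,
) -> list[SimGenotype]:
    """Both parents plus F1 progeny selected to a fixed phenotype composition.

    Mirrors how a sequencing panel is assembled in practice: progeny are
    chosen from the segregating population so that the panel has a known
    number of producers (including the producer parent) and non-producers
    (including the non-producer parent).  Progeny are drawn from a
    simulated F1 batch until each class is filled.
    """
    if n_producers < 1 or n_nonproducers < 1:
        raise ValueError("panel needs at least one genotype per class")
    locus = LocusModel()
    parents = [
        SimGenotype(
            id="P_producer", role="parent_producer", carrier=True,
            trend_class=TrendClass.PEAK,
        ),
        SimGenotype(id="P_nonproducer", role="parent_nonproducer", carrier=False),
    ]
    need_carriers = n_producers - 1
    need_null = n_nonproducers - 1
    batch_size = max(4 * (need_carriers + need_null), 32)
    chosen: list[SimGenotype] = []
    carriers = null = 0
    while carriers < need_carriers or null < need_null:
        for g in simulate_cross(locus, "F1", batch_size, cfg.seed):
            if g.carrier and carriers < need_carriers:
                carriers += 1
            elif not g.carrier and null < need_null:
                null += 1
            else:
                continue
            chosen.append(
                SimGenotype(
                    id=f"F1_{len(chosen):03d}",
                    role="F1",
                    carrier=g.carrier,
                    trend_class=g.trend_class,
                )
            )
            if carriers >= need_carriers and null >= need_null:
                break
        batch_size *= 2
    return parents + chosen


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = mean + dispersion * mean^2."""
    r = 1.0 / dispersion
    mean = np.asarray(mean, dtype=float)
    p = np.where(mean > 0, r / (r + np.maximum(mean, 1e-300)), 1.0)
    counts = rng.negative_binomial(r, p)
    return np.where(mean > 0, counts, 0)


def simulate_expression(
    genotypes: Sequence[SimGenotype],
    cfg: SimConfig,
    stage: str = "ripe",
) -> ExpressionMatrix:
    """Gene-level counts for a panel at one developmental stage.

    Background genes share a per-gene negative-binomial mean across
    genotypes (log-uniform over ``nb_mean_range``), modulated by lognormal
    per-cell noise.  The causal gene has strictly zero counts in
    non-carriers and ripening-scaled NB counts in carriers (stage factors
    1/ripening_fold : 1 : ripening_fold for green : blushing : ripe, so
    the ripe/blushing ratio is the configured ripening fold).  Decoy genes
    are present/absent per genotype by a fair coin, independent of
    phenotype.  Gene structure (lengths, means, decoy pattern) is shared
    across stages under one seed.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    if not genotypes:
        raise ValueError("genotypes must be non-empty")
    n_genes, n_samp = cfg.n_genes, len(genotypes)
    struct = _rng(cfg.seed, "genes")
    lengths = struct.integers(
        cfg.gene_length_range[0], cfg.gene_length_range[1] + 1, size=n_genes
    )
    # the causal transcript is ~1.5 kb (a typical desaturase mRNA); fixing it
    # keeps the carrier RPKM calibration independent of the length draw
    lengths[cfg.causal_gene_index] = CAUSAL_GENE_LENGTH
    lo, hi = cfg.nb_mean_range
    base_means = np.exp(struct.uniform(np.log(lo), np.log(hi), size=n_genes))
    target_libs = struct.integers(
        cfg.library_size_range[0], cfg.library_size_range[1] + 1, size=n_samp
    ).astype(float)

    decoy_rng = _rng(cfg.seed, "decoys")
    eligible = np.setdiff1d(np.arange(n_genes), [cfg.causal_gene_index])
    decoy_idx = decoy_rng.choice(eligible, size=cfg.n_decoy_genes, replace=False)
    decoy_present = decoy_rng.random((cfg.n_decoy_genes, n_samp)) < 0.5

    # scale per-gene means so each genotype's expected total matches its
    # target library size
    mean = base_means[:, None] * (target_libs / base_means.sum())[None, :]
    mean[decoy_idx, :] *= decoy_present.astype(float)

    stage_factor = {
        "green": 1.0 / cfg.ripening_fold,
        "blushing": 1.0,
        "ripe": cfg.ripening_fold,
    }[stage]
    # causal carrier mean count chosen so ripe-stage RPKM ~ causal_mean_rpkm
    causal_len = float(lengths[cfg.causal_gene_index])
    ripe_count = cfg.causal_mean_rpkm * causal_len * target_libs / 1e9
    carrier = np.array([g.carrier for g in genotypes])
    mean[cfg.causal_gene_index, :] = np.where(
        carrier, ripe_count * stage_factor / cfg.ripening_fold, 0.0
    )

    noise_rng = _rng(cfg.seed, f"expr:{stage}")
    if cfg.detect_noise_sd > 0:
        mean = mean * np.exp(
            noise_rng.normal(0.0, cfg.detect_noise_sd, size=mean.shape)
        )
    counts = _nb_draw(noise_rng, mean, cfg.nb_dispersion)

    ids = gene_ids(cfg)
    cols = [g.id for g in genotypes]
    counts_df = pd.DataFrame(counts, index=ids, columns=cols, dtype=np.int64)
    lib = counts_df.sum(axis=0).astype(float)
    if (lib <= 0).any():
        lib = lib.clip(lower=1.0)
    return ExpressionMatrix(
        counts=counts_df,
        gene_lengths=pd.Series(lengths, index=ids, dtype=float),
        library_sizes=lib,
    )


def _trend_shape(trend: TrendClass, n_harvests: int) -> np.ndarray:
    base = np.asarray(TREND_SHAPES[trend])
    if n_harvests == 3:
        return base
    return np.interp(np.linspace(0, 2, n_harvests), [0, 1, 2], base)


def simulate_volatile_tables(
    genotypes: Sequence[SimGenotype],
    cfg: SimConfig,
    n_harvests: int = 3,
    environments: Sequence[str] | None = None,
) -> list[PeakSample]:
    """GC/MS peak tables across a season.

    Non-carriers emit uniform background noise on [0, volatile_baseline]
    (normalized units), so ``volatile_baseline`` is their exact noise
    ceiling.  Carriers emit ``volatile_signal`` shaped by their trend class
    over harvests, multiplied by ``env_effect_fold`` in harvests labelled
    "inductive", with lognormal noise.  Each genotype × harvest yields
    ``n_replicates`` technical replicates.
    """
    if n_harvests < 3:
        raise ValueError(
            "n_harvests must be >= 3: producer/non-producer calling requires "
            "at least three harvests"
        )
    if environments is None:
        environments = ["inductive"] * n_harvests
    if len(environments) != n_harvests:
        raise ValueError("environments must have one label per harvest")
    rng = _rng(cfg.seed, "volatiles")
    env_factor = np.array(
        [cfg.env_effect_fold if e == "inductive" else 1.0 for e in environments]
    )
    samples: list[PeakSample] = []
    for g in genotypes:
        if g.carrier:
            signal = cfg.volatile_signal * _trend_shape(g.trend_class, n_harvests)
            signal = signal * env_factor
        for h in range(n_harvests):
            for rep in range(1, cfg.n_replicates + 1):
                is_area = _INTERNAL_STANDARD_AREA * np.exp(rng.normal(0.0, 0.05))
                if g.carrier:
                    ratio = signal[h] * np.exp(rng.normal(0.0, cfg.volatile_noise_sd))
                else:
                    ratio = rng.uniform(0.0, cfg.volatile_baseline)
                samples.append(
                    PeakSample(
                        genotype_id=g.id,
                        harvest_id=f"H{h + 1}",
                        environment=environments[h],
                        gd_area=float(ratio * is_area),
                        is_area=float(is_area),
                        replicate=rep,
                    )
                )
    return samples


def simulate_marker_panel(
    genotypes: Sequence[SimGenotype],
    seed: int = 0,
) -> tuple[list[MarkerCall], list[SSRGenotype]]:
    """Diagnostic PCR marker and linked SSR alleles for a panel.

    The 500 bp amplicon and SSR allele 205 sit inside/next to the deletion,
    so both are present iff the genotype carries the causal copy.  Allele
    209 is monomorphic (present in everyone); alleles 215 and 219 segregate
    independently of the phenotype (fair coin per genotype).
    """
    if not genotypes:
        raise ValueError("genotypes must be non-empty")
    rng = _rng(seed, "ssr")
    markers: list[MarkerCall] = []
    ssr: list[SSRGenotype] = []
    for g in genotypes:
        markers.append(
            MarkerCall(genotype_id=g.id, amplicon_present=g.carrier, control_present=True)
        )
        alleles = {209}
        if g.carrier:
            alleles.add(205)
        if rng.random() < 0.5:
            alleles.add(215)
        if rng.random() < 0.5:
            alleles.add(219)
        ssr.append(SSRGenotype(genotype_id=g.id, alleles=frozenset(alleles)))
    return markers, ssr


def simulate_pileups(
    n_sites: int,
    n_genotypes: int,
    cfg: SimConfig,
    seed: int | None = None,
) -> list[SiteObservation]:
    """Per-site read-support summaries with a planted passing fraction.

    Depth is Poisson(``pileup_mean_depth``); background non-reference
    counts are Binomial(depth, ``pileup_error_rate``), which essentially
    never reaches a 95% allele fraction.  A ``snp_pass_fraction`` of sites
    is planted to pass the SNP criteria in exactly two genotypes (depth
    forced to >= 10 and all reads non-reference).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if n_genotypes < 1:
        raise ValueError("n_genotypes must be >= 1")
    rng = _rng(cfg.seed if seed is None else seed, "pileups")
    gids = [f"G{i:03d}" for i in range(n_genotypes)]
    bases = np.array(list("ACGT"))
    sites: list[SiteObservation] = []
    planted = rng.random(n_sites) < cfg.snp_pass_fraction
    for i in range(n_sites):
        depth = rng.poisson(cfg.pileup_mean_depth, size=n_genotypes)
        nonref = rng.binomial(depth, cfg.pileup_error_rate)
        if planted[i]:
            chosen = rng.choice(n_genotypes, size=min(2, n_genotypes), replace=False)
            depth[chosen] = np.maximum(depth[chosen], 10)
            nonref[chosen] = depth[chosen]
        ref, alt = rng.choice(4, size=2, replace=False)
        sites.append(
            SiteObservation(
                chrom="chr1",
                pos=10 * (i + 1),
                ref_allele=str(bases[ref]),
                alt_allele=str(bases[alt]),
                observations={
                    gids[j]: (int(depth[j]), int(nonref[j])) for j in range(n_genotypes)
                },
            )
        )
    return sites


@dataclass(frozen=True)
class QPCRDesign:
    """What the qPCR experiment contrasts.

    ``stage_pair`` compares two conditions (e.g. ripe vs blushing fruit of
    one carrier genotype) with a configured true target induction;
    ``genotype_panel`` compares each genotype against a carrier calibrator,
    with no target amplification in non-carriers.
    """

    kind: Literal["stage_pair", "genotype_panel"] = "stage_pair"
    fold: float = 21.0
    conditions: tuple[str, str] = ("blushing", "ripe")  # (calibrator, sample)
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.kind not in ("stage_pair", "genotype_panel"):
            raise ValueError(f"unknown design kind {self.kind!r}")
        if self.fold <= 0:
            raise ValueError("fold must be positive")


def simulate_qpcr(
    genotypes: Sequence[SimGenotype],
    cfg: SimConfig,
    design: QPCRDesign,
) -> list[QPCRMeasurement]:
    """Triplicate CT values for target and housekeeping genes.

    CTs are Gaussian around fixed baselines with sd ``ct_noise_sd``; the
    sample-condition target baseline is shifted by −log2(fold) so the true
    fold change equals the configured value.  Non-carrier target reactions
    in a genotype panel never amplify (ct None).
    """
    rng = _rng(cfg.seed, f"qpcr:{design.kind}")

    def cts(base: float, n: int) -> list[float]:
        return [float(base + rng.normal(0.0, cfg.ct_noise_sd)) for _ in range(n)]

    out: list[QPCRMeasurement] = []
    n = design.n_replicates
    if design.kind == "stage_pair":
        calibrator, sample = design.conditions
        shift = {calibrator: 0.0, sample: -float(np.log2(design.fold))}
        for cond in (calibrator, sample):
            for rep, ct in enumerate(cts(_HOUSEKEEPING_CT, n), start=1):
                out.append(QPCRMeasurement("series", cond, HOUSEKEEPING, ct, rep))
            for rep, ct in enumerate(cts(_TARGET_CT + shift[cond], n), start=1):
                out.append(QPCRMeasurement("series", cond, TARGET, ct, rep))
        return out
    # genotype_panel: condition = genotype id, calibrator = first carrier
    carriers = [g for g in genotypes if g.carrier]
    if not carriers:
        raise ValueError("genotype panel needs at least one carrier as calibrator")
    for g in genotypes:
        for rep, ct in enumerate(cts(_HOUSEKEEPING_CT, n), start=1):
            out.append(QPCRMeasurement(g.id, g.id, HOUSEKEEPING, ct, rep))
        if g.carrier:
            for rep, ct in enumerate(cts(_TARGET_CT, n), start=1):
                out.append(QPCRMeasurement(g.id, g.id, TARGET, ct, rep))
        else:
            for rep in range(1, n + 1):
                out.append(QPCRMeasurement(g.id, g.id, TARGET, None, rep))
    return out
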