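"""In-silico bulked-segregant expression filtering.

The discovery computation: normalize gene-level counts to RPKM, compare
the two parental transcriptomes, pool segregating progeny by phenotype
class after the fact ("computational bulking"), and keep only genes whose
transcript support is more than ``fold_threshold``-fold higher in every
producer than in every non-producer.  Survivors are then screened for a
perfect presence/absence correlation with the phenotype — the signature of
a hemizygous deletion allele, where non-producers physically lack the gene.

All comparisons are deterministic thresholds, not statistical tests: the
design relies on segregation itself to cancel genotype-specific noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "PhenotypePools",
    "ParentalDEResult",
    "CandidateGene",
    "compute_rpkm",
    "detection_flags",
    "parental_comparison",
    "pairwise_candidate_filter",
    "presence_correlation_screen",
    "rank_by_parent_abundance",
]

#: RPKM above which a transcript counts as "detected" in a genotype.
DEFAULT_DETECT_THRESHOLD = 1.0
#: RPKM pseudocount added to numerator and denominator of pairwise folds.
DEFAULT_PSEUDOCOUNT = 0.1
#: Final pairwise exclusion fold (the screen is run at 2-4; 4 is strictest).
DEFAULT_FOLD_THRESHOLD = 4.0


@dataclass
class ExpressionMatrix:
    """Gene × genotype raw counts plus the metadata RPKM needs.

    ``counts`` is indexed by gene id with one column per genotype;
    ``gene_lengths`` (bp) aligns with the index and ``library_sizes``
    (total mapped reads) with the columns.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64, copy=False)
        self.gene_lengths = self.gene_lengths.astype(float)
        self.library_sizes = self.library_sizes.astype(float)
        if not self.counts.index.equals(self.gene_lengths.index):
            raise ValueError("gene_lengths index must match counts index")
        if not self.counts.columns.equals(self.library_sizes.index):
            raise ValueError("library_sizes index must match counts columns")
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids in counts")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate genotype ids in counts")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.gene_lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def genotype_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass(frozen=True)
class PhenotypePools:
    """The in-silico bulks: producer and non-producer genotype id sets."""

    producers: frozenset[str]
    nonproducers: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "producers", frozenset(self.producers))
        object.__setattr__(self, "nonproducers", frozenset(self.nonproducers))
        overlap = self.producers & self.nonproducers
        if overlap:
            raise ValueError(f"genotypes in both pools: {sorted(overlap)}")

    def validate_against(self, genotype_ids: Iterable[str]) -> None:
        known = set(genotype_ids)
        missing = (self.producers | self.nonproducers) - known
        if missing:
            raise ValueError(f"pool genotypes absent from matrix: {sorted(missing)}")
        if not self.producers or not self.nonproducers:
            raise ValueError("both pools must be non-empty for filtering")


@dataclass(frozen=True)
class ParentalDEResult:
    """Parent-vs-parent comparison among adequately expressed transcripts."""

    unique_to_a: frozenset[str]
    unique_to_b: frozenset[str]
    overexpressed_a: frozenset[str]
    overexpressed_b: frozenset[str]
    thresholds: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class CandidateGene:
    """A gene surviving the pairwise fold filter, with its evidence."""

    gene_id: str
    min_pairwise_fold: float
    detected_in: frozenset[str]
    perfect_correlation: bool
    producer_mean_rpkm: float
    nonproducer_mean_rpkm: float


def compute_rpkm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    ``RPKM[g, s] = counts[g, s] * 1e9 / (library_sizes[s] * gene_lengths[g])``.
    Zero counts map to zero RPKM.
    """
    return (
        matrix.counts.astype(float)
        .mul(1e9)
        .div(matrix.gene_lengths, axis=0)
        .div(matrix.library_sizes, axis=1)
    )


def detection_flags(rpkm: pd.DataFrame, detect_threshold: float = DEFAULT_DETECT_THRESHOLD) -> pd.DataFrame:
    """Boolean presence calls: RPKM strictly above the detection threshold."""
    if detect_threshold < 0:
        raise ValueError("detect_threshold must be >= 0")
    return rpkm > detect_threshold


def parental_comparison(
    rpkm: pd.DataFrame,
    parent_a: str,
    parent_b: str,
    min_rpkm: float = 10.0,
    fold: float = 5.0,
    detect_threshold: float = DEFAULT_DETECT_THRESHOLD,
) -> ParentalDEResult:
    """Unique and overexpressed transcript sets between the two parents.

    Only transcripts with RPKM > ``min_rpkm`` in at least one parent are
    considered.  A considered transcript is *unique* to a parent when
    detected there and undetected in the other, and *overexpressed* when
    detected in both at >= ``fold``-fold higher RPKM.
    """
    for p in (parent_a, parent_b):
        if p not in rpkm.columns:
            raise KeyError(f"unknown genotype id {p!r}")
    a = rpkm[parent_a]
    b = rpkm[parent_b]
    considered = (a > min_rpkm) | (b > min_rpkm)
    det_a = a > detect_threshold
    det_b = b > detect_threshold
    unique_a = considered & det_a & ~det_b
    unique_b = considered & det_b & ~det_a
    both = considered & det_a & det_b
    over_a = both & (a >= fold * b)
    over_b = both & (b >= fold * a)
    idx = rpkm.index
    return ParentalDEResult(
        unique_to_a=frozenset(idx[unique_a]),
        unique_to_b=frozenset(idx[unique_b]),
        overexpressed_a=frozenset(idx[over_a]),
        overexpressed_b=frozenset(idx[over_b]),
        thresholds={
            "min_rpkm": min_rpkm,
            "fold": fold,
            "detect_threshold": detect_threshold,
        },
    )


def pairwise_candidate_filter(
    rpkm: pd.DataFrame,
    pools: PhenotypePools,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    detect_threshold: float = DEFAULT_DETECT_THRESHOLD,
    mode: str = "pairwise",
) -> list[CandidateGene]:
    """Keep genes whose every producer/non-producer fold exceeds the threshold.

    In ``"pairwise"`` mode (the default) a gene survives iff

        (RPKM[g, p] + pseudocount) / (RPKM[g, q] + pseudocount) > fold_threshold

    for EVERY pair of producer ``p`` and non-producer ``q`` — equivalently,
    the worst pair (min over producers vs max over non-producers) clears the
    threshold.  ``"pool_mean"`` mode compares pool means instead and exists
    for sensitivity analysis.

    The pseudocount keeps folds finite where a non-producer has zero RPKM
    (the expected deletion signature) without reordering genes.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if mode not in ("pairwise", "pool_mean"):
        raise ValueError(f"unknown mode {mode!r}")
    pools.validate_against(rpkm.columns)
    prod = sorted(pools.producers)
    nonp = sorted(pools.nonproducers)
    P = rpkm[prod]
    Q = rpkm[nonp]
    if mode == "pairwise":
        with np.errstate(divide="ignore"):
            min_fold = (P.min(axis=1) + pseudocount) / (Q.max(axis=1) + pseudocount)
    else:
        min_fold = (P.mean(axis=1) + pseudocount) / (Q.mean(axis=1) + pseudocount)
    flags = detection_flags(rpkm, detect_threshold)
    perfect = flags[prod].all(axis=1) & ~flags[nonp].any(axis=1)
    survivors = min_fold > fold_threshold
    out: list[CandidateGene] = []
    for gene in rpkm.index[survivors]:
        out.append(
            CandidateGene(
                gene_id=gene,
                min_pairwise_fold=float(min_fold.loc[gene]),
                detected_in=frozenset(rpkm.columns[flags.loc[gene]]),
                perfect_correlation=bool(perfect.loc[gene]),
                producer_mean_rpkm=float(P.loc[gene].mean()),
                nonproducer_mean_rpkm=float(Q.loc[gene].mean()),
            )
        )
    return out


def presence_correlation_screen(
    candidates: Sequence[CandidateGene],
    flags: pd.DataFrame,
    pools: PhenotypePools,
) -> list[CandidateGene]:
    """Retain candidates detected in all producers and in no non-producer.

    This is the 100%-cosegregation screen: under the deletion model the
    causal transcript must be present in every producer and absent from
    every non-producer, with no exception allowed.
    """
    pools.validate_against(flags.columns)
    prod = sorted(pools.producers)
    nonp = sorted(pools.nonproducers)
    kept: list[CandidateGene] = []
    for cand in candidates:
        row = flags.loc[cand.gene_id]
        perfect = bool(row[prod].all() and not row[nonp].any())
        if perfect:
            kept.append(cand)
    return kept


def rank_by_parent_abundance(
    rpkm: pd.DataFrame,
    producer_parent: str,
    nonproducer_parent: str,
    k: int = 12,
    detect_threshold: float = DEFAULT_DETECT_THRESHOLD,
) -> list[str]:
    """Top-k genes by producer-parent RPKM among those the other parent lacks.

    Mirrors the "most abundant producer-specific transcripts" shortlist.
    Ties break lexicographically on gene id; if fewer than ``k`` genes are
    eligible, all of them are returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    for p in (producer_parent, nonproducer_parent):
        if p not in rpkm.columns:
            raise KeyError(f"unknown genotype id {p!r}")
    eligible = rpkm.index[rpkm[nonproducer_parent] <= detect_threshold]
    ranked = sorted(eligible, key=lambda g: (-rpkm.at[g, producer_parent], g))
    return ranked[:k]
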