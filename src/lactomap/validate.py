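"""Marker and expression validation statistics.

Confirmatory statistics around a candidate gene: comparative-CT
(2^-ΔΔCT) fold changes from qPCR, chi-square goodness-of-fit against a
Mendelian segregation ratio, PCR-marker/phenotype concordance with a 2×2
cosegregation test, and per-allele SSR association summaries.

No multiple-testing correction is applied: these are single-locus
confirmatory tests, and per-allele SSR rows are reported unadjusted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .volatiles import ProducerStatus

__all__ = [
    "QPCRMeasurement",
    "FoldChangeResult",
    "MarkerCall",
    "SSRGenotype",
    "SegregationTest",
    "ConcordanceResult",
    "ddct_fold_change",
    "chi_square_ratio",
    "marker_concordance",
    "ssr_allele_association",
]

TARGET = "target"
HOUSEKEEPING = "housekeeping"


@dataclass(frozen=True)
class QPCRMeasurement:
    """One technical-replicate CT reading.

    ``ct`` is None when the reaction never crossed threshold
    (no amplification) — expected for the target gene in genotypes that
    physically lack it.
    """

    sample_id: str
    condition: str
    gene: str  # "target" | "housekeeping"
    ct: float | None
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.gene not in (TARGET, HOUSEKEEPING):
            raise ValueError(f"gene must be 'target' or 'housekeeping', got {self.gene!r}")
        if self.ct is not None and self.ct <= 0:
            raise ValueError(f"amplified CT must be positive, got {self.ct}")


@dataclass(frozen=True)
class FoldChangeResult:
    """2^-ΔΔCT relative quantification for one condition vs a calibrator.

    ``sd`` is the sample ΔCT standard deviation in cycles, propagated as
    sqrt(sd_target^2 + sd_housekeeping^2); ``fold_lo``/``fold_hi`` translate
    that ±1 SD band to fold units (the two scales are reported separately
    because a CT SD and a fold SD are not interchangeable).
    """

    fold: float
    ddct: float
    sd: float
    fold_lo: float
    fold_hi: float
    no_amplification: bool = False


@dataclass(frozen=True)
class MarkerCall:
    """Presence/absence of the diagnostic PCR amplicon in one genotype."""

    genotype_id: str
    amplicon_present: bool
    control_present: bool = True


@dataclass(frozen=True)
class SSRGenotype:
    """Microsatellite fragment sizes (bp) observed in one genotype."""

    genotype_id: str
    alleles: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", frozenset(int(a) for a in self.alleles))
        if not self.alleles:
            raise ValueError(f"empty allele set for {self.genotype_id}")


@dataclass(frozen=True)
class SegregationTest:
    observed: tuple[int, ...]
    expected_ratio: tuple[float, ...]
    expected: tuple[float, ...]
    chi_square: float
    df: int
    p_value: float


@dataclass(frozen=True)
class ConcordanceResult:
    concordance: float
    n: int
    discordant: tuple[str, ...]
    table: tuple[tuple[int, int], tuple[int, int]]  # marker +/- x phenotype +/-
    chi_square: float | None
    p_value: float
    p_method: str  # "chi_square" | "exact_binomial"


def _ct_stats(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0


def ddct_fold_change(
    measurements: Iterable[QPCRMeasurement],
    sample_condition: str,
    calibrator_condition: str,
) -> FoldChangeResult:
    """Comparative-CT fold change of ``sample_condition`` vs the calibrator.

    ΔCT = mean CT(target) − mean CT(housekeeping) within each condition,
    ΔΔCT = ΔCT(sample) − ΔCT(calibrator), fold = 2^-ΔΔCT, assuming 100%
    amplification efficiency.  If the target never amplified in the sample
    the result is fold 0 with ``no_amplification`` set — absence of the
    gene, not low expression, so no max-cycle CT is imputed.
    """
    by: dict[tuple[str, str], list[float | None]] = {}
    for m in measurements:
        by.setdefault((m.condition, m.gene), []).append(m.ct)
    for cond in (sample_condition, calibrator_condition):
        if (cond, HOUSEKEEPING) not in by or not any(
            ct is not None for ct in by[(cond, HOUSEKEEPING)]
        ):
            raise ValueError(f"missing housekeeping CTs for condition {cond!r}")
        if (cond, TARGET) not in by:
            raise ValueError(f"missing target CTs for condition {cond!r}")

    def amplified(cond: str, gene: str) -> list[float]:
        return [ct for ct in by[(cond, gene)] if ct is not None]

    sample_target = amplified(sample_condition, TARGET)
    if not sample_target:
        return FoldChangeResult(
            fold=0.0, ddct=math.inf, sd=0.0, fold_lo=0.0, fold_hi=0.0,
            no_amplification=True,
        )
    cal_target = amplified(calibrator_condition, TARGET)
    if not cal_target:
        raise ValueError("target never amplified in the calibrator condition")
    mean_t, sd_t = _ct_stats(sample_target)
    mean_h, sd_h = _ct_stats(amplified(sample_condition, HOUSEKEEPING))
    cal_t, _ = _ct_stats(cal_target)
    cal_h, _ = _ct_stats(amplified(calibrator_condition, HOUSEKEEPING))
    dct_sample = mean_t - mean_h
    dct_cal = cal_t - cal_h
    ddct = dct_sample - dct_cal
    sd = math.sqrt(sd_t**2 + sd_h**2)
    fold = 2.0 ** (-ddct)
    return FoldChangeResult(
        fold=fold,
        ddct=ddct,
        sd=sd,
        fold_lo=2.0 ** (-(ddct + sd)),
        fold_hi=2.0 ** (-(ddct - sd)),
    )


def chi_square_ratio(
    observed: Sequence[int], expected_ratio: Sequence[float]
) -> SegregationTest:
    """Pearson goodness-of-fit of observed category counts to a ratio.

    E.g. producer:non-producer counts against the 1:1 expected for a
    simplex dominant locus.  df = number of categories − 1.
    """
    obs = np.asarray(observed, dtype=float)
    ratio = np.asarray(expected_ratio, dtype=float)
    if obs.shape != ratio.shape:
        raise ValueError("observed and expected_ratio must have equal length")
    if obs.sum() <= 0:
        raise ValueError("total observed count must be positive")
    if (ratio <= 0).any():
        raise ValueError("all expected ratio terms must be positive")
    expected = ratio / ratio.sum() * obs.sum()
    chi2, p = stats.chisquare(obs, f_exp=expected)
    return SegregationTest(
        observed=tuple(int(o) for o in obs),
        expected_ratio=tuple(float(r) for r in ratio),
        expected=tuple(float(e) for e in expected),
        chi_square=float(chi2),
        df=len(obs) - 1,
        p_value=float(p),
    )


def marker_concordance(
    marker_calls: Iterable[MarkerCall],
    phenotypes: Mapping[str, ProducerStatus | str],
) -> ConcordanceResult:
    """Fraction of genotypes where amplicon presence matches producer status.

    Genotypes with a failed PCR control or with an INSUFFICIENT_DATA
    phenotype are excluded.  Alongside the concordance fraction the 2×2
    marker × phenotype cosegregation test is reported: Pearson chi-square
    for ordinary tables, or — when a margin is zero, as with perfect
    cosegregation — the exact probability 0.5^(n-1) that an independent
    fair presence/absence marker would be perfectly concordant or
    perfectly anti-concordant with the phenotype.
    """
    usable: list[tuple[str, bool, bool]] = []
    for call in marker_calls:
        if not call.control_present:
            continue
        status = phenotypes.get(call.genotype_id)
        if status is None:
            continue
        status = ProducerStatus(status)
        if status is ProducerStatus.INSUFFICIENT_DATA:
            continue
        usable.append(
            (call.genotype_id, call.amplicon_present, status is ProducerStatus.PRODUCER)
        )
    if not usable:
        raise ValueError("no genotypes with both a valid marker call and a phenotype")
    n = len(usable)
    discordant = tuple(g for g, marker, pheno in usable if marker != pheno)
    concordance = (n - len(discordant)) / n
    table = np.zeros((2, 2), dtype=int)
    for _, marker, pheno in usable:
        table[0 if marker else 1, 0 if pheno else 1] += 1
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        chi2 = None
        p = 0.5 ** (n - 1)
        method = "exact_binomial"
    else:
        chi2_val, p, _, _ = stats.chi2_contingency(table, correction=False)
        chi2, p = float(chi2_val), float(p)
        method = "chi_square"
    return ConcordanceResult(
        concordance=concordance,
        n=n,
        discordant=discordant,
        table=tuple(map(tuple, table.tolist())),
        chi_square=chi2,
        p_value=float(p),
        p_method=method,
    )


def ssr_allele_association(
    ssr_genotypes: Iterable[SSRGenotype],
    phenotypes: Mapping[str, ProducerStatus | str],
) -> pd.DataFrame:
    """Per-allele frequencies by phenotype class, with predictor flags.

    Returns a DataFrame indexed by allele size with columns
    ``freq_producers``, ``freq_nonproducers``, ``monomorphic`` (present in
    every genotype) and ``perfect_predictor`` (present in all producers and
    in no non-producer).  Fragment sizes are exact integers; no binning.
    """
    entries: list[tuple[frozenset[int], bool]] = []
    for g in ssr_genotypes:
        status = phenotypes.get(g.genotype_id)
        if status is None:
            continue
        status = ProducerStatus(status)
        if status is ProducerStatus.INSUFFICIENT_DATA:
            continue
        entries.append((g.alleles, status is ProducerStatus.PRODUCER))
    n_prod = sum(1 for _, is_p in entries if is_p)
    n_nonp = len(entries) - n_prod
    if n_prod == 0 or n_nonp == 0:
        raise ValueError("need at least one genotype per phenotype class")
    all_alleles = sorted(set().union(*(a for a, _ in entries)))
    rows = []
    for allele in all_alleles:
        in_prod = sum(1 for a, is_p in entries if is_p and allele in a)
        in_nonp = sum(1 for a, is_p in entries if not is_p and allele in a)
        rows.append(
            {
                "allele": allele,
                "freq_producers": in_prod / n_prod,
                "freq_nonproducers": in_nonp / n_nonp,
                "monomorphic": in_prod + in_nonp == len(entries),
                "perfect_predictor": in_prod == n_prod and in_nonp == 0,
            }
        )
    return pd.DataFrame(rows).set_index("allele")
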