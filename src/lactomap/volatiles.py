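"""GC/MS volatile phenotyping.

Turns integrated peak-area tables into internal-standard-normalized
responses, producer / non-producer calls, estimated concentrations from a
spiked-puree standard curve, and a five-class seasonal trend label per
genotype.

The qualitative phenotype is whether a genotype ever emits the target
lactone above background noise.  Because accumulation is strongly
environment- and harvest-dependent, a genotype is only declared a
*non-producer* when the compound stayed at or below the noise floor across
at least three harvests; fewer harvests give ``INSUFFICIENT_DATA``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PeakSample",
    "VolatileSeries",
    "StandardCurve",
    "ConcentrationEstimate",
    "TrendClass",
    "ProducerStatus",
    "InvalidSampleError",
    "normalize_to_internal_standard",
    "series_from_peaks",
    "call_producer_status",
    "classify_seasonal_trend",
    "fit_standard_curve",
    "estimate_concentration",
    "noise_floor_from_blanks",
]

#: Default relative tolerance for trend classification (the shapes are
#: classified visually in practice; 20% separates "different" harvests).
DEFAULT_REL_TOL = 0.2

#: Minimum number of harvests required to call a non-producer.
MIN_HARVESTS_FOR_NONPRODUCER = 3

#: Calibrated spike range of the standard curve, mM.
CALIBRATION_RANGE = (0.005, 0.3)


class InvalidSampleError(ValueError):
    """A peak sample that cannot be normalized (failed internal standard)."""


class TrendClass(str, enum.Enum):
    """Seasonal accumulation pattern over three harvests."""

    NONPRODUCER = "NONPRODUCER"
    PEAK = "PEAK"            # mid-season maximum
    VALLEY = "VALLEY"        # mid-season minimum
    DECREASE = "DECREASE"    # high early, then flat-low
    INCREASE = "INCREASE"    # monotone rise through the season


class ProducerStatus(str, enum.Enum):
    PRODUCER = "PRODUCER"
    NONPRODUCER = "NONPRODUCER"
    INSUFFICIENT_DATA = "INSUFFICIENT_DATA"


@dataclass(frozen=True)
class PeakSample:
    """One integrated GC/MS measurement of one genotype at one harvest.

    ``gd_area`` is the target-lactone peak area and ``is_area`` the peak
    area of the spiked internal standard (3-hexanone at fixed
    concentration), both in arbitrary detector units.
    """

    genotype_id: str
    harvest_id: str
    environment: str
    gd_area: float
    is_area: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.gd_area < 0:
            raise InvalidSampleError(
                f"negative target peak area for {self.genotype_id}/{self.harvest_id}"
            )


@dataclass(frozen=True)
class VolatileSeries:
    """Per-harvest normalized responses for one genotype.

    Technical replicates are averaged per harvest; the replicate SD is
    retained for reporting.  ``means``/``sds`` are indexed by harvest id in
    chronological (sorted) order.
    """

    genotype_id: str
    means: pd.Series
    sds: pd.Series

    @property
    def n_harvests(self) -> int:
        return len(self.means)


@dataclass(frozen=True)
class StandardCurve:
    """OLS calibration line of baseline-corrected response on spiked mM."""

    slope: float
    intercept: float
    baseline: float
    r_squared: float
    cal_range: tuple[float, float] = CALIBRATION_RANGE


@dataclass(frozen=True)
class ConcentrationEstimate:
    mM: float
    flag: str = "ok"  # "ok" | "below_calibration" | "above_calibration"

    @property
    def extrapolated(self) -> bool:
        return self.flag != "ok"

    def __str__(self) -> str:
        if self.flag == "below_calibration":
            return f"< {CALIBRATION_RANGE[0]} mM (below calibration)"
        return f"{self.mM:.4g} mM" + (" (above calibration)" if self.extrapolated else "")


def normalize_to_internal_standard(sample: PeakSample) -> float:
    """Target peak area divided by the internal-standard peak area.

    The internal standard is spiked at a fixed concentration before
    blending, so the ratio is comparable across runs and instruments.
    """
    if sample.is_area <= 0:
        raise InvalidSampleError(
            f"internal-standard area {sample.is_area} <= 0 for "
            f"{sample.genotype_id}/{sample.harvest_id} (failed spike?)"
        )
    return sample.gd_area / sample.is_area


def series_from_peaks(samples: Iterable[PeakSample]) -> dict[str, VolatileSeries]:
    """Average technical replicates per genotype × harvest.

    Returns one :class:`VolatileSeries` per genotype, harvests sorted by id.
    """
    rows = [
        {
            "genotype_id": s.genotype_id,
            "harvest_id": s.harvest_id,
            "response": normalize_to_internal_standard(s),
        }
        for s in samples
    ]
    if not rows:
        return {}
    df = pd.DataFrame(rows)
    out: dict[str, VolatileSeries] = {}
    for gid, sub in df.groupby("genotype_id", sort=True):
        grp = sub.groupby("harvest_id", sort=True)["response"]
        out[gid] = VolatileSeries(
            genotype_id=gid, means=grp.mean(), sds=grp.std(ddof=1).fillna(0.0)
        )
    return out


def call_producer_status(series: VolatileSeries, noise_floor: float) -> ProducerStatus:
    """Producer if the compound ever rose above the noise floor.

    A non-producer call additionally requires at least three harvests all at
    or below the floor; with fewer silent harvests the genotype is
    ``INSUFFICIENT_DATA`` (a producer may simply have hit non-inductive
    conditions).
    """
    if noise_floor < 0:
        raise ValueError("noise_floor must be >= 0")
    if series.n_harvests == 0:
        raise ValueError(f"empty volatile series for {series.genotype_id}")
    if (series.means > noise_floor).any():
        return ProducerStatus.PRODUCER
    if series.n_harvests >= MIN_HARVESTS_FOR_NONPRODUCER:
        return ProducerStatus.NONPRODUCER
    return ProducerStatus.INSUFFICIENT_DATA


def classify_seasonal_trend(
    series: VolatileSeries,
    noise_floor: float,
    rel_tol: float = DEFAULT_REL_TOL,
) -> TrendClass:
    """Assign one of five seasonal accumulation classes.

    Requires exactly three harvest means ``v1, v2, v3``.  Two values are
    considered *different* when they differ by more than ``rel_tol`` times
    the seasonal maximum.  Rules, checked in order:

    * NONPRODUCER — all three at or below the noise floor;
    * PEAK — v2 above both neighbours;
    * VALLEY — v2 below both neighbours;
    * DECREASE — v1 above both v2 and v3, which are mutually similar;
    * INCREASE — v3 > v2 > v1, each step a real difference.

    Profiles where no rule fires (near-flat producers) fall through to a
    documented weak-maximum tie-break with priority
    PEAK > DECREASE > INCREASE.
    """
    if not 0 <= rel_tol < 1:
        raise ValueError("rel_tol must be in [0, 1)")
    if series.n_harvests != 3:
        raise ValueError(
            f"trend classification needs exactly 3 harvests, got {series.n_harvests} "
            f"for {series.genotype_id}"
        )
    v1, v2, v3 = (float(x) for x in series.means)
    if max(v1, v2, v3) <= noise_floor:
        return TrendClass.NONPRODUCER
    m = max(v1, v2, v3)
    gap = rel_tol * m

    def above(a: float, b: float) -> bool:
        return a - b > gap

    if above(v2, v1) and above(v2, v3):
        return TrendClass.PEAK
    if above(v1, v2) and above(v3, v2):
        return TrendClass.VALLEY
    if above(v1, v2) and above(v1, v3) and abs(v2 - v3) <= gap:
        return TrendClass.DECREASE
    if above(v3, v2) and above(v2, v1):
        return TrendClass.INCREASE
    # flat or mixed producer profile: weak-maximum tie-break
    if v2 >= v1 and v2 >= v3:
        return TrendClass.PEAK
    if v1 >= v2 and v1 >= v3:
        return TrendClass.DECREASE
    return TrendClass.INCREASE


def fit_standard_curve(
    spike_concentrations: Sequence[float],
    responses: Sequence[float],
    baseline_response: float,
    cal_range: tuple[float, float] | None = None,
) -> StandardCurve:
    """Fit an OLS line of baseline-corrected response on spiked concentration.

    The curve is built by spiking pure compound into half-ripe fruit puree
    (mimicking the ripe-fruit matrix); ``baseline_response`` is the response
    of unspiked puree and is subtracted before fitting.
    """
    conc = np.asarray(spike_concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.shape != resp.shape:
        raise ValueError("concentrations and responses must have equal length")
    if (conc < 0).any():
        raise ValueError("spike concentrations must be >= 0")
    if len(np.unique(conc)) < 3:
        raise ValueError("need at least 3 distinct spike concentrations")
    fit = stats.linregress(conc, resp - baseline_response)
    if cal_range is None:
        cal_range = (float(conc.min()), float(conc.max()))
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        baseline=float(baseline_response),
        r_squared=float(fit.rvalue) ** 2,
        cal_range=cal_range,
    )


def estimate_concentration(curve: StandardCurve, response: float) -> ConcentrationEstimate:
    """Invert the standard curve at a measured response.

    Values outside the calibrated spike range are returned but flagged as
    extrapolated; negative inversions clip to 0 mM (below calibration).
    """
    if curve.slope <= 0:
        raise ValueError(f"invalid standard curve: slope {curve.slope} <= 0")
    raw = (response - curve.baseline - curve.intercept) / curve.slope
    value = max(0.0, raw)
    lo, hi = curve.cal_range
    # tolerate round-off at the range edges so an exact inversion of the
    # lowest/highest spike is not flagged
    eps = 1e-9
    if value < lo * (1 - eps):
        flag = "below_calibration"
    elif value > hi * (1 + eps):
        flag = "above_calibration"
    else:
        flag = "ok"
    return ConcentrationEstimate(mM=value, flag=flag)


def noise_floor_from_blanks(blank_responses: Sequence[float]) -> float:
    """Default detection floor: mean + 3·SD of blank (or known-null) responses."""
    arr = np.asarray(blank_responses, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one blank response")
    return float(arr.mean() + 3.0 * arr.std(ddof=1 if arr.size > 1 else 0))
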