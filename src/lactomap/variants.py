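"""SNP filtering from per-site, per-genotype pileup summaries.

A lightweight presence filter rather than a genotype-likelihood caller: a
genotype supports a variant site when it has adequate read depth and a
near-fixed non-reference allele fraction, and a site is reported when
enough genotypes support it.  Thresholds are inclusive ("10 or greater"
depth, "95% minimum" fraction).
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

__all__ = ["SiteObservation", "SNPCall", "filter_snps", "write_vcf"]

DEFAULT_MIN_NONREF_FRAC = 0.95
DEFAULT_MIN_DEPTH = 10
DEFAULT_MIN_GENOTYPES = 2


@dataclass(frozen=True)
class SiteObservation:
    """Read support at one site: per-genotype (depth, non-reference count)."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    observations: Mapping[str, tuple[int, int]]  # genotype_id -> (depth, nonref)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be 1-based, got {self.pos}")

    def validate(self) -> None:
        for gid, (depth, nonref) in self.observations.items():
            if depth < 0 or nonref < 0 or nonref > depth:
                raise ValueError(
                    f"malformed pileup at {self.chrom}:{self.pos} genotype {gid}: "
                    f"nonref {nonref} vs depth {depth}"
                )


@dataclass(frozen=True)
class SNPCall:
    site: SiteObservation
    passing_genotypes: frozenset[str]

    @property
    def n_passing(self) -> int:
        return len(self.passing_genotypes)


def filter_snps(
    sites: Sequence[SiteObservation],
    min_nonref_frac: float = DEFAULT_MIN_NONREF_FRAC,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_genotypes: int = DEFAULT_MIN_GENOTYPES,
) -> list[SNPCall]:
    """Emit sites supported by at least ``min_genotypes`` genotypes.

    A genotype passes at a site iff ``depth >= min_depth`` and
    ``nonref/depth >= min_nonref_frac`` (both inclusive).  Zero-depth
    genotypes never pass.
    """
    if not 0 < min_nonref_frac <= 1:
        raise ValueError("min_nonref_frac must be in (0, 1]")
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if min_genotypes < 1:
        raise ValueError("min_genotypes must be >= 1")
    calls: list[SNPCall] = []
    for site in sites:
        site.validate()
        passing = frozenset(
            gid
            for gid, (depth, nonref) in site.observations.items()
            if depth >= min_depth and nonref / depth >= min_nonref_frac
        )
        if len(passing) >= min_genotypes:
            calls.append(SNPCall(site=site, passing_genotypes=passing))
    return calls


def write_vcf(
    calls: Sequence[SNPCall],
    sample_ids: Sequence[str],
    out: str | Path,
    source: str = "lactomap",
) -> Path:
    """Write calls as minimal VCF 4.2 with a per-sample pass flag.

    INFO carries ``NPASS`` (number of passing genotypes); FORMAT field
    ``PF`` is 1 for genotypes that passed the depth/fraction criteria at
    the site.  Input must already be sorted by (chrom, pos).
    """
    keys = [(c.site.chrom, c.site.pos) for c in calls]
    if keys != sorted(keys):
        raise ValueError("calls must be sorted by (chrom, pos) before writing VCF")
    out = Path(out)
    lines = [
        "##fileformat=VCFv4.2",
        f"##fileDate={datetime.date.today():%Y%m%d}",
        f"##source={source}",
        '##INFO=<ID=NPASS,Number=1,Type=Integer,Description='
        '"Number of genotypes passing depth and non-reference-fraction criteria">',
        '##FORMAT=<ID=PF,Number=1,Type=Integer,Description='
        '"1 if this genotype passed the per-genotype SNP criteria at this site">',
    ]
    for chrom in dict.fromkeys(c.site.chrom for c in calls):
        lines.append(f"##contig=<ID={chrom}>")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header.extend(sample_ids)
    lines.append("\t".join(header))
    for call in calls:
        s = call.site
        row = [
            s.chrom,
            str(s.pos),
            ".",
            s.ref_allele,
            s.alt_allele,
            ".",
            "PASS",
            f"NPASS={call.n_passing}",
            "PF",
        ]
        row.extend("1" if gid in call.passing_genotypes else "0" for gid in sample_ids)
        lines.append("\t".join(row))
    out.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return out
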