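"""Table readers and writers for every pipeline format.

All tables are plain text with a mandatory header row: tab-separated for
pipeline tables, comma-separated for instrument-style tables (GC/MS peaks,
qPCR).  Missing numeric cells are written as ``.`` (or left empty in CSV)
and are distinguished from zeros on read.  Duplicate gene or genotype ids
are rejected; files are UTF-8.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bulkseg import ExpressionMatrix
from .validate import MarkerCall, QPCRMeasurement, SSRGenotype
from .variants import SiteObservation
from .volatiles import PeakSample

__all__ = [
    "SchemaError",
    "read_counts", "write_counts",
    "read_peaks", "write_peaks",
    "read_phenotypes", "write_phenotypes",
    "read_markers", "write_markers",
    "read_ssr", "write_ssr",
    "read_pileups", "write_pileups",
    "read_qpcr", "write_qpcr",
]

MISSING = "."


class SchemaError(ValueError):
    """Input file does not match its documented schema."""


def _read(path: str | Path, sep: str, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def _numeric(df: pd.DataFrame, col: str, path: Path | str, allow_missing: bool = False) -> pd.Series:
    raw = df[col].replace({MISSING: None, "": None})
    if not allow_missing and raw.isna().any():
        line = int(raw.index[raw.isna()][0]) + 2  # header + 1-based
        raise SchemaError(f"{path}: missing value in column {col!r} at line {line}")
    try:
        # float() is correctly rounded, so written values round-trip exactly
        return pd.Series(
            [np.nan if v is None else float(v) for v in raw],
            index=raw.index,
        )
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{path}: non-numeric value in column {col!r}: {exc}") from exc


# -- expression counts --------------------------------------------------------

def read_counts(
    counts_path: str | Path,
    genes_path: str | Path,
    libsizes_path: str | Path | None = None,
    libsizes_from_colsums: bool = False,
) -> ExpressionMatrix:
    """Read a counts TSV plus its companion gene-length table.

    The counts file has ``gene_id`` as first column and one column per
    genotype.  Library sizes come from an explicit two-column TSV
    (``genotype_id``, ``library_size``) or, with
    ``libsizes_from_colsums=True``, from the count column sums.
    """
    if not Path(counts_path).exists():
        raise SchemaError(f"{counts_path}: file not found")
    # pandas mangles duplicate headers, so inspect the raw header line first
    with open(counts_path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    dupes = [c for c in set(header) if header.count(c) > 1]
    if dupes:
        raise SchemaError(f"{counts_path}: duplicate genotype column {dupes[0]!r}")
    counts = _read(counts_path, "\t", ["gene_id"])
    if counts["gene_id"].duplicated().any():
        dup = counts["gene_id"][counts["gene_id"].duplicated()].iloc[0]
        raise SchemaError(f"{counts_path}: duplicate gene id {dup!r}")
    genotype_cols = [c for c in counts.columns if c != "gene_id"]
    if not genotype_cols:
        raise SchemaError(f"{counts_path}: no genotype columns")
    for c in genotype_cols:
        counts[c] = _numeric(counts, c, counts_path)
    counts = counts.set_index("gene_id").astype(np.int64)

    genes = _read(genes_path, "\t", ["gene_id", "length_bp"])
    if genes["gene_id"].duplicated().any():
        raise SchemaError(f"{genes_path}: duplicate gene id")
    lengths = pd.Series(
        _numeric(genes, "length_bp", genes_path).to_numpy(dtype=float),
        index=genes["gene_id"].tolist(),
    )
    try:
        lengths = lengths.loc[counts.index]
    except KeyError:
        missing = set(counts.index) - set(lengths.index)
        raise SchemaError(f"{genes_path}: no length for gene(s) {sorted(missing)[:5]}")

    if libsizes_from_colsums:
        libs = counts.sum(axis=0).astype(float)
    elif libsizes_path is not None:
        lt = _read(libsizes_path, "\t", ["genotype_id", "library_size"])
        libs = pd.Series(
            _numeric(lt, "library_size", libsizes_path).to_numpy(dtype=float),
            index=lt["genotype_id"].tolist(),
        )
        try:
            libs = libs.loc[counts.columns]
        except KeyError:
            missing = set(counts.columns) - set(libs.index)
            raise SchemaError(
                f"{libsizes_path}: no library size for genotype(s) {sorted(missing)}"
            )
    else:
        raise SchemaError("provide libsizes_path or set libsizes_from_colsums=True")
    return ExpressionMatrix(counts=counts, gene_lengths=lengths, library_sizes=libs)


def write_counts(
    matrix: ExpressionMatrix,
    counts_path: str | Path,
    genes_path: str | Path,
    libsizes_path: str | Path | None = None,
) -> None:
    matrix.counts.rename_axis("gene_id").reset_index().to_csv(
        counts_path, sep="\t", index=False
    )
    pd.DataFrame(
        {"gene_id": matrix.gene_lengths.index,
         "length_bp": matrix.gene_lengths.astype(int).to_numpy()}
    ).to_csv(genes_path, sep="\t", index=False)
    if libsizes_path is not None:
        pd.DataFrame(
            {"genotype_id": matrix.library_sizes.index,
             "library_size": matrix.library_sizes.astype(int).to_numpy()}
        ).to_csv(libsizes_path, sep="\t", index=False)


# -- GC/MS peaks --------------------------------------------------------------

PEAK_COLUMNS = ["genotype_id", "harvest_id", "environment", "replicate", "gd_area", "is_area"]


def read_peaks(path: str | Path) -> list[PeakSample]:
    df = _read(path, ",", PEAK_COLUMNS)
    gd = _numeric(df, "gd_area", path)
    is_ = _numeric(df, "is_area", path)
    rep = _numeric(df, "replicate", path)
    return [
        PeakSample(
            genotype_id=row.genotype_id,
            harvest_id=row.harvest_id,
            environment=row.environment,
            gd_area=float(gd.iloc[i]),
            is_area=float(is_.iloc[i]),
            replicate=int(rep.iloc[i]),
        )
        for i, row in enumerate(df.itertuples())
    ]


def write_peaks(samples: Iterable[PeakSample], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "genotype_id": s.genotype_id,
                "harvest_id": s.harvest_id,
                "environment": s.environment,
                "replicate": s.replicate,
                "gd_area": s.gd_area,
                "is_area": s.is_area,
            }
            for s in samples
        ]
    ).to_csv(path, index=False)


# -- phenotypes ---------------------------------------------------------------

def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = _read(path, "\t", ["genotype_id", "status"])
    if df["genotype_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate genotype id")
    return df.set_index("genotype_id")


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.rename_axis("genotype_id").reset_index().to_csv(
        path, sep="\t", index=False, na_rep=MISSING
    )


# -- markers ------------------------------------------------------------------

def read_markers(path: str | Path) -> list[MarkerCall]:
    df = _read(path, "\t", ["genotype_id", "amplicon", "control"])
    if df["genotype_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate genotype id")
    amp = _numeric(df, "amplicon", path)
    ctl = _numeric(df, "control", path)
    return [
        MarkerCall(
            genotype_id=df["genotype_id"].iloc[i],
            amplicon_present=bool(amp.iloc[i]),
            control_present=bool(ctl.iloc[i]),
        )
        for i in range(len(df))
    ]


def write_markers(calls: Iterable[MarkerCall], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "genotype_id": c.genotype_id,
                "amplicon": int(c.amplicon_present),
                "control": int(c.control_present),
            }
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)


# -- SSR ----------------------------------------------------------------------

def read_ssr(path: str | Path) -> list[SSRGenotype]:
    df = _read(path, "\t", ["genotype_id", "alleles"])
    if df["genotype_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate genotype id")
    out = []
    for i in range(len(df)):
        raw = df["alleles"].iloc[i]
        try:
            alleles = frozenset(int(a) for a in raw.split(",") if a.strip())
        except ValueError as exc:
            raise SchemaError(
                f"{path}: bad allele list {raw!r} at line {i + 2}"
            ) from exc
        out.append(SSRGenotype(genotype_id=df["genotype_id"].iloc[i], alleles=alleles))
    return out


def write_ssr(genotypes: Iterable[SSRGenotype], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"genotype_id": g.genotype_id,
             "alleles": ",".join(str(a) for a in sorted(g.alleles))}
            for g in genotypes
        ]
    ).to_csv(path, sep="\t", index=False)


# -- pileups ------------------------------------------------------------------

PILEUP_COLUMNS = ["chrom", "pos", "ref", "alt", "genotype_id", "depth", "nonref_count"]


def read_pileups(path: str | Path) -> list[SiteObservation]:
    """Read a long-format pileup TSV into per-site observations.

    Rows sharing (chrom, pos) are collected into one site; sites come back
    sorted by coordinate.
    """
    df = _read(path, "\t", PILEUP_COLUMNS)
    pos = _numeric(df, "pos", path)
    depth = _numeric(df, "depth", path)
    nonref = _numeric(df, "nonref_count", path)
    df = df.assign(pos=pos.astype(int), depth=depth.astype(int),
                   nonref_count=nonref.astype(int))
    sites = []
    for (chrom, p, ref, alt), sub in df.groupby(["chrom", "pos", "ref", "alt"], sort=True):
        if sub["genotype_id"].duplicated().any():
            raise SchemaError(f"{path}: duplicate genotype at {chrom}:{p}")
        sites.append(
            SiteObservation(
                chrom=chrom,
                pos=int(p),
                ref_allele=ref,
                alt_allele=alt,
                observations={
                    row.genotype_id: (int(row.depth), int(row.nonref_count))
                    for row in sub.itertuples()
                },
            )
        )
    return sites


def write_pileups(sites: Iterable[SiteObservation], path: str | Path) -> None:
    rows = []
    for s in sites:
        for gid, (depth, nonref) in s.observations.items():
            rows.append(
                {"chrom": s.chrom, "pos": s.pos, "ref": s.ref_allele,
                 "alt": s.alt_allele, "genotype_id": gid,
                 "depth": depth, "nonref_count": nonref}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- qPCR ---------------------------------------------------------------------

QPCR_COLUMNS = ["sample_id", "condition", "gene", "replicate", "ct"]


def read_qpcr(path: str | Path) -> list[QPCRMeasurement]:
    """Read qPCR CSV; an empty or ``.`` ct cell means no amplification."""
    df = _read(path, ",", QPCR_COLUMNS)
    ct = _numeric(df, "ct", path, allow_missing=True)
    rep = _numeric(df, "replicate", path)
    return [
        QPCRMeasurement(
            sample_id=df["sample_id"].iloc[i],
            condition=df["condition"].iloc[i],
            gene=df["gene"].iloc[i],
            ct=None if pd.isna(ct.iloc[i]) else float(ct.iloc[i]),
            replicate=int(rep.iloc[i]),
        )
        for i in range(len(df))
    ]


def write_qpcr(measurements: Iterable[QPCRMeasurement], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"sample_id": m.sample_id, "condition": m.condition, "gene": m.gene,
             "replicate": m.replicate, "ct": "" if m.ct is None else m.ct}
            for m in measurements
        ]
    ).to_csv(path, index=False)
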