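"""Plain-text readers and writers for all module schemas.

Conventions: TSV with a header line; coordinates 0-based half-open (a
``one_based`` flag on readers shifts positions by -1); comment lines
start with ``#`` and may carry the run's config hash and seed.  Floats
are written with a fixed format so that identical runs produce
byte-identical files.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chip import BinCountTrack, SpikeInCounts
from .genome import BinGrid, GeneAnnotation, GenomeLayout, SnpRecord
from .wgbs import BinMethylation, CALL_COLUMNS, CpgCallSet

FLOAT_FMT = "%.6g"


def _header_lines(header: dict | None) -> str:
    if not header:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in sorted(header.items()))


def _read_tsv(path, columns, dtypes, one_based_col=None, one_based=False):
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame({c: pd.Series(dtype=dtypes[c]) for c in columns})
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = {}
    for c in columns:
        try:
            out[c] = df[c].astype(dtypes[c])
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[c], errors="coerce").isna()]
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise ValueError(f"{path}: malformed {c!r} value at line {line}")
    res = pd.DataFrame(out)
    if one_based and one_based_col:
        res[one_based_col] = res[one_based_col] - 1
    return res


# -- genome ---------------------------------------------------------------

def read_chrom_sizes(path, x_names: Sequence[str] = ("chrX", "X")) -> GenomeLayout:
    """Two-column chrom.sizes file (name, length) -> GenomeLayout."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], comment="#")
    return GenomeLayout.from_lengths(
        dict(zip(df["chrom"], df["length"].astype(int))), x_names=x_names
    )


def write_chrom_sizes(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for c in layout.chromosomes:
            fh.write(f"{c.name}\t{c.length}\n")


def read_bed6(path) -> list[GeneAnnotation]:
    genes = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}: line {i}: BED6 needs 6 fields")
            chrom, start, end, name, _score, strand = parts[:6]
            genes.append(GeneAnnotation(name, chrom, int(start), int(end), strand))
    return genes


def write_bed6(genes: Iterable[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


SNP_COLUMNS = ["chrom", "pos", "maternal", "paternal", "shared"]


def read_snps(path, one_based: bool = False) -> list[SnpRecord]:
    df = _read_tsv(
        path, SNP_COLUMNS,
        {"chrom": str, "pos": np.int64, "maternal": str, "paternal": str, "shared": np.int64},
        one_based_col="pos", one_based=one_based,
    )
    return [
        SnpRecord(r.chrom, int(r.pos), r.maternal, r.paternal, bool(r.shared))
        for r in df.itertuples(index=False)
    ]


def write_snps(snps: Iterable[SnpRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SNP_COLUMNS) + "\n")
        for s in snps:
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.maternal_allele}\t{s.paternal_allele}"
                f"\t{int(s.shared_with_third_strain)}\n"
            )


# -- WGBS -----------------------------------------------------------------

def read_cpg_calls(path, sample_id: str | None = None, one_based: bool = False) -> CpgCallSet:
    """CpG call TSV (chrom, pos, meth_count, total_count).

    Also accepts a bedGraph-like dialect with columns
    (chrom, start, end, level, meth, unmeth): counts are reconstructed as
    meth and meth+unmeth, positions from start.
    """
    path = Path(path)
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n").split("\t")
                break
        else:
            header = []
    if {"start", "meth", "unmeth"}.issubset(header):
        df = _read_tsv(
            path, ["chrom", "start", "meth", "unmeth"],
            {"chrom": str, "start": np.int64, "meth": np.int64, "unmeth": np.int64},
            one_based_col="start", one_based=one_based,
        )
        calls = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "pos": df["start"],
                "meth_count": df["meth"],
                "total_count": df["meth"] + df["unmeth"],
            }
        )
    else:
        calls = _read_tsv(
            path, CALL_COLUMNS,
            {"chrom": str, "pos": np.int64, "meth_count": np.int64, "total_count": np.int64},
            one_based_col="pos", one_based=one_based,
        )
    return CpgCallSet(sample_id or path.stem, calls)


def write_cpg_calls(calls: CpgCallSet, path, header: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(header))
        calls.df[CALL_COLUMNS].to_csv(fh, sep="\t", index=False)


def write_bedgraph(
    grid: BinGrid, values: np.ndarray, path, header: dict | None = None,
    drop_missing: bool = True,
) -> None:
    """Per-bin values as bedGraph (chrom, start, end, value), 0-based half-open."""
    df = grid.df[["chrom", "start", "end"]].copy()
    df["value"] = values
    if drop_missing:
        df = df[~np.isnan(df["value"])]
    with open(path, "w") as fh:
        fh.write(_header_lines(header))
        df.to_csv(fh, sep="\t", index=False, header=False, float_format=FLOAT_FMT)


def read_bedgraph(path, grid: BinGrid) -> np.ndarray:
    """bedGraph values re-aligned to a grid (NaN where absent)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"],
    )
    values = np.full(grid.n_bins, np.nan)
    for chrom, sub in df.groupby("chrom", sort=False):
        idx = grid.locate_indices(chrom, sub["start"].to_numpy())
        values[idx] = sub["value"].to_numpy()
    return values


def write_bin_methylation(binmeth: BinMethylation, path, header: dict | None = None) -> None:
    write_bedgraph(binmeth.grid, binmeth.level, path, header=header)


# -- ChIP -----------------------------------------------------------------

BIN_COUNT_COLUMNS = ["chrom", "start", "end", "count"]


def read_bin_counts(path, grid: BinGrid, sample_id: str | None = None) -> BinCountTrack:
    df = _read_tsv(
        path, BIN_COUNT_COLUMNS,
        {"chrom": str, "start": np.int64, "end": np.int64, "count": np.float64},
    )
    counts = np.zeros(grid.n_bins)
    for chrom, sub in df.groupby("chrom", sort=False):
        idx = grid.locate_indices(chrom, sub["start"].to_numpy())
        counts[idx] = sub["count"].to_numpy()
    return BinCountTrack(sample_id or Path(path).stem, grid, counts)


def write_bin_counts(track: BinCountTrack, path, header: dict | None = None) -> None:
    df = track.grid.df[["chrom", "start", "end"]].copy()
    df["count"] = track.counts
    with open(path, "w") as fh:
        fh.write(_header_lines(header))
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def read_spikein_table(path) -> dict[str, SpikeInCounts]:
    df = _read_tsv(
        path, ["sample", "state", "count"],
        {"sample": str, "state": str, "count": np.int64},
    )
    out: dict[str, SpikeInCounts] = {}
    for sample, sub in df.groupby("sample", sort=False):
        out[sample] = SpikeInCounts(sample, dict(zip(sub["state"], sub["count"].astype(int))))
    return out


def write_spikein_table(rows: Iterable[tuple[str, str, int]], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tstate\tcount\n")
        for sample, state, count in rows:
            fh.write(f"{sample}\t{state}\t{count}\n")


# -- generic --------------------------------------------------------------

def write_table(df: pd.DataFrame, path, header: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(header))
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
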