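"""Plain-text genomics I/O: BED6, bedGraph, FASTA, expression TSV.

All coordinates are 0-based half-open (BED dialect).  bigWig coverage
input is supported when pyBigWig is importable.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from valleytf.annotation import GeneModel
from valleytf.coverage import READ_COLUMNS, CoverageTrack, ValleyCall


def read_bed_reads(path) -> pd.DataFrame:
    """Read aligned reads from BED (first 6 columns used)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ValueError(f"{path}: BED6 with a strand column is required for reads")
    df = df.iloc[:, [0, 1, 2, 5]]
    df.columns = READ_COLUMNS
    return df


def write_bed_reads(reads: pd.DataFrame, path) -> None:
    out = reads.copy()
    out.insert(3, "name", [f"read{i}" for i in range(len(out))])
    out.insert(4, "score", 0)
    out.to_csv(path, sep="\t", header=False, index=False)


def read_genes_bed(path) -> list[GeneModel]:
    """Gene models from BED6: name = gene_id, TSS = 5' end per strand."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ValueError(f"{path}: BED6 gene models require name and strand columns")
    genes = []
    for _, row in df.iterrows():
        strand = str(row[5])
        tss = int(row[1]) if strand == "+" else int(row[2]) - 1
        genes.append(GeneModel(str(row[3]), str(row[0]), tss, strand))
    return genes


def write_genes_bed(genes: Sequence[GeneModel], path, span: int = 2000) -> None:
    rows = []
    for g in genes:
        if g.strand == "+":
            start, end = g.tss, g.tss + span
        else:
            start, end = max(0, g.tss + 1 - span), g.tss + 1
        rows.append((g.chrom, start, end, g.gene_id, 0, g.strand))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_valleys_bed(valleys: Iterable[ValleyCall], path) -> None:
    """Merged valley calls as BED6 (score field = valley score)."""
    rows = [
        (v.chrom, v.start, v.end, f"valley{i}", f"{v.score:.4f}", ".")
        for i, v in enumerate(valleys)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_valleys_bed(path, time_point: float | None = None) -> list[ValleyCall]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return [
        ValleyCall(str(r[0]), int(r[1]), int(r[2]), float(r[4]), time_point)
        for _, r in df.iterrows()
    ]


def write_bedgraph(track: CoverageTrack, path, mode: str = "w") -> None:
    """One step-sized interval per bin (zero-valued bins skipped)."""
    pos = track.positions
    vals = track.values
    nz = vals != 0
    df = pd.DataFrame(
        {
            "chrom": track.chrom,
            "start": pos[nz],
            "end": pos[nz] + track.step,
            "value": vals[nz],
        }
    )
    header = not (mode == "a" and Path(path).exists())
    with open(path, mode) as fh:
        if header:
            fh.write(f'track type=bedGraph name="{Path(str(path)).stem}"\n')
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_bedgraph(path, step: int = 10) -> dict[str, CoverageTrack]:
    """Sample a bedGraph onto a fixed-step grid (value at bin start)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", skiprows=_count_track_lines(path)
    )
    df.columns = ["chrom", "start", "end", "value"][: df.shape[1]]
    tracks = {}
    for chrom, grp in df.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        origin = int(grp["start"].min() // step) * step
        last = int(grp["end"].max())
        n_bins = (last - origin) // step + 1
        pos = origin + step * np.arange(n_bins)
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        vals = grp["value"].to_numpy(dtype=float)
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        values = np.where(inside, vals[np.clip(idx, 0, None)], 0.0)
        tracks[str(chrom)] = CoverageTrack(str(chrom), origin, step, values)
    return tracks


def _count_track_lines(path) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "browser")):
                n += 1
            else:
                break
    return n


def read_bigwig(path, step: int = 10) -> dict[str, CoverageTrack]:
    """Sample a bigWig onto a fixed-step grid (requires pyBigWig)."""
    import pyBigWig  # local import: optional dependency

    tracks = {}
    with pyBigWig.open(str(path)) as bw:
        for chrom, length in bw.chroms().items():
            n_bins = length // step
            vals = np.array(bw.values(chrom, 0, n_bins * step))
            values = np.nan_to_num(vals[::step])
            tracks[chrom] = CoverageTrack(chrom, 0, step, values)
    return tracks


def write_fasta(genome: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = str(genome[name])
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_expression_tsv(path) -> pd.DataFrame:
    """Gene x sample log2 expression matrix; first column = gene IDs."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")
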