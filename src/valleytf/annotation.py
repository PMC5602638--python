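"""Gene models, promoter windows, APR assignment, sequence extraction.

An active promoter region (APR) is a called HAc valley lying within
+-5 kbp of a gene's transcription start site.  Promoter windows are
strand-aware (-1500/+500 for motif background promoters, -2000/+500
for ChIP-seq read counting).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from valleytf.coverage import ValleyCall


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    tss: int
    strand: str
    expressed: bool = True

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"{self.gene_id}: tss must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


@dataclass(frozen=True)
class WindowSpec:
    """Strand-aware window around a TSS, in bp upstream/downstream."""

    upstream: int
    downstream: int

    def __post_init__(self) -> None:
        if self.upstream + self.downstream <= 0:
            raise ValueError("window must have positive extent")


PROMOTER_MOTIF = WindowSpec(1500, 500)  # motif-background promoter window
PROMOTER_CHIP = WindowSpec(2000, 500)  # ChIP-seq read-counting window
APR_RADIUS = 5000


def promoter_window(gene: GeneModel, spec: WindowSpec) -> tuple[str, int, int]:
    """Half-open genomic interval of the gene's promoter window (clamped at 0)."""
    if gene.strand == "+":
        start, end = gene.tss - spec.upstream, gene.tss + spec.downstream
    else:
        start, end = gene.tss - spec.downstream, gene.tss + spec.upstream
    return gene.chrom, max(0, start), end


APRSet = dict[str, list[tuple[float, ValleyCall]]]


def assign_aprs(
    valleys_by_time: Mapping[float, Sequence[ValleyCall]],
    genes: Sequence[GeneModel],
    radius: int = APR_RADIUS,
) -> APRSet:
    """Assign each valley to every gene whose TSS +-radius window it overlaps.

    A valley near two TSSs serves both genes.  Valleys on chromosomes
    with no genes are left unassigned.  Returns gene_id -> list of
    (time_point, valley), with times in ascending order.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    sorted_tss: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
    for chrom, glist in by_chrom.items():
        glist = sorted(glist, key=lambda g: g.tss)
        sorted_tss[chrom] = (np.array([g.tss for g in glist]), glist)

    aprs: APRSet = {g.gene_id: [] for g in genes}
    for time_point in sorted(valleys_by_time):
        for v in valleys_by_time[time_point]:
            if v.chrom not in sorted_tss:
                continue
            tss, glist = sorted_tss[v.chrom]
            # overlap of [v.start, v.end) with [tss-radius, tss+radius)
            # <=> v.start - radius < tss < v.end + radius
            lo = int(np.searchsorted(tss, v.start - radius, side="right"))
            hi = int(np.searchsorted(tss, v.end + radius, side="left"))
            for g in glist[lo:hi]:
                aprs[g.gene_id].append((time_point, v))
    return aprs


def _get_chrom_seq(genome, chrom: str) -> str:
    if isinstance(genome, Mapping):
        if chrom not in genome:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        return str(genome[chrom])
    # pyfaidx.Fasta or similar mapping-like object
    try:
        return str(genome[chrom][:])
    except KeyError as exc:
        raise KeyError(f"chromosome {chrom!r} not in genome") from exc


def extract_sequences(
    regions: Iterable[tuple[str, str, int, int]], genome
) -> list[tuple[str, str]]:
    """Extract uppercase sequences for named half-open regions.

    ``regions`` yields (name, chrom, start, end).  ``genome`` is a
    mapping chrom -> sequence (dict of strings or a pyfaidx.Fasta).
    Regions outside the chromosome raise with the offending name.
    """
    cache: dict[str, str] = {}
    out: list[tuple[str, str]] = []
    for name, chrom, start, end in regions:
        if chrom not in cache:
            cache[chrom] = _get_chrom_seq(genome, chrom)
        seq = cache[chrom]
        if start < 0 or end > len(seq) or start >= end:
            raise ValueError(
                f"region {name!r} [{start},{end}) outside chromosome {chrom} "
                f"(length {len(seq)})"
            )
        out.append((name, seq[start:end].upper()))
    return out


def apr_sequences(
    aprs: APRSet,
    genome,
    time_point: float,
    gene_ids: Iterable[str] | None = None,
) -> list[tuple[str, str]]:
    """Sequences of APR valleys at one time point, one entry per valley.

    Regions stay separate (never concatenated) so a motif placement can
    never span two valleys.
    """
    ids = list(gene_ids) if gene_ids is not None else list(aprs)
    regions = []
    for gid in ids:
        for t, v in aprs.get(gid, []):
            if t == time_point:
                regions.append((f"{gid}|{v.chrom}:{v.start}-{v.end}", v.chrom, v.start, v.end))
    return extract_sequences(regions, genome)


def promoter_sequences(
    genes: Sequence[GeneModel], genome, spec: WindowSpec = PROMOTER_MOTIF
) -> list[tuple[str, str]]:
    """Promoter-window sequences for a gene list (clamped at chromosome ends)."""
    cache: dict[str, int] = {}
    regions = []
    for g in genes:
        chrom, start, end = promoter_window(g, spec)
        if chrom not in cache:
            cache[chrom] = len(_get_chrom_seq(genome, chrom))
        end = min(end, cache[chrom])
        if start < end:
            regions.append((g.gene_id, chrom, start, end))
    return extract_sequences(regions, genome)
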