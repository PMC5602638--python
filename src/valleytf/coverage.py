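"""Read preprocessing, 10 bp coverage tracks, and HAc valley calling.

A valley is a local dip in an otherwise histone-acetylated region: the
smoothed signal at a sample point falls below 70% of the smaller of the
two flanking-window maxima (windows 50-500 bp to either side).  The
valley score at such a point is that smaller flanking maximum; runs of
consecutive valley points are merged into one call scored by the
maximum point score in the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import gaussian_filter1d

logger = logging.getLogger(__name__)

READ_COLUMNS = ["chrom", "start", "end", "strand"]


@dataclass(frozen=True)
class SmoothingParams:
    """Gaussian smoothing of the sampled signal.

    sigma is in bp; the kernel is truncated at +-4 sigma and
    renormalized (tail mass < 1e-4).
    """

    sigma: float = 40.0
    truncate: float = 4.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class ValleyParams:
    """Flanking-window geometry and dip threshold for valley calling."""

    near: int = 50  # bp; inner edge of each flanking window
    far: int = 500  # bp; outer edge
    dip_fraction: float = 0.70

    def __post_init__(self) -> None:
        if not 0 < self.near < self.far:
            raise ValueError(f"need 0 < near < far, got {self.near}, {self.far}")
        if not 0 < self.dip_fraction < 1:
            raise ValueError(f"dip_fraction must be in (0,1), got {self.dip_fraction}")


@dataclass
class CoverageTrack:
    """Signal sampled on a fixed-step bp grid along one chromosome.

    ``values[i]`` is the signal at genomic position ``origin + i*step``.
    """

    chrom: str
    origin: int
    step: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")

    @property
    def positions(self) -> np.ndarray:
        return self.origin + self.step * np.arange(len(self.values))

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ValleyCall:
    """A merged run of valley sample points (half-open bp interval)."""

    chrom: str
    start: int
    end: int
    score: float
    time_point: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("valley interval must be non-empty")
        if self.score <= 0:
            raise ValueError("valley score must be > 0")

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and self.end > start


def validate_reads(reads: pd.DataFrame) -> pd.DataFrame:
    """Check a read table (chrom/start/end/strand) against basic invariants."""
    missing = [c for c in READ_COLUMNS if c not in reads.columns]
    if missing:
        raise ValueError(f"read table missing columns: {missing}")
    if len(reads) and not (reads["start"] < reads["end"]).all():
        raise ValueError("reads must satisfy start < end")
    if len(reads) and not reads["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-' for every read")
    return reads


def preprocess_reads(reads: pd.DataFrame, extension: int = 122) -> pd.DataFrame:
    """Deduplicate reads and extend each by `extension` bp in its 3' direction.

    Exact duplicates (same chrom/start/end/strand) collapse to one
    record.  Plus-strand reads grow at the end, minus-strand reads at
    the start (floored at 0).
    """
    if extension < 0:
        raise ValueError(f"extension must be >= 0, got {extension}")
    validate_reads(reads)
    out = reads.drop_duplicates(subset=READ_COLUMNS).reset_index(drop=True).copy()
    plus = out["strand"] == "+"
    out.loc[plus, "end"] = out.loc[plus, "end"] + extension
    out.loc[~plus, "start"] = (out.loc[~plus, "start"] - extension).clip(lower=0)
    return out


def build_coverage(reads: pd.DataFrame, step: int = 10) -> dict[str, CoverageTrack]:
    """Per-chromosome coverage sampled every `step` bp.

    The value of bin i is the number of reads covering the bin's start
    coordinate (bedGraph-style point sampling; the grid is anchored at
    genomic coordinate 0).
    """
    validate_reads(reads)
    if len(reads) == 0:
        logger.warning("empty read set: no coverage tracks built")
        return {}
    tracks: dict[str, CoverageTrack] = {}
    for chrom, grp in reads.groupby("chrom", sort=True):
        starts = np.sort(grp["start"].to_numpy())
        ends = np.sort(grp["end"].to_numpy())
        origin = int(starts[0] // step) * step
        last = int(ends[-1])
        n_bins = (last - origin) // step + 1
        pos = origin + step * np.arange(n_bins)
        # depth at pos = #reads with start <= pos  minus  #reads with end <= pos
        depth = np.searchsorted(starts, pos, side="right") - np.searchsorted(
            ends, pos, side="right"
        )
        tracks[str(chrom)] = CoverageTrack(str(chrom), origin, step, depth.astype(float))
    return tracks


def smooth(track: CoverageTrack, params: SmoothingParams | None = None) -> CoverageTrack:
    """Convolve the track with a normalized Gaussian (sigma given in bp)."""
    params = params or SmoothingParams()
    sigma_bins = params.sigma / track.step
    out = gaussian_filter1d(
        track.values, sigma=sigma_bins, mode="nearest", truncate=params.truncate
    )
    return CoverageTrack(track.chrom, track.origin, track.step, out)


def _flank_window_maxima(
    values: np.ndarray, near_bins: int, far_bins: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Left/right flanking-window maxima for every bin, plus a callable mask.

    The left window of bin i covers bins [i-far_bins, i-near_bins],
    truncated at the track edge; a bin is callable only if both windows
    retain at least one bin.  The interior is vectorized with sliding
    windows; the <= far_bins bins at each edge use a direct scan.
    """
    n = len(values)
    w = far_bins - near_bins + 1
    left = np.full(n, np.nan)
    right = np.full(n, np.nan)
    if n > far_bins:
        win_max = sliding_window_view(values, w).max(axis=1)  # max over [j, j+w-1]
        # full left window for bin i starts at i - far_bins
        left[far_bins:] = win_max[: n - far_bins]
        right[: n - far_bins] = win_max[near_bins : near_bins + n - far_bins]
    # truncated windows near the edges
    for i in range(min(far_bins, n)):
        if i - near_bins >= 0:
            left[i] = values[max(0, i - far_bins) : i - near_bins + 1].max()
    for i in range(max(0, n - far_bins), n):
        if i + near_bins <= n - 1:
            right[i] = values[i + near_bins : min(n - 1, i + far_bins) + 1].max()
    callable_mask = ~np.isnan(left) & ~np.isnan(right)
    return left, right, callable_mask


def flanking_maxima(
    track: CoverageTrack, i: int, params: ValleyParams | None = None
) -> tuple[float, float]:
    """Max smoothed signal in the two flanking windows of sample point i.

    Raises ValueError if either window falls entirely off the track.
    """
    params = params or ValleyParams()
    nb = params.near // track.step
    fb = params.far // track.step
    n = len(track.values)
    if not 0 <= i < n:
        raise IndexError(f"bin index {i} out of range")
    lo, hi = max(0, i - fb), i - nb
    if hi < lo:
        raise ValueError(f"left flanking window of bin {i} is off the track")
    left = float(track.values[lo : hi + 1].max())
    lo, hi = i + nb, min(n - 1, i + fb)
    if lo > hi:
        raise ValueError(f"right flanking window of bin {i} is off the track")
    right = float(track.values[lo : hi + 1].max())
    return left, right


def valley_score_signal(
    track: CoverageTrack, params: ValleyParams | None = None
) -> CoverageTrack:
    """Per-point valley score: min of the flanking maxima at valley points, else 0."""
    params = params or ValleyParams()
    nb = params.near // track.step
    fb = params.far // track.step
    left, right, ok = _flank_window_maxima(track.values, nb, fb)
    with np.errstate(invalid="ignore"):
        flank_min = np.minimum(left, right)
        is_valley = ok & (track.values < params.dip_fraction * flank_min)
    scores = np.where(is_valley, flank_min, 0.0)
    return CoverageTrack(track.chrom, track.origin, track.step, scores)


def call_valleys(
    track: CoverageTrack,
    params: ValleyParams | None = None,
    time_point: float | None = None,
    min_score: float = 0.0,
    enriched_mask: np.ndarray | None = None,
) -> list[ValleyCall]:
    """Call valleys on a smoothed track and merge consecutive valley points.

    Each maximal run of valley sample points becomes one call spanning
    ``[first_point, last_point + step)`` whose score is the maximum
    point score within the run.

    ``min_score`` and ``enriched_mask`` restrict calls to acetylated
    (signal-enriched) regions: points whose valley score falls below
    ``min_score``, or lying outside the boolean per-bin mask, are not
    called.  This stands in for an IP-vs-control enriched-region map
    when none is supplied.
    """
    params = params or ValleyParams()
    signal = valley_score_signal(track, params)
    if min_score > 0:
        signal.values[signal.values < min_score] = 0.0
    if enriched_mask is not None:
        if len(enriched_mask) != len(signal.values):
            raise ValueError("enriched_mask length must match the track")
        signal.values[~np.asarray(enriched_mask, dtype=bool)] = 0.0
    scores = signal.values
    is_valley = scores > 0
    calls: list[ValleyCall] = []
    if not is_valley.any():
        return calls
    padded = np.concatenate([[False], is_valley, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for run_start, run_end in zip(edges[::2], edges[1::2]):
        start = track.origin + track.step * int(run_start)
        end = track.origin + track.step * int(run_end - 1) + track.step
        score = float(scores[run_start:run_end].max())
        calls.append(ValleyCall(track.chrom, start, end, score, time_point))
    return calls
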