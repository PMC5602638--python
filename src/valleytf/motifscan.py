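"""PWM handling and Clover-style motif over-representation scoring.

The raw score of a motif on a sequence set is the log of the average
likelihood ratio (ALR) over all PWM placements on both strands of every
sequence, relative to a background base composition:

    ALR(seq) = (1 / (2*(L-w+1))) * sum over placements of
               prod_j P_pwm(base_j) / P_bg(base_j)
    raw_score = ln( mean over sequences of ALR )

Sequences are scored independently, so no placement can span two
regions.  Enrichment p-values come from resampling length-matched
fragments of a background sequence set (promoters of all expressed
genes): p = (1 + #draws with raw_score >= observed) / (R + 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_ENCODE = np.full(256, 4, dtype=np.uint8)  # anything non-ACGT -> 4 (neutral)
for _i, _b in enumerate(_BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

DEFAULT_PSEUDOCOUNT = 0.375


def encode_sequence(seq: str) -> np.ndarray:
    """Encode A/C/G/T (case-insensitive) as 0..3; other letters as 4 (neutral)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class PWM:
    """A TFBS position-weight matrix.

    ``counts`` are the raw (possibly float) observation counts, one row
    per position in A/C/G/T order; ``probs`` are the pseudocounted
    column-normalized probabilities actually used for scoring.
    """

    motif_id: str
    counts: np.ndarray
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError(f"{self.motif_id}: counts must be w x 4")
        if self.counts.shape[0] < 1:
            raise ValueError(f"{self.motif_id}: motif width must be >= 1")
        padded = self.counts + self.pseudocount
        self.probs = padded / padded.sum(axis=1, keepdims=True)

    @property
    def width(self) -> int:
        return int(self.counts.shape[0])

    def reverse_complement(self) -> np.ndarray:
        """Probability matrix of the reverse-complement motif."""
        return self.probs[::-1, ::-1]


def read_motifs(path, fmt: str = "transfac", pseudocount: float = DEFAULT_PSEUDOCOUNT) -> list[PWM]:
    """Read PWMs from a TRANSFAC flat file or MEME minimal file.

    Count matrices are converted to probabilities with a per-base
    pseudocount; motif IDs are preserved verbatim.
    """
    fmt = fmt.lower()
    if fmt not in ("transfac", "meme", "minimal"):
        raise ValueError(f"unknown motif format {fmt!r}")
    bio_fmt = "transfac" if fmt == "transfac" else "minimal"
    with open(path) as fh:
        try:
            records = bio_motifs.parse(fh, bio_fmt)
            pwms = []
            for m in records:
                name = m.get("ID", m.name) if bio_fmt == "transfac" else m.name
                counts = np.array([[m.counts[b][i] for b in _BASES] for i in range(m.length)])
                pwms.append(PWM(str(name), counts, pseudocount))

        except Exception as exc:
            raise ValueError(f"malformed motif file {path}: {exc}") from exc
    if not pwms:
        raise ValueError(f"no motifs found in {path}")
    return pwms


def write_motifs_transfac(pwms: list[PWM], path) -> None:
    """Write PWMs as a TRANSFAC flat file (counts preserved)."""
    with open(path, "w") as fh:
        fh.write("VV  valleytf motif export\nXX\n//\n")
        for pwm in pwms:
            fh.write(f"ID  {pwm.motif_id}\nBF  undefined\nP0      A      C      G      T\n")
            for i, row in enumerate(pwm.counts, start=1):
                cells = "".join(f" {v:6.2f}" for v in row)
                fh.write(f"{i:02d}  {cells}   N\n")
            fh.write("XX\n//\n")


@dataclass
class Background:
    """Background model: promoter sequences of all expressed genes.

    Base frequencies are estimated from the sequences themselves unless
    given.  Per-PWM placement-likelihood profiles are cached so that the
    ALR of any substring of any background sequence is O(1) via prefix
    sums, which makes fragment resampling cheap.
    """

    sequences: list[str]
    base_frequencies: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("background requires at least one sequence")
        self.encoded = [encode_sequence(s) for s in self.sequences]
        self.lengths = np.array([len(e) for e in self.encoded])
        if self.base_frequencies is None:
            counts = np.zeros(4)
            for e in self.encoded:
                counts += np.bincount(e[e < 4], minlength=4)
            if counts.sum() == 0:
                raise ValueError("background sequences contain no unambiguous bases")
            self.base_frequencies = counts / counts.sum()
        else:
            self.base_frequencies = np.asarray(self.base_frequencies, dtype=float)
            if not np.isclose(self.base_frequencies.sum(), 1.0):
                raise ValueError("background base frequencies must sum to 1")
        self._cache: dict[str, list[np.ndarray]] = {}

    def placement_cumsums(self, pwm: PWM) -> tuple[np.ndarray, np.ndarray]:
        """Concatenated cumulative sums of both-strand placement LR products.

        Returns (flat, offsets): the cumsum array of sequence i occupies
        flat[offsets[i] : offsets[i+1]], with element k holding the sum
        of placement values v[0..k-1] where v[j] = LR(forward placement
        at j) + LR(reverse placement at j).  The sum of placements
        [s, s+n) of sequence i is flat[off+s+n] - flat[off+s].
        """
        if pwm.motif_id not in self._cache:
            per_seq = [
                np.concatenate([[0.0], np.cumsum(placement_values(pwm, e, self.base_frequencies))])
                for e in self.encoded
            ]
            offsets = np.concatenate([[0], np.cumsum([len(c) for c in per_seq])])
            self._cache[pwm.motif_id] = (np.concatenate(per_seq), offsets[:-1])
        return self._cache[pwm.motif_id]


def _log_ratio_table(probs: np.ndarray, bg_freqs: np.ndarray) -> np.ndarray:
    """(w, 5) table of log likelihood ratios; column 4 (N) contributes 0."""
    w = probs.shape[0]
    tab = np.zeros((w, 5))
    with np.errstate(divide="ignore"):
        tab[:, :4] = np.log(probs) - np.log(bg_freqs)[None, :]
    return tab


def placement_values(pwm: PWM, encoded: np.ndarray, bg_freqs: np.ndarray) -> np.ndarray:
    """Both-strand likelihood-ratio products for every placement start.

    Returns an array of length L-w+1 with v[i] = LR_forward(i) +
    LR_reverse(i); empty if the sequence is shorter than the motif.
    Ambiguous bases (N) contribute a neutral factor of 1.
    """
    w = pwm.width
    n_place = len(encoded) - w + 1
    if n_place <= 0:
        return np.zeros(0)
    fwd = _log_ratio_table(pwm.probs, bg_freqs)
    # reverse-strand placements score the reverse complement of the window
    # against the PWM, so the background likelihood uses the complementary
    # base at each position (bg reversed in ACGT order = complemented);
    # this keeps ALR(seq) == ALR(revcomp(seq)) exactly for any background.
    rev = _log_ratio_table(pwm.reverse_complement(), np.asarray(bg_freqs)[::-1])
    sf = np.zeros(n_place)
    sr = np.zeros(n_place)
    for j in range(w):
        col = encoded[j : j + n_place]
        sf += fwd[j, col]
        sr += rev[j, col]
    return np.exp(sf) + np.exp(sr)


def sequence_alr(pwm: PWM, seq: str | np.ndarray, bg: Background) -> float:
    """Average likelihood ratio of the PWM over all placements of one sequence.

    Averages the per-placement likelihood-ratio products over both
    strands, i.e. over 2*(L-w+1) placements.
    """
    encoded = encode_sequence(seq) if isinstance(seq, str) else seq
    v = placement_values(pwm, encoded, bg.base_frequencies)
    if len(v) == 0:
        raise ValueError(f"sequence shorter than motif width {pwm.width}")
    return float(v.sum() / (2 * len(v)))


def raw_score(pwm: PWM, seqs: list[str] | list[np.ndarray], bg: Background) -> float:
    """ln of the mean per-sequence ALR; nan if no sequence is long enough.

    Sequences shorter than the motif are skipped with a warning.
    """
    alrs = []
    n_skipped = 0
    for s in seqs:
        encoded = encode_sequence(s) if isinstance(s, str) else s
        if len(encoded) < pwm.width:
            n_skipped += 1
            continue
        alrs.append(sequence_alr(pwm, encoded, bg))
    if n_skipped:
        warnings.warn(
            f"{pwm.motif_id}: skipped {n_skipped} sequence(s) shorter than motif",
            stacklevel=2,
        )
    if not alrs:
        return float("nan")
    return float(np.log(np.mean(alrs)))


def _fragment_null_scores(
    pwm: PWM,
    target_lengths: np.ndarray,
    bg: Background,
    n_draws: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null raw scores from length-matched fragment resampling.

    For each target sequence length, a random same-length substring of a
    random (long-enough) background sequence is drawn; the draw's raw
    score is the log mean ALR of those fragments.  Substring ALRs are
    read off cached placement-product prefix sums.
    """
    flat, offsets = bg.placement_cumsums(pwm)
    w = pwm.width
    usable = np.sort(target_lengths[target_lengths >= w])
    if len(usable) == 0:
        return np.full(n_draws, np.nan)
    alr_sum = np.zeros(n_draws)
    lengths, counts = np.unique(usable, return_counts=True)
    for lt, m in zip(lengths, counts):
        eligible = np.flatnonzero(bg.lengths >= lt)
        if len(eligible) == 0:
            raise ValueError(
                f"no background sequence is as long as a target sequence ({lt} bp)"
            )
        n_total = n_draws * int(m)
        seq_idx = eligible[rng.integers(0, len(eligible), size=n_total)]
        n_place = int(lt) - w + 1
        # fragment [s, s+lt) has placements s .. s+lt-w
        max_start = bg.lengths[seq_idx] - lt
        starts = (rng.random(n_total) * (max_start + 1)).astype(np.int64)
        base = offsets[seq_idx] + starts
        vals = (flat[base + n_place] - flat[base]) / (2 * n_place)
        alr_sum += vals.reshape(n_draws, int(m)).sum(axis=1)
    return np.log(alr_sum / len(usable))


def enrichment_p(
    pwm: PWM,
    target_seqs: list[str] | list[np.ndarray],
    bg: Background,
    n_draws: int = 1000,
    seed: int | np.random.Generator = 0,
    observed: float | None = None,
) -> float:
    """Resampling enrichment p-value of the observed raw score.

    p = (1 + #{null draws with raw_score >= observed}) / (n_draws + 1),
    using length-matched background fragments as the null.
    """
    rng = np.random.default_rng(seed)
    if observed is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            observed = raw_score(pwm, target_seqs, bg)
    if np.isnan(observed):
        return float("nan")
    lengths = np.array(
        [len(s) if not isinstance(s, str) else len(s) for s in target_seqs]
    )
    null = _fragment_null_scores(pwm, lengths, bg, n_draws, rng)
    return float((1 + np.sum(null >= observed)) / (n_draws + 1))


@dataclass
class MotifScoreSeries:
    """Per (motif, cluster): raw score and enrichment p at each time point."""

    motif_id: str
    cluster: str
    times: np.ndarray
    raw_scores: np.ndarray  # nan where undefined (no sequence at that time)
    p_values: np.ndarray
    retention_p: float = 0.01

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.raw_scores = np.asarray(self.raw_scores, dtype=float)
        self.p_values = np.asarray(self.p_values, dtype=float)

    @property
    def retained(self) -> bool:
        ok = ~np.isnan(self.p_values)
        return bool(ok.any() and (self.p_values[ok] <= self.retention_p).any())

    @property
    def score_range(self) -> float:
        ok = ~np.isnan(self.raw_scores)
        if not ok.any():
            return float("nan")
        return float(self.raw_scores[ok].max() - self.raw_scores[ok].min())


def score_series(
    pwm: PWM,
    seqs_by_time: dict[float, list[str]],
    bg: Background,
    cluster: str = "",
    n_draws: int = 1000,
    seed: int | np.random.Generator = 0,
    retention_p: float = 0.01,
) -> MotifScoreSeries:
    """Raw score and enrichment p per time point for one motif and cluster.

    A time point with no APR sequence gets nan score and p (excluded
    from ranking and from the retention rule).
    """
    rng = np.random.default_rng(seed)
    times = sorted(seqs_by_time)
    raws, ps = [], []
    for t in times:
        seqs = seqs_by_time[t]
        if not seqs:
            raws.append(float("nan"))
            ps.append(float("nan"))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = raw_score(pwm, seqs, bg)
        raws.append(r)
        ps.append(enrichment_p(pwm, seqs, bg, n_draws, rng, observed=r))
    return MotifScoreSeries(pwm.motif_id, cluster, np.array(times), np.array(raws),
                            np.array(ps), retention_p)


RANK_METHODS = ("score_range", "max_score", "score_at_peak", "lag_correlation")


def rank_motifs(
    series: list[MotifScoreSeries],
    method: str = "score_range",
    peak_time: float | None = None,
    lag_r: dict[str, float] | None = None,
) -> list[tuple[MotifScoreSeries, float]]:
    """Order retained series descending by the chosen statistic.

    * score_range: max(score) - min(score) across time points
    * max_score: highest raw score at any time point
    * score_at_peak: raw score at the signal time nearest `peak_time`
      (the time of maximum cluster expression)
    * lag_correlation: |R| at the optimal lag, from `lag_r` keyed by motif_id

    Ties break lexicographically by motif_id.
    """
    if method not in RANK_METHODS:
        raise ValueError(f"unknown ranking method {method!r}; choose from {RANK_METHODS}")
    retained = [s for s in series if s.retained]

    def stat(s: MotifScoreSeries) -> float:
        ok = ~np.isnan(s.raw_scores)
        if not ok.any():
            return float("-inf")
        if method == "score_range":
            return s.score_range
        if method == "max_score":
            return float(s.raw_scores[ok].max())
        if method == "score_at_peak":
            if peak_time is None:
                raise ValueError("score_at_peak ranking requires peak_time")
            i = int(np.argmin(np.abs(s.times[ok] - peak_time)))
            return float(s.raw_scores[ok][i])
        if lag_r is None:
            raise ValueError("lag_correlation ranking requires lag_r")
        return abs(lag_r.get(s.motif_id, float("nan")))

    scored = [(s, stat(s)) for s in retained]
    scored.sort(key=lambda pair: (-pair[1] if not np.isnan(pair[1]) else np.inf,
                                  pair[0].motif_id))
    return scored
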