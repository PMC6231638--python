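"""Local nucleotide alignment with an empirical windowed-shuffle null.

Two modes of local alignment with an integer match/mismatch scheme
(defaults +5/-4, typical for DNA in the FASTA program family):

* ungapped (default) -- the best-scoring contiguous diagonal segment,
  found per diagonal by maximum-sum subarray; appropriate when similarity
  "at the same position" is the question;
* gapped -- Smith-Waterman with affine gaps (a gap of length L costs
  ``gap_open + (L-1) * gap_extend``).

Significance is empirical: the target sequence is shuffled within fixed
windows (default 10 bases, preserving local composition), the alignment is
recomputed for each shuffle, and the add-one estimator
``(1 + #{score >= observed}) / (n_shuffles + 1)`` gives the p-value.  A
Gumbel (extreme-value) fit to the shuffled score sample provides an
extrapolated tail p-value below the empirical resolution, reported
separately and labeled as extrapolated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from ripdecay.records import canonicalize_rna

_ENC = {b: i for i, b in enumerate("ACGU")}


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_ENC[c] for c in seq), dtype=np.int8, count=len(seq))


@dataclass
class AlignmentResult:
    """A local alignment segment; intervals are 1-based inclusive.

    For ungapped alignments ``aligned_length`` equals the span of both
    intervals; for gapped alignments it counts alignment columns including
    gaps.  A score of 0 with ``aligned_length`` 0 means no positive-scoring
    segment exists.
    """

    score: int
    query_interval: tuple[int, int]
    target_interval: tuple[int, int]
    identities: int
    aligned_length: int
    gapped: bool
    query_aligned: str = ""
    target_aligned: str = ""
    empirical_p: Optional[float] = None
    shuffles_used: int = 0

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.identities / self.aligned_length if self.aligned_length else 0.0

    def pretty(self) -> str:
        marks = "".join(
            "|" if a == b and a != "-" else " "
            for a, b in zip(self.query_aligned, self.target_aligned)
        )
        head = (
            f"score={self.score} identities={self.identities}/{self.aligned_length} "
            f"({self.percent_identity:.1f}%) "
            f"query {self.query_interval[0]}-{self.query_interval[1]} "
            f"target {self.target_interval[0]}-{self.target_interval[1]}"
        )
        if self.empirical_p is not None:
            head += f" empirical_p={self.empirical_p:.4g} (n={self.shuffles_used})"
        return "\n".join(
            [head, f"  query  {self.query_aligned}", f"         {marks}",
             f"  target {self.target_aligned}"]
        )


def _ungapped_align(q: str, t: str, match: int, mismatch: int) -> AlignmentResult:
    """Exact best contiguous diagonal segment via Kadane per diagonal.

    Ties are broken by earliest query start, then earliest target start.
    """
    n, m = len(q), len(t)
    best_score = 0
    best = None  # (qstart, tstart, length) 0-based
    for k in range(-(n - 1), m):  # diagonal offset j - i
        i = max(0, -k)
        j = i + k
        cur = 0
        cur_start = (i, j)
        while i < n and j < m:
            s = match if q[i] == t[j] else mismatch
            if cur <= 0:
                cur = s
                cur_start = (i, j)
            else:
                cur += s
            cand = (cur_start[0], cur_start[1], i - cur_start[0] + 1)
            if cur > best_score or (
                cur == best_score
                and best is not None
                and (cand[0], cand[1]) < (best[0], best[1])
            ):
                best_score = cur
                best = cand
            i += 1
            j += 1
    if best is None:
        return AlignmentResult(0, (0, 0), (0, 0), 0, 0, gapped=False)
    qs, ts, length = best
    qa = q[qs:qs + length]
    ta = t[ts:ts + length]
    idents = sum(a == b for a, b in zip(qa, ta))
    return AlignmentResult(
        score=best_score,
        query_interval=(qs + 1, qs + length),
        target_interval=(ts + 1, ts + length),
        identities=idents,
        aligned_length=length,
        gapped=False,
        query_aligned=qa,
        target_aligned=ta,
    )


def _smith_waterman(
    q: str, t: str, match: int, mismatch: int, gap_open: int, gap_extend: int
) -> AlignmentResult:
    """Affine-gap Smith-Waterman (Gotoh) with traceback.

    Ties for the best cell are broken by earliest query end then target
    end, which together with high-road traceback yields a deterministic
    alignment.
    """
    n, m = len(q), len(t)
    NEG = -(10 ** 9)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in query (move along t)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in target
    best_score, best_cell = 0, None
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + gap_open, E[i, j - 1] + gap_extend)
            F[i, j] = max(H[i - 1, j] + gap_open, F[i - 1, j] + gap_extend)
            s = match if q[i - 1] == t[j - 1] else mismatch
            h = max(0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
            H[i, j] = h
            if h > best_score:
                best_score, best_cell = h, (i, j)
    if best_cell is None:
        return AlignmentResult(0, (0, 0), (0, 0), 0, 0, gapped=True)
    qa, ta = [], []
    i, j = best_cell
    state = "H"
    while i > 0 and j > 0 and not (state == "H" and H[i, j] == 0):
        if state == "H":
            s = match if q[i - 1] == t[j - 1] else mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                qa.append(q[i - 1])
                ta.append(t[j - 1])
                i, j = i - 1, j - 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            qa.append("-")
            ta.append(t[j - 1])
            if E[i, j] == H[i, j - 1] + gap_open:
                state = "H"
            j -= 1
        else:
            qa.append(q[i - 1])
            ta.append("-")
            if F[i, j] == H[i - 1, j] + gap_open:
                state = "H"
            i -= 1
    qa.reverse()
    ta.reverse()
    qs = i + 1
    ts = j + 1
    idents = sum(a == b for a, b in zip(qa, ta) if a != "-" and b != "-")
    return AlignmentResult(
        score=int(best_score),
        query_interval=(qs, best_cell[0]),
        target_interval=(ts, best_cell[1]),
        identities=idents,
        aligned_length=len(qa),
        gapped=True,
        query_aligned="".join(qa),
        target_aligned="".join(ta),
    )


def local_align(
    query: str,
    target: str,
    match: int = 5,
    mismatch: int = -4,
    gap_open: int = -12,
    gap_extend: int = -4,
    gapped: bool = False,
) -> AlignmentResult:
    """Optimal local alignment of two nucleotide strings.

    Sequences are U/T-canonicalized.  See the module docstring for the two
    modes; the ungapped mode is the default for element-vs-element
    comparisons.
    """
    if not query or not target:
        raise ValueError("empty sequence")
    if match <= 0:
        raise ValueError("match score must be positive")
    q = canonicalize_rna(query)
    t = canonicalize_rna(target)
    if gapped:
        return _smith_waterman(q, t, match, mismatch, gap_open, gap_extend)
    return _ungapped_align(q, t, match, mismatch)


# ---------------------------------------------------------------------------
# shuffle significance
# ---------------------------------------------------------------------------

def window_shuffle(seq: str, window: int = 10, rng: np.random.Generator | int = 0) -> str:
    """Permute characters uniformly within consecutive fixed-width windows.

    The last window may be shorter and is shuffled as-is.  Length and
    per-window composition are preserved exactly.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    chars = np.array(list(seq))
    for start in range(0, len(chars), window):
        block = chars[start:start + window]
        rng.shuffle(block)
        chars[start:start + window] = block
    return "".join(chars)


def _batch_ungapped_scores(
    q_idx: np.ndarray, targets: np.ndarray, match: int, mismatch: int
) -> np.ndarray:
    """Best ungapped local score of one query against a batch of targets.

    ``targets`` is (B, m) of encoded bases.  Row-scan recurrence of the
    per-diagonal maximum-sum subarray, vectorized over the batch; scores
    are floored at 0 (empty segment).
    """
    B, m = targets.shape
    best = np.zeros(B)
    R = np.zeros((B, m))
    for qi in q_idx:
        s = np.where(targets == qi, match, mismatch).astype(float)
        R[:, 1:] = np.maximum(R[:, :-1], 0.0)[:, : m - 1]
        R[:, 0] = 0.0
        R += s
        np.maximum(best, R.max(axis=1), out=best)
    return best


@dataclass
class ShuffleSignificance:
    observed_score: int
    empirical_p: float
    shuffles_used: int
    gumbel_p_extrapolated: Optional[float]
    shuffled_scores: Optional[np.ndarray] = None


def shuffle_significance(
    query: str,
    target: str,
    n_shuffles: int = 1000,
    window: int = 10,
    match: int = 5,
    mismatch: int = -4,
    gap_open: int = -12,
    gap_extend: int = -4,
    gapped: bool = False,
    rng_seed: int = 0,
    keep_scores: bool = False,
) -> ShuffleSignificance:
    """Empirical alignment significance by windowed target shuffling.

    The target (only) is shuffled ``n_shuffles`` times in windows of
    ``window`` bases; ``empirical_p = (1 + #{shuffled score >= observed})
    / (n_shuffles + 1)``.  A Gumbel fit to the shuffled scores yields an
    extrapolated tail p-value, reported separately.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    observed = local_align(
        query, target, match=match, mismatch=mismatch,
        gap_open=gap_open, gap_extend=gap_extend, gapped=gapped,
    ).score
    q = canonicalize_rna(query)
    t = canonicalize_rna(target)
    rng = np.random.default_rng(rng_seed)

    if gapped:
        scores = np.array(
            [
                _smith_waterman(
                    q, window_shuffle(t, window, rng), match, mismatch, gap_open, gap_extend
                ).score
                for _ in range(n_shuffles)
            ],
            dtype=float,
        )
    else:
        q_idx = _encode(q)
        t_idx = _encode(t)
        m = len(t_idx)
        scores = np.empty(n_shuffles)
        chunk = max(1, min(n_shuffles, 4_000_000 // max(1, len(q) * m)))
        done = 0
        while done < n_shuffles:
            b = min(chunk, n_shuffles - done)
            batch = np.empty((b, m), dtype=np.int8)
            for r in range(b):
                row = t_idx.copy()
                for start in range(0, m, window):
                    rng.shuffle(row[start:start + window])
                batch[r] = row
            scores[done:done + b] = _batch_ungapped_scores(q_idx, batch, match, mismatch)
            done += b

    exceed = int(np.sum(scores >= observed))
    empirical_p = (1 + exceed) / (n_shuffles + 1)
    gumbel_p = None
    if n_shuffles >= 30 and np.ptp(scores) > 0:
        loc, scale = stats.gumbel_r.fit(scores)
        gumbel_p = float(stats.gumbel_r.sf(observed, loc=loc, scale=scale))
    return ShuffleSignificance(
        observed_score=int(observed),
        empirical_p=float(empirical_p),
        shuffles_used=n_shuffles,
        gumbel_p_extrapolated=gumbel_p,
        shuffled_scores=scores if keep_scores else None,
    )


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity of two equal-length sequences, position by position."""
    a = canonicalize_rna(a)
    b = canonicalize_rna(b)
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    if not a:
        raise ValueError("empty sequence")
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)
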