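"""Sequence-derived predictor variables and the enrichment-correlation screen.

Features are computed per transcript over two scopes -- the 3'UTR alone and
the full mRNA: single-nucleotide percentages, combined A+U and G+U content,
overlapping occurrence counts of a configurable oligonucleotide set, an
AU-rich-element-like score, an ARED-like cluster flag, and length.  The
screen then ranks each feature against per-transcript RNP-IP enrichment with
Spearman's rank correlation (average ranks for ties, t-approximation for the
p-value).

The ARE-like score and ARED-like flag are deliberately simple, configurable
surrogates built on AUUUA-pentamer counting with clustering and AU-context
bonuses; they are not a reimplementation of any published scoring program or
database.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ripdecay.records import TranscriptRecord, canonicalize_rna

#: Default oligonucleotide set for the correlation screen: the U-rich
#: trimers/tetramers/pentamers with the strongest observed enrichment
#: association, the published cross-linking consensus pentamers, and the
#: canonical ARE pentamer/hexamer.
DEFAULT_MOTIFS = (
    "UUA", "UUU", "UAA", "GUU", "UUG",
    "GUUA", "UUAA", "UUUU", "UUUA", "GUUU",
    "CGUUA", "GUUAA", "GUUAC", "CGAUA", "UUAAU", "UUGUU",
    "AGUUU", "GUUUG", "UUAGA",
    "AUUUA", "AUUUAA",
)

PENTAMER = "AUUUA"


def extract_utr3(record: TranscriptRecord) -> str:
    """The substring strictly after the CDS end (stop codon is in the CDS)."""
    if record.cds[1] > len(record.sequence):
        raise ValueError("cds end beyond sequence end")
    return record.sequence[record.cds[1]:]


def count_overlapping(seq: str, motif: str) -> int:
    """Occurrences of `motif` in `seq`, counting every start position."""
    if not motif:
        raise ValueError("empty motif")
    count = start = 0
    while True:
        i = seq.find(motif, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


def _find_starts(seq: str, motif: str) -> list[int]:
    out, start = [], 0
    while True:
        i = seq.find(motif, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


@dataclass
class FeatureVector:
    """Composition, motif counts and ARE-like scores for one sequence.

    Percentages are ``None`` (and ``undefined`` True) for empty sequences
    rather than silently zero.
    """

    scope: str
    length: int
    pct_A: Optional[float]
    pct_C: Optional[float]
    pct_G: Optional[float]
    pct_U: Optional[float]
    pct_AU: Optional[float]
    pct_GU: Optional[float]
    motif_counts: dict[str, int] = field(default_factory=dict)
    are_like_score: float = 0.0
    ared_like_flag: bool = False
    undefined: bool = False

    def as_series(self) -> pd.Series:
        d = {
            "scope": self.scope,
            "length": self.length,
            "pct_A": self.pct_A,
            "pct_C": self.pct_C,
            "pct_G": self.pct_G,
            "pct_U": self.pct_U,
            "pct_AU": self.pct_AU,
            "pct_GU": self.pct_GU,
            "are_like_score": self.are_like_score,
            "ared_like_flag": self.ared_like_flag,
        }
        for m, c in self.motif_counts.items():
            d[f"n_{m}"] = c
        return pd.Series(d)


def feature_vector(
    seq: str, motifs: Sequence[str] = DEFAULT_MOTIFS, scope: str = "utr3"
) -> FeatureVector:
    """Compute the full feature vector for one sequence."""
    seq = canonicalize_rna(seq)
    motifs = [canonicalize_rna(m) for m in motifs]
    counts = {m: count_overlapping(seq, m) if seq else 0 for m in motifs}
    n = len(seq)
    if n == 0:
        return FeatureVector(
            scope=scope, length=0, pct_A=None, pct_C=None, pct_G=None,
            pct_U=None, pct_AU=None, pct_GU=None, motif_counts=counts,
            are_like_score=0.0, ared_like_flag=False, undefined=True,
        )
    pa = 100.0 * seq.count("A") / n
    pc = 100.0 * seq.count("C") / n
    pg = 100.0 * seq.count("G") / n
    pu = 100.0 * seq.count("U") / n
    flag, _run = ared_like_flag(seq)
    return FeatureVector(
        scope=scope, length=n, pct_A=pa, pct_C=pc, pct_G=pg, pct_U=pu,
        pct_AU=pa + pu, pct_GU=pg + pu, motif_counts=counts,
        are_like_score=are_like_score(seq), ared_like_flag=flag,
    )


def _au_fraction(seq: str) -> float:
    return (seq.count("A") + seq.count("U")) / len(seq) if seq else 0.0


def are_like_score(
    utr: str,
    cluster_window: int = 15,
    cluster_bonus: float = 0.5,
    context_window: int = 10,
    context_au_min: float = 0.7,
    context_bonus: float = 0.3,
) -> float:
    """AU-rich-element-like score based on AUUUA pentamers and their context.

    Each AUUUA occurrence contributes 1, plus ``cluster_bonus`` if another
    AUUUA starts within ``cluster_window`` bases, plus ``context_bonus`` if
    the flanking sequence (up to ``context_window`` bases on each side,
    pentamer excluded) is at least ``context_au_min`` A/U.  Monotone
    non-decreasing in the number of AUUUA occurrences, 0 without any.
    """
    if min(cluster_window, context_window) < 0 or min(cluster_bonus, context_bonus) < 0:
        raise ValueError("parameters must be non-negative")
    utr = canonicalize_rna(utr)
    starts = _find_starts(utr, PENTAMER)
    score = 0.0
    for p in starts:
        term = 1.0
        if any(q != p and abs(q - p) <= cluster_window for q in starts):
            term += cluster_bonus
        flank = utr[max(0, p - context_window):p] + utr[p + 5:p + 5 + context_window]
        if flank and _au_fraction(flank) >= context_au_min:
            term += context_bonus
        score += term
    return score


def ared_like_flag(
    utr: str,
    min_pentamers: int = 1,
    context_window: int = 13,
    context_au_min: float = 0.6,
) -> tuple[bool, int]:
    """ARE-cluster surrogate flag.

    True iff at least ``min_pentamers`` AUUUA occurrences each sit in an
    AU-rich window (the pentamer plus up to ``context_window`` bases on
    each side, A/U fraction >= ``context_au_min``).  Also returns the
    maximum length of a chain of mutually overlapping AUUUA pentamers.
    """
    utr = canonicalize_rna(utr)
    starts = _find_starts(utr, PENTAMER)
    in_context = 0
    for p in starts:
        window = utr[max(0, p - context_window):p + 5 + context_window]
        if _au_fraction(window) >= context_au_min:
            in_context += 1
    max_run = run = 0
    prev = None
    for p in starts:
        run = run + 1 if prev is not None and p - prev < len(PENTAMER) else 1
        max_run = max(max_run, run)
        prev = p
    return in_context >= min_pentamers, max_run


def feature_table(
    records: Iterable[TranscriptRecord],
    motifs: Sequence[str] = DEFAULT_MOTIFS,
    scopes: Sequence[str] = ("utr3", "full_mrna"),
) -> pd.DataFrame:
    """One row per transcript x scope, columns as in :meth:`FeatureVector.as_series`."""
    rows = []
    for r in records:
        for scope in scopes:
            seq = extract_utr3(r) if scope == "utr3" else r.sequence
            s = feature_vector(seq, motifs, scope=scope)
            row = s.as_series()
            row["transcript_id"] = r.transcript_id
            rows.append(row)
    df = pd.DataFrame(rows)
    return df.set_index(["transcript_id", "scope"])


@dataclass
class CorrelationScreenResult:
    feature: str
    scope: str
    rho: Optional[float]
    p: Optional[float]
    n: int
    undefined: bool = False


def correlation_screen(
    features: pd.DataFrame,
    enrichment: pd.Series,
    scope: str = "utr3",
) -> pd.DataFrame:
    """Spearman correlation of each feature column with enrichment.

    ``features``: numeric columns indexed by transcript id (one scope).
    Constant features are reported with an ``undefined`` flag instead of
    being dropped.  Returns a table (feature, scope, rho, p, n, undefined)
    sorted by rho descending.
    """
    if len(features) != len(enrichment):
        raise ValueError("feature table and enrichment vector differ in length")
    if len(features) < 10:
        raise ValueError("need >= 10 transcripts for the screen")
    enr = enrichment.reindex(features.index)
    if enr.isna().any():
        raise ValueError("enrichment values missing for some transcripts")
    results = []
    for col in features.columns:
        x = pd.to_numeric(features[col], errors="coerce")
        if x.isna().any() or x.nunique() <= 1:
            results.append(
                CorrelationScreenResult(col, scope, None, None, len(x), undefined=True)
            )
            continue
        rho, p = stats.spearmanr(x, enr)
        results.append(CorrelationScreenResult(col, scope, float(rho), float(p), len(x)))
    df = pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "scope": [r.scope for r in results],
            "rho": [r.rho for r in results],
            "p": [r.p for r in results],
            "n": [r.n for r in results],
            "undefined": [r.undefined for r in results],
        }
    )
    return df.sort_values("rho", ascending=False, na_position="last").reset_index(drop=True)


def score_histogram(
    scores: Sequence[float], bin_edges: Sequence[float]
) -> pd.DataFrame:
    """Frequency table over half-open bins with a terminal open bin.

    Bins are [e0,e1), [e1,e2), ..., [e_last, inf); frequencies sum to 1.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) == 0:
        raise ValueError("empty score list")
    edges = list(bin_edges) + [np.inf]
    counts, _ = np.histogram(scores, bins=edges)
    labels = [
        f"[{edges[i]:g},{edges[i+1]:g})" if np.isfinite(edges[i + 1]) else f">={edges[i]:g}"
        for i in range(len(edges) - 1)
    ]
    return pd.DataFrame(
        {"bin": labels, "count": counts, "frequency": counts / counts.sum()}
    )
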