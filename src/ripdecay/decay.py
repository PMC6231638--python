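"""mRNA half-life estimation and instability-element calling.

Transcription-shutoff time courses (tet-off or actinomycin D) are modelled as
first-order decay: ``abundance(t) = A0 * exp(-lambda * t)``.  Half-lives are
obtained by ordinary least squares of ln(abundance) on time,
``t_half = ln 2 / (-slope)``.  Instability elements are mapped by comparing
per-pool decay slopes of deletion / linker-scanning constructs against the
wild-type construct.

Coordinates are 1-based inclusive on the parent UTR in all public interfaces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

LN2 = math.log(2.0)

#: 15-base linker used for scanning mutagenesis (carries a unique MluI site).
LINKER15 = "AGCAACGCGTAGCTC"

#: BglII restriction-site marker left in place of larger deletions.
DELETION_MARKER = "AGATCT"


# ---------------------------------------------------------------------------
# construct panels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Edit:
    """A single edit on the parent UTR.

    kind: ``delete`` (interval removed, BglII marker left),
    ``linker_scan`` (15-base interval replaced by :data:`LINKER15`).
    """

    kind: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in ("delete", "linker_scan"):
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid edit interval {self.start}-{self.end}")
        if self.kind == "linker_scan" and self.end - self.start + 1 != len(LINKER15):
            raise ValueError(
                f"linker_scan interval {self.start}-{self.end} must span "
                f"{len(LINKER15)} bases"
            )

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class Construct:
    construct_id: str
    parent_utr_id: str
    edits: list[Edit] = field(default_factory=list)

    def removes(self, interval: tuple[int, int]) -> bool:
        """True if any edit overlaps the given 1-based inclusive interval."""
        s, e = interval
        return any(not (ed.end < s or ed.start > e) for ed in self.edits)


@dataclass
class ConstructPanel:
    parent_utr_id: str
    parent_length: int
    constructs: list[Construct]

    def __post_init__(self) -> None:
        for c in self.constructs:
            for ed in c.edits:
                if ed.end > self.parent_length:
                    raise ValueError(
                        f"{c.construct_id}: edit {ed.start}-{ed.end} outside "
                        f"parent UTR of length {self.parent_length}"
                    )

    def __iter__(self):
        return iter(self.constructs)

    def get(self, construct_id: str) -> Construct:
        for c in self.constructs:
            if c.construct_id == construct_id:
                return c
        raise KeyError(construct_id)

    @property
    def wildtype(self) -> Construct:
        """The construct without edits (there must be exactly one)."""
        wt = [c for c in self.constructs if not c.edits]
        if len(wt) != 1:
            raise ValueError(f"panel must contain exactly one edit-free construct, found {len(wt)}")
        return wt[0]


def make_scanning_panel(
    parent_utr_id: str,
    parent_length: int,
    scan_start: int,
    n_scans: int,
    window: int = 15,
    wildtype_id: str = "wt",
) -> ConstructPanel:
    """Build a wild-type plus consecutive linker-scanning mutant panel.

    Mutant *i* replaces the 1-based interval
    ``[scan_start + i*window, scan_start + (i+1)*window - 1]`` by the linker.
    """
    constructs = [Construct(wildtype_id, parent_utr_id, [])]
    for i in range(n_scans):
        s = scan_start + i * window
        e = s + window - 1
        constructs.append(
            Construct(f"scan_{s}_{e}", parent_utr_id, [Edit("linker_scan", s, e)])
        )
    return ConstructPanel(parent_utr_id, parent_length, constructs)


# ---------------------------------------------------------------------------
# decay series
# ---------------------------------------------------------------------------

@dataclass
class DecaySeries:
    """One shutoff time course for one construct in one cell pool.

    ``points`` is a sequence of (time_min, abundance) with abundance on a
    positive, reference-normalized scale (100 = level at the first
    timepoint after normalization).
    """

    construct_id: str
    pool_id: str
    points: list[tuple[float, float]]

    def __post_init__(self) -> None:
        pts = [(float(t), float(a)) for t, a in self.points]
        if any(t < 0 for t, _ in pts):
            raise ValueError("negative time in decay series")
        if len({t for t, _ in pts}) < 2:
            raise ValueError("decay series needs >= 2 distinct timepoints")
        self.points = pts

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.points])

    @property
    def abundances(self) -> np.ndarray:
        return np.array([a for _, a in self.points])


def normalize_series(
    construct_id: str,
    pool_id: str,
    times: Sequence[float],
    target: Sequence[float],
    reference: Sequence[float],
) -> DecaySeries:
    """Reference-normalize a raw qPCR time course.

    abundance = target/reference, rescaled so the first timepoint is 100%;
    the clock is shifted so the first timepoint becomes t = 0 (the paper's
    convention of treating the 8-min point as the start of decay).
    """
    t = np.asarray(times, dtype=float)
    tg = np.asarray(target, dtype=float)
    rf = np.asarray(reference, dtype=float)
    if len(t) == 0:
        raise ValueError("missing timepoints")
    if np.any(rf <= 0):
        raise ValueError("reference quantities must be positive")
    order = np.argsort(t)
    t, tg, rf = t[order], tg[order], rf[order]
    ratio = tg / rf
    if ratio[0] <= 0:
        raise ValueError("target quantity at the first timepoint must be positive")
    abundance = 100.0 * ratio / ratio[0]
    return DecaySeries(construct_id, pool_id, list(zip(t - t[0], abundance)))


# ---------------------------------------------------------------------------
# half-life fitting
# ---------------------------------------------------------------------------

def _ln_slope(times: np.ndarray, abundances: np.ndarray) -> tuple[float, float, int]:
    """OLS slope of ln(abundance) on time; returns (slope, stderr, n)."""
    if np.any(abundances <= 0):
        raise ValueError("non-positive abundance; cannot take log")
    if len(np.unique(times)) < 2:
        raise ValueError("all points at one timepoint")
    res = stats.linregress(times, np.log(abundances))
    return float(res.slope), float(res.stderr), len(times)


def _slope_to_thalf(slope: float) -> float:
    return math.inf if slope >= 0 else LN2 / (-slope)


@dataclass
class HalfLifeResults:
    """Fitted half-life for one construct.

    ``t_half`` is in minutes and may be ``inf`` ("stable") when the fitted
    slope is non-negative.  For the pooled method the 95% CI is the
    Student-t CI on the regression slope mapped through s -> ln2/(-s); if
    the CI crosses zero slope the upper bound is infinite.  For the
    per-pool method the bounds are mean -/+ SD of per-pool half-lives,
    matching the reporting convention "average +/- SD".
    """

    construct_id: str
    t_half: float
    ci95_low: float
    ci95_high: float
    slope: float
    method: str
    n_pools: int
    n_points: int
    stable: bool
    pool_slopes: Optional[np.ndarray] = None
    pool_halflives: Optional[np.ndarray] = None

    def summary(self) -> str:
        th = "stable" if self.stable else f"{self.t_half:.1f} min"
        lo = "inf" if math.isinf(self.ci95_low) else f"{self.ci95_low:.1f}"
        hi = "inf" if math.isinf(self.ci95_high) else f"{self.ci95_high:.1f}"
        return (
            f"Half-life fit: {self.construct_id}\n"
            f"  method      : {self.method} ({self.n_pools} pools, {self.n_points} points)\n"
            f"  slope       : {self.slope:.3e} /min (natural log scale)\n"
            f"  t1/2        : {th}  [95% {lo}, {hi}]\n"
        )


class HalfLifeModel:
    """First-order decay model for one construct's shutoff time courses.

    Parameters
    ----------
    series
        One or more :class:`DecaySeries` for the same construct (one per
        independently transfected cell pool).
    """

    def __init__(self, series: Sequence[DecaySeries]):
        series = list(series)
        if not series:
            raise ValueError("no decay series supplied")
        ids = {s.construct_id for s in series}
        if len(ids) > 1:
            raise ValueError(f"series mix constructs: {sorted(ids)}")
        self.construct_id = series[0].construct_id
        self.series = series

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, construct_id: str) -> "HalfLifeModel":
        """Build from a long table (construct_id, pool_id, time_min,
        target_qty, reference_qty), normalizing each pool's course."""
        sub = df[df["construct_id"] == construct_id]
        if sub.empty:
            raise ValueError(f"no rows for construct {construct_id!r}")
        series = [
            normalize_series(
                construct_id, str(pool), g["time_min"], g["target_qty"], g["reference_qty"]
            )
            for pool, g in sub.groupby("pool_id")
        ]
        return cls(series)

    def fit(self, method: str = "pooled") -> HalfLifeResults:
        if method not in ("pooled", "per_pool"):
            raise ValueError(f"unknown method {method!r}")
        n_pools = len(self.series)
        all_t = np.concatenate([s.times for s in self.series])
        all_a = np.concatenate([s.abundances for s in self.series])
        n_points = len(all_t)

        pool_fits = [_ln_slope(s.times, s.abundances) for s in self.series]
        pool_slopes = np.array([f[0] for f in pool_fits])
        pool_halflives = np.array([_slope_to_thalf(s) for s in pool_slopes])

        if method == "pooled":
            slope, stderr, n = _ln_slope(all_t, all_a)
            t_half = _slope_to_thalf(slope)
            df_resid = n - 2
            tcrit = stats.t.ppf(0.975, df_resid) if df_resid > 0 else math.inf
            s_lo = slope - tcrit * stderr  # most negative slope -> fastest decay
            s_hi = slope + tcrit * stderr
            ci_low = _slope_to_thalf(s_lo) if s_lo < 0 else math.inf
            ci_high = _slope_to_thalf(s_hi)  # inf when s_hi >= 0
            if math.isinf(t_half):
                ci_low, ci_high = math.inf, math.inf
        else:
            slope = float(np.mean(pool_slopes))
            t_half = float(np.mean(pool_halflives))
            sd = float(np.std(pool_halflives, ddof=1)) if n_pools > 1 else 0.0
            if math.isinf(t_half):
                ci_low, ci_high = math.inf, math.inf
            else:
                ci_low, ci_high = t_half - sd, t_half + sd

        return HalfLifeResults(
            construct_id=self.construct_id,
            t_half=t_half,
            ci95_low=ci_low,
            ci95_high=ci_high,
            slope=slope,
            method=method,
            n_pools=n_pools,
            n_points=n_points,
            stable=slope >= 0,
            pool_slopes=pool_slopes,
            pool_halflives=pool_halflives,
        )


def fit_halflife(series: Sequence[DecaySeries] | DecaySeries, method: str = "pooled") -> HalfLifeResults:
    """Convenience wrapper: fit a half-life from one or more decay series."""
    if isinstance(series, DecaySeries):
        series = [series]
    return HalfLifeModel(series).fit(method=method)


# ---------------------------------------------------------------------------
# element calling
# ---------------------------------------------------------------------------

@dataclass
class ElementCall:
    """Verdict for one edited interval (or a merged run of adjacent ones)."""

    interval: tuple[int, int]
    construct_ids: list[str]
    wildtype_t_half: float
    mutant_t_half: float
    delta: float
    p: float
    verdict: str  # "instability_element" | "no_effect"


def _per_pool_slopes(series: Sequence[DecaySeries]) -> np.ndarray:
    if len(series) < 2:
        raise ValueError(
            "element calling needs >= 2 independent cell pools per construct"
        )
    return np.array([_ln_slope(s.times, s.abundances)[0] for s in series])


def call_elements(
    wildtype: Sequence[DecaySeries],
    mutants: Mapping[str, Sequence[DecaySeries]],
    panel: ConstructPanel,
    alpha: float = 0.05,
    merge_adjacent: bool = True,
    stat_method: str = "ttest",
) -> list[ElementCall]:
    """Call instability elements from a scanning/deletion construct panel.

    For each mutant construct, per-pool ln-decay slopes are compared to the
    wild-type slopes with a two-sample two-tailed t-test (``stat_method=
    "ttest"``, the default) or, alternatively, by requiring the pooled-fit
    95% confidence intervals of the two slopes to be disjoint
    (``stat_method="ci_overlap"``; the reported p is then 0 or 1).  A
    construct's edited interval is called an instability element iff its
    half-life exceeds the wild-type's and the test is significant.
    Adjacent significant linker-scan intervals are merged into a single
    element.
    """
    if stat_method not in ("ttest", "ci_overlap"):
        raise ValueError(f"unknown stat_method {stat_method!r}")
    wt_slopes = _per_pool_slopes(wildtype)
    wt_fit = fit_halflife(list(wildtype))
    wt_thalf = wt_fit.t_half

    raw_calls: list[ElementCall] = []
    for cid, series in mutants.items():
        construct = panel.get(cid)
        if not construct.edits:
            raise ValueError(f"{cid}: mutant construct has no edits")
        mu_slopes = _per_pool_slopes(series)
        mu_fit = fit_halflife(list(series))
        mu_thalf = mu_fit.t_half
        if stat_method == "ci_overlap":
            disjoint = mu_fit.ci95_low > wt_fit.ci95_high or mu_fit.ci95_high < wt_fit.ci95_low
            p = 0.0 if disjoint else 1.0
        elif np.var(mu_slopes) == 0 and np.var(wt_slopes) == 0:
            # degenerate zero-variance groups: t is 0/0
            p = 1.0 if mu_slopes.mean() == wt_slopes.mean() else 0.0
        else:
            _, p = stats.ttest_ind(mu_slopes, wt_slopes, equal_var=True)
        # a construct may carry several edits; the called interval spans them
        start = min(ed.start for ed in construct.edits)
        end = max(ed.end for ed in construct.edits)
        stabilized = mu_thalf > wt_thalf
        verdict = "instability_element" if (stabilized and p < alpha) else "no_effect"
        raw_calls.append(
            ElementCall(
                interval=(start, end),
                construct_ids=[cid],
                wildtype_t_half=wt_thalf,
                mutant_t_half=mu_thalf,
                delta=mu_thalf - wt_thalf,
                p=float(p),
                verdict=verdict,
            )
        )

    raw_calls.sort(key=lambda c: c.interval)
    if not merge_adjacent:
        return raw_calls

    merged: list[ElementCall] = []
    for call in raw_calls:
        if (
            call.verdict == "instability_element"
            and merged
            and merged[-1].verdict == "instability_element"
            and call.interval[0] <= merged[-1].interval[1] + 1
        ):
            prev = merged[-1]
            members = prev.construct_ids + call.construct_ids
            mu = float(np.mean([prev.mutant_t_half, call.mutant_t_half]))
            merged[-1] = ElementCall(
                interval=(prev.interval[0], max(prev.interval[1], call.interval[1])),
                construct_ids=members,
                wildtype_t_half=prev.wildtype_t_half,
                mutant_t_half=mu,
                delta=mu - prev.wildtype_t_half,
                p=max(prev.p, call.p),  # conservative: worst member p
                verdict="instability_element",
            )
        else:
            merged.append(call)
    return merged


def element_spacing(call_a, call_b) -> int:
    """Number of intervening bases between two non-overlapping elements.

    Accepts :class:`ElementCall` objects or plain 1-based inclusive
    ``(start, end)`` tuples.  For inclusive coordinates the count of bases
    strictly between the elements is ``start(later) - end(earlier) - 1``.
    """
    a = call_a.interval if hasattr(call_a, "interval") else tuple(call_a)
    b = call_b.interval if hasattr(call_b, "interval") else tuple(call_b)
    first, second = sorted([a, b])
    if second[0] <= first[1]:
        raise ValueError(f"intervals {a} and {b} overlap")
    return second[0] - first[1] - 1


def halflife_table(results: Iterable[HalfLifeResults]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "construct_id": [r.construct_id for r in results],
            "t_half_min": [r.t_half for r in results],
            "ci95_low": [r.ci95_low for r in results],
            "ci95_high": [r.ci95_high for r in results],
            "slope_per_min": [r.slope for r in results],
            "method": [r.method for r in results],
            "n_pools": [r.n_pools for r in results],
            "n_points": [r.n_points for r in results],
            "stable": [r.stable for r in results],
        }
    )


def element_table(calls: Iterable[ElementCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "start": [c.interval[0] for c in calls],
            "end": [c.interval[1] for c in calls],
            "construct_ids": [",".join(c.construct_ids) for c in calls],
            "wildtype_t_half": [c.wildtype_t_half for c in calls],
            "mutant_t_half": [c.mutant_t_half for c in calls],
            "delta_min": [c.delta for c in calls],
            "p": [c.p for c in calls],
            "verdict": [c.verdict for c in calls],
        }
    )
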