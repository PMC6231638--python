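"""Fractionated RNP-IP qPCR: percent bound and relative enrichment.

An immunoprecipitation splits the lysate into a bead-bound "pellet" and a
non-bound "supernatant"; an aliquot taken before the IP is the "input".
For each mRNA species, total = supernatant + pellet, recovery = total/input
(a QC quantity, typically 0.5-0.8), and percent bound = pellet/total.  The
relative enrichment of the reporter (target) mRNA is its percent bound
divided by that of a non-binding reference mRNA (e.g. GAPDH).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RipMeasurement:
    """One RNP-IP experiment's qPCR quantities for target and reference mRNA.

    Raw quantities are on a linear scale (standard-curve processed).  The
    derived fields are ``None`` until :func:`compute_binding` fills them.
    """

    experiment_id: str
    construct_id: str
    target_input: float
    target_supernatant: float
    target_pellet: float
    reference_input: float
    reference_supernatant: float
    reference_pellet: float
    # derived
    target_total: Optional[float] = None
    reference_total: Optional[float] = None
    target_recovery: Optional[float] = None
    reference_recovery: Optional[float] = None
    target_pct_bound: Optional[float] = None
    reference_pct_bound: Optional[float] = None
    relative_enrichment: Optional[float] = None
    recovery_qc_flag: bool = False


def compute_binding(
    m: RipMeasurement, recovery_qc: tuple[float, float] = (0.5, 0.8)
) -> RipMeasurement:
    """Fill the derived binding fields of a measurement.

    Enrichment uses Total (= supernatant + pellet), not Input, as the
    denominator; Input serves only for the recovery QC.  A recovery outside
    ``recovery_qc`` sets ``recovery_qc_flag`` (a warning, not an error).
    """
    for name in ("target_input", "reference_input"):
        if getattr(m, name) <= 0:
            raise ValueError(f"{name} must be positive")
    for name in (
        "target_supernatant",
        "reference_supernatant",
        "target_pellet",
        "reference_pellet",
    ):
        if getattr(m, name) < 0:
            raise ValueError(f"{name} must be non-negative")

    t_total = m.target_supernatant + m.target_pellet
    r_total = m.reference_supernatant + m.reference_pellet
    if t_total <= 0 or r_total <= 0:
        raise ValueError("total (supernatant+pellet) must be positive")
    t_rec = t_total / m.target_input
    r_rec = r_total / m.reference_input
    t_pct = m.target_pellet / t_total
    r_pct = m.reference_pellet / r_total
    enr = t_pct / r_pct if r_pct > 0 else (0.0 if t_pct == 0 else float("inf"))
    lo, hi = recovery_qc
    flag = not (lo <= t_rec <= hi and lo <= r_rec <= hi)
    return replace(
        m,
        target_total=t_total,
        reference_total=r_total,
        target_recovery=t_rec,
        reference_recovery=r_rec,
        target_pct_bound=t_pct,
        reference_pct_bound=r_pct,
        relative_enrichment=enr,
        recovery_qc_flag=flag,
    )


def compare_enrichment(
    test_group: Sequence[float],
    reference_group: Sequence[float],
    equal_var: bool = True,
) -> float:
    """Two-tailed t-test p for relative enrichments vs the empty-vector group.

    The default is the homoscedastic (pooled-variance) t-test; pass
    ``equal_var=False`` for Welch's test.
    """
    if len(test_group) < 2 or len(reference_group) < 2:
        raise ValueError("each group needs n >= 2")
    a = np.asarray(test_group, dtype=float)
    b = np.asarray(reference_group, dtype=float)
    if np.var(a) == 0 and np.var(b) == 0:
        # degenerate: no within-group variance; t is 0/0
        return 1.0 if a.mean() == b.mean() else 0.0
    _, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(p)


@dataclass
class BindingProfile:
    """Per-base enrichment profile over a parent UTR (1-based positions)."""

    start: int
    end: int
    values: np.ndarray  # length end - start + 1; NaN where uncovered
    peaks: list[tuple[int, int]]

    def value_at(self, pos: int) -> float:
        return float(self.values[pos - self.start])


def binding_profile(
    fragments: Mapping[str, tuple[tuple[int, int], float]],
    threshold: Optional[float] = None,
    aggregate: str = "max",
) -> BindingProfile:
    """Project fragment enrichments onto per-base values.

    Each fragment maps construct_id -> ((start, end), mean relative
    enrichment).  The per-base value is the maximum enrichment among
    fragments covering that base (conservative localization; ``aggregate=
    "mean"`` averages instead).  Peaks are maximal runs of covered bases at
    or above ``threshold``.
    """
    if not fragments:
        raise ValueError("empty fragment set")
    if aggregate not in ("max", "mean"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    start = min(iv[0] for iv, _ in fragments.values())
    end = max(iv[1] for iv, _ in fragments.values())
    n = end - start + 1
    if aggregate == "max":
        values = np.full(n, -np.inf)
        for (s, e), enr in fragments.values():
            lo, hi = s - start, e - start + 1
            values[lo:hi] = np.maximum(values[lo:hi], enr)
        values[np.isinf(values)] = np.nan
    else:
        total = np.zeros(n)
        cover = np.zeros(n)
        for (s, e), enr in fragments.values():
            lo, hi = s - start, e - start + 1
            total[lo:hi] += enr
            cover[lo:hi] += 1
        with np.errstate(invalid="ignore"):
            values = np.where(cover > 0, total / np.maximum(cover, 1), np.nan)

    peaks: list[tuple[int, int]] = []
    if threshold is not None:
        above = np.nan_to_num(values, nan=-np.inf) >= threshold
        i = 0
        while i < n:
            if above[i]:
                j = i
                while j + 1 < n and above[j + 1]:
                    j += 1
                peaks.append((start + i, start + j))
                i = j + 1
            else:
                i += 1
    return BindingProfile(start=start, end=end, values=values, peaks=peaks)


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def measurements_from_table(df: pd.DataFrame) -> list[RipMeasurement]:
    """Parse a long table (experiment_id, construct_id, fraction, species,
    quantity) into measurements; fraction in {input, supernatant, pellet},
    species in {target, reference}."""
    required = {"experiment_id", "construct_id", "fraction", "species", "quantity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"RNP-IP table missing columns: {sorted(missing)}")
    out = []
    for (eid, cid), g in df.groupby(["experiment_id", "construct_id"], sort=False):
        qty = {}
        for _, row in g.iterrows():
            fr, sp = str(row["fraction"]), str(row["species"])
            if fr not in ("input", "supernatant", "pellet"):
                raise ValueError(f"unknown fraction {fr!r}")
            if sp not in ("target", "reference"):
                raise ValueError(f"unknown species {sp!r}")
            qty[f"{sp}_{fr}"] = float(row["quantity"])
        missing_q = {
            f"{sp}_{fr}"
            for sp in ("target", "reference")
            for fr in ("input", "supernatant", "pellet")
        } - set(qty)
        if missing_q:
            raise ValueError(f"{eid}/{cid}: missing quantities {sorted(missing_q)}")
        out.append(RipMeasurement(experiment_id=str(eid), construct_id=str(cid), **qty))
    return out


def binding_table(measurements: Sequence[RipMeasurement]) -> pd.DataFrame:
    derived = [compute_binding(m) if m.relative_enrichment is None else m for m in measurements]
    return pd.DataFrame(
        {
            "experiment_id": [m.experiment_id for m in derived],
            "construct_id": [m.construct_id for m in derived],
            "target_recovery": [m.target_recovery for m in derived],
            "reference_recovery": [m.reference_recovery for m in derived],
            "target_pct_bound": [m.target_pct_bound for m in derived],
            "reference_pct_bound": [m.reference_pct_bound for m in derived],
            "relative_enrichment": [m.relative_enrichment for m in derived],
            "recovery_qc_flag": [m.recovery_qc_flag for m in derived],
        }
    )
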