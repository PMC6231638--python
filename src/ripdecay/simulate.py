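"""Seeded generators emulating every raw input of the pipeline.

The simulations carry their planted ground truth alongside the data so that
recovery tests can score the downstream callers:

* :func:`generate_transcripts` -- random transcripts with U-rich binding
  motifs planted into a fraction of 3'UTRs;
* :func:`simulate_rip_intensities` -- replicate IP+/IP-/total intensity
  tables with a non-selective, abundance-proportional background-adsorption
  component and log-normal noise;
* :func:`simulate_decay_panel` -- first-order transcription-shutoff time
  courses for a deletion/linker-scanning construct panel under an
  additive-rate element model;
* :func:`simulate_rip_qpcr` -- fractionated RNP-IP qPCR quantities.

All noise is multiplicative log-normal (qPCR and array intensities are
ratio-scale quantities); a coefficient of variation ``cv`` parameterizes
sigma via ``sigma^2 = ln(1 + cv^2)``, and factors are mean-one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ripdecay.records import TranscriptRecord, canonicalize_rna
from ripdecay.decay import ConstructPanel, DecaySeries
from ripdecay.ripqpcr import RipMeasurement

__all__ = [
    "SimulationConfig",
    "RipIntensitySim",
    "generate_transcripts",
    "simulate_rip_intensities",
    "simulate_decay_panel",
    "simulate_rip_qpcr",
    "lognormal_factors",
]


def lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative log-normal noise factors with the given CV."""
    if cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic RNP-IP universe.

    Defaults emulate the screen this pipeline is built for: a transcript
    universe with AU-biased composition (gc_content 0.4), 3'UTRs averaging
    ~1.7 kb, a small planted-target fraction bound through three copies of a
    short U-rich motif, and a weak non-selective background capture that
    mirrors total mRNA composition.
    """

    n_transcripts: int = 1000
    utr_length_range: tuple[int, int] = (500, 3000)
    gc_content: float = 0.4
    planted_fraction: float = 0.05
    motif: str = "UUUAA"
    motif_copies: int = 3
    binding_gain_per_copy: float = 1.6
    background_capture: float = 0.05
    noise_cv: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        self.motif = canonicalize_rna(self.motif)
        for name in ("gc_content", "planted_fraction", "background_capture"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_transcripts < 1 or self.motif_copies < 1:
            raise ValueError("counts must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        lo, hi = self.utr_length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid utr_length_range {self.utr_length_range}")
        if len(self.motif) * self.motif_copies > lo:
            raise ValueError(
                f"{self.motif_copies} copies of motif {self.motif!r} cannot fit "
                f"in the minimum UTR length {lo}"
            )

    def as_dict(self) -> dict:
        d = asdict(self)
        d["utr_length_range"] = list(self.utr_length_range)
        return d


_BASES = np.array(list("ACGU"))


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def _plant_motif(
    rng: np.random.Generator, utr: str, motif: str, copies: int, max_tries: int = 1000
) -> str:
    """Overwrite `copies` non-overlapping positions of `utr` with `motif`.

    Replacement (not insertion) keeps UTR lengths fixed; non-overlap is
    enforced by rejection sampling.
    """
    k = len(motif)
    n = len(utr) - k
    for _ in range(max_tries):
        starts = np.sort(rng.integers(0, n + 1, size=copies))
        if copies == 1 or np.all(np.diff(starts) >= k):
            chars = list(utr)
            for s in starts:
                chars[s : s + k] = motif
            return "".join(chars)
    raise RuntimeError("could not place non-overlapping motif copies")


def generate_transcripts(config: SimulationConfig) -> list[TranscriptRecord]:
    """Generate a reproducible transcript universe with planted targets.

    Exactly ``round(n_transcripts * planted_fraction)`` records carry
    ``motif_copies`` non-overlapping copies of the motif written into their
    3'UTR; the rest contain the motif only by chance.
    """
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_transcripts
    n_planted = round(n * config.planted_fraction)
    planted = np.zeros(n, dtype=bool)
    planted[rng.choice(n, size=n_planted, replace=False)] = True

    records = []
    for i in range(n):
        utr5 = _random_seq(rng, 30, config.gc_content)
        n_codons = int(rng.integers(100, 500))
        cds = _random_seq(rng, 3 * n_codons, config.gc_content)
        utr_len = int(rng.integers(config.utr_length_range[0], config.utr_length_range[1] + 1))
        utr3 = _random_seq(rng, utr_len, config.gc_content)
        if planted[i]:
            utr3 = _plant_motif(rng, utr3, config.motif, config.motif_copies)
        records.append(
            TranscriptRecord(
                transcript_id=f"TX{i:05d}",
                gene_symbol=f"Gene{i:05d}",
                sequence=utr5 + cds + utr3,
                cds=(len(utr5) + 1, len(utr5) + len(cds)),
                is_planted_target=bool(planted[i]),
                planted_motif=config.motif if planted[i] else None,
            )
        )
    return records


@dataclass
class RipIntensitySim:
    """Simulated intensity table plus its design and planted truth."""

    intensities: pd.DataFrame  # transcripts x samples, positive reals
    design: pd.DataFrame  # sample_id, condition, replicate
    truth: pd.DataFrame  # transcript_id, abundance, true_enrichment, is_planted_target


def simulate_rip_intensities(
    records: Sequence[TranscriptRecord],
    config: SimulationConfig,
    n_reps_ip_plus: int = 2,
    n_reps_ip_minus: int = 2,
    n_reps_total: int = 1,
    abundances: Optional[np.ndarray] = None,
) -> RipIntensitySim:
    """Simulate replicate IP+/IP-/total intensities.

    The anti-tag beads adsorb a non-selective background proportional to
    each transcript's cellular abundance (composition matching total mRNA);
    planted targets are additionally captured with a multiplicative gain of
    ``binding_gain_per_copy`` per planted motif copy.  Per-sample, per-
    transcript noise is mean-one log-normal with CV ``noise_cv``.
    """
    if not records:
        raise ValueError("no transcript records")
    if n_reps_ip_plus < 2 or n_reps_ip_minus < 2:
        raise ValueError("need >= 2 replicates in IP+ and IP-")
    if n_reps_total < 1:
        raise ValueError("need >= 1 total-mRNA sample")
    rng = np.random.default_rng([config.seed, 1])
    n = len(records)
    if abundances is None:
        abundances = rng.lognormal(mean=math.log(1000.0), sigma=1.0, size=n)
    else:
        abundances = np.asarray(abundances, dtype=float)
        if np.any(abundances <= 0):
            raise ValueError("abundances must be positive")

    copies = np.array(
        [config.motif_copies if r.is_planted_target else 0 for r in records]
    )
    gain = config.binding_gain_per_copy ** copies

    samples: dict[str, np.ndarray] = {}
    design_rows = []
    for cond, nrep, expected in (
        ("ip_plus", n_reps_ip_plus, abundances * config.background_capture * gain),
        ("ip_minus", n_reps_ip_minus, abundances * config.background_capture),
        ("total", n_reps_total, abundances),
    ):
        for rep in range(1, nrep + 1):
            sid = f"{cond}_{rep}"
            samples[sid] = expected * lognormal_factors(rng, config.noise_cv, n)
            design_rows.append({"sample_id": sid, "condition": cond, "replicate": rep})

    ids = [r.transcript_id for r in records]
    return RipIntensitySim(
        intensities=pd.DataFrame(samples, index=pd.Index(ids, name="transcript_id")),
        design=pd.DataFrame(design_rows),
        truth=pd.DataFrame(
            {
                "transcript_id": ids,
                "abundance": abundances,
                "true_enrichment": gain,
                "is_planted_target": [r.is_planted_target for r in records],
            }
        ).set_index("transcript_id"),
    )


def simulate_decay_panel(
    stable_halflife: float,
    elements: Sequence[tuple[tuple[int, int], float]],
    panel: ConstructPanel,
    timepoints: Sequence[float],
    n_pools: int = 3,
    noise_cv: float = 0.1,
    seed: int = 0,
) -> tuple[list[DecaySeries], pd.DataFrame]:
    """Simulate shutoff time courses for a construct panel.

    Each instability element contributes additively to the decay rate; a
    construct's rate is ``lambda0 + sum(contribution of elements whose
    interval it does NOT edit away)`` with ``lambda0 = ln2 /
    stable_halflife`` (the empty-vector reporter's half-life).  Abundance
    follows ``100 * exp(-lambda * (t - t0))`` with per-point, per-pool
    mean-one log-normal noise; t0 is the first timepoint.

    Returns the series and a truth table (construct_id, decay_rate, t_half).
    """
    if stable_halflife <= 0:
        raise ValueError("stable_halflife must be positive")
    if len(timepoints) == 0:
        raise ValueError("empty timepoints")
    t = np.sort(np.asarray(timepoints, dtype=float))
    if np.any(t < 0):
        raise ValueError("negative times")
    for (s, e), contrib in elements:
        if contrib < 0:
            raise ValueError("element rate contributions must be >= 0")
        if s < 1 or e < s or e > panel.parent_length:
            raise ValueError(f"element interval {(s, e)} outside parent UTR")

    rng = np.random.default_rng([seed, 2])
    lam0 = math.log(2.0) / stable_halflife
    series: list[DecaySeries] = []
    truth_rows = []
    for construct in panel:
        lam = lam0 + sum(
            contrib for iv, contrib in elements if not construct.removes(iv)
        )
        expected = 100.0 * np.exp(-lam * (t - t[0]))
        for pool in range(1, n_pools + 1):
            noisy = expected * lognormal_factors(rng, noise_cv, len(t))
            series.append(
                DecaySeries(construct.construct_id, f"pool{pool}", list(zip(t, noisy)))
            )
        truth_rows.append(
            {
                "construct_id": construct.construct_id,
                "decay_rate": lam,
                "t_half": math.log(2.0) / lam,
            }
        )
    return series, pd.DataFrame(truth_rows).set_index("construct_id")


def simulate_rip_qpcr(
    true_bound_fraction_target: float,
    true_bound_fraction_reference: float,
    recovery: float = 0.65,
    noise_cv: float = 0.15,
    n: int = 5,
    seed: int = 0,
    construct_id: str = "construct",
) -> list[RipMeasurement]:
    """Simulate replicate fractionated RNP-IP qPCR measurements.

    For each species, pellet = input * recovery * bound_fraction * noise and
    supernatant = input * recovery * (1 - bound_fraction) * noise, so that
    pellet + supernatant = input * recovery exactly when ``noise_cv`` is 0.
    """
    for name, v in (
        ("true_bound_fraction_target", true_bound_fraction_target),
        ("true_bound_fraction_reference", true_bound_fraction_reference),
    ):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    if not (0.0 < recovery <= 1.0):
        raise ValueError("recovery must be in (0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng([seed, 3])
    input_qty = 100.0
    out = []
    for i in range(1, n + 1):
        f = lognormal_factors(rng, noise_cv, 4)
        out.append(
            RipMeasurement(
                experiment_id=f"exp{i}",
                construct_id=construct_id,
                target_input=input_qty,
                target_pellet=input_qty * recovery * true_bound_fraction_target * f[0],
                target_supernatant=input_qty
                * recovery
                * (1 - true_bound_fraction_target)
                * f[1],
                reference_input=input_qty,
                reference_pellet=input_qty
                * recovery
                * true_bound_fraction_reference
                * f[2],
                reference_supernatant=input_qty
                * recovery
                * (1 - true_bound_fraction_reference)
                * f[3],
            )
        )
    return out
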