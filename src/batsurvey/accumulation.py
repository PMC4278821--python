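"""Species accumulation curves over sampling nights.

Effort is counted in detector-nights: the incidence matrix records, for a
sampling unit (one plot or one cell under a given scheme), which taxa were
detected on which nights; nights without any detection remain as all-zero
columns because a sampled night with no bats is still effort.

Two estimators of the expected accumulation curve are provided:

* :func:`accumulation_permuted` — the resampling estimator: night order is
  permuted (1000 times by default) and cumulative richness averaged,
  yielding a smooth curve with a spread.
* :func:`accumulation_exact` — the closed-form expectation over all night
  orderings, via hypergeometric inclusion probabilities:

      E[S(t)] = sum_i [ 1 - C(T - n_i, t) / C(T, t) ]

  where ``n_i`` is the number of nights taxon *i* was present and ``T``
  the total nights.  This is the exact limit of the permutation estimator
  and serves as its oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np

from .records import (
    DetectionRecord,
    SamplingScheme,
    filter_design,
    filter_temporal,
)

__all__ = [
    "IncidenceMatrix",
    "AccumulationCurve",
    "build_incidence",
    "accumulation_permuted",
    "accumulation_exact",
]


@dataclass
class IncidenceMatrix:
    """Binary taxon x night presence matrix for one sampling unit."""

    taxa: list[str]
    nights: list[str]
    presence: np.ndarray  # (n_taxa, n_nights) bool

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.taxa), len(self.nights)):
            raise ValueError(
                f"presence shape {self.presence.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.nights)} nights"
            )

    @property
    def n_nights(self) -> int:
        return len(self.nights)

    @property
    def richness(self) -> int:
        """Total observed richness (taxa present on >= 1 night)."""
        if self.presence.size == 0:
            return 0
        return int(self.presence.any(axis=1).sum())


@dataclass
class AccumulationCurve:
    """Mean (+/- spread) cumulative richness as a function of effort."""

    effort: np.ndarray        # 1..T nights
    mean_richness: np.ndarray
    sd_richness: np.ndarray
    n_permutations: int       # 0 for the exact closed form


def build_incidence(
    records: Sequence[DetectionRecord],
    scheme: SamplingScheme,
    unit: str,
    unit_id: str,
    nights: Sequence[str] | None = None,
) -> IncidenceMatrix:
    """Incidence matrix for a scheme applied to one sampling unit.

    ``unit`` is ``"plot"`` or ``"cell"``; presence is pooled over all the
    unit's sites that the scheme's design retains.  Records should already
    be taxon-collapsed so grouped congeners count as one taxon.  The night
    set defaults to every night with at least one record in the unit
    (before temporal filtering, so nights emptied by the filter stay as
    zero columns); pass ``nights`` explicitly to include fully silent
    sampled nights.
    """
    if unit not in ("plot", "cell"):
        raise ValueError(f"unit must be 'plot' or 'cell', got {unit!r}")
    attr = "plot_id" if unit == "plot" else "cell_id"
    unit_records = [r for r in records if getattr(r, attr) == unit_id]
    if nights is None:
        nights = sorted({r.night_id for r in unit_records})
    else:
        nights = list(nights)
    if not nights:
        raise ValueError(f"{unit} {unit_id!r} has no sampled nights")

    kept = filter_temporal(filter_design(unit_records, scheme.design), scheme.pattern)
    taxa = sorted({r.taxon for r in kept})
    night_ix = {n: j for j, n in enumerate(nights)}
    taxon_ix = {t: i for i, t in enumerate(taxa)}
    presence = np.zeros((len(taxa), len(nights)), dtype=bool)
    for r in kept:
        j = night_ix.get(r.night_id)
        if j is None:
            raise ValueError(f"record night {r.night_id!r} not in the supplied night set")
        presence[taxon_ix[r.taxon], j] = True
    return IncidenceMatrix(taxa=taxa, nights=nights, presence=presence)


def accumulation_permuted(
    incidence: IncidenceMatrix,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> AccumulationCurve:
    """Permutation (rarefaction) estimate of the accumulation curve.

    Night order is randomized ``n_perm`` times; for each ordering the
    cumulative number of distinct taxa is recorded, and the mean and
    standard deviation across orderings are returned per effort level.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    T = incidence.n_nights
    effort = np.arange(1, T + 1)
    if len(incidence.taxa) == 0:
        z = np.zeros(T)
        return AccumulationCurve(effort, z, z.copy(), n_perm)

    presence = incidence.presence
    paths = np.empty((n_perm, T))
    for k in range(n_perm):
        order = rng.permutation(T)
        perm = presence[:, order]
        # first night (in permuted order) each taxon appears; absent taxa
        # get a sentinel past the end
        any_seen = perm.any(axis=1)
        first = np.where(any_seen, perm.argmax(axis=1), T)
        paths[k] = np.cumsum(np.bincount(first, minlength=T + 1)[:T])
    return AccumulationCurve(
        effort=effort,
        mean_richness=paths.mean(axis=0),
        sd_richness=paths.std(axis=0),
        n_permutations=n_perm,
    )


def accumulation_exact(incidence: IncidenceMatrix) -> AccumulationCurve:
    """Exact expected accumulation curve over all night orderings.

    The probability that a taxon present on ``n_i`` of ``T`` nights is
    missed by a random subset of ``t`` nights is hypergeometric,
    ``C(T - n_i, t) / C(T, t)``; summing the complements over taxa gives
    the expectation.  The spread is reported as zero (the quantity is an
    expectation, not a resample).
    """
    T = incidence.n_nights
    effort = np.arange(1, T + 1)
    n_i = incidence.presence.sum(axis=1).astype(int)
    n_i = n_i[n_i > 0]
    mean = np.array(
        [sum(1.0 - comb(T - n, t) / comb(T, t) for n in n_i) for t in effort]
    )
    return AccumulationCurve(
        effort=effort,
        mean_richness=mean,
        sd_richness=np.zeros(T),
        n_permutations=0,
    )
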