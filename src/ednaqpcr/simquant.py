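"""Poisson single-molecule detection statistics and LOD/LOQ schemes.

When template is partitioned into reactions at a mean of λ copies per
reaction, the number of copies a reaction receives is Poisson(λ), so the
probability that a reaction is positive is ``p = 1 - exp(-λ)``.  Inverting
this on an observed positive fraction gives the most-probable-number (MPN,
single-molecule quantification) estimate of the copy number:
``λ̂ = -ln(n_negative / n_total)``.  A template load of about one copy per
reaction yields a 7:3 positive:negative ratio (70% detection).

Two empirical limit-of-detection / limit-of-quantification conventions are
implemented:

* *replicate scheme* — LOD is the lowest standard concentration with at
  least one positive replicate, LOQ the lowest at which every replicate
  amplifies (aquatic-eDNA practice, typically 3 replicates per dilution);
* *statistical scheme* — LOD is the lowest concentration whose
  false-negative probability ``exp(-λ)`` is below 5% (λ* = ln 20 ≈ 3
  copies/reaction), and LOQ additionally requires replicate Ct standard
  deviation below ±0.5 cycles (food/veterinary diagnostics practice).
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from typing import Sequence

from scipy import stats

from .io_plate import StandardPoint

__all__ = [
    "ReplicateOutcomeSet",
    "LodLoqResult",
    "SaturatedOutcomeError",
    "LodUndefinedError",
    "detection_probability",
    "mpn_estimate",
    "mpn_confidence_interval",
    "propagate_standard_copies",
    "lod_statistical",
    "false_negative_rate",
    "lod_loq_danish",
    "loq_norwegian",
]

#: Ct above (or at) which a positive signal is regarded unreliable.
DEFAULT_CT_CUTOFF = 41.0


class SaturatedOutcomeError(ValueError):
    """All replicates positive: the MPN closed form is undefined.

    The practical remedy is to run more replicates at this dilution (or use
    a more dilute standard) until at least one negative is observed.
    """


class LodUndefinedError(ValueError):
    """No standard concentration satisfies the detection rule."""


@dataclass(frozen=True)
class ReplicateOutcomeSet:
    """Positive/negative tally of replicate reactions at one template level."""

    n_total: int
    n_positive: int
    nominal_copies: float | None = None
    ct_values: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if not (0 <= self.n_positive <= self.n_total):
            raise ValueError("need 0 <= n_positive <= n_total")
        object.__setattr__(self, "ct_values", tuple(self.ct_values))

    @property
    def n_negative(self) -> int:
        return self.n_total - self.n_positive

    @property
    def positive_fraction(self) -> float:
        return self.n_positive / self.n_total

    @classmethod
    def from_standard_point(cls, point: StandardPoint,
                            ct_cutoff: float = DEFAULT_CT_CUTOFF) -> "ReplicateOutcomeSet":
        """Tally a standard's replicates; a positive needs Ct below the cut-off."""
        detected = [ct for ct in point.replicate_cts if ct is not None and ct < ct_cutoff]
        return cls(
            n_total=point.n_total,
            n_positive=len(detected),
            nominal_copies=point.nominal_copies_per_reaction,
            ct_values=tuple(detected),
        )


@dataclass(frozen=True)
class LodLoqResult:
    """LOD and LOQ in copies/reaction with the per-concentration evidence."""

    scheme: str
    lod_copies_per_reaction: float
    loq_copies_per_reaction: float
    evidence: tuple[dict, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (0 <= self.lod_copies_per_reaction <= self.loq_copies_per_reaction):
            raise ValueError("need 0 <= LOD <= LOQ")


def detection_probability(lambda_copies: float) -> float:
    """P(reaction positive) = 1 - exp(-λ) under Poisson template partitioning."""
    if lambda_copies < 0:
        raise ValueError(f"mean copy number must be >= 0, got {lambda_copies}")
    return 1.0 - math.exp(-lambda_copies)


def mpn_estimate(outcomes: ReplicateOutcomeSet) -> float:
    """Most-probable-number copy estimate from one dilution's tally.

    λ̂ = -ln(n_negative / n_total); the maximum-likelihood inverse of
    :func:`detection_probability`.  Raises :class:`SaturatedOutcomeError`
    when every replicate is positive.
    """
    if outcomes.n_negative == 0:
        raise SaturatedOutcomeError(
            f"all {outcomes.n_total} replicates positive: MPN undefined; "
            "run additional replicates at this dilution"
        )
    return -math.log(outcomes.n_negative / outcomes.n_total)


def mpn_confidence_interval(outcomes: ReplicateOutcomeSet,
                            level: float = 0.95) -> tuple[float, float]:
    """Clopper–Pearson interval on the positive fraction, mapped to λ.

    The exact binomial interval on p is transformed through
    λ = -ln(1 - p).  The upper bound is ``inf`` when all replicates are
    positive.
    """
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    k, n = outcomes.n_positive, outcomes.n_total
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else stats.beta.ppf(alpha / 2, k, n - k + 1)
    hi = 1.0 if k == n else stats.beta.ppf(1 - alpha / 2, k + 1, n - k)
    lam_lo = 0.0 if lo <= 0 else -math.log(1 - lo)
    lam_hi = math.inf if hi >= 1 else -math.log(1 - hi)
    return (lam_lo, lam_hi)


def propagate_standard_copies(anchor_index: int, anchor_lambda: float,
                              fold: float, indices: Sequence[int]) -> list[float]:
    """Copy numbers of the other standards from one MPN-anchored dilution.

    Standard ``i`` (0 = most concentrated) receives
    ``anchor_lambda * fold**(anchor_index - i)``, so e.g. an anchor of 2.4
    copies at step 7 of a four-fold series puts 2.4·4⁷ = 39321.6 copies in
    the top standard.
    """
    if fold <= 1:
        raise ValueError(f"fold must be > 1, got {fold}")
    if anchor_lambda < 0:
        raise ValueError("anchor copy number must be >= 0")
    return [anchor_lambda * fold ** (anchor_index - i) for i in indices]


def lod_statistical(alpha: float = 0.05) -> float:
    """Smallest λ whose false-negative probability is at most ``alpha``.

    exp(-λ) <= alpha  ⇔  λ >= ln(1/alpha); at the conventional 5% level
    this is ln 20 ≈ 2.996 copies/reaction.
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return math.log(1.0 / alpha)


def false_negative_rate(lambda_copies: float) -> float:
    """P(no template in the reaction) = exp(-λ); e.g. 0.67% at 5 copies."""
    if lambda_copies < 0:
        raise ValueError(f"mean copy number must be >= 0, got {lambda_copies}")
    return math.exp(-lambda_copies)


def _sorted_outcomes(series: Sequence[StandardPoint],
                     ct_cutoff: float) -> list[ReplicateOutcomeSet]:
    pts = sorted(series, key=lambda p: p.nominal_copies_per_reaction)
    return [ReplicateOutcomeSet.from_standard_point(p, ct_cutoff) for p in pts]


def lod_loq_danish(series: Sequence[StandardPoint],
                   ct_cutoff: float = DEFAULT_CT_CUTOFF) -> LodLoqResult:
    """Replicate-based LOD/LOQ over a standard dilution series.

    LOD = lowest concentration with >= 1 positive replicate; LOQ = lowest
    concentration at which every replicate amplified.  Both in
    copies/reaction.  The two frequently coincide when the same dilution is
    the first to satisfy both rules.
    """
    outcomes = _sorted_outcomes(series, ct_cutoff)
    lod = next((o.nominal_copies for o in outcomes if o.n_positive >= 1), None)
    loq = next((o.nominal_copies for o in outcomes if o.n_positive == o.n_total), None)
    if lod is None:
        raise LodUndefinedError("no standard concentration produced any positive replicate")
    if loq is None:
        raise LodUndefinedError("no standard concentration amplified in all replicates")
    evidence = tuple(
        {"copies_per_reaction": o.nominal_copies,
         "positive": o.n_positive, "total": o.n_total}
        for o in outcomes
    )
    return LodLoqResult("danish_replicate", lod, loq, evidence)


def loq_norwegian(series: Sequence[StandardPoint], sd_limit: float = 0.5,
                  ct_cutoff: float = DEFAULT_CT_CUTOFF) -> float:
    """LOQ by replicate repeatability: lowest fully-detected concentration
    whose replicate Ct standard deviation is below ``sd_limit`` cycles.
    """
    if sd_limit <= 0:
        raise ValueError("sd_limit must be > 0")
    for point in sorted(series, key=lambda p: p.nominal_copies_per_reaction):
        outcome = ReplicateOutcomeSet.from_standard_point(point, ct_cutoff)
        if outcome.n_positive != outcome.n_total or outcome.n_positive < 2:
            continue
        if statistics.stdev(outcome.ct_values) < sd_limit:
            return point.nominal_copies_per_reaction
    raise LodUndefinedError(
        f"no fully-detected concentration has replicate Ct SD < {sd_limit}"
    )
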