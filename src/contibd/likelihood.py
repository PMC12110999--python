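"""Exact likelihoods of observed IBD segment sets and likelihood ratios.

The likelihood of a chromosome's alternating segments factorizes over
segments: the hidden vector must stay in the class matching the observed
state for the segment's length (Poisson-conditioned forward recursion) and,
for interior segments, exit to the complementary class exactly at the
boundary.  The exit contributes the intensity flux across the class
boundary, i.e. the likelihood is a density with respect to the interior
breakpoint positions; the final segment contributes a staying probability
only, so a fully-IBD0 chromosome reduces exactly to the no-IBD probability.

Whole-genome log-likelihoods are sums over independent chromosomes.
Composite hypotheses mix whole-genome likelihoods with their prior weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .errors import UndefinedLRError, ValidationError
from .pedigree import Pedigree, build_relationship
from .segments import ChromosomeSegments, IBDSegmentSet
from .statespace import DEFAULT_EPSILON, StateSpace, chain_for

__all__ = [
    "Hypothesis",
    "LRResult",
    "segment_loglikelihood",
    "genome_loglikelihood",
    "likelihood_ratio",
]

_LOG10 = math.log(10.0)


def _chromosome_loglik(
    space: StateSpace, chrom: ChromosomeSegments, epsilon: float
) -> float:
    """Natural-log likelihood of one chromosome's segments.

    Returns ``-inf`` when the hypothesis assigns zero probability (e.g. a
    kappa1 = 1 relationship observed with an IBD0 segment).
    """
    x0 = int(chrom.states[0])
    idx = space.class_indices(x0)
    if idx.size == 0:
        return -np.inf
    alpha = np.full(idx.size, space.prior)
    logp = 0.0
    n = chrom.n_segments
    for i in range(n):
        x = int(chrom.states[i])
        length = float(chrom.ends[i] - chrom.starts[i])
        alpha = space.propagate_stay(alpha, x, length, epsilon)
        if i < n - 1:
            alpha = space.exit_matrix(x) @ alpha
        total = float(alpha.sum())
        if total <= 0.0:
            return -np.inf
        logp += math.log(total)
        alpha = alpha / total
    return logp


def segment_loglikelihood(
    ped: Pedigree, segs: IBDSegmentSet, epsilon: float = DEFAULT_EPSILON
) -> float:
    """Natural-log likelihood of a segment set under one relationship.

    Sum of per-chromosome log-likelihoods; ``-inf`` flags a degenerate
    (zero-probability) observation.  The truncation error of each
    uniformization sum is at most ``epsilon``.
    """
    space = chain_for(ped)
    out = 0.0
    for _, chrom in segs:
        out += _chromosome_loglik(space, chrom, epsilon)
        if out == -np.inf:
            return -np.inf
    return out


@dataclass(frozen=True)
class Hypothesis:
    """A single relationship or an equal/weighted mixture of relationships."""

    components: tuple[Pedigree, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValidationError("a hypothesis needs at least one component")
        if len(self.weights) != len(self.components):
            raise ValidationError("weights and components differ in count")
        if any(w <= 0 for w in self.weights):
            raise ValidationError("hypothesis weights must be positive")
        total = float(sum(self.weights))
        if abs(total - 1.0) > 1e-9:
            object.__setattr__(
                self, "weights", tuple(w / total for w in self.weights)
            )

    @classmethod
    def of(cls, spec) -> "Hypothesis":
        """Build from a pedigree, abbreviation, iterable, or spec string.

        Strings may be comma-separated composites with optional weights,
        e.g. ``"HS,N"`` (equal weights) or ``"HS:0.5,N:0.5"``.
        """
        if isinstance(spec, Hypothesis):
            return spec
        if isinstance(spec, Pedigree):
            return cls((spec,), (1.0,))
        if isinstance(spec, str):
            parts = [p.strip() for p in spec.split(",") if p.strip()]
            peds, weights = [], []
            for part in parts:
                if ":" in part:
                    tok, w = part.rsplit(":", 1)
                    weights.append(float(w))
                else:
                    tok = part
                    weights.append(np.nan)
                peds.append(build_relationship(tok))
            warr = np.asarray(weights)
            if np.isnan(warr).all():
                warr = np.full(len(peds), 1.0 / len(peds))
            elif np.isnan(warr).any():
                raise ValidationError(
                    "give weights for all components or none"
                )
            return cls(tuple(peds), tuple(float(w) for w in warr))
        peds = tuple(
            p if isinstance(p, Pedigree) else build_relationship(p) for p in spec
        )
        return cls(peds, tuple(1.0 / len(peds) for _ in peds))

    @property
    def label(self) -> str:
        names = [p.label or p.pair[0] + "-" + p.pair[1] for p in self.components]
        if len(names) == 1:
            return names[0]
        return "{" + ",".join(names) + "}"


def genome_loglikelihood(
    hyp: Hypothesis | Pedigree | str,
    segs: IBDSegmentSet,
    epsilon: float = DEFAULT_EPSILON,
) -> float:
    """Natural-log likelihood under a (possibly composite) hypothesis.

    Mixture components combine at the genome level:
    ``log sum_i w_i * Pr(E | component_i)``.
    """
    hyp = Hypothesis.of(hyp)
    logs = np.array(
        [segment_loglikelihood(p, segs, epsilon) for p in hyp.components]
    )
    if np.all(np.isneginf(logs)):
        return -np.inf
    return float(logsumexp(logs, b=np.asarray(hyp.weights)))


@dataclass(frozen=True)
class LRResult:
    """log10 likelihoods under two hypotheses and their log10 ratio."""

    log10_h1: float
    log10_h2: float
    log10_lr: float

    @property
    def lr(self) -> float:
        return 10.0 ** self.log10_lr


def likelihood_ratio(
    segs: IBDSegmentSet,
    h1: Hypothesis | Pedigree | str,
    h2: Hypothesis | Pedigree | str,
    epsilon: float = DEFAULT_EPSILON,
) -> LRResult:
    """Likelihood ratio of ``h1`` versus ``h2`` for a segment set.

    Swapping the hypotheses negates ``log10_lr`` exactly.  A 0/0 ratio
    raises :class:`UndefinedLRError`; one-sided zeros give ``+/-inf``.
    """
    l1 = genome_loglikelihood(h1, segs, epsilon)
    l2 = genome_loglikelihood(h2, segs, epsilon)
    if l1 == -np.inf and l2 == -np.inf:
        raise UndefinedLRError(
            "both hypotheses assign zero probability to the observation"
        )
    return LRResult(
        log10_h1=l1 / _LOG10,
        log10_h2=l2 / _LOG10,
        log10_lr=(l1 - l2) / _LOG10,
    )
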