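"""Exact (non-simulation) summary statistics of the continuous IBD process.

Identity coefficients are exact rationals obtained by enumerating the
(reduced) IBD-vector space.  Two-locus probabilities and total-IBD variances
use the spectral form of the bit-flip walk: with ``a_j`` the Walsh weights
of the IBD1 indicator,

    kappa11(d) = sum_j a_j * exp(-0.02 * j * d),

so ``E(T^2) = 2 * int_0^L (L - d) kappa11(d) dd`` has a closed form.  The
probability of no IBD on a chromosome uses the Poisson-conditioned forward
algorithm (uniformization) restricted to the IBD0 states.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .genmap import GeneticMap
from .pedigree import Pedigree
from .simulate import simulate_totals
from .statespace import DEFAULT_EPSILON, chain_for

__all__ = [
    "IdentityCoefficients",
    "TotalIBDMoments",
    "DispersionEstimate",
    "identity_coefficients",
    "two_locus_kappa11",
    "total_ibd_moments",
    "expected_segment_count",
    "pr_no_ibd",
    "pr_no_ibd_genome",
    "ibd1_survival",
    "ibd1_start_hazard",
    "segment_count_dispersion",
]


@dataclass(frozen=True)
class IdentityCoefficients:
    """Single-locus identity coefficients as exact rationals."""

    kappa0: Fraction
    kappa1: Fraction
    kappa2: Fraction

    def __post_init__(self) -> None:
        assert self.kappa0 + self.kappa1 + self.kappa2 == 1


def identity_coefficients(ped: Pedigree) -> IdentityCoefficients:
    """Exact identity coefficients by enumeration of the IBD-vector space.

    Enumerates the reduced space (relevant meioses); each reduced vector
    stands for an equal-probability block of raw vectors, so the fractions
    equal the raw-space counts.
    """
    counts = ped.ibd_counts
    nv = counts.size
    k1 = Fraction(int((counts == 1).sum()), nv)
    k2 = Fraction(int((counts == 2).sum()), nv)
    return IdentityCoefficients(kappa0=1 - k1 - k2, kappa1=k1, kappa2=k2)


def two_locus_kappa11(ped: Pedigree, d: float) -> float:
    """Probability that two loci ``d`` cM apart are both IBD1."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    space = chain_for(ped)
    a = space.walsh_spectrum()
    j = np.arange(a.size)
    return float(np.sum(a * np.exp(-0.02 * j * d)))


def _e_t2(a: np.ndarray, L: float) -> float:
    """Closed form of ``2 * int_0^L (L - d) kappa11(d) dd``."""
    j = np.arange(a.size)
    g = np.empty_like(a)
    g[0] = 0.5 * L * L
    r = 0.02 * j[1:]
    g[1:] = L / r - (1.0 - np.exp(-r * L)) / (r * r)
    return float(2.0 * np.sum(a * g))


def pr_no_ibd(
    ped: Pedigree, L: float, epsilon: float = DEFAULT_EPSILON
) -> float:
    """Probability of no IBD anywhere on a chromosome of length ``L`` cM.

    Poisson-truncated forward sum over IBD0-restricted paths; the truncation
    error is at most ``epsilon``.
    """
    if L < 0:
        raise ValueError("chromosome length must be non-negative")
    space = chain_for(ped)
    idx0 = space.class_indices(0)
    alpha = np.full(idx0.size, space.prior)
    alpha = space.propagate_stay(alpha, 0, L, epsilon)
    return float(alpha.sum())


def pr_no_ibd_genome(
    ped: Pedigree, gmap: GeneticMap, epsilon: float = DEFAULT_EPSILON
) -> float:
    """``Pr(T+ = 0)``: product of per-chromosome no-IBD probabilities."""
    out = 1.0
    for _, L in gmap:
        out *= pr_no_ibd(ped, L, epsilon)
    return out


def ibd1_survival(
    ped: Pedigree, L: float, epsilon: float = DEFAULT_EPSILON
) -> float:
    """``Pr(IBD1 everywhere on [0, L] | IBD1 at 0)`` (segment survival)."""
    space = chain_for(ped)
    idx1 = space.class_indices(1)
    alpha = np.full(idx1.size, space.prior)
    alpha = space.propagate_stay(alpha, 1, L, epsilon)
    kappa1 = float(space.kappa1)
    return float(alpha.sum()) / kappa1


def ibd1_start_hazard(ped: Pedigree) -> float:
    """Instantaneous IBD1 -> IBD0 hazard at the start of a segment.

    The stationary exit intensity out of the IBD1 class divided by kappa1.
    """
    space = chain_for(ped)
    flux = space.exit_matrix(1).sum() * space.prior
    return float(flux / float(space.kappa1))


def _crossing_flux(ped: Pedigree) -> float:
    """Stationary IBD0 -> IBD1 up-crossing intensity per cM."""
    space = chain_for(ped)
    return float(space.exit_matrix(0).sum() * space.prior)


def expected_segment_count(ped: Pedigree, gmap: GeneticMap) -> float:
    """Expected genome-wide number of IBD1 segments.

    Each chromosome contributes ``kappa1`` (IBD1 at the start) plus the
    stationary up-crossing flux times its length.
    """
    k1 = float(chain_for(ped).kappa1)
    return len(gmap) * k1 + _crossing_flux(ped) * gmap.total


@dataclass(frozen=True)
class TotalIBDMoments:
    """Exact moments of total IBD and related genome-wide summaries."""

    chromosome_labels: tuple[str, ...]
    e_t: tuple[float, ...]
    var_t: tuple[float, ...]
    pr_t0: tuple[float, ...]
    e_total: float
    sd_total: float
    expected_segment_count: float
    pr_total_zero: float
    n0_mean: float
    n0_sd: float


def total_ibd_moments(
    ped: Pedigree, gmap: GeneticMap, epsilon: float = DEFAULT_EPSILON
) -> TotalIBDMoments:
    """Exact per-chromosome and genome-wide total-IBD summaries.

    ``E(T) = kappa1 * L`` exactly; ``Var(T)`` from the closed-form reduction
    of the double integral of the two-locus probability; chromosomes are
    independent, so genome-wide moments are sums.
    """
    space = chain_for(ped)
    k1 = float(space.kappa1)
    a = space.walsh_spectrum()
    labels, e_t, var_t, p0 = [], [], [], []
    for label, L in gmap:
        labels.append(label)
        e = k1 * L
        e_t.append(e)
        var_t.append(_e_t2(a, L) - e * e)
        p0.append(pr_no_ibd(ped, L, epsilon))
    p0_arr = np.asarray(p0)
    return TotalIBDMoments(
        chromosome_labels=tuple(labels),
        e_t=tuple(e_t),
        var_t=tuple(var_t),
        pr_t0=tuple(p0),
        e_total=float(np.sum(e_t)),
        sd_total=float(np.sqrt(np.sum(var_t))),
        expected_segment_count=expected_segment_count(ped, gmap),
        pr_total_zero=float(np.prod(p0_arr)),
        n0_mean=float(np.sum(p0_arr)),
        n0_sd=float(np.sqrt(np.sum(p0_arr * (1.0 - p0_arr)))),
    )


@dataclass(frozen=True)
class DispersionEstimate:
    """Monte-Carlo standard deviation with its standard error."""

    sd: float
    se: float
    reps: int


def segment_count_dispersion(
    ped: Pedigree, gmap: GeneticMap, reps: int, seed: int
) -> DispersionEstimate:
    """Monte-Carlo s.d. of the genome-wide IBD1 segment count.

    The standard error uses the normal approximation ``sd / sqrt(2(n-1))``.
    """
    if reps < 1000:
        raise ValueError("use at least 1000 replicates for a stable s.d.")
    sample = simulate_totals(ped, gmap, reps, seed)
    sd = float(np.std(sample.segment_count, ddof=1))
    return DispersionEstimate(sd=sd, se=sd / np.sqrt(2.0 * (reps - 1)), reps=reps)
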