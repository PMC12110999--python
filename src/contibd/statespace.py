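"""State space and transition structure of the IBD-vector Markov chain.

Under Haldane's model each meiosis experiences crossovers at 0.01 per cM, so
the IBD vector performs a continuous-time random walk on a hypercube: the
transition intensity between vectors at Hamming distance 1 is 0.01, all
other off-diagonal intensities are 0.

Two representations are supported:

* the *full* space over all ``2 * nnf`` meioses (``2**(2 nnf)`` states),
  feasible only for small pedigrees and used for validation; and
* the *reduced* space over the relevant meioses only (default).  Irrelevant
  meioses flip independently of the observation, so marginalizing them is an
  exact lumping: the reduced chain is again an independent bit-flip walk and
  the observed IBD process has the same law.

The uniformized jump chain moves to one of the ``nbits`` Hamming-1
neighbours with probability ``1 / nbits`` at Poisson(0.01 * nbits * L)
epochs.  (The rate counts crossovers across all tracked meioses; a one-bit
step probability of ``1 / nbits`` is the only normalizing choice.)

The Walsh basis diagonalizes the product chain: the character indexed by
``s`` decays as ``exp(-0.02 * popcount(s) * d)`` over distance ``d``, which
yields closed forms for two-locus probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

import numpy as np
import scipy.sparse as sp
from scipy.stats import poisson

from .errors import CapacityError, ValidationError
from .pedigree import Pedigree

__all__ = [
    "CROSSOVER_RATE",
    "StateSpace",
    "UniformizationPlan",
    "make_plan",
    "transition_intensity",
    "one_step_kernel",
    "chain_for",
]

#: Crossovers per cM per meiosis (Haldane model).
CROSSOVER_RATE = 0.01

#: Default Poisson truncation tolerance.
DEFAULT_EPSILON = 1e-10

_FULL_SPACE_LIMIT = 16  # max meioses for the raw (unreduced) representation


def transition_intensity(a: int, b: int, nnf: int) -> float:
    """Intensity (per cM) between full IBD-vector states ``a`` and ``b``.

    0.01 at Hamming distance 1, 0 at distance >= 2, and minus the row sum
    on the diagonal.
    """
    nbits = 2 * nnf
    nv = 1 << nbits
    for x in (a, b):
        if not 0 <= x < nv:
            raise ValidationError(f"state {x} out of range [0, {nv})")
    if a == b:
        return -CROSSOVER_RATE * nbits
    h = int(a ^ b).bit_count()
    return CROSSOVER_RATE if h == 1 else 0.0


@dataclass(frozen=True)
class UniformizationPlan:
    """Poisson-truncation plan for one chromosome.

    ``rate_total = 0.01 * length * nbits`` is the total crossover rate over
    the tracked meioses; ``kmax`` is the smallest integer with
    Poisson upper-tail mass at most ``epsilon``.
    """

    nbits: int
    length_cM: float
    rate_total: float
    epsilon: float
    kmax: int


def poisson_kmax(lam: float, epsilon: float) -> int:
    if lam <= 0:
        return 0
    return int(poisson.ppf(1.0 - epsilon, lam))


def poisson_weights(lam: float, epsilon: float) -> np.ndarray:
    """Poisson pmf values ``0..kmax`` where ``kmax`` is the smallest integer
    whose cumulative mass reaches ``1 - epsilon`` (tail mass <= epsilon)."""
    w = np.exp(-lam)
    out = [w]
    cum = w
    k = 0
    while cum < 1.0 - epsilon:
        k += 1
        w *= lam / k
        out.append(w)
        cum += w
    return np.asarray(out)


def make_plan(nbits: int, length_cM: float, epsilon: float = DEFAULT_EPSILON) -> UniformizationPlan:
    lam = CROSSOVER_RATE * length_cM * nbits
    return UniformizationPlan(
        nbits=nbits,
        length_cM=length_cM,
        rate_total=lam,
        epsilon=epsilon,
        kmax=poisson_kmax(lam, epsilon),
    )


@lru_cache(maxsize=64)
def _hypercube_adjacency(nbits: int) -> sp.csr_matrix:
    n = 1 << nbits
    states = np.arange(n)
    rows = np.concatenate([states] * nbits) if nbits else np.empty(0, dtype=int)
    cols = (
        np.concatenate([states ^ (1 << b) for b in range(nbits)])
        if nbits
        else np.empty(0, dtype=int)
    )
    data = np.ones(rows.size)
    return sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()


def one_step_kernel(plan: UniformizationPlan) -> sp.csr_matrix:
    """One-crossover kernel: ``1 / nbits`` to each Hamming-1 neighbour."""
    if plan.nbits == 0:
        return sp.identity(1, format="csr")
    return _hypercube_adjacency(plan.nbits) / plan.nbits


def _fwht(a: np.ndarray) -> np.ndarray:
    """In-place fast Walsh–Hadamard transform (unnormalized)."""
    a = a.copy()
    h = 1
    n = a.size
    while h < n:
        a = a.reshape(-1, 2 * h)
        left = a[:, :h].copy()
        a[:, :h] = left + a[:, h:]
        a[:, h:] = left - a[:, h:]
        a = a.reshape(n)
        h *= 2
    return a


class StateSpace:
    """IBD-vector state space for a pedigree pair.

    Parameters
    ----------
    ped
        An accepted pedigree (zero IBD2 probability).
    reduced
        Use the relevant-meioses representation (default).  With
        ``reduced=False`` the raw space over all ``2 * nnf`` meioses is
        built, which is only feasible for small pedigrees.
    """

    def __init__(self, ped: Pedigree, reduced: bool = True):
        ped.validate_pair()
        self.pedigree = ped
        self.reduced = bool(reduced)
        counts = ped.ibd_counts
        rel = ped.relevant_meioses
        if reduced:
            self.nbits = len(rel)
            self.ibd1 = counts == 1
        else:
            nbits = ped.n_meioses
            if nbits > _FULL_SPACE_LIMIT:
                raise CapacityError(
                    f"full state space over {nbits} meioses exceeds the "
                    f"{_FULL_SPACE_LIMIT}-meiosis limit; use the reduced space"
                )
            self.nbits = nbits
            full = np.arange(1 << nbits)
            proj = np.zeros(1 << nbits, dtype=np.int64)
            for j, idx in enumerate(rel):
                proj |= ((full >> idx) & 1) << j
            self.ibd1 = counts[proj] == 1
        self.nv = 1 << self.nbits
        self._idx = (np.flatnonzero(~self.ibd1), np.flatnonzero(self.ibd1))
        self._stay: dict[int, sp.csr_matrix] = {}
        self._exit: dict[int, sp.csr_matrix] = {}

    # -- basic structure ---------------------------------------------------

    @property
    def prior(self) -> float:
        """Uniform prior probability of each state, ``1 / nv``."""
        return 1.0 / self.nv

    def class_indices(self, x: int) -> np.ndarray:
        """State indices observing IBD state ``x`` (0 or 1)."""
        if x not in (0, 1):
            raise ValidationError(f"IBD state must be 0 or 1, got {x!r}")
        return self._idx[x]

    @property
    def kappa1(self) -> Fraction:
        return Fraction(int(self.ibd1.sum()), self.nv)

    def lump(self, full_probs: np.ndarray) -> np.ndarray:
        """Aggregate raw-space probabilities onto the reduced space."""
        if self.reduced:
            raise ValidationError("lump() applies to a raw (reduced=False) space")
        rel = self.pedigree.relevant_meioses
        full = np.arange(self.nv)
        proj = np.zeros(self.nv, dtype=np.int64)
        for j, idx in enumerate(rel):
            proj |= ((full >> idx) & 1) << j
        return np.bincount(proj, weights=full_probs, minlength=1 << len(rel))

    # -- kernels -----------------------------------------------------------

    @property
    def total_rate(self) -> float:
        """Total crossover rate per cM across tracked meioses."""
        return CROSSOVER_RATE * self.nbits

    def kernel(self) -> sp.csr_matrix:
        return one_step_kernel(make_plan(self.nbits, 1.0))

    _DENSE_LIMIT = 256  # below this, dense matvecs beat sparse overhead

    def stay_kernel(self, x: int):
        """One-step kernel restricted to the class observing ``x``."""
        if x not in self._stay:
            idx = self.class_indices(x)
            K = self.kernel()[idx][:, idx].tocsr()
            self._stay[x] = K.toarray() if idx.size <= self._DENSE_LIMIT else K
        return self._stay[x]

    def exit_matrix(self, x: int):
        """Intensity flux (per cM) from class ``x`` into its complement.

        Shape ``(|class 1-x|, |class x|)`` so that ``exit @ alpha_x`` is the
        arrival density over the complementary class.
        """
        if x not in self._exit:
            src = self.class_indices(x)
            dst = self.class_indices(1 - x)
            A = _hypercube_adjacency(self.nbits)
            E = (CROSSOVER_RATE * A[dst][:, src]).tocsr()
            small = max(src.size, dst.size) <= self._DENSE_LIMIT
            self._exit[x] = E.toarray() if small else E
        return self._exit[x]

    def intensity_matrix(self) -> np.ndarray:
        """Dense intensity matrix ``Q`` (per cM); small spaces only."""
        if self.nbits > 12:
            raise CapacityError("dense intensity matrix limited to 12 bits")
        A = _hypercube_adjacency(self.nbits).toarray()
        return CROSSOVER_RATE * (A - self.nbits * np.eye(self.nv))

    # -- propagation -------------------------------------------------------

    def propagate_stay(
        self,
        alpha: np.ndarray,
        x: int,
        length_cM: float,
        epsilon: float = DEFAULT_EPSILON,
    ) -> np.ndarray:
        """Propagate class-restricted mass over ``length_cM`` staying in ``x``.

        ``alpha`` is indexed by ``class_indices(x)``.  Returns the joint
        probability (vector over the same class) of ending in each state
        while the observation never leaves ``x``, via the Poisson-truncated
        uniformization sum.
        """
        if length_cM < 0:
            raise ValidationError("segment length must be non-negative")
        lam = self.total_rate * length_cM
        if lam <= 0 or alpha.size == 0:
            return alpha.copy()
        weights = poisson_weights(lam, epsilon)
        K = self.stay_kernel(x)
        acc = weights[0] * alpha
        cur = alpha
        for w in weights[1:]:
            cur = K @ cur
            acc += w * cur
        return acc

    def transition_matrix(self, d: float) -> np.ndarray:
        """Exact state-transition matrix over genetic distance ``d`` cM.

        Product form of the independent bit-flip walk: each bit differs
        with probability ``(1 - exp(-0.02 d)) / 2``.
        """
        if self.nbits > 12:
            raise CapacityError("dense transition matrix limited to 12 bits")
        p = 0.5 * (1.0 - np.exp(-2.0 * CROSSOVER_RATE * d))
        single = np.array([[1.0 - p, p], [p, 1.0 - p]])
        out = np.ones((1, 1))
        for _ in range(self.nbits):
            out = np.kron(single, out)
        return out

    # -- spectral structure ------------------------------------------------

    def walsh_spectrum(self) -> np.ndarray:
        """Spectral weights ``a_j`` of the IBD1 indicator, ``j = 0..nbits``.

        The two-locus probability is ``kappa11(d) = sum_j a_j exp(-0.02 j d)``
        with ``a_0 = kappa1**2`` and ``sum_j a_j = kappa1``.
        """
        f = self.ibd1.astype(float)
        fh = _fwht(f) / self.nv
        coef = fh * fh
        j = np.bitwise_count(np.arange(self.nv, dtype=np.uint64)).astype(int)
        return np.bincount(j, weights=coef, minlength=self.nbits + 1)


@lru_cache(maxsize=256)
def chain_for(ped: Pedigree, reduced: bool = True) -> StateSpace:
    """Cached :class:`StateSpace` for a pedigree."""
    return StateSpace(ped, reduced=reduced)
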