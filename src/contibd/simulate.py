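"""Simulation of continuous IBD along the genome.

The IBD vector starts uniform at position 0 of each chromosome; crossovers
arrive at total rate ``0.01 * 2 * nnf`` per cM (exponential inter-arrival
times) and each crossover flips one uniformly chosen meiosis bit.  The
observed process is the IBD state of the vector, with equal-state runs
merged into alternating segments.  Chromosomes are independent.

Random-number contract: a single integer seed determines the whole genome;
the substream for chromosome ``i`` (0-based index in the map) is derived
from ``(seed, i)``, so per-chromosome draws are reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genmap import GeneticMap
from .pedigree import Pedigree
from .segments import ChromosomeSegments, IBDSegmentSet

__all__ = ["simulate_ibd", "simulate_totals", "TotalsSample"]

_RATE = 0.01  # crossovers per cM per meiosis


def _reduced_setup(ped: Pedigree):
    """Per-meiosis XOR masks on the reduced space and the IBD1 lookup."""
    rel = ped.relevant_meioses
    pos = {idx: j for j, idx in enumerate(rel)}
    masks = np.array(
        [1 << pos[i] if i in pos else 0 for i in range(ped.n_meioses)],
        dtype=np.int64,
    )
    ibd1 = ped.ibd_counts == 1
    return masks, ibd1, len(rel)


def simulate_ibd(ped: Pedigree, gmap: GeneticMap, seed) -> IBDSegmentSet:
    """Simulate one genome of continuous IBD segments.

    Deterministic in ``seed`` (an integer or a sequence of integers);
    chromosomes use independent substreams derived from (seed, index).
    """
    ped.validate_pair()
    masks, ibd1, m = _reduced_setup(ped)
    nmei = ped.n_meioses
    seed_key = [int(seed)] if np.isscalar(seed) else [int(s) for s in seed]
    out: dict[str, ChromosomeSegments] = {}
    for ci, (label, L) in enumerate(gmap):
        rng = np.random.default_rng([*seed_key, ci])
        v0_bits = rng.integers(0, 2, size=nmei)
        # project the uniform full start vector onto the relevant bits
        r0 = int(np.bitwise_or.reduce(masks[v0_bits.astype(bool)], initial=0))
        n = int(rng.poisson(_RATE * nmei * L)) if nmei else 0
        pos = np.sort(rng.uniform(0.0, L, size=n))
        mei = rng.integers(0, nmei, size=n) if n else np.empty(0, dtype=int)
        flips = masks[mei] if n else np.empty(0, dtype=np.int64)
        codes = np.empty(n + 1, dtype=np.int64)
        codes[0] = r0
        if n:
            codes[1:] = r0 ^ np.bitwise_xor.accumulate(flips)
        bounds = np.concatenate(([0.0], pos, [L]))
        states = ibd1[codes].astype(np.int8)
        out[str(label)] = ChromosomeSegments.from_intervals(L, bounds, states)
    return IBDSegmentSet(out)


@dataclass(frozen=True)
class TotalsSample:
    """Batched genome summaries from :func:`simulate_totals`."""

    total_ibd: np.ndarray
    segment_count: np.ndarray
    chromosomes_without_ibd: np.ndarray

    @property
    def reps(self) -> int:
        return int(self.total_ibd.size)

    @property
    def zero_sharing(self) -> np.ndarray:
        return self.segment_count == 0


def simulate_totals(
    ped: Pedigree, gmap: GeneticMap, reps: int, seed: int
) -> TotalsSample:
    """Vectorized simulation of per-genome total IBD and IBD1 segment count.

    Same stochastic model as :func:`simulate_ibd` but batched over ``reps``
    genomes (its own substream layout; draws do not match single-genome
    simulation seed-for-seed).
    """
    ped.validate_pair()
    masks, ibd1, m = _reduced_setup(ped)
    nmei = ped.n_meioses
    totals = np.zeros(reps)
    counts = np.zeros(reps, dtype=np.int64)
    nzero = np.zeros(reps, dtype=np.int64)
    for ci, (label, L) in enumerate(gmap):
        rng = np.random.default_rng([seed, ci])
        n = rng.poisson(_RATE * nmei * L, size=reps)
        N = int(n.sum())
        rep_of_event = np.repeat(np.arange(reps), n)
        pos = rng.uniform(0.0, L, size=N)
        order = np.lexsort((pos, rep_of_event))
        pos = pos[order]
        mei = rng.integers(0, nmei, size=N) if nmei else np.empty(0, dtype=int)
        flips = masks[mei] if N else np.empty(0, dtype=np.int64)
        r0 = (
            rng.integers(0, 1 << m, size=reps, dtype=np.int64)
            if m
            else np.zeros(reps, dtype=np.int64)
        )
        starts = np.concatenate(([0], np.cumsum(n)))[:-1]
        acc = np.bitwise_xor.accumulate(flips) if N else flips
        before = np.concatenate(([0], acc))[starts]  # accumulated xor before rep
        codes_after = np.repeat(r0 ^ before, n) ^ acc if N else acc
        # per-rep interval structure: [r0, codes_after...] with bounds [0, pos..., L]
        lefts = np.insert(pos, starts, 0.0)
        rights = np.insert(pos, np.cumsum(n), L)
        lengths = rights - lefts
        codes = np.insert(codes_after, starts, r0)
        rep_of_iv = np.repeat(np.arange(reps), n + 1)
        ibd = ibd1[codes]
        totals += np.bincount(rep_of_iv, weights=lengths * ibd, minlength=reps)
        first = np.zeros(ibd.size, dtype=bool)
        first[starts + np.arange(reps)] = True
        prev = np.concatenate(([False], ibd[:-1]))
        upcross = ibd & (first | ~prev)
        chrom_counts = np.bincount(rep_of_iv, weights=upcross, minlength=reps)
        counts += chrom_counts.astype(np.int64)
        nzero += (chrom_counts == 0).astype(np.int64)
    return TotalsSample(totals, counts, nzero)
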