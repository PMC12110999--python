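"""Observed continuous IBD: alternating half-open segments per chromosome."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["ChromosomeSegments", "IBDSegmentSet"]

_TILE_TOL = 1e-9


@dataclass(frozen=True)
class ChromosomeSegments:
    """Alternating IBD segments tiling ``[0, length)`` on one chromosome.

    Segments are half-open ``[start, end)`` with no gaps or overlaps and
    adjacent segments in different IBD states.
    """

    length: float
    starts: np.ndarray
    ends: np.ndarray
    states: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=float)
        ends = np.asarray(self.ends, dtype=float)
        states = np.asarray(self.states, dtype=np.int8)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        object.__setattr__(self, "states", states)
        n = starts.size
        if not (ends.size == n and states.size == n):
            raise ValidationError("segment arrays have mismatched lengths")
        if n == 0:
            raise ValidationError("a chromosome needs at least one segment")
        if not np.isin(states, (0, 1)).all():
            raise ValidationError("IBD states must be 0 or 1")
        if abs(starts[0]) > _TILE_TOL:
            raise ValidationError(
                f"first segment starts at {starts[0]}, expected 0"
            )
        if abs(ends[-1] - self.length) > _TILE_TOL:
            raise ValidationError(
                f"last segment ends at {ends[-1]}, expected chromosome "
                f"length {self.length}"
            )
        if np.any(ends <= starts):
            raise ValidationError("segments must have positive length")
        gaps = starts[1:] - ends[:-1]
        if gaps.size and np.max(np.abs(gaps)) > _TILE_TOL:
            i = int(np.argmax(np.abs(gaps)))
            raise ValidationError(
                f"segments do not tile: gap/overlap of {gaps[i]:g} cM between "
                f"segment ending at {ends[i]:g} and segment starting at "
                f"{starts[i + 1]:g}"
            )
        if np.any(states[1:] == states[:-1]):
            raise ValidationError("adjacent segments must alternate IBD state")

    @property
    def n_segments(self) -> int:
        return int(self.states.size)

    @property
    def total_ibd(self) -> float:
        """Combined length of the IBD1 segments (cM)."""
        keep = self.states == 1
        return float(np.sum((self.ends - self.starts)[keep]))

    @property
    def ibd1_count(self) -> int:
        return int(np.sum(self.states == 1))

    @classmethod
    def from_intervals(
        cls, length: float, bounds: np.ndarray, states: np.ndarray
    ) -> "ChromosomeSegments":
        """Build from raw intervals, merging adjacent runs of equal state.

        ``bounds`` has ``k + 1`` edges for ``k`` intervals with per-interval
        ``states`` (not necessarily alternating).
        """
        bounds = np.asarray(bounds, dtype=float)
        states = np.asarray(states)
        keep = np.concatenate(([True], states[1:] != states[:-1]))
        starts = bounds[:-1][keep]
        ends = np.concatenate((starts[1:], [bounds[-1]]))
        return cls(length, starts, ends, states[keep])


@dataclass(frozen=True)
class IBDSegmentSet:
    """Per-chromosome segment lists for a genome realization."""

    chromosomes: dict[str, ChromosomeSegments] = field(hash=False)

    def __post_init__(self) -> None:
        for label in self.chromosomes:
            if not isinstance(label, str):
                raise ValidationError("chromosome labels must be strings")

    def __len__(self) -> int:
        return len(self.chromosomes)

    def __iter__(self):
        return iter(self.chromosomes.items())

    @property
    def total_ibd(self) -> float:
        """Genome-wide total IBD1 length (cM)."""
        return float(sum(c.total_ibd for c in self.chromosomes.values()))

    @property
    def segment_count(self) -> int:
        """Genome-wide number of IBD1 segments."""
        return int(sum(c.ibd1_count for c in self.chromosomes.values()))

    @property
    def n_chromosomes_without_ibd(self) -> int:
        return sum(1 for c in self.chromosomes.values() if c.ibd1_count == 0)

    def approx_equal(self, other: "IBDSegmentSet", tol: float = 1e-9) -> bool:
        if set(self.chromosomes) != set(other.chromosomes):
            return False
        for label, c in self.chromosomes.items():
            o = other.chromosomes[label]
            if c.n_segments != o.n_segments:
                return False
            if not np.array_equal(c.states, o.states):
                return False
            if np.max(np.abs(c.starts - o.starts), initial=0) > tol:
                return False
            if np.max(np.abs(c.ends - o.ends), initial=0) > tol:
                return False
        return True
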