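"""Genetic maps: ordered autosome lengths in centiMorgan.

The packaged 22-autosome fixture uses lengths proportional to a published
sex-averaged human linkage map, rescaled so the genome totals exactly
3391.36 cM.  A 2-chromosome toy map (100 and 50 cM) is provided for fast
tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ParseError, ValidationError

__all__ = ["GeneticMap", "fixture_map", "toy_map", "read_map", "write_map"]

#: Sex-averaged autosome lengths (cM) before rescaling.
_RAW_LENGTHS = (
    284.0, 269.9, 223.2, 214.5, 204.1, 192.6, 187.1, 168.3, 166.4, 181.7,
    158.2, 174.1, 126.0, 119.4, 141.3, 134.8, 128.7, 117.1, 107.8, 108.2,
    62.9, 74.0,
)

#: Genome total forced by the kappa1 = 1/2 expectation of 1695.68 cM.
FIXTURE_TOTAL_CM = 3391.36


@dataclass(frozen=True)
class GeneticMap:
    """Ordered chromosome labels with genetic lengths in cM."""

    labels: tuple[str, ...]
    lengths: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.lengths):
            raise ValidationError("labels and lengths differ in count")
        if len(self.labels) == 0:
            raise ValidationError("a genetic map needs at least one chromosome")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("duplicate chromosome labels")
        if any(L <= 0 for L in self.lengths):
            raise ValidationError("chromosome lengths must be positive")

    @property
    def total(self) -> float:
        return float(sum(self.lengths))

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(zip(self.labels, self.lengths))

    def length_of(self, label: str) -> float:
        try:
            return self.lengths[self.labels.index(str(label))]
        except ValueError:
            raise ValidationError(f"chromosome {label!r} not in map") from None


def fixture_map() -> GeneticMap:
    """The packaged 22-autosome map, totalling exactly 3391.36 cM."""
    raw = np.asarray(_RAW_LENGTHS)
    scaled = np.round(raw * (FIXTURE_TOTAL_CM / raw.sum()), 2)
    # absorb the rounding residual into chromosome 1 (two-decimal exactness)
    scaled[0] = np.round(scaled[0] + (FIXTURE_TOTAL_CM - scaled.sum()), 2)
    return GeneticMap(
        labels=tuple(str(i) for i in range(1, 23)),
        lengths=tuple(float(x) for x in scaled),
    )


def toy_map() -> GeneticMap:
    """Two chromosomes of 100 and 50 cM for fast tests."""
    return GeneticMap(labels=("1", "2"), lengths=(100.0, 50.0))


def read_map(path: str | Path) -> GeneticMap:
    """Read a tab-delimited map (columns: chromosome, length_cM)."""
    labels: list[str] = []
    lengths: list[float] = []
    text = Path(path).read_text()
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0].lower() in ("chromosome", "chrom", "chr"):
            continue
        if len(fields) < 2:
            raise ParseError(f"{path}:{ln}: expected columns chromosome, length_cM")
        try:
            lengths.append(float(fields[1]))
        except ValueError:
            raise ParseError(f"{path}:{ln}: bad length {fields[1]!r}") from None
        labels.append(fields[0])
    return GeneticMap(tuple(labels), tuple(lengths))


def write_map(gmap: GeneticMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chromosome\tlength_cM\n")
        for label, L in gmap:
            fh.write(f"{label}\t{L!r}\n")
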