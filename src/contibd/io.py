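"""Text formats: segment tables, maps, fixtures, provenance records.

Segment files are tab-delimited with columns ``chromosome``, ``start_cM``,
``end_cM``, ``ibd_state`` and tile each chromosome with alternating
half-open segments.  Full float precision is written by default so that
write/read round-trips are bit-exact; report tables round for display.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import __version__
from .errors import ParseError
from .genmap import fixture_map, toy_map, write_map
from .pedigree import build_relationship
from .segments import ChromosomeSegments, IBDSegmentSet
from .simulate import simulate_ibd

__all__ = [
    "read_segments",
    "write_segments",
    "generate_fixtures",
    "write_provenance",
]

_HEADER = ("chromosome", "start_cM", "end_cM", "ibd_state")


def write_segments(
    segs: IBDSegmentSet, path: str | Path, precision: int | None = None
) -> None:
    """Write a segment set as TSV; ``precision=None`` keeps full precision."""

    def fmt(x: float) -> str:
        return repr(float(x)) if precision is None else f"{x:.{precision}f}"

    with open(path, "w") as fh:
        fh.write("\t".join(_HEADER) + "\n")
        for label, chrom in segs:
            for s, e, x in zip(chrom.starts, chrom.ends, chrom.states):
                fh.write(f"{label}\t{fmt(s)}\t{fmt(e)}\t{int(x)}\n")


def read_segments(path: str | Path) -> IBDSegmentSet:
    """Read and validate a segment TSV (tiling and alternation enforced).

    An empty file yields an empty segment set, which is distinct from a
    genome of all-IBD0 segments.
    """
    rows: dict[str, list[tuple[float, float, int]]] = {}
    text = Path(path).read_text()
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if [f.lower() for f in fields[:4]] == [h.lower() for h in _HEADER]:
            continue
        if len(fields) < 4:
            raise ParseError(
                f"{path}:{ln}: expected 4 tab-separated columns "
                "(chromosome, start_cM, end_cM, ibd_state)"
            )
        try:
            start, end = float(fields[1]), float(fields[2])
            state = int(fields[3])
        except ValueError as exc:
            raise ParseError(f"{path}:{ln}: {exc}") from None
        rows.setdefault(fields[0], []).append((start, end, state))
    chroms: dict[str, ChromosomeSegments] = {}
    for label, segs in rows.items():
        segs.sort(key=lambda r: r[0])
        starts = np.array([r[0] for r in segs])
        ends = np.array([r[1] for r in segs])
        states = np.array([r[2] for r in segs])
        chroms[label] = ChromosomeSegments(float(ends[-1]), starts, ends, states)
    return IBDSegmentSet(chroms)


def generate_fixtures(outdir: str | Path, seed: int = 0) -> list[Path]:
    """Write the packaged maps and example segment sets for GP/HS/N/1C."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, gmap in (("map_autosomes.tsv", fixture_map()),
                       ("map_toy.tsv", toy_map())):
        p = outdir / name
        write_map(gmap, p)
        written.append(p)
    for tok in ("GP", "HS", "N", "1C"):
        ped = build_relationship(tok)
        segs = simulate_ibd(ped, fixture_map(), seed)
        p = outdir / f"segments_{tok}.tsv"
        write_segments(segs, p)
        written.append(p)
    return written


def write_provenance(path: str | Path, config: dict) -> Path:
    """Write a provenance record (config, seed, versions) next to an output."""
    out = Path(str(path) + ".prov.json")
    record = {
        "contibd": __version__,
        "numpy": np.__version__,
        "config": {k: v for k, v in sorted(config.items())},
    }
    out.write_text(json.dumps(record, indent=2, default=str) + "\n")
    return out
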