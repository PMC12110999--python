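"""Two-person pedigree relationships and IBD evaluation by founder-label dropping.

A pedigree pair is represented by a :class:`Pedigree` holding the members,
parent links and the ordered target pair ``(a, b)``.  Each non-founder
contributes two meioses; a binary *IBD vector* assigns one transmission bit
per meiosis (0 = paternal/grandpaternal haplotype of the parent, 1 =
maternal/grandmaternal).  Dropping two distinct haplotype labels per founder
through the pedigree under a given vector determines how many founder
haplotypes the target pair shares at a locus: 0, 1 or 2.

Only relationships whose IBD2 probability is zero are accepted (the binary
IBD0/IBD1 observation model); full siblings are rejected.

Meiosis bit order (frozen): meioses are sorted by (index of the child in the
member list, paternal before maternal), and bit ``i`` of an integer-coded
vector ``v`` is ``(v >> i) & 1``.  Integer state codes depend on this
convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np

from .errors import CapacityError, ParseError, ValidationError

__all__ = [
    "Pedigree",
    "RelationshipSpec",
    "parse_relationship",
    "build_relationship",
    "build_pedigree",
    "ibd_state",
    "shared_label_count",
    "read_ped",
    "write_ped",
    "MAX_RELEVANT_MEIOSES",
]

#: Hard cap on the number of relevant meioses (reduced state space 2**cap).
MAX_RELEVANT_MEIOSES = 22


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Pedigree:
    """A pedigree with a designated ordered pair of members.

    Parameters
    ----------
    members
        All member identifiers, in a fixed order (parents must precede
        children is *not* required; a topological order is computed).
    parents
        Mapping from non-founder id to ``(father_id, mother_id)``.  Members
        absent from the mapping are founders.
    pair
        The ordered pair ``(a, b)`` whose relatedness is studied.
    label
        Optional display label (canonical relationship abbreviation).
    """

    members: tuple[str, ...]
    parents: dict[str, tuple[str, str]] = field(hash=False)
    pair: tuple[str, str]
    label: str | None = None

    def __post_init__(self) -> None:
        seen = set(self.members)
        if len(seen) != len(self.members):
            raise ValidationError("duplicate member identifiers")
        for child, (fa, mo) in self.parents.items():
            if child not in seen:
                raise ValidationError(f"parent link for unknown member {child!r}")
            for p in (fa, mo):
                if p not in seen:
                    raise ValidationError(
                        f"member {child!r} has parent {p!r} outside the pedigree"
                    )
            if fa == mo:
                raise ValidationError(f"member {child!r} has identical parents")
        for t in self.pair:
            if t not in seen:
                raise ValidationError(f"pair member {t!r} not in pedigree")
        if self.pair[0] == self.pair[1]:
            raise ValidationError("pair must consist of two distinct members")
        self._toposort()  # raises on cycles

    # -- structure ---------------------------------------------------------

    @cached_property
    def founders(self) -> tuple[str, ...]:
        return tuple(m for m in self.members if m not in self.parents)

    @cached_property
    def non_founders(self) -> tuple[str, ...]:
        return tuple(m for m in self.members if m in self.parents)

    @property
    def nnf(self) -> int:
        """Number of non-founders; the vector has ``2 * nnf`` meioses."""
        return len(self.non_founders)

    @property
    def n_meioses(self) -> int:
        return 2 * self.nnf

    @cached_property
    def meioses(self) -> tuple[tuple[str, str], ...]:
        """Ordered meioses as ``(child, parent)`` — the frozen bit order."""
        out: list[tuple[str, str]] = []
        for m in self.members:
            if m in self.parents:
                fa, mo = self.parents[m]
                out.append((m, fa))
                out.append((m, mo))
        return tuple(out)

    def _toposort(self) -> tuple[str, ...]:
        order: list[str] = []
        state: dict[str, int] = {}

        def visit(m: str) -> None:
            st = state.get(m, 0)
            if st == 1:
                raise ValidationError("parent links contain a cycle")
            if st == 2:
                return
            state[m] = 1
            if m in self.parents:
                for p in self.parents[m]:
                    visit(p)
            state[m] = 2
            order.append(m)

        for m in self.members:
            visit(m)
        return tuple(order)

    @cached_property
    def topo_order(self) -> tuple[str, ...]:
        return self._toposort()

    # -- relevant meioses --------------------------------------------------

    @cached_property
    def relevant_meioses(self) -> tuple[int, ...]:
        """Indices of meioses that can affect the pair's IBD state.

        A meiosis ``(child, parent)`` is irrelevant when the parent is a
        founder with a single child in the pedigree: swapping that founder's
        two haplotype labels maps one bit value onto the other without
        changing any sharing status.  All other meioses are retained
        (conservative), so the IBD state is an exact function of the
        retained bits.
        """
        n_children: dict[str, int] = {}
        for child, (fa, mo) in self.parents.items():
            n_children[fa] = n_children.get(fa, 0) + 1
            n_children[mo] = n_children.get(mo, 0) + 1
        out = []
        for i, (child, parent) in enumerate(self.meioses):
            if parent in self.parents or n_children.get(parent, 0) >= 2:
                out.append(i)
        return tuple(out)

    # -- label dropping ----------------------------------------------------

    @cached_property
    def _meiosis_index(self) -> dict[tuple[str, str], int]:
        return {mei: i for i, mei in enumerate(self.meioses)}

    def drop_labels(self, bits) -> dict[str, tuple[int, int]]:
        """Drop founder haplotype labels given per-meiosis bits.

        ``bits`` is indexable by meiosis index; bit 0 selects the parent's
        paternal haplotype, bit 1 the maternal one.  Founder ``k`` (in member
        order) carries labels ``(2k, 2k+1)``.
        """
        meiosis_index = self._meiosis_index
        labels: dict[str, tuple[int, int]] = {}
        fcount = 0
        for m in self.topo_order:
            if m not in self.parents:
                labels[m] = (2 * fcount, 2 * fcount + 1)
                fcount += 1
            else:
                fa, mo = self.parents[m]
                bp = bits[meiosis_index[(m, fa)]]
                bm = bits[meiosis_index[(m, mo)]]
                labels[m] = (labels[fa][bp], labels[mo][bm])
        return labels

    def shared_label_count(self, v) -> int:
        """Number of founder haplotype labels shared by the pair under ``v``."""
        bits = _as_bits(v, self.n_meioses)
        labels = self.drop_labels(bits)
        a, b = self.pair
        return len(set(labels[a]) & set(labels[b]))

    # -- reduced IBD lookup table -----------------------------------------

    @cached_property
    def ibd_counts(self) -> np.ndarray:
        """Shared-label count for every vector over the *relevant* meioses.

        Entry ``r`` gives the count for the reduced vector ``r`` (bit ``j``
        of ``r`` is the bit of relevant meiosis ``self.relevant_meioses[j]``;
        irrelevant meioses are fixed to 0, which is exact).
        """
        rel = self.relevant_meioses
        m = len(rel)
        if m > MAX_RELEVANT_MEIOSES:
            raise CapacityError(
                f"{m} relevant meioses exceed the limit of "
                f"{MAX_RELEVANT_MEIOSES} (state space 2**{m})"
            )
        nbits = self.n_meioses
        counts = np.zeros(1 << m, dtype=np.int8)
        bits = [0] * nbits
        for r in range(1 << m):
            for j, idx in enumerate(rel):
                bits[idx] = (r >> j) & 1
            counts[r] = self.shared_label_count(bits)
        return counts

    def validate_pair(self) -> None:
        """Reject pairs with nonzero IBD2 probability (binary model only)."""
        if int(self.ibd_counts.max(initial=0)) >= 2:
            raise ValidationError(
                f"pair {self.pair} has nonzero IBD2 probability; only "
                "IBD0/IBD1 relationships are supported (full siblings and "
                "other IBD2-capable pairs are out of scope)"
            )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        lab = f" {self.label}" if self.label else ""
        return (
            f"<Pedigree{lab} members={len(self.members)} nnf={self.nnf} "
            f"pair={self.pair}>"
        )


def _as_bits(v, n: int) -> list[int]:
    if isinstance(v, (int, np.integer)):
        if v < 0 or v >= (1 << n):
            raise ValidationError(f"vector code {v} out of range for {n} meioses")
        return [(int(v) >> i) & 1 for i in range(n)]
    bits = [int(b) for b in v]
    if len(bits) != n:
        raise ValidationError(
            f"IBD vector has length {len(bits)}, expected {n} (2 x nnf)"
        )
    if any(b not in (0, 1) for b in bits):
        raise ValidationError("IBD vector bits must be 0 or 1")
    return bits


def ibd_state(ped: Pedigree, v) -> int:
    """IBD state (0 or 1) of the pedigree pair under IBD vector ``v``.

    ``v`` may be an integer code or a sequence of ``2 * nnf`` bits.
    Exactly one shared founder haplotype label gives IBD1.
    """
    return 1 if ped.shared_label_count(v) == 1 else 0


def shared_label_count(ped: Pedigree, v) -> int:
    """Shared founder-haplotype label count (0, 1 or 2) under ``v``."""
    return ped.shared_label_count(v)


# ---------------------------------------------------------------------------
# Relationship specifications
# ---------------------------------------------------------------------------

_FAMILIES = (
    "linear",
    "half-sibling",
    "avuncular",
    "half-avuncular",
    "cousin",
    "half-cousin",
)


@dataclass(frozen=True)
class RelationshipSpec:
    """A named two-person relationship.

    ``family`` is one of ``linear`` (degree ``n >= 1``; degree 2 is GP),
    ``half-sibling``, ``avuncular`` / ``half-avuncular`` (``k >= 1``
    generations below the sibling; ``k = 1`` is the uncle–nephew N), and
    ``cousin`` / ``half-cousin`` (``s >= 1`` th cousins, ``t >= 0`` times
    removed).
    """

    family: str
    n: int = 0  # linear degree
    k: int = 0  # avuncular generations below the sibling
    s: int = 0  # cousin order
    t: int = 0  # removal

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ParseError(f"unknown relationship family {self.family!r}")
        if self.family == "linear" and self.n < 1:
            raise ParseError("linear relationships require degree n >= 1")
        if self.family.endswith("avuncular") and self.k < 1:
            raise ParseError("avuncular relationships require k >= 1")
        if self.family.endswith("cousin"):
            if self.s < 1:
                raise ParseError(
                    "cousin relationships require s >= 1; 0th cousins are "
                    "full siblings, whose IBD2-capable states are out of scope"
                )
            if self.t < 0:
                raise ParseError("cousin removal t must be >= 0")

    @property
    def abbreviation(self) -> str:
        """Canonical abbreviation; round-trips through :func:`parse_relationship`."""
        f = self.family
        if f == "linear":
            return {1: "PO", 2: "GP", 3: "GGP"}.get(self.n, f"G{self.n - 2}GP")
        if f == "half-sibling":
            return "HS"
        if f == "avuncular":
            return {1: "N", 2: "GN"}.get(self.k, f"G{self.k - 1}N")
        if f == "half-avuncular":
            return "H" + RelationshipSpec("avuncular", k=self.k).abbreviation
        core = f"{self.s}C" + (f"{self.t}R" if self.t else "")
        return core if f == "cousin" else "H" + core


_LINEAR_RE = re.compile(r"^(?:PO|GP|GGP|G(\d+)GP)$")
_AVUNC_RE = re.compile(r"^(?:N|GN|G(\d+)N)$")
_COUSIN_RE = re.compile(r"^(\d+)C(?:(\d+)R)?$")


def parse_relationship(token: str) -> RelationshipSpec:
    """Parse a relationship abbreviation (GP, G2GP, HS, N, GN, 1C, H1C2R, ...)."""
    tok = token.strip()
    if not tok:
        raise ParseError("empty relationship token")
    if tok.upper() in ("FS", "0C"):
        raise ParseError(
            "full siblings (0th cousins) are rejected: IBD2-capable "
            "states are out of scope"
        )
    t = tok.upper()
    half = False
    if t == "HS":
        return RelationshipSpec("half-sibling")
    if t.startswith("H") and t != "HS":
        half = True
        t = t[1:]
    m = _LINEAR_RE.match(t)
    if m and not half:
        n = {"PO": 1, "GP": 2, "GGP": 3}.get(t, None)
        if n is None:
            n = int(m.group(1)) + 2
        return RelationshipSpec("linear", n=n)
    m = _AVUNC_RE.match(t)
    if m:
        k = {"N": 1, "GN": 2}.get(t, None)
        if k is None:
            k = int(m.group(1)) + 1
        return RelationshipSpec("half-avuncular" if half else "avuncular", k=k)
    m = _COUSIN_RE.match(t)
    if m:
        s = int(m.group(1))
        rem = int(m.group(2)) if m.group(2) else 0
        if s == 0:
            raise ParseError(
                "full siblings (0th cousins) are rejected: IBD2-capable "
                "states are out of scope"
            )
        return RelationshipSpec("half-cousin" if half else "cousin", s=s, t=rem)
    raise ParseError(f"unknown relationship abbreviation {token!r}")


# ---------------------------------------------------------------------------
# Canonical pedigree construction
# ---------------------------------------------------------------------------

def _chain(members, parents, top: str, prefix: str, length: int) -> str:
    """Append a lineage chain of ``length`` members below ``top``; return tip."""
    cur = top
    for i in range(1, length + 1):
        spouse = f"{prefix}sp{i}"
        child = f"{prefix}{i}"
        members += [spouse, child]
        parents[child] = (cur, spouse)
        cur = child
    return cur


def build_relationship(spec: RelationshipSpec | str) -> Pedigree:
    """Build the minimal pedigree realizing a relationship specification.

    The target pair is stored in ``pedigree.pair``; all founders are
    mutually unrelated.  Accepts a :class:`RelationshipSpec` or an
    abbreviation string.
    """
    if isinstance(spec, str):
        spec = parse_relationship(spec)
    members: list[str] = []
    parents: dict[str, tuple[str, str]] = {}
    f = spec.family
    if f == "linear":
        members += ["anc"]
        tip = _chain(members, parents, "anc", "d", spec.n)
        pair = ("anc", tip)
    elif f in ("half-sibling", "half-avuncular", "half-cousin"):
        members += ["p", "qa", "qb", "s1", "s2"]
        parents["s1"] = ("p", "qa")
        parents["s2"] = ("p", "qb")
        pair = _descend(spec, members, parents)
    else:  # avuncular, cousin — full-sibling top couple
        members += ["f", "m", "s1", "s2"]
        parents["s1"] = ("f", "m")
        parents["s2"] = ("f", "m")
        pair = _descend(spec, members, parents)
    ped = Pedigree(
        members=tuple(members),
        parents=parents,
        pair=pair,
        label=spec.abbreviation,
    )
    ped.validate_pair()
    return ped


def _descend(spec, members, parents) -> tuple[str, str]:
    f = spec.family
    if f == "half-sibling":
        return ("s1", "s2")
    if f.endswith("avuncular"):
        tip = _chain(members, parents, "s2", "b", spec.k)
        return ("s1", tip)
    a = _chain(members, parents, "s1", "a", spec.s)
    b = _chain(members, parents, "s2", "b", spec.s + spec.t)
    return (a, b)


def build_pedigree(source: str | Path | RelationshipSpec) -> Pedigree:
    """Build a pedigree from an abbreviation, spec, or PED file path."""
    if isinstance(source, RelationshipSpec):
        return build_relationship(source)
    s = str(source)
    p = Path(s)
    if p.suffix.lower() in (".ped", ".txt", ".tsv") or p.exists():
        raise ValidationError(
            "PED files require a target pair; use read_ped(path, pair=...)"
        )
    return build_relationship(s)


# ---------------------------------------------------------------------------
# PED-like text format
# ---------------------------------------------------------------------------

def read_ped(path: str | Path, pair: tuple[str, str]) -> Pedigree:
    """Read a PED-like file (family, member, father, mother, sex; 0 = founder).

    The target ``pair`` is supplied separately.  The returned pedigree is
    validated for acyclicity and zero IBD2 probability.
    """
    members: list[str] = []
    parents: dict[str, tuple[str, str]] = {}
    text = Path(path).read_text()
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 5:
            raise ParseError(
                f"{path}:{ln}: expected 5 columns "
                "(family, member, father, mother, sex)"
            )
        _, member, father, mother = fields[:4]
        if member in members:
            raise ParseError(f"{path}:{ln}: duplicate member {member!r}")
        members.append(member)
        has_f, has_m = father != "0", mother != "0"
        if has_f != has_m:
            raise ValidationError(
                f"{path}:{ln}: member {member!r} has exactly one parent; "
                "every non-founder needs two parents in the pedigree"
            )
        if has_f:
            parents[member] = (father, mother)
    ped = Pedigree(tuple(members), parents, pair)
    ped.validate_pair()
    return ped


def write_ped(ped: Pedigree, path: str | Path, family: str = "FAM1") -> None:
    """Write a pedigree in the PED-like text format."""
    mothers = {mo for _, (_, mo) in ped.parents.items()}
    with open(path, "w") as fh:
        for m in ped.members:
            fa, mo = ped.parents.get(m, ("0", "0"))
            sex = 2 if m in mothers else (1 if m in {f for _, (f, _) in ped.parents.items()} else 0)
            fh.write(f"{family}\t{m}\t{fa}\t{mo}\t{sex}\n")
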