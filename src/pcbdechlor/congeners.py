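"""PCB congener structures, canonical naming, and chlorine-site classification.

A polychlorinated biphenyl (PCB) congener is a biphenyl carrying 1-10
chlorines at ring positions 2-6 and 2'-6' (carbon 1/1' bears the
inter-ring bond and is never chlorinated).  Congeners are named here in
the per-ring shorthand used throughout the microbial-dechlorination
literature, e.g. ``2345-245-CB``: each ring is written as its sorted
chlorine positions, the more-chlorinated ring first.

Each phenyl ring has a mirror symmetry (2<->6, 3<->5, 4 fixed), so a ring
substitution pattern is represented by the lexicographically smaller of
the two mirror images.  There are exactly 20 canonical ring patterns
(including the unsubstituted ring) and exactly 209 congeners, i.e. the
unordered pairs of canonical rings carrying at least one chlorine.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Iterator

VALID_POSITIONS = frozenset({2, 3, 4, 5, 6})

#: ring mirror symmetry of a 1-substituted phenyl ring
MIRROR = {2: 6, 3: 5, 4: 4, 5: 3, 6: 2}

#: homolog class names indexed by chlorine count 1..10
HOMOLOG_NAMES = (
    "mono", "di", "tri", "tetra", "penta",
    "hexa", "hepta", "octa", "nona", "deca",
)

#: mass of the unsubstituted biphenyl skeleton, g/mol
BIPHENYL_MASS = 154.21
#: per-chlorine H -> Cl substitution increment, g/mol (35.45 - 1.008)
CHLORINE_INCREMENT = 34.44

ORTHO_POSITIONS = frozenset({2, 6})
META_POSITIONS = frozenset({3, 5})
PARA_POSITIONS = frozenset({4})


class CongenerError(ValueError):
    """Malformed congener name or invalid ring substitution pattern."""


def _canonical_tuple(positions: Iterable[int]) -> tuple[int, ...]:
    pos = frozenset(positions)
    bad = pos - VALID_POSITIONS
    if bad:
        raise CongenerError(
            f"invalid ring position(s) {sorted(bad)}: must be within 2-6"
        )
    direct = tuple(sorted(pos))
    mirrored = tuple(sorted(MIRROR[p] for p in pos))
    return min(direct, mirrored)


@dataclass(frozen=True, order=True)
class RingPattern:
    """Canonical chlorine substitution pattern on one phenyl ring.

    ``positions`` is the mirror-minimal sorted tuple of chlorinated
    positions; the empty tuple is the unsubstituted ring.
    """

    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", _canonical_tuple(self.positions))

    @property
    def n_chlorines(self) -> int:
        return len(self.positions)

    def __contains__(self, position: int) -> bool:
        return position in self.positions

    def __str__(self) -> str:
        return "".join(str(p) for p in self.positions)

    def mirror_image(self) -> tuple[int, ...]:
        """The sorted mirror image of the stored (canonical) positions."""
        return tuple(sorted(MIRROR[p] for p in self.positions))

    def remove(self, position: int) -> "RingPattern":
        """Pattern with one chlorine removed (re-canonicalized)."""
        if position not in self.positions:
            raise CongenerError(
                f"position {position} is not chlorinated on ring '{self}'"
            )
        return RingPattern(tuple(p for p in self.positions if p != position))


def canonicalize_ring(positions: Iterable[int]) -> RingPattern:
    """Return the mirror-minimal canonical form of a ring pattern.

    Idempotent: canonicalizing a canonical pattern is a no-op.
    """
    return RingPattern(tuple(positions))


@lru_cache(maxsize=1)
def all_ring_patterns() -> tuple[RingPattern, ...]:
    """All 20 canonical ring patterns, sorted by (chlorine count, positions)."""
    seen = set()
    for r in range(6):
        for combo in itertools.combinations(sorted(VALID_POSITIONS), r):
            seen.add(RingPattern(combo))
    return tuple(sorted(seen, key=lambda rp: (rp.n_chlorines, rp.positions)))


def _ring_sort_key(ring: RingPattern) -> tuple[int, tuple[int, ...]]:
    # more chlorines first; ties broken by the smaller position string,
    # matching printed names such as 24-25-CB and 235-245-CB
    return (-ring.n_chlorines, ring.positions)


@dataclass(frozen=True, order=True)
class Congener:
    """A PCB congener: an unordered pair of canonical ring patterns.

    Rings are stored in canonical order (more chlorines first, then the
    numerically smaller position string), so two congeners are equal iff
    their names are equal.
    """

    ring_a: RingPattern
    ring_b: RingPattern

    def __post_init__(self) -> None:
        a, b = sorted((self.ring_a, self.ring_b), key=_ring_sort_key)
        if a.n_chlorines + b.n_chlorines == 0:
            raise CongenerError("a congener must carry at least one chlorine")
        object.__setattr__(self, "ring_a", a)
        object.__setattr__(self, "ring_b", b)

    @property
    def rings(self) -> tuple[RingPattern, RingPattern]:
        return (self.ring_a, self.ring_b)

    @property
    def n_chlorines(self) -> int:
        return self.ring_a.n_chlorines + self.ring_b.n_chlorines

    @property
    def homolog(self) -> str:
        return HOMOLOG_NAMES[self.n_chlorines - 1]

    @property
    def name(self) -> str:
        if self.ring_b.n_chlorines == 0:
            return f"{self.ring_a}-CB"
        return f"{self.ring_a}-{self.ring_b}-CB"

    def __str__(self) -> str:
        return self.name

    def replace_ring(self, ring_index: int, new_ring: RingPattern) -> "Congener":
        """Congener with the ring at ``ring_index`` (0 or 1) replaced."""
        if ring_index == 0:
            return Congener(new_ring, self.ring_b)
        if ring_index == 1:
            return Congener(self.ring_a, new_ring)
        raise IndexError(f"ring_index must be 0 or 1, got {ring_index}")


_NAME_RE = re.compile(r"^(\d+)(?:-(\d+))?-CB$")


def parse_congener(name: str) -> Congener:
    """Parse a congener name such as ``2345-245-CB`` or ``2345-CB``.

    Parsing then re-rendering any valid printed name yields the same
    string.  Raises :class:`CongenerError` naming the offending token on
    malformed input.
    """
    m = _NAME_RE.match(name.strip())
    if not m:
        raise CongenerError(
            f"malformed congener name {name!r}: expected "
            "'<digits>-<digits>-CB' or '<digits>-CB' with digits in 2-6"
        )
    rings = []
    for token in m.groups():
        if token is None:
            rings.append(RingPattern(()))
            continue
        digits = [int(ch) for ch in token]
        bad = [d for d in digits if d not in VALID_POSITIONS]
        if bad:
            raise CongenerError(
                f"ring token {token!r} in {name!r}: position(s) {bad} "
                "outside 2-6 (carbon 1 bears the biphenyl bond)"
            )
        if len(set(digits)) != len(digits):
            raise CongenerError(
                f"ring token {token!r} in {name!r}: duplicate positions"
            )
        rings.append(RingPattern(tuple(digits)))
    return Congener(rings[0], rings[1])


@lru_cache(maxsize=1)
def enumerate_all_congeners() -> tuple[Congener, ...]:
    """All 209 distinct PCB congeners, each exactly once.

    Ordered by (chlorine count, name) for deterministic iteration.
    Partitioning by homolog gives the standard counts
    mono 3, di 12, tri 24, tetra 42, penta 46, hexa 42, hepta 24,
    octa 12, nona 3, deca 1.
    """
    rings = all_ring_patterns()
    out = set()
    for i, a in enumerate(rings):
        for b in rings[i:]:
            if a.n_chlorines + b.n_chlorines >= 1:
                out.add(Congener(a, b))
    return tuple(sorted(out, key=lambda c: (c.n_chlorines, c.name)))


def congeners_of_homolog(homolog: str) -> tuple[Congener, ...]:
    """All congeners of one homolog class (``"mono"`` ... ``"deca"``)."""
    if homolog not in HOMOLOG_NAMES:
        raise CongenerError(
            f"unknown homolog {homolog!r}; expected one of {HOMOLOG_NAMES}"
        )
    return tuple(c for c in enumerate_all_congeners() if c.homolog == homolog)


@dataclass(frozen=True)
class ChlorineSite:
    """One chlorine on a congener with its positional and flanking class.

    ``position_class`` is ortho (2,6), meta (3,5) or para (4) relative to
    the inter-ring bond.  A chlorine is flanked by a chlorinated neighbor
    at an adjacent ring position within 2-6 (carbon 1 never flanks), so
    position 2 can only be flanked by 3, position 6 only by 5, and only
    positions 3, 4, 5 can be doubly flanked.
    """

    congener: Congener
    ring_index: int
    position: int
    position_class: str  # "ortho" | "meta" | "para"
    flanking: str  # "unflanked" | "singly_flanked" | "doubly_flanked"


def position_class(position: int) -> str:
    if position in ORTHO_POSITIONS:
        return "ortho"
    if position in META_POSITIONS:
        return "meta"
    if position in PARA_POSITIONS:
        return "para"
    raise CongenerError(f"position {position} outside 2-6")


def flanking_of(ring: RingPattern, position: int) -> str:
    """Flanking class of a chlorine at ``position`` on ``ring``."""
    if position not in ring:
        raise CongenerError(f"position {position} not chlorinated on '{ring}'")
    neighbors = [p for p in (position - 1, position + 1) if p in VALID_POSITIONS]
    n = sum(1 for p in neighbors if p in ring)
    return ("unflanked", "singly_flanked", "doubly_flanked")[n]


def classify_chlorines(c: Congener) -> list[ChlorineSite]:
    """One :class:`ChlorineSite` per chlorine of ``c``, ring 0 then ring 1."""
    sites = []
    for ring_index, ring in enumerate(c.rings):
        for p in ring.positions:
            sites.append(
                ChlorineSite(
                    congener=c,
                    ring_index=ring_index,
                    position=p,
                    position_class=position_class(p),
                    flanking=flanking_of(ring, p),
                )
            )
    return sites


def molecular_weight(c: Congener) -> float:
    """Molecular weight in g/mol: biphenyl skeleton plus H->Cl increments."""
    return round(BIPHENYL_MASS + c.n_chlorines * CHLORINE_INCREMENT, 2)


def homolog_molecular_weight(n_chlorines: int) -> float:
    """Molecular weight shared by every congener of one homolog class."""
    if not 1 <= n_chlorines <= 10:
        raise CongenerError(f"chlorine count {n_chlorines} outside 1-10")
    return round(BIPHENYL_MASS + n_chlorines * CHLORINE_INCREMENT, 2)
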