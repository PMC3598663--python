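"""Declarative microbial dechlorination rule sets and single-step application.

Anaerobic PCB dechlorination removes one chlorine at a time from one
phenyl ring.  Field and microcosm studies classify the observed activity
into named "processes" by which chlorine classes are removed from which
ring motifs: Process H removes flanked para- and doubly flanked
meta-chlorines (rings 34, 234, 245, 2345); Process N removes flanked
meta-chlorines; Process T removes the doubly flanked meta-chlorine of
2345 rings only.  CG1 is the novel pattern of an enrichment culture that
mainly removes doubly flanked meta-chlorines and partially para- and
ortho-chlorines.

A rule set is ring-local: a rule names a substrate ring pattern and the
position removed; the product ring is derived, never stored.  Rule sets
are either *strict* (only the evidenced transformations) or *generic*
(a structural predicate over all rings; available for Process N).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

from .congeners import (
    Congener,
    CongenerError,
    META_POSITIONS,
    RingPattern,
    VALID_POSITIONS,
    canonicalize_ring,
)


class RuleError(ValueError):
    """Invalid or inapplicable dechlorination rule."""


#: default rate/weight multiplier for "partial" (minor) transformations
PARTIAL_WEIGHT = 0.2


@dataclass(frozen=True, order=True)
class DechlorRule:
    """Removal of one chlorine from one ring pattern.

    ``weight`` is a relative kinetic multiplier (1.0 for the main
    transformations of a process, :data:`PARTIAL_WEIGHT` for the ones a
    culture performs only partially).
    """

    substrate: RingPattern
    removed_position: int
    tag: str = ""
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.removed_position not in self.substrate:
            raise RuleError(
                f"removed position {self.removed_position} is not "
                f"chlorinated on substrate ring '{self.substrate}'"
            )
        if self.weight < 0:
            raise RuleError(f"rule weight must be >= 0, got {self.weight}")

    @property
    def product(self) -> RingPattern:
        """Product ring pattern, canonicalized."""
        return self.substrate.remove(self.removed_position)

    def __str__(self) -> str:
        return (
            f"{self.substrate}-{self.removed_position}->{self.product}"
            + (f" [{self.tag}]" if self.tag else "")
        )


def _flanked_meta(ring: RingPattern, position: int) -> bool:
    """True for a meta chlorine with at least one chlorinated neighbor."""
    if position not in META_POSITIONS or position not in ring:
        return False
    neighbors = [p for p in (position - 1, position + 1) if p in VALID_POSITIONS]
    return any(p in ring for p in neighbors)


#: structural predicates available to generic-mode rule sets
GENERIC_PREDICATES: dict[str, Callable[[RingPattern, int], bool]] = {
    "flanked_meta": _flanked_meta,
}


@dataclass(frozen=True)
class ProcessRuleSet:
    """Named collection of dechlorination rules.

    In ``strict`` mode only the listed rules apply.  In ``generic`` mode
    rules are generated on the fly from a registered structural
    predicate, which over-generates relative to the evidenced lists and
    is intended for exploration.
    """

    name: str
    rules: tuple[DechlorRule, ...] = ()
    mode: str = "strict"  # "strict" | "generic"
    predicate: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("strict", "generic"):
            raise RuleError(f"unknown mode {self.mode!r}")
        if self.mode == "generic" and self.predicate not in GENERIC_PREDICATES:
            raise RuleError(
                f"generic mode requires a registered predicate, "
                f"got {self.predicate!r}"
            )

    def rules_for_ring(self, ring: RingPattern) -> tuple[DechlorRule, ...]:
        """Rules of this set whose substrate matches ``ring``."""
        if self.mode == "generic":
            pred = GENERIC_PREDICATES[self.predicate]
            return tuple(
                DechlorRule(ring, p, tag=f"generic {self.predicate}")
                for p in ring.positions
                if pred(ring, p)
            )
        return tuple(r for r in self.rules if r.substrate == ring)

    def product_rings(self, ring: RingPattern) -> set[RingPattern]:
        return {r.product for r in self.rules_for_ring(ring)}


def _r(substrate: str, position: int, tag: str, weight: float = 1.0) -> DechlorRule:
    ring = canonicalize_ring(int(ch) for ch in substrate)
    return DechlorRule(ring, position, tag=tag, weight=weight)


_BUILTINS: dict[str, ProcessRuleSet] = {
    "H": ProcessRuleSet(
        name="H",
        rules=(
            _r("34", 4, "flanked para"),
            _r("234", 3, "doubly flanked meta"),
            _r("245", 4, "flanked para"),
            _r("2345", 4, "doubly flanked para"),
            _r("2345", 3, "doubly flanked meta"),
        ),
        description=(
            "Process H: removes flanked para- and doubly flanked "
            "meta-chlorines from rings 34, 234, 245 and 2345"
        ),
    ),
    "N": ProcessRuleSet(
        name="N",
        rules=(
            _r("234", 3, "flanked meta"),
            _r("235", 3, "flanked meta"),
            _r("236", 3, "flanked meta"),
            _r("245", 5, "flanked meta"),
            _r("2345", 3, "flanked meta"),
            _r("2345", 5, "flanked meta"),
        ),
        description=(
            "Process N: removes flanked meta-chlorines (rings 234, 235, "
            "236, 245, 2345)"
        ),
    ),
    "T": ProcessRuleSet(
        name="T",
        rules=(_r("2345", 3, "doubly flanked meta"),),
        description=(
            "Process T: removes the doubly flanked meta-chlorine of "
            "2345 rings only"
        ),
    ),
    "CG1": ProcessRuleSet(
        name="CG1",
        rules=(
            _r("234", 3, "doubly flanked meta"),
            _r("2345", 3, "doubly flanked meta"),
            _r("2345", 4, "partial para", PARTIAL_WEIGHT),
            _r("234", 2, "partial ortho", PARTIAL_WEIGHT),
        ),
        description=(
            "Culture CG-1 pattern: mainly doubly flanked meta-chlorines, "
            "partially para- and ortho-chlorines of 234/2345 rings"
        ),
    ),
}

BUILTIN_PROCESS_NAMES = tuple(sorted(_BUILTINS))


def builtin_process(name: str, mode: str = "strict") -> ProcessRuleSet:
    """Return a built-in rule set (``H``, ``N``, ``T`` or ``CG1``).

    ``mode="generic"`` is available for Process N only, replacing the
    evidenced list with the flanked-meta structural predicate.
    """
    key = name.upper().replace("-", "")
    if key not in _BUILTINS:
        raise RuleError(
            f"unknown process {name!r}; built-ins are {BUILTIN_PROCESS_NAMES}"
        )
    rs = _BUILTINS[key]
    if mode == "strict":
        return rs
    if mode == "generic":
        if key != "N":
            raise RuleError(f"generic mode is only defined for Process N, not {name!r}")
        return ProcessRuleSet(
            name="N",
            rules=rs.rules,
            mode="generic",
            predicate="flanked_meta",
            description="Process N (generic): remove any flanked meta-chlorine",
        )
    raise RuleError(f"unknown mode {mode!r}")


def applicable_rules(
    c: Congener, rs: ProcessRuleSet
) -> list[tuple[int, DechlorRule]]:
    """All (ring_index, rule) pairs of ``rs`` applicable to ``c``.

    An empty list means ``c`` is terminal under ``rs``.  Symmetric
    congeners list each rule once per ring (two equivalent sites).
    """
    out: list[tuple[int, DechlorRule]] = []
    for ring_index, ring in enumerate(c.rings):
        for rule in rs.rules_for_ring(ring):
            out.append((ring_index, rule))
    return out


def apply_rule(c: Congener, ring_index: int, rule: DechlorRule) -> Congener:
    """Apply one dechlorination rule; the product has one chlorine fewer."""
    ring = c.rings[ring_index]
    if rule.substrate != ring:
        raise RuleError(
            f"rule {rule} does not apply to ring {ring_index} "
            f"('{ring}') of {c.name}"
        )
    return c.replace_ring(ring_index, rule.product)


def write_ruleset(rs: ProcessRuleSet, path: str | Path) -> None:
    """Export a strict rule set as tab-separated text.

    One rule per line: ``substrate_ring<TAB>removed_position<TAB>tag<TAB>weight``.
    The product ring is derived on read, never stored.
    """
    lines = [f"# process: {rs.name}"]
    if rs.description:
        lines.append(f"# {rs.description}")
    for r in rs.rules:
        lines.append(f"{r.substrate}\t{r.removed_position}\t{r.tag}\t{r.weight:g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ruleset(path: str | Path, name: str | None = None) -> ProcessRuleSet:
    """Read a strict rule set from the tab-separated format."""
    path = Path(path)
    rules: list[DechlorRule] = []
    rs_name = name or path.stem
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            if line.startswith("# process:") and name is None:
                rs_name = line.split(":", 1)[1].strip()
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise RuleError(f"{path}:{lineno}: expected at least 2 tab-separated fields")
        substrate, pos = parts[0], parts[1]
        tag = parts[2] if len(parts) > 2 else ""
        weight = float(parts[3]) if len(parts) > 3 else 1.0
        try:
            ring = canonicalize_ring(int(ch) for ch in substrate)
            rules.append(DechlorRule(ring, int(pos), tag=tag, weight=weight))
        except (ValueError, CongenerError, RuleError) as exc:
            raise RuleError(f"{path}:{lineno}: {exc}") from exc
    return ProcessRuleSet(name=rs_name, rules=tuple(rules))
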