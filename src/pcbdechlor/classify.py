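"""Attribute an observed congener-profile change to a dechlorination process.

Field studies assign a culture's activity to a named dechlorination
process by inspecting which congeners were lost and which products
appeared.  This module formalizes that pattern-matching as an
explained-fraction score: for a candidate rule set P,

* a *decreased* congener is explained if at least one rule of P applies
  to it (P can attack it), and
* an *increased* congener is explained if it is reachable under P, in
  one or more steps, from some decreased congener.

The two fractions — weighted by |delta mol%| (``mole`` weighting) or by
counts (``unit`` weighting, for published loss/gain lists) — are
combined (by default, their unweighted mean) and candidates are ranked.
The score is a formalization of expert inspection, so every verdict
carries per-congener witness paths that can be audited directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .congeners import Congener, parse_congener
from .pathways import reachable
from .profiles import (
    CongenerProfile,
    DEFAULT_CHANGE_THRESHOLD,
    ProfileError,
    delta_profile,
)
from .rules import DechlorRule, ProcessRuleSet, applicable_rules


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class LossRecord:
    """Why one decreased congener is (or is not) attackable by a process."""

    congener: Congener
    weight: float
    explained: bool
    rules: tuple[DechlorRule, ...]


@dataclass(frozen=True)
class GainRecord:
    """Which decreased congener, via which path, explains one product."""

    congener: Congener
    weight: float
    explained: bool
    source: Congener | None
    path: tuple[Congener, ...] | None


@dataclass(frozen=True)
class ProcessScore:
    """Explained-fraction score of one candidate process."""

    process: str
    explained_loss_fraction: float
    explained_gain_fraction: float | None
    combined: float
    loss_records: tuple[LossRecord, ...]
    gain_records: tuple[GainRecord, ...]


@dataclass(frozen=True)
class ClassificationResult:
    """Ranked process scores with winner(s) and audit records."""

    scores: tuple[ProcessScore, ...]
    threshold: float
    weighting: str
    combine: str
    no_classification: bool = False

    @property
    def winner(self) -> str | None:
        if self.no_classification or not self.scores:
            return None
        return self.scores[0].process

    @property
    def tie(self) -> bool:
        if len(self.scores) < 2:
            return False
        return abs(self.scores[0].combined - self.scores[1].combined) < 1e-12

    def score_for(self, process: str) -> ProcessScore:
        for s in self.scores:
            if s.process == process:
                return s
        raise KeyError(process)

    def summary(self) -> str:
        """Human-readable ranking table with per-congener witnesses."""
        if self.no_classification:
            return (
                "No classification: no congener changed beyond "
                f"{self.threshold} mol%."
            )
        lines = [
            "Dechlorination process classification",
            f"  weighting={self.weighting}  combine={self.combine}  "
            f"threshold={self.threshold} mol%",
            "",
            f"{'process':<8}{'loss expl.':>12}{'gain expl.':>12}{'combined':>12}",
        ]
        for s in self.scores:
            gain = "-" if s.explained_gain_fraction is None else (
                f"{s.explained_gain_fraction:.3f}"
            )
            lines.append(
                f"{s.process:<8}{s.explained_loss_fraction:>12.3f}"
                f"{gain:>12}{s.combined:>12.3f}"
            )
        top = self.scores[0]
        lines.append("")
        flag = " (tie)" if self.tie else ""
        lines.append(f"winner: {top.process}{flag}")
        for rec in top.gain_records:
            if rec.explained and rec.path:
                route = " -> ".join(c.name for c in rec.path)
                lines.append(f"  {rec.congener.name}: {route}")
            else:
                lines.append(
                    f"  {rec.congener.name}: NOT explained by {top.process}"
                )
        return "\n".join(lines)


def _as_congener(c: "Congener | str") -> Congener:
    return c if isinstance(c, Congener) else parse_congener(c)


def explain_congener(
    gained: "Congener | str",
    losses: "set[Congener] | list | tuple | dict",
    rs: ProcessRuleSet,
) -> list[tuple[Congener, tuple[Congener, ...]]]:
    """All (loss, shortest witness path) pairs explaining one product.

    Sorted with the shortest paths first; empty if no decreased congener
    reaches the product under ``rs``.
    """
    g = _as_congener(gained)
    out = []
    for loss in losses:
        src = _as_congener(loss)
        if src == g:
            continue
        ok, path = reachable(src, g, rs)
        if ok:
            out.append((src, tuple(path)))
    out.sort(key=lambda item: (len(item[1]), item[0].name))
    return out


def _normalize_changes(
    changes: "dict | list | tuple | set",
) -> dict[Congener, float]:
    if isinstance(changes, dict):
        return {_as_congener(k): float(v) for k, v in changes.items()}
    return {_as_congener(k): 1.0 for k in changes}


def classify_profile_change(
    before: CongenerProfile | None = None,
    after: CongenerProfile | None = None,
    *,
    losses: "dict | list | None" = None,
    gains: "dict | list | None" = None,
    candidates: list[ProcessRuleSet],
    threshold: float = DEFAULT_CHANGE_THRESHOLD,
    weighting: str = "mole",
    combine: str = "mean",
) -> ClassificationResult:
    """Rank candidate processes by how well they explain a profile change.

    Input is either a before/after profile pair (losses and gains are the
    congeners whose mol% changed by at least ``threshold``) or explicit
    loss/gain lists as published in screening tables.  ``weighting``
    is ``mole`` (|delta mol%|) or ``unit`` (each congener counts once);
    explicit lists without magnitudes imply unit weighting.  ``combine``
    is ``mean`` (default), ``harmonic`` or ``gain_only``.
    """
    if not candidates:
        raise ClassificationError("no candidate rule sets supplied")
    if weighting not in ("mole", "unit"):
        raise ClassificationError(f"unknown weighting {weighting!r}")
    if combine not in ("mean", "harmonic", "gain_only"):
        raise ClassificationError(f"unknown combine mode {combine!r}")

    if before is not None or after is not None:
        if before is None or after is None:
            raise ClassificationError("both before and after profiles required")
        before.require_congener_level("classification")
        after.require_congener_level("classification")
        delta = delta_profile(before, after, threshold=threshold)
        loss_w = _normalize_changes(delta.losses())
        gain_w = _normalize_changes(delta.gains())
    elif losses is not None:
        loss_w = _normalize_changes(losses)
        gain_w = _normalize_changes(gains or [])
    else:
        raise ClassificationError(
            "supply either before/after profiles or losses/gains lists"
        )

    if weighting == "unit":
        loss_w = {k: 1.0 for k in loss_w}
        gain_w = {k: 1.0 for k in gain_w}

    if not loss_w:
        return ClassificationResult(
            scores=(), threshold=threshold, weighting=weighting,
            combine=combine, no_classification=True,
        )

    scores = []
    for rs in candidates:
        loss_records = []
        for c, w in sorted(loss_w.items(), key=lambda kv: kv[0].name):
            rules = tuple(rule for _, rule in applicable_rules(c, rs))
            loss_records.append(
                LossRecord(congener=c, weight=w, explained=bool(rules),
                           rules=rules)
            )
        gain_records = []
        for c, w in sorted(gain_w.items(), key=lambda kv: kv[0].name):
            witnesses = explain_congener(c, loss_w, rs)
            if witnesses:
                src, path = witnesses[0]
                gain_records.append(
                    GainRecord(congener=c, weight=w, explained=True,
                               source=src, path=path)
                )
            else:
                gain_records.append(
                    GainRecord(congener=c, weight=w, explained=False,
                               source=None, path=None)
                )
        loss_total = sum(r.weight for r in loss_records)
        loss_frac = (
            sum(r.weight for r in loss_records if r.explained) / loss_total
        )
        if gain_records:
            gain_total = sum(r.weight for r in gain_records)
            gain_frac = (
                sum(r.weight for r in gain_records if r.explained) / gain_total
            )
        else:
            gain_frac = None

        if gain_frac is None:
            combined = loss_frac if combine != "gain_only" else 0.0
        elif combine == "mean":
            combined = 0.5 * (loss_frac + gain_frac)
        elif combine == "harmonic":
            combined = (
                0.0
                if loss_frac + gain_frac == 0
                else 2 * loss_frac * gain_frac / (loss_frac + gain_frac)
            )
        else:  # gain_only
            combined = gain_frac

        scores.append(
            ProcessScore(
                process=rs.name,
                explained_loss_fraction=loss_frac,
                explained_gain_fraction=gain_frac,
                combined=combined,
                loss_records=tuple(loss_records),
                gain_records=tuple(gain_records),
            )
        )

    scores.sort(key=lambda s: (-s.combined, s.process))
    return ClassificationResult(
        scores=tuple(scores),
        threshold=threshold,
        weighting=weighting,
        combine=combine,
    )
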