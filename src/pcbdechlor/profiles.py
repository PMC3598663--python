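"""Mixture profile arithmetic for congener-resolved PCB data.

A :class:`CongenerProfile` is the unit of all table arithmetic: a map
from congener (or homolog pseudo-congener) to percent of total PCBs,
summing to 100 within a small ingest tolerance, optionally annotated
with the total PCB concentration in µM (1 µM of PCB carrying n
chlorines holds n nmol/mL of organic chlorine).

Profiles may be congener-level (keys are canonical congener names) or
homolog-level (keys are homolog class names such as ``hexa``), since
published homolog distributions are often the only quantitative data.
Structure-aware operations (pathways, classification) reject
homolog-level profiles; purely mass-balance operations (homolog
distribution, mean chlorines, chlorine removal) accept both.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

from .congeners import (
    CongenerError,
    HOMOLOG_NAMES,
    homolog_molecular_weight,
    molecular_weight,
    parse_congener,
)

#: tolerated drift of a profile's percent sum away from 100 (rounding in
#: published tables)
SUM_TOLERANCE = 0.5

#: default mol% change threshold separating real congener losses/gains
#: from noise, as used for microcosm screening tables
DEFAULT_CHANGE_THRESHOLD = 2.0

#: nominal total PCB concentration of the study cultures, µM (30 ppm)
DEFAULT_TOTAL_UM = 81.0


class ProfileError(ValueError):
    """Invalid profile contents, units or combination of profiles."""


def _normalize_homolog_key(key: str) -> str | None:
    k = key.strip().lower()
    if k.endswith("-cb"):
        k = k[:-3]
    return k if k in HOMOLOG_NAMES else None


def _entry_n_chlorines(key: str, level: str) -> int:
    if level == "homolog":
        return HOMOLOG_NAMES.index(key) + 1
    return parse_congener(key).n_chlorines


@dataclass(frozen=True)
class CongenerProfile:
    """Mapping congener -> percent of total PCBs.

    ``unit`` is ``mol_percent`` (the default working unit) or
    ``weight_percent`` (raw GC quantitation; convert with
    :func:`weight_to_mol` before mole arithmetic).
    """

    entries: dict[str, float]
    unit: str = "mol_percent"
    total_um: float | None = None
    label: str = ""
    level: str = field(init=False, default="congener")

    def __post_init__(self) -> None:
        if self.unit not in ("mol_percent", "weight_percent"):
            raise ProfileError(f"unknown unit {self.unit!r}")
        if not self.entries:
            raise ProfileError("profile has no entries")
        canon: dict[str, float] = {}
        homolog_keys = 0
        for key, value in self.entries.items():
            if value < 0:
                raise ProfileError(f"negative fraction for {key!r}: {value}")
            h = _normalize_homolog_key(key)
            if h is not None:
                canon[h] = canon.get(h, 0.0) + float(value)
                homolog_keys += 1
            else:
                name = parse_congener(key).name
                if name in canon:
                    raise ProfileError(f"duplicate congener {name!r}")
                canon[name] = float(value)
        if 0 < homolog_keys < len(self.entries):
            raise ProfileError("profile mixes congener and homolog entries")
        total = sum(canon.values())
        if abs(total - 100.0) > SUM_TOLERANCE:
            raise ProfileError(
                f"profile percentages sum to {total:.4f}, "
                f"outside 100 +/- {SUM_TOLERANCE}"
            )
        object.__setattr__(self, "entries", canon)
        object.__setattr__(
            self, "level", "homolog" if homolog_keys else "congener"
        )

    def require_congener_level(self, operation: str) -> None:
        if self.level != "congener":
            raise ProfileError(
                f"{operation} requires a congener-level profile; "
                f"{self.label or 'profile'} is homolog-level"
            )

    def require_mol(self, operation: str) -> None:
        if self.unit != "mol_percent":
            raise ProfileError(
                f"{operation} requires mol_percent; convert weight-percent "
                "profiles with weight_to_mol first"
            )

    def renormalized(self) -> "CongenerProfile":
        """Explicitly rescale entries to sum to exactly 100."""
        total = sum(self.entries.values())
        return replace(
            self,
            entries={k: v * 100.0 / total for k, v in self.entries.items()},
        )

    def mean_chlorines(self) -> float:
        """Average number of chlorines per biphenyl (mole-weighted)."""
        self.require_mol("mean_chlorines")
        total = sum(self.entries.values())
        return (
            sum(
                _entry_n_chlorines(k, self.level) * v
                for k, v in self.entries.items()
            )
            / total
        )


@dataclass(frozen=True)
class HomologDistribution:
    """Mol% of total PCBs per homolog class, and mean chlorines per biphenyl."""

    mol_percent: dict[str, float]
    mean_chlorines: float

    def __getitem__(self, homolog: str) -> float:
        return self.mol_percent.get(homolog, 0.0)


def homolog_profile(
    mol_percent_by_homolog: dict[str, float],
    total_um: float | None = None,
    label: str = "",
) -> CongenerProfile:
    """Build a homolog-level profile from e.g. a published homolog table."""
    return CongenerProfile(
        entries=dict(mol_percent_by_homolog),
        unit="mol_percent",
        total_um=total_um,
        label=label,
    )


def weight_to_mol(
    weights: "CongenerProfile | dict[str, float]",
    total_um: float | None = None,
    label: str = "",
) -> CongenerProfile:
    """Convert weight-percent quantitation to mole percent.

    mol%_i = (w_i / MW_i) / sum_j (w_j / MW_j) * 100, where MW depends
    only on the chlorine count.
    """
    if isinstance(weights, CongenerProfile):
        prof = weights
    else:
        prof = CongenerProfile(
            entries=dict(weights), unit="weight_percent",
            total_um=total_um, label=label,
        )
    moles = {
        k: v / homolog_molecular_weight(_entry_n_chlorines(k, prof.level))
        for k, v in prof.entries.items()
    }
    total = sum(moles.values())
    return CongenerProfile(
        entries={k: m * 100.0 / total for k, m in moles.items()},
        unit="mol_percent",
        total_um=total_um if total_um is not None else prof.total_um,
        label=label or prof.label,
    )


def mol_to_weight(p: CongenerProfile) -> CongenerProfile:
    """Inverse of :func:`weight_to_mol` (weights recovered to float precision)."""
    p.require_mol("mol_to_weight")
    masses = {
        k: v * homolog_molecular_weight(_entry_n_chlorines(k, p.level))
        for k, v in p.entries.items()
    }
    total = sum(masses.values())
    return CongenerProfile(
        entries={k: m * 100.0 / total for k, m in masses.items()},
        unit="weight_percent",
        total_um=p.total_um,
        label=p.label,
    )


def homolog_distribution(p: CongenerProfile) -> HomologDistribution:
    """Per-homolog mol% sums and the mean chlorines per biphenyl."""
    p.require_mol("homolog_distribution")
    sums: dict[str, float] = {}
    for key, value in p.entries.items():
        n = _entry_n_chlorines(key, p.level)
        h = HOMOLOG_NAMES[n - 1]
        sums[h] = sums.get(h, 0.0) + value
    ordered = {h: sums[h] for h in HOMOLOG_NAMES if h in sums}
    return HomologDistribution(
        mol_percent=ordered, mean_chlorines=p.mean_chlorines()
    )


@dataclass(frozen=True)
class DeltaProfile:
    """Signed per-congener and per-homolog mol% changes (after - before)."""

    per_congener: dict[str, float]
    per_homolog: dict[str, float]
    threshold: float
    decreased: tuple[str, ...]
    increased: tuple[str, ...]
    unchanged: tuple[str, ...]

    def losses(self) -> dict[str, float]:
        """Decreased congeners mapped to the magnitude of their loss."""
        return {k: -self.per_congener[k] for k in self.decreased}

    def gains(self) -> dict[str, float]:
        """Increased congeners mapped to the magnitude of their gain."""
        return {k: self.per_congener[k] for k in self.increased}


def delta_profile(
    before: CongenerProfile,
    after: CongenerProfile,
    threshold: float = DEFAULT_CHANGE_THRESHOLD,
) -> DeltaProfile:
    """Signed changes between two profiles of the same unit and level.

    Congeners are partitioned into decreased / increased / unchanged by
    comparing |delta| with ``threshold`` (default 2 mol%, the screening
    convention separating real losses/gains from noise).
    """
    if before.unit != after.unit:
        raise ProfileError(
            f"unit mismatch: {before.unit} vs {after.unit}"
        )
    if before.level != after.level:
        raise ProfileError(
            f"level mismatch: {before.level} vs {after.level}"
        )
    keys = sorted(set(before.entries) | set(after.entries))
    per_congener = {
        k: after.entries.get(k, 0.0) - before.entries.get(k, 0.0) for k in keys
    }
    per_homolog: dict[str, float] = {}
    for k, d in per_congener.items():
        h = HOMOLOG_NAMES[_entry_n_chlorines(k, before.level) - 1]
        per_homolog[h] = per_homolog.get(h, 0.0) + d
    per_homolog = {h: per_homolog[h] for h in HOMOLOG_NAMES if h in per_homolog}
    decreased = tuple(
        sorted((k for k, d in per_congener.items() if d <= -threshold),
               key=lambda k: per_congener[k])
    )
    increased = tuple(
        sorted((k for k, d in per_congener.items() if d >= threshold),
               key=lambda k: -per_congener[k])
    )
    unchanged = tuple(
        k for k in keys if k not in decreased and k not in increased
    )
    return DeltaProfile(
        per_congener=per_congener,
        per_homolog=per_homolog,
        threshold=threshold,
        decreased=decreased,
        increased=increased,
        unchanged=unchanged,
    )


def percent_decrease_by_homolog(
    before: HomologDistribution, after: HomologDistribution
) -> dict[str, float]:
    """100 * (before - after) / before per homolog class.

    Homologs that increased (dechlorination products) get no entry;
    homologs absent from the "before" distribution are omitted with a
    warning (division by zero).
    """
    out: dict[str, float] = {}
    for h in HOMOLOG_NAMES:
        b = before[h]
        a = after[h]
        if b == 0.0:
            if a > 0.0:
                warnings.warn(
                    f"homolog {h!r} absent before incubation; "
                    "% decrease undefined, omitted",
                    stacklevel=2,
                )
            continue
        if a > b:
            continue
        out[h] = 100.0 * (b - a) / b
    return out


def chlorine_removal(
    before: CongenerProfile, after: CongenerProfile
) -> float:
    """Organic chlorine removed between two profiles, nmol per mL.

    (mean chlorines before - mean chlorines after) x total concentration
    in µM; 1 µM of removable chlorine is 1 nmol/mL.  Depends only on the
    homolog marginals, never on within-homolog composition.
    """
    if before.total_um is None or after.total_um is None:
        raise ProfileError(
            "chlorine_removal requires total_um on both profiles"
        )
    if not math.isclose(before.total_um, after.total_um):
        raise ProfileError(
            f"total PCB concentrations differ: "
            f"{before.total_um} vs {after.total_um} µM"
        )
    return (before.mean_chlorines() - after.mean_chlorines()) * before.total_um


@dataclass(frozen=True)
class GrowthYield:
    """Dechlorinator growth normalized to chlorine released."""

    cell_growth: float  # cells per mL
    chlorine_removed: float  # nmol per mL
    yield_cells_per_mol: float  # cells per mole chlorine


def growth_yield(cells_grown: float, cl_removed: float) -> GrowthYield:
    """Cells produced per mole of chlorine released.

    ``cells_grown`` in cells/mL, ``cl_removed`` in nmol/mL; zero growth
    yields zero, but zero or negative chlorine removal is an error.
    """
    if cl_removed <= 0:
        raise ProfileError(
            f"chlorine removal must be positive, got {cl_removed} nmol/mL"
        )
    if cells_grown < 0:
        raise ProfileError(f"negative cell growth: {cells_grown}")
    return GrowthYield(
        cell_growth=cells_grown,
        chlorine_removed=cl_removed,
        yield_cells_per_mol=cells_grown / (cl_removed * 1e-9),
    )
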