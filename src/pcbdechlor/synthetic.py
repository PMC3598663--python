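"""Synthetic Aroclor-1260-like data: mixtures, noisy dechlorinated
replicates, and growth/chlorine-release series.

The generator emulates the measured inputs of a sediment-free
dechlorination experiment so every pipeline stage is testable without
chromatography data:

* a congener-level mixture whose homolog marginals equal, by
  construction, the published control homolog distribution of weathered
  Aroclor 1260 (hexa 47.75 mol%, hepta 36.26 mol%, ...), with the named
  dominant hepta/hexa congeners carrying most of their homolog's mass
  and the remainder spread by a seeded Dirichlet draw;
* replicate profiles after simulated dechlorination, perturbed by
  zero-mean Gaussian measurement noise scaled so homolog-level standard
  deviations match the published replicate SDs;
* paired (chlorine removed, cell count) observations at a configurable
  growth yield (cells per mole of chlorine released).

All randomness flows through explicit seeds; identical seeds give
identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .congeners import HOMOLOG_NAMES, congeners_of_homolog, parse_congener
from .kinetics import DEFAULT_RATES, RateAssignment, SimulationResult, simulate
from .profiles import CongenerProfile, DEFAULT_TOTAL_UM, ProfileError
from .rules import ProcessRuleSet

#: control (undechlorinated) homolog distribution of the study's
#: weathered Aroclor 1260, mol% of total PCBs
AROCLOR1260_CONTROL_HOMOLOGS: dict[str, float] = {
    "tri": 0.07,
    "tetra": 0.21,
    "penta": 9.63,
    "hexa": 47.75,
    "hepta": 36.26,
    "octa": 5.51,
    "nona": 0.57,
}

#: homolog distribution after three months of extensive (Process N)
#: dechlorination of the same mixture
DECHLORINATED_CG5_HOMOLOGS: dict[str, float] = {
    "tri": 1.18,
    "tetra": 26.93,
    "penta": 21.20,
    "hexa": 19.52,
    "hepta": 25.22,
    "octa": 5.39,
    "nona": 0.56,
}

#: replicate standard deviations of the dechlorinated homolog
#: distribution (triplicate cultures), mol%
REPLICATE_HOMOLOG_SD: dict[str, float] = {
    "tri": 0.47,
    "tetra": 1.54,
    "penta": 1.89,
    "hexa": 2.10,
    "hepta": 1.33,
    "octa": 0.06,
    "nona": 0.01,
}

#: congeners dominating Aroclor 1260's hepta and hexa homologs
DOMINANT_CONGENERS: dict[str, tuple[str, ...]] = {
    "hepta": ("2345-245-CB", "2345-236-CB", "2356-234-CB", "2345-234-CB"),
    "hexa": ("245-245-CB", "236-245-CB", "234-245-CB", "234-236-CB",
             "2345-25-CB"),
}

#: average dechlorinator growth yield, cells per mole of chlorine released
DEFAULT_YIELD_CELLS_PER_MOL = 3.30e14


@dataclass(frozen=True)
class MixtureSpec:
    """Recipe for an Aroclor-1260-like congener-level mixture.

    ``dominant_share`` is the fraction of each homolog's mass split
    evenly over its named dominant congeners (the four dominant hexa-CBs
    of the real mixture hold ~72% of total hexa); the remainder is
    allocated by a Dirichlet(1) draw over the homolog's other congeners.
    """

    homolog_mol_percent: Mapping[str, float] = field(
        default_factory=lambda: dict(AROCLOR1260_CONTROL_HOMOLOGS)
    )
    dominant_congeners: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DOMINANT_CONGENERS.items()}
    )
    dominant_share: float = 0.70
    total_um: float = DEFAULT_TOTAL_UM
    seed: int = 0
    label: str = "synthetic Aroclor 1260"


@dataclass(frozen=True)
class NoiseSpec:
    """Replicate measurement-noise model at the homolog SD scale."""

    homolog_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(REPLICATE_HOMOLOG_SD)
    )
    n_replicates: int = 3
    seed: int = 0


def generate_mixture(
    spec: MixtureSpec = MixtureSpec(), seed: int | None = None
) -> CongenerProfile:
    """Congener-level mixture whose homolog marginals equal ``spec`` exactly.

    Reproducible: the same spec and seed give an identical profile.
    """
    targets = {h: float(v) for h, v in spec.homolog_mol_percent.items() if v > 0}
    total = sum(targets.values())
    if abs(total - 100.0) > 0.5:
        raise ProfileError(
            f"homolog targets sum to {total:.4f}, outside 100 +/- 0.5"
        )
    if not 0.0 <= spec.dominant_share <= 1.0:
        raise ProfileError(f"dominant_share outside [0,1]: {spec.dominant_share}")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    entries: dict[str, float] = {}
    for homolog in HOMOLOG_NAMES:  # fixed iteration order for determinism
        if homolog not in targets:
            continue
        target = targets[homolog]
        members = [c.name for c in congeners_of_homolog(homolog)]
        dominants = [
            parse_congener(d).name
            for d in spec.dominant_congeners.get(homolog, ())
        ]
        for d in dominants:
            if d not in members:
                raise ProfileError(
                    f"dominant congener {d} is not a {homolog}-CB"
                )
        others = [m for m in members if m not in dominants]
        if dominants:
            dom_mass = target * spec.dominant_share
            for d in dominants:
                entries[d] = dom_mass / len(dominants)
            rest = target - dom_mass
        else:
            rest = target
        if others and rest > 0:
            shares = rng.dirichlet(np.ones(len(others)))
            for name, s in zip(others, shares):
                entries[name] = entries.get(name, 0.0) + rest * s
        elif rest > 0:
            # no non-dominant congeners exist (e.g. deca); put the rest
            # back on the dominants evenly
            for d in dominants:
                entries[d] += rest / len(dominants)
    return CongenerProfile(
        entries=entries,
        unit="mol_percent",
        total_um=spec.total_um,
        label=spec.label,
    )


def generate_dechlorinated_replicates(
    initial: CongenerProfile,
    rs: ProcessRuleSet,
    rates: RateAssignment = DEFAULT_RATES,
    t: float = 3.0,
    noise: NoiseSpec = NoiseSpec(),
    seed: int | None = None,
) -> list[CongenerProfile]:
    """Simulate dechlorination, then emit noisy replicate profiles.

    Noise is applied post-simulation (measurement noise, not process
    noise): each homolog class draws one zero-mean Gaussian perturbation
    with the homolog-level replicate SD sigma_h, allocated over its
    detected congeners in proportion to their abundance (so the homolog
    sum has SD exactly sigma_h and trace congeners are perturbed on
    their own scale rather than swamped).  Profiles are clipped at zero
    and renormalized to 100.
    """
    sim = simulate(initial, rs, rates=rates, times=[0.0, t])
    base = sim.final
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    detected = {k: v for k, v in base.entries.items() if v > 0}
    by_homolog: dict[str, list[str]] = {}
    for name in sorted(detected):
        by_homolog.setdefault(parse_congener(name).homolog, []).append(name)
    replicates = []
    for _ in range(noise.n_replicates):
        entries = dict(detected)
        for h in HOMOLOG_NAMES:  # fixed order for determinism
            if h not in by_homolog:
                continue
            sd_h = float(noise.homolog_sd.get(h, 0.0))
            if sd_h <= 0:
                continue
            members = by_homolog[h]
            total_h = sum(detected[m] for m in members)
            delta = rng.normal(0.0, sd_h)
            for m in members:
                entries[m] = max(
                    detected[m] * (1.0 + delta / total_h), 0.0
                )
        total = sum(entries.values())
        entries = {k: v * 100.0 / total for k, v in entries.items()}
        replicates.append(
            CongenerProfile(
                entries=entries,
                unit="mol_percent",
                total_um=base.total_um,
                label=f"{initial.label} replicate".strip(),
            )
        )
    return replicates


def generate_growth_series(
    cl_removed_series: Sequence[float],
    yield_cells_per_mol: float = DEFAULT_YIELD_CELLS_PER_MOL,
    noise_fraction: float = 0.0,
    seed: int | None = None,
) -> list[tuple[float, float]]:
    """Paired (chlorine removed nmol/mL, cells/mL) observations.

    cells = yield x mol chlorine removed x (1 + eps), with eps drawn
    from N(0, noise_fraction).  With zero noise, dividing cells by moles
    of chlorine recovers the input yield exactly.
    """
    if yield_cells_per_mol <= 0:
        raise ProfileError(f"growth yield must be > 0: {yield_cells_per_mol}")
    rng = np.random.default_rng(seed)
    out = []
    for cl in cl_removed_series:
        if cl < 0:
            raise ProfileError(f"negative chlorine removal: {cl}")
        cells = yield_cells_per_mol * cl * 1e-9
        if noise_fraction > 0:
            cells *= 1.0 + rng.normal(0.0, noise_fraction)
        out.append((float(cl), max(float(cells), 0.0)))
    return out
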