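"""Broken-stick planting design and enumeration of subsampling combinations.

The experiment plants a pool of 16 tree species in plots whose communities
come from recursively halving the pool: 16 monocultures, 8 two-species
plots, 4 four-species plots, 2 eight-species plots and 1 sixteen-species
plot (31 plots).  For analysis, plots are pooled into three diversity
classes (monoculture, two-species, "high" = 4/8/16), and the analysis runs
over all subsampling combinations of 7 tree species with 7 sampling cells
(one species sampled per plot) at each class.

Enumeration is driven by the two-species level: every choice of 7 of the 8
two-species plots together with one planted species per chosen plot defines
the 7 species; monoculture cells are then forced, and the high-diversity
cells come from a deterministic perfect matching of species to high plots.
With no exclusions the full design yields 8 x 2^7 = 1024 combinations; with
one species excluded it yields 576.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from typing import Iterable, Sequence

from .io_tables import SampleRecord, ValidationError

__all__ = [
    "DiversityClass",
    "PlotDesign",
    "SubsampleCombination",
    "build_design",
    "enumerate_combinations",
    "match_high_plots",
    "InfeasibleMatching",
]

logger = logging.getLogger(__name__)


class DiversityClass(str, Enum):
    """Tree diversity class; HIGH aggregates richness 4, 8 and 16."""

    MONO = "MONO"
    TWO = "TWO"
    HIGH = "HIGH"

    @classmethod
    def from_richness(cls, richness: int) -> "DiversityClass":
        if richness == 1:
            return cls.MONO
        if richness == 2:
            return cls.TWO
        if richness in (4, 8, 16):
            return cls.HIGH
        raise ValueError(f"no diversity class for richness {richness}")

    @property
    def order(self) -> int:
        return {"MONO": 0, "TWO": 1, "HIGH": 2}[self.value]

    def __lt__(self, other: object) -> bool:  # type: ignore[override]
        if isinstance(other, DiversityClass):
            return self.order < other.order
        return NotImplemented


@dataclass(frozen=True)
class PlotDesign:
    """One plot: its id and the set of tree species planted in it."""

    plot_id: str
    species_set: frozenset[str]

    @property
    def richness(self) -> int:
        return len(self.species_set)

    @property
    def diversity_class(self) -> DiversityClass:
        return DiversityClass.from_richness(self.richness)


@dataclass(frozen=True)
class SubsampleCombination:
    """One choice of 7 species with 7 (plot, species) cells per class."""

    combination_id: int
    species: tuple[str, ...]
    cells: dict  # DiversityClass -> tuple[(plot_id, species), ...]

    def cells_at(self, level: DiversityClass) -> tuple[tuple[str, str], ...]:
        return self.cells[level]


class InfeasibleMatching(Exception):
    """No perfect matching of species to high-diversity plots exists."""


def build_design(metadata: Sequence[SampleRecord]) -> list[PlotDesign]:
    """Derive the plot design from sample metadata.

    The species set of a plot is the set of species sampled there; the
    declared plot_richness column must agree with the observed species count.
    """
    if not metadata:
        raise ValidationError("metadata is empty")
    species: dict[str, set[str]] = {}
    declared: dict[str, int] = {}
    order: list[str] = []
    for rec in metadata:
        if rec.plot_id not in species:
            species[rec.plot_id] = set()
            order.append(rec.plot_id)
        species[rec.plot_id].add(rec.tree_species)
        prev = declared.setdefault(rec.plot_id, rec.plot_richness)
        if prev != rec.plot_richness:
            raise ValidationError(
                f"plot {rec.plot_id!r} has conflicting declared richness "
                f"{prev} vs {rec.plot_richness}"
            )
    plots = []
    for pid in order:
        if len(species[pid]) != declared[pid]:
            raise ValidationError(
                f"plot {pid!r}: declared richness {declared[pid]} but "
                f"{len(species[pid])} species observed"
            )
        plots.append(PlotDesign(pid, frozenset(species[pid])))
    return plots


def validate_broken_stick(design: Sequence[PlotDesign]) -> None:
    """Check that each richness level's species sets partition the pool."""
    pool = frozenset().union(*(p.species_set for p in design))
    by_richness: dict[int, list[PlotDesign]] = {}
    for p in design:
        by_richness.setdefault(p.richness, []).append(p)
    for r, plots in by_richness.items():
        seen: set[str] = set()
        for p in plots:
            if seen & p.species_set:
                raise ValidationError(
                    f"richness-{r} plots overlap in species {seen & p.species_set}"
                )
            seen |= p.species_set
        if seen != pool:
            raise ValidationError(
                f"richness-{r} plots cover {len(seen)} of {len(pool)} species"
            )


def _lex_smallest_perfect_matching(
    species: Sequence[str],
    candidates: dict[str, list[str]],
    plot_ids: Sequence[str],
) -> list[tuple[str, str]] | None:
    """Lexicographically smallest perfect matching under (species order,
    sorted plot id), via greedy fixing with a feasibility check."""

    def feasible(assigned: dict[str, str], remaining: list[str]) -> bool:
        # augmenting-path maximum matching on the residual problem
        used = set(assigned.values())
        match: dict[str, str] = {}  # plot -> species

        def try_assign(sp: str, visited: set[str]) -> bool:
            for pl in candidates[sp]:
                if pl in used or pl in visited:
                    continue
                visited.add(pl)
                if pl not in match or try_assign(match[pl], visited):
                    match[pl] = sp
                    return True
            return False

        return all(try_assign(sp, set()) for sp in remaining)

    assigned: dict[str, str] = {}
    for i, sp in enumerate(species):
        rest = list(species[i + 1:])
        placed = False
        for pl in candidates[sp]:
            if pl in assigned.values():
                continue
            assigned[sp] = pl
            if feasible(assigned, rest):
                placed = True
                break
            del assigned[sp]
        if not placed:
            return None
    return [(assigned[sp], sp) for sp in species]


def match_high_plots(
    species: Sequence[str], high_plots: Sequence[PlotDesign]
) -> list[tuple[str, str]]:
    """Assign each species a distinct high-diversity plot that contains it.

    Returns the lexicographically smallest perfect matching under the given
    species order with plot ids tried in sorted order; raises
    :class:`InfeasibleMatching` if none exists.
    """
    plot_ids = sorted(p.plot_id for p in high_plots)
    by_id = {p.plot_id: p for p in high_plots}
    candidates = {
        sp: [pid for pid in plot_ids if sp in by_id[pid].species_set]
        for sp in species
    }
    result = _lex_smallest_perfect_matching(species, candidates, plot_ids)
    if result is None:
        raise InfeasibleMatching(
            f"no perfect matching of {list(species)} to high plots"
        )
    return result


def enumerate_combinations(
    design: Sequence[PlotDesign],
    excluded_species: Iterable[str] = (),
    n_cells: int = 7,
) -> list[SubsampleCombination]:
    """Enumerate all subsampling combinations of the design.

    All choices of ``n_cells`` of the two-species plots and one planted
    species per chosen plot are generated; choices containing an excluded
    species are discarded.  Monoculture cells are the chosen species' (unique)
    monoculture plots; high-diversity cells come from
    :func:`match_high_plots`.  Output is sorted lexicographically by
    (chosen plot ids, chosen species) and indexed from 0; fully deterministic.
    """
    validate_broken_stick(design)
    excluded = set(excluded_species)
    pool = frozenset().union(*(p.species_set for p in design))
    unknown = excluded - pool
    if unknown:
        raise ValidationError(f"excluded species not in the pool: {sorted(unknown)}")
    if len(excluded) > 9:
        raise ValidationError("at most 9 species may be excluded")

    two_plots = sorted(
        (p for p in design if p.diversity_class is DiversityClass.TWO),
        key=lambda p: p.plot_id,
    )
    mono_plot = {
        next(iter(p.species_set)): p.plot_id
        for p in design
        if p.diversity_class is DiversityClass.MONO
    }
    high_plots = [p for p in design if p.diversity_class is DiversityClass.HIGH]
    if len(two_plots) < n_cells or len(high_plots) < n_cells:
        raise ValidationError(
            f"need at least {n_cells} two-species and high-diversity plots"
        )

    combos: list[SubsampleCombination] = []
    n_infeasible = 0
    for plot_subset in combinations(two_plots, n_cells):
        # one planted, non-excluded species per chosen two-species plot
        per_plot_choices = [
            sorted(p.species_set - excluded) for p in plot_subset
        ]
        if any(not c for c in per_plot_choices):
            continue

        def emit(idx: int, chosen: list[str]) -> None:
            nonlocal n_infeasible
            if idx == len(plot_subset):
                species = tuple(chosen)
                try:
                    high_cells = tuple(match_high_plots(species, high_plots))
                except InfeasibleMatching:
                    n_infeasible += 1
                    return
                mono_cells = tuple((mono_plot[sp], sp) for sp in species)
                two_cells = tuple(
                    (p.plot_id, sp) for p, sp in zip(plot_subset, species)
                )
                combos.append(
                    SubsampleCombination(
                        combination_id=-1,
                        species=species,
                        cells={
                            DiversityClass.MONO: mono_cells,
                            DiversityClass.TWO: two_cells,
                            DiversityClass.HIGH: high_cells,
                        },
                    )
                )
                return
            for sp in per_plot_choices[idx]:
                emit(idx + 1, chosen + [sp])

        emit(0, [])

    if n_infeasible:
        logger.info("%d species choices discarded (no high-plot matching)",
                    n_infeasible)
    combos.sort(
        key=lambda c: (
            tuple(pid for pid, _ in c.cells[DiversityClass.TWO]),
            c.species,
        )
    )
    return [
        SubsampleCombination(i, c.species, c.cells) for i, c in enumerate(combos)
    ]
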