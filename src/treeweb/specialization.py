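"""Phi-coefficient specialization analysis of fungal OTUs.

For each subsampling combination and diversity class, every OTU gets a phi
association coefficient with each of the 7 tree species, computed from the
2x2 table of plot-level presence/absence over the combination's 7 plots:

    phi = (a d - b c) / sqrt((a+b)(c+d)(a+c)(b+d))

where a is the OTU's presence (0/1) in the plot assigned to the focal
species, b its presences among the other 6 plots, c = 1 - a and d = 6 - b.
Phi lies in [-1, 1]; it is undefined (and excluded) when a margin is zero,
i.e. when the OTU occurs in none or in all 7 plots.  Downstream summaries:
the median of positive phi values per combination, Kruskal-Wallis contrasts
between functional guilds, a ranked matrix of the top specialists ordered
by hierarchical clustering, and the frequent-OTU classification (an OTU is
frequent at a level if some combination has it in all 7 plots).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .design import DiversityClass, SubsampleCombination
from .io_tables import CountTable, GuildMap
from .stats import PairwiseComparison, kruskal_posthoc, kruskal_wallis

__all__ = [
    "ContingencyCounts",
    "PhiRecord",
    "phi_coefficient",
    "phi_table",
    "median_positive_phi",
    "group_phi_comparison",
    "GroupPhiReport",
    "rank_specialists",
    "accumulate_max_phi",
    "rank_specialists_from_max",
    "frequent_otus",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyCounts:
    """2x2 occurrence table: a, b, c, d cell counts."""

    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.n < 1:
            raise ValueError("empty contingency table")


@dataclass(frozen=True)
class PhiRecord:
    otu_id: str
    tree_species: str
    combination_id: int
    level: DiversityClass
    phi: float | None  # None marks an undefined (zero-margin) coefficient


def phi_coefficient(t: ContingencyCounts) -> float | None:
    """Phi association coefficient of a 2x2 table, or None if a margin is zero.

    Equals sign(ad - bc) * sqrt(X^2 / N) where X^2 is the table's chi-square
    statistic.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    m1, m2, m3, m4 = a + b, c + d, a + c, b + d
    if min(m1, m2, m3, m4) == 0:
        return None
    return (a * d - b * c) / np.sqrt(float(m1) * m2 * m3 * m4)


def _plot_presence(
    incidence: CountTable,
    combo: SubsampleCombination,
    level: DiversityClass,
    sample_index: Mapping[tuple[str, str], Sequence[str]],
    min_samples_present: int = 1,
) -> np.ndarray:
    """(n_plots x n_otus) binary matrix of plot-level presence.

    A plot counts as occupied when the OTU is present in at least
    ``min_samples_present`` of the cell's 5 samples.
    """
    rows = []
    for plot_id, species in combo.cells_at(level):
        sids = sample_index.get((plot_id, species))
        if not sids:
            raise ValueError(f"no samples for cell ({plot_id!r}, {species!r})")
        cols = [incidence.sample_index(s) for s in sids]
        present = (incidence.counts[:, cols] > 0).sum(axis=1)
        rows.append(present >= min_samples_present)
    return np.array(rows)


def phi_table(
    incidence: CountTable,
    combo: SubsampleCombination,
    level: DiversityClass,
    sample_index: Mapping[tuple[str, str], Sequence[str]],
    min_samples_present: int = 1,
) -> list[PhiRecord]:
    """Phi records for every (present OTU, tree species) at one level.

    Only OTUs present in at least one of the combination's plots are
    scored; an OTU present in all plots has a zero margin and its phi is
    recorded as undefined (None).
    """
    pres = _plot_presence(incidence, combo, level, sample_index,
                          min_samples_present)
    n_plots = pres.shape[0]
    occ = pres.sum(axis=0)  # plots occupied per OTU
    records: list[PhiRecord] = []
    cells = combo.cells_at(level)
    for k, otu in enumerate(incidence.otu_ids):
        if occ[k] == 0:
            continue
        for p_idx, (_, species) in enumerate(cells):
            a = int(pres[p_idx, k])
            b = int(occ[k]) - a
            c = 1 - a
            d = (n_plots - 1) - b
            phi = phi_coefficient(ContingencyCounts(a, b, c, d))
            records.append(
                PhiRecord(otu, species, combo.combination_id, level, phi)
            )
    return records


def median_positive_phi(records: Sequence[PhiRecord]) -> float | None:
    """Median of the defined, strictly positive phi values; None if none."""
    pos = [r.phi for r in records if r.phi is not None and r.phi > 0]
    if not pos:
        return None
    return float(np.median(pos))


@dataclass
class GroupPhiReport:
    groups: list[str]
    n_per_group: list[int]
    h: float
    p: float
    posthoc: list[PairwiseComparison]


def group_phi_comparison(
    records: Sequence[PhiRecord],
    guilds: GuildMap,
    strata: Mapping[str, str] | None = None,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    min_group_size: int = 1,
) -> GroupPhiReport:
    """Kruskal-Wallis contrast of positive phi values between guilds.

    ``strata`` optionally maps tree species to a stratum label (e.g. tree
    mycorrhizal type); when given, only records whose species is in the
    mapping are used and group labels become "guild|stratum".
    """
    grouped: dict[str, list[float]] = {}
    for r in records:
        if r.phi is None or r.phi <= 0:
            continue
        label = guilds[r.otu_id]
        if strata is not None:
            if r.tree_species not in strata:
                continue
            label = f"{label}|{strata[r.tree_species]}"
        grouped.setdefault(label, []).append(r.phi)
    grouped = {g: v for g, v in grouped.items() if len(v) >= min_group_size}
    if len(grouped) < 2:
        raise ValueError("need at least two guild groups with positive phi")
    names = sorted(grouped)
    values = [grouped[g] for g in names]
    h, p = kruskal_wallis(values)
    posthoc = kruskal_posthoc(values, alpha=alpha, correction=correction)
    return GroupPhiReport(names, [len(v) for v in values], h, p, posthoc)


def accumulate_max_phi(
    records: Sequence[PhiRecord], agg: dict[tuple[str, str], float]
) -> dict[tuple[str, str], float]:
    """Fold phi records into a running (otu, species) -> max-phi map."""
    for r in records:
        if r.phi is None:
            continue
        key = (r.otu_id, r.tree_species)
        if key not in agg or r.phi > agg[key]:
            agg[key] = r.phi
    return agg


def rank_specialists_from_max(
    max_phi: Mapping[tuple[str, str], float], top_n: int = 200
) -> tuple[list[str], list[str], np.ndarray]:
    """Ranking/clustering step of :func:`rank_specialists` from an
    already-aggregated (otu, species) -> max-phi map."""
    if not max_phi:
        raise ValueError("no phi values")
    species = sorted({s for _, s in max_phi})
    sp_idx = {s: i for i, s in enumerate(species)}
    best: dict[str, float] = {}
    per_species: dict[str, np.ndarray] = {}
    for (otu, sp), v in max_phi.items():
        row = per_species.setdefault(otu, np.full(len(species), -np.inf))
        j = sp_idx[sp]
        row[j] = max(row[j], v)
        best[otu] = max(best.get(otu, -np.inf), v)
    ranked = sorted(best, key=lambda o: (-best[o], o))[:top_n]
    mat = np.array([np.where(np.isfinite(per_species[o]), per_species[o], 0.0)
                    for o in ranked])
    if len(ranked) > 2:
        order = leaves_list(linkage(pdist(mat), method="average"))
    else:
        order = np.arange(len(ranked))
    return [ranked[i] for i in order], species, mat[order]


def rank_specialists(
    records: Sequence[PhiRecord], top_n: int = 200
) -> tuple[list[str], list[str], np.ndarray]:
    """Top specialists and their per-species maximum phi matrix.

    Each OTU is scored by its maximum defined phi over all species and
    combinations; the ``top_n`` highest-scoring OTUs (ties broken by OTU
    id) form the rows of an OTU x species matrix of per-species maximum
    phi (0 where never defined), ordered by average-linkage hierarchical
    clustering on Euclidean row distances.

    Returns (ordered OTU ids, species order, matrix in that order).
    """
    if not records:
        raise ValueError("no phi records")
    return rank_specialists_from_max(accumulate_max_phi(records, {}), top_n)


def frequent_otus(
    incidence: CountTable,
    combos: Sequence[SubsampleCombination],
    levels: Sequence[DiversityClass],
    sample_index: Mapping[tuple[str, str], Sequence[str]],
    min_samples_present: int = 1,
) -> dict:
    """Classify OTUs as frequent per diversity level.

    An OTU is frequent at a level if at least one combination has it
    present in all of that combination's plots.  Returns a dict with:
    ``frequent`` (level -> sorted OTU ids), ``all_levels`` (OTUs frequent
    at every requested level), ``unique`` (OTUs frequent at exactly one
    level), and ``occupancy`` (level -> OTU -> histogram over 1..n_plots
    plot-occupancy across combinations, for the unique-frequent OTUs).
    """
    if not combos:
        raise ValueError("no combinations")
    n_otus = len(incidence.otu_ids)
    frequent: dict[DiversityClass, set[str]] = {lv: set() for lv in levels}
    occ_hist: dict[DiversityClass, np.ndarray] = {}
    n_plots = len(combos[0].cells_at(levels[0]))
    for lv in levels:
        hist = np.zeros((n_otus, n_plots + 1), dtype=np.int64)
        for combo in combos:
            pres = _plot_presence(incidence, combo, lv, sample_index,
                                  min_samples_present)
            occ = pres.sum(axis=0)
            hist[np.arange(n_otus), occ] += 1
            full = occ == pres.shape[0]
            frequent[lv].update(
                o for o, f in zip(incidence.otu_ids, full) if f
            )
        occ_hist[lv] = hist
    sets = [frequent[lv] for lv in levels]
    all_levels = sorted(set.intersection(*sets)) if sets else []
    membership: dict[str, list[DiversityClass]] = {}
    for lv in levels:
        for o in frequent[lv]:
            membership.setdefault(o, []).append(lv)
    unique = sorted(o for o, lvs in membership.items() if len(lvs) == 1)
    idx = {o: i for i, o in enumerate(incidence.otu_ids)}
    occupancy = {
        lv: {o: occ_hist[lv][idx[o], 1:].tolist() for o in unique}
        for lv in levels
    }
    return {
        "frequent": {lv: sorted(frequent[lv]) for lv in levels},
        "all_levels": all_levels,
        "unique": unique,
        "occupancy": occupancy,
    }
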