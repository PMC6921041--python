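"""Synthetic OTU tables with planted specialist/generalist structure.

Generates the kind of data the analysis consumes: a broken-stick planting
design (for 16 species: 16 monocultures + 8 two-species + 4 four-species +
2 eight-species + 1 sixteen-species plot = 31 plots, five soil samples per
sampled (plot, species) cell, 400 samples), an OTU count table whose
occurrence structure mixes tree specialists (elevated presence probability
in plots containing their preferred species) with generalists, guild labels
with configurable proportions, and the ground-truth parameters needed for
parameter-recovery experiments.

Occurrence and abundance are modelled separately (zero-inflation): presence
is Bernoulli per sample with probability p_focal or p_bg depending on
whether the sample's plot contains the OTU's preferred species; conditional
abundance comes from a log-series draw scaled by a per-OTU abundance
parameter, and each sample's reads are drawn multinomially at a uniform
random depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import DiversityClass, PlotDesign
from .io_tables import CountTable, GuildMap, SampleRecord

__all__ = [
    "TruthParams",
    "SyntheticTruth",
    "generate_design",
    "generate_counts",
    "make_fixture",
    "FIXTURES",
]

#: Guild proportions of the generated OTU pool (saprotrophs dominate).
DEFAULT_GUILD_PROPORTIONS = {
    "saprotroph": 0.31,
    "ectomycorrhizal": 0.07,
    "arbuscular_mycorrhizal": 0.05,
    "plant_pathogen": 0.05,
    "unknown": 0.46,
    "other": 0.06,
}


@dataclass
class TruthParams:
    """Knobs of the planted occurrence structure.

    specialist_fraction : share of OTUs given a preferred tree species.
    p_focal / p_bg      : per-sample presence probabilities of specialists
                          in plots with / without their preferred species.
    generalist_p_range  : per-OTU occupancy range for generalists (uniform).
    guild_proportions   : OTU pool composition.
    """

    specialist_fraction: float = 0.2
    p_focal: float = 0.5
    p_bg: float = 0.08
    generalist_p_range: tuple[float, float] = (0.02, 0.3)
    guild_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_GUILD_PROPORTIONS)
    )

    def __post_init__(self) -> None:
        if self.p_focal < self.p_bg:
            raise ValueError("p_focal must be >= p_bg")


@dataclass
class SyntheticTruth:
    """Per-OTU ground truth emitted next to the generated counts."""

    otu_ids: list[str]
    guild: list[str]
    specialist: list[bool]
    preferred_species: list[str | None]
    p_focal: list[float]
    p_bg: list[float]
    abundance_scale: list[float]


def generate_design(
    n_species: int = 16, seed: int = 0, n_missing_samples: int = 0
) -> tuple[list[PlotDesign], list[SampleRecord]]:
    """Broken-stick plot design plus 5 sample records per (plot, species).

    The species pool is recursively halved at random (seeded) into the
    plot communities of each richness level.  For 16 species this gives 31
    plots and 400 samples; ``n_missing_samples`` randomly removes whole
    samples (not cells) to emulate field losses.
    """
    if n_species < 8 or n_species & (n_species - 1):
        raise ValueError("n_species must be a power of two, at least 8")
    rng = np.random.default_rng(seed)
    pool = [f"sp{i + 1:02d}" for i in range(n_species)]

    plots: list[PlotDesign] = []
    level_sets: list[list[list[str]]] = []
    current = [list(pool)]
    while True:
        level_sets.append(current)
        if len(current[0]) == 1:
            break
        nxt: list[list[str]] = []
        for group in current:
            perm = list(rng.permutation(group))
            half = len(perm) // 2
            nxt.append(sorted(perm[:half]))
            nxt.append(sorted(perm[half:]))
        current = nxt
    for sets in level_sets:
        r = len(sets[0])
        for k, sp_set in enumerate(sorted(sets)):
            pid = f"r{r:02d}_p{k + 1:02d}"
            plots.append(PlotDesign(pid, frozenset(sp_set)))

    records: list[SampleRecord] = []
    for plot in sorted(plots, key=lambda p: p.plot_id):
        for sp in sorted(plot.species_set):
            for rep in range(1, 6):
                records.append(
                    SampleRecord(
                        sample_id=f"{plot.plot_id}.{sp}.{rep}",
                        plot_id=plot.plot_id,
                        tree_species=sp,
                        plot_richness=plot.richness,
                        replicate=rep,
                    )
                )
    if n_missing_samples:
        if n_missing_samples >= len(records):
            raise ValueError("cannot drop every sample")
        drop = set(rng.choice(len(records), size=n_missing_samples,
                              replace=False))
        records = [r for i, r in enumerate(records) if i not in drop]
    return plots, records


def generate_counts(
    design: list[PlotDesign],
    metadata: list[SampleRecord],
    truth_params: TruthParams | None = None,
    n_otus: int = 2000,
    depth_range: tuple[int, int] = (700, 3000),
    seed: int = 0,
) -> tuple[CountTable, GuildMap, SyntheticTruth]:
    """Generate an OTU x sample count table with planted structure."""
    params = truth_params or TruthParams()
    rng = np.random.default_rng(seed)
    pool = sorted(frozenset().union(*(p.species_set for p in design)))
    otu_ids = [f"OTU{i + 1:05d}" for i in range(n_otus)]

    guild_names = list(params.guild_proportions)
    probs = np.array([params.guild_proportions[g] for g in guild_names])
    probs = probs / probs.sum()
    guilds = [guild_names[i] for i in rng.choice(len(guild_names),
                                                 size=n_otus, p=probs)]

    specialist = rng.random(n_otus) < params.specialist_fraction
    preferred = [
        pool[rng.integers(len(pool))] if s else None for s in specialist
    ]
    lo, hi = params.generalist_p_range
    gen_p = rng.uniform(lo, hi, size=n_otus)
    p_focal = np.where(specialist, params.p_focal, gen_p)
    p_bg = np.where(specialist, params.p_bg, gen_p)
    # lognormal abundance scales: a few dominant OTUs, a long tail
    scale = rng.lognormal(mean=0.0, sigma=1.2, size=n_otus)

    plot_species = {p.plot_id: p.species_set for p in design}
    mat = np.zeros((n_otus, len(metadata)), dtype=np.int64)
    for j, rec in enumerate(metadata):
        contains = np.array([
            pref is not None and pref in plot_species[rec.plot_id]
            for pref in preferred
        ])
        p = np.where(contains, p_focal, p_bg)
        present = rng.random(n_otus) < p
        if not present.any():
            continue
        # log-series-like conditional abundance, scaled per OTU
        raw = rng.logseries(0.95, size=n_otus) * scale * present
        depth = int(rng.integers(depth_range[0], depth_range[1] + 1))
        w = raw / raw.sum()
        mat[:, j] = rng.multinomial(depth, w)

    counts = CountTable(otu_ids, [r.sample_id for r in metadata], mat)
    guild_map = GuildMap({o: g for o, g in zip(otu_ids, guilds)})
    truth = SyntheticTruth(
        otu_ids=otu_ids,
        guild=guilds,
        specialist=specialist.tolist(),
        preferred_species=preferred,
        p_focal=p_focal.tolist(),
        p_bg=p_bg.tolist(),
        abundance_scale=scale.tolist(),
    )
    return counts, guild_map, truth


FIXTURES = {
    "tiny": dict(n_species=8, n_otus=200, depth_range=(700, 1500)),
    "paperlike": dict(n_species=16, n_otus=2000, depth_range=(700, 3000)),
    "null": dict(n_species=8, n_otus=200, depth_range=(700, 1500),
                 null_structure=True),
}


def make_fixture(
    name: str, seed: int = 0
) -> tuple[list[PlotDesign], list[SampleRecord], CountTable, GuildMap, SyntheticTruth]:
    """Reproducible packaged datasets: "tiny", "paperlike" or "null"."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    cfg = dict(FIXTURES[name])
    null_structure = cfg.pop("null_structure", False)
    design, metadata = generate_design(cfg.pop("n_species"), seed=seed)
    params = TruthParams()
    if null_structure:
        params = TruthParams(specialist_fraction=0.0)
    counts, guilds, truth = generate_counts(
        design, metadata, truth_params=params, seed=seed, **cfg
    )
    return design, metadata, counts, guilds, truth
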