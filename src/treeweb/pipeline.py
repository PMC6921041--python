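"""End-to-end orchestration: from a config mapping to the result tables.

The full analysis reads (or synthesizes) a count table, metadata and guild
map; preprocesses; enumerates subsampling combinations; builds webs and
computes network metrics per (combination, diversity class, threshold);
compares observed NODF against a fixed-margin null model; computes phi
specialization records and their summaries; and writes everything as
long-format TSVs plus a JSON run manifest.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import bipartite_metrics as bm
from . import specialization as spec_mod
from .design import DiversityClass, build_design, enumerate_combinations
from .io_tables import (
    CountTable,
    GuildMap,
    read_count_table,
    read_guild_map,
    read_sample_metadata,
    write_table,
)
from .nullmodel import null_nodf_comparison, patefield_shuffle
from .preprocess import preprocess_pipeline
from .stats import format_p, kruskal_posthoc, kruskal_wallis
from .synthetic_data import make_fixture

__all__ = ["run_full_analysis", "DEFAULT_CONFIG"]

logger = logging.getLogger(__name__)

LEVELS = [DiversityClass.MONO, DiversityClass.TWO, DiversityClass.HIGH]

DEFAULT_CONFIG: dict[str, Any] = {
    "inputs": {},           # counts / metadata / guilds paths
    "synth": {},            # preset + seed; used when inputs are absent
    "preprocess": {"max_total": 3, "depth": 700, "min_reads": 10, "seed": 0},
    "design": {"exclude": [], "n_cells": 7, "max_combinations": None},
    "networks": {"thresholds": [1, 2, 3, 4, 5], "modularity_restarts": 20,
                 "seed": 0},
    "nullmodel": {"reps": 1, "threshold": 3, "seed": 0},
    "phi": {"min_samples_present": 1, "top_n": 200, "write_records": True},
    "stats": {"alpha": 0.05, "correction": "holm"},
}

OUTPUT_FILES = [
    "metrics.tsv",
    "medians.tsv",
    "kw_tests.tsv",
    "nodf_null.tsv",
    "phi.tsv",
    "phi_medians.tsv",
    "guild_phi.tsv",
    "specialists.tsv",
    "frequent.tsv",
]


def _merge(base: Mapping, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), Mapping):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _load_inputs(cfg: Mapping) -> tuple[CountTable, list, GuildMap]:
    inputs = cfg.get("inputs") or {}
    if inputs.get("counts"):
        counts = read_count_table(inputs["counts"],
                                  inputs.get("counts_format"))
        metadata = read_sample_metadata(inputs["metadata"])
        guilds = (read_guild_map(inputs["guilds"]) if inputs.get("guilds")
                  else GuildMap({}))
        return counts, metadata, guilds
    synth = cfg.get("synth") or {}
    preset = synth.get("preset", "tiny")
    seed = int(synth.get("seed", 0))
    _, metadata, counts, guilds, _ = make_fixture(preset, seed=seed)
    return counts, metadata, guilds


def _subset_combos(combos: list, max_combinations: int | None) -> list:
    if max_combinations is None or len(combos) <= max_combinations:
        return combos
    # deterministic, evenly spaced subset across the enumeration order
    idx = np.linspace(0, len(combos) - 1, max_combinations).round().astype(int)
    return [combos[i] for i in sorted(set(idx.tolist()))]


def run_full_analysis(config: Mapping[str, Any], outdir: str | Path) -> dict:
    """Run the whole analysis; writes result TSVs + manifest into ``outdir``.

    Returns the manifest dict.  On error, any partially written outputs in
    ``outdir`` are removed and the failing stage/combination is reported.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(cfg, outdir, written)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _write(outdir: Path, written: list[Path], name: str, rows, schema) -> None:
    path = outdir / name
    write_table(path, rows, schema)
    written.append(path)


def _run(cfg: dict, outdir: Path, written: list[Path]) -> dict:
    counts_raw, metadata, guilds = _load_inputs(cfg)

    pp = cfg["preprocess"]
    rarefied, incidence = preprocess_pipeline(
        counts_raw, max_total=pp["max_total"], depth=pp["depth"],
        min_reads=pp["min_reads"], seed=pp["seed"],
    )
    kept = set(rarefied.sample_ids)
    metadata = [r for r in metadata if r.sample_id in kept]

    dcfg = cfg["design"]
    design = build_design(metadata)
    combos = enumerate_combinations(design, dcfg["exclude"],
                                    n_cells=dcfg["n_cells"])
    n_enumerated = len(combos)
    combos = _subset_combos(combos, dcfg["max_combinations"])
    sample_index = bm.build_sample_index(metadata)

    ncfg = cfg["networks"]
    thresholds = list(ncfg["thresholds"])
    metric_rows: list[dict] = []
    metric_names = None
    current = None
    try:
        for combo in combos:
            current = combo.combination_id
            for level in LEVELS:
                for t in thresholds:
                    web = bm.build_web(incidence, combo, level, t,
                                       sample_index)
                    m = bm.compute_metrics(
                        web, rarefied, combo, level, sample_index,
                        seed=ncfg["seed"] + combo.combination_id,
                        restarts=ncfg["modularity_restarts"],
                        strict=False,
                    ).as_dict()
                    if metric_names is None:
                        metric_names = list(m)
                    for name, value in m.items():
                        metric_rows.append({
                            "combination_id": combo.combination_id,
                            "level": level.value,
                            "threshold": t,
                            "metric": name,
                            "value": value,
                        })
            logger.info("combination %d done", combo.combination_id)
    except Exception as exc:
        raise RuntimeError(
            f"network stage failed at combination {current}: {exc}"
        ) from exc
    _write(outdir, written, "metrics.tsv", metric_rows,
           ["combination_id", "level", "threshold", "metric", "value"])

    # Table-1-style medians and Kruskal-Wallis contrasts across levels
    by_key: dict[tuple, list[float]] = {}
    for row in metric_rows:
        by_key.setdefault((row["level"], row["threshold"], row["metric"]),
                          []).append(row["value"])
    median_rows = []
    for (lv, t, met), v in sorted(by_key.items()):
        finite = [x for x in v if np.isfinite(x)]
        median_rows.append(
            {"level": lv, "threshold": t, "metric": met,
             "median": float(np.median(finite)) if finite else float("nan")}
        )
    _write(outdir, written, "medians.tsv", median_rows,
           ["level", "threshold", "metric", "median"])

    scfg = cfg["stats"]
    kw_rows = []
    for t in thresholds:
        for met in metric_names or []:
            groups = [
                [x for x in by_key[(lv.value, t, met)] if np.isfinite(x)]
                for lv in LEVELS
            ]
            if any(not g for g in groups):
                continue
            h, p = kruskal_wallis(groups)
            posthoc = kruskal_posthoc(groups, alpha=scfg["alpha"],
                                      correction=scfg["correction"])
            sig = ";".join(
                f"{LEVELS[c.group_i].value}-{LEVELS[c.group_j].value}"
                for c in posthoc if c.significant
            )
            kw_rows.append({"threshold": t, "metric": met, "H": h,
                            "p": format_p(p), "significant_pairs": sig})
    _write(outdir, written, "kw_tests.tsv", kw_rows,
           ["threshold", "metric", "H", "p", "significant_pairs"])

    # observed vs fixed-margin null NODF (Table-2 analogue)
    nmcfg = cfg["nullmodel"]
    t_null = nmcfg["threshold"]
    obs_nodf = {lv: [v for (l, t, met), vs in by_key.items()
                     if l == lv.value and t == t_null and met == "nodf"
                     for v in vs] for lv in LEVELS}
    null_nodf: dict[DiversityClass, list[float]] = {lv: [] for lv in LEVELS}
    for rep in range(nmcfg["reps"]):
        shuffled = patefield_shuffle(rarefied, seed=nmcfg["seed"] + rep)
        from .preprocess import to_incidence
        inc_null = to_incidence(shuffled)
        for combo in combos:
            for lv in LEVELS:
                web = bm.build_web(inc_null, combo, lv, t_null, sample_index)
                if web.shape[1] >= 2:
                    null_nodf[lv].append(bm.nodf(web))
    null_rows = []
    for lv in LEVELS:
        om, nm, p = null_nodf_comparison(obs_nodf[lv], null_nodf[lv])
        null_rows.append({"level": lv.value, "observed_median": om,
                          "null_median": nm, "wilcox_p": format_p(p)})
    _write(outdir, written, "nodf_null.tsv", null_rows,
           ["level", "observed_median", "null_median", "wilcox_p"])

    # phi specialization
    pcfg = cfg["phi"]
    phi_rows: list[dict] = []
    phi_median_rows: list[dict] = []
    guild_values: dict[str, list[float]] = {}
    max_phi: dict[tuple[str, str], float] = {}
    level_positive: dict[DiversityClass, list[float]] = {lv: [] for lv in LEVELS}
    frequent = spec_mod.frequent_otus(
        incidence, combos, LEVELS, sample_index,
        min_samples_present=pcfg["min_samples_present"],
    )
    for combo in combos:
        for lv in LEVELS:
            records = spec_mod.phi_table(
                incidence, combo, lv, sample_index,
                min_samples_present=pcfg["min_samples_present"],
            )
            med = spec_mod.median_positive_phi(records)
            phi_median_rows.append({
                "combination_id": combo.combination_id, "level": lv.value,
                "median_positive_phi": "" if med is None else med,
            })
            spec_mod.accumulate_max_phi(records, max_phi)
            for r in records:
                if r.phi is not None and r.phi > 0:
                    guild_values.setdefault(guilds[r.otu_id], []).append(r.phi)
                    level_positive[lv].append(r.phi)
            if pcfg["write_records"]:
                phi_rows.extend(
                    {"otu_id": r.otu_id, "tree_species": r.tree_species,
                     "combination_id": r.combination_id, "level": r.level.value,
                     "phi": "" if r.phi is None else r.phi}
                    for r in records
                )
    _write(outdir, written, "phi.tsv", phi_rows,
           ["otu_id", "tree_species", "combination_id", "level", "phi"])
    _write(outdir, written, "phi_medians.tsv", phi_median_rows,
           ["combination_id", "level", "median_positive_phi"])

    guild_rows = []
    usable = {g: v for g, v in guild_values.items() if v}
    if len(usable) >= 2:
        names = sorted(usable)
        h, p = kruskal_wallis([usable[g] for g in names])
        for g in names:
            guild_rows.append({
                "guild": g, "n_positive": len(usable[g]),
                "median_positive_phi": float(np.median(usable[g])),
                "kw_H": h, "kw_p": format_p(p),
            })
    _write(outdir, written, "guild_phi.tsv", guild_rows,
           ["guild", "n_positive", "median_positive_phi", "kw_H", "kw_p"])

    otu_order, species_order, mat = spec_mod.rank_specialists_from_max(
        max_phi, top_n=pcfg["top_n"]
    )
    spec_rows = [
        dict({"otu_id": otu}, **{sp: mat[i, j]
                                 for j, sp in enumerate(species_order)})
        for i, otu in enumerate(otu_order)
    ]
    _write(outdir, written, "specialists.tsv", spec_rows,
           ["otu_id", *species_order])

    freq_rows = []
    for lv in LEVELS:
        for otu in frequent["frequent"][lv]:
            freq_rows.append({
                "otu_id": otu, "level": lv.value,
                "all_levels": otu in frequent["all_levels"],
                "unique_level": otu in frequent["unique"],
            })
    _write(outdir, written, "frequent.tsv", freq_rows,
           ["otu_id", "level", "all_levels", "unique_level"])

    manifest = {
        "config": cfg,
        "n_samples": len(metadata),
        "n_otus_after_preprocess": len(incidence.otu_ids),
        "n_plots": len(design),
        "n_combinations_enumerated": n_enumerated,
        "n_combinations_analyzed": len(combos),
        "thresholds": thresholds,
        "metric_rows": len(metric_rows),
        "level_median_positive_phi": {
            lv.value: (float(np.median(level_positive[lv]))
                       if level_positive[lv] else None)
            for lv in LEVELS
        },
        "n_frequent_all_levels": len(frequent["all_levels"]),
        "outputs": OUTPUT_FILES,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    written.append(path)
    return manifest
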