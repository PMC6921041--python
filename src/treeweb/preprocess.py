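"""Count-table preprocessing: rare-OTU removal, rarefaction, pruning, incidence.

The pipeline applies these in a fixed order: OTUs totalling at most three
reads are discarded, samples are rarefied to a uniform depth (default 700
reads) by uniform subsampling without replacement, OTUs with fewer than ten
reads in the rarefied table are pruned, and finally counts are reduced to
presence/absence.
"""

from __future__ import annotations

import logging
import zlib

import numpy as np

from .io_tables import CountTable

__all__ = [
    "drop_rare_otus",
    "rarefy",
    "prune_low_abundance",
    "to_incidence",
    "preprocess_pipeline",
]

logger = logging.getLogger(__name__)


def drop_rare_otus(counts: CountTable, max_total: int = 3) -> CountTable:
    """Remove OTUs whose total count across all samples is <= ``max_total``.

    With the default of 3 this discards singleton, doubleton and tripleton
    OTUs. The sample set is unchanged; an empty result is allowed.
    """
    totals = counts.counts.sum(axis=1)
    keep = totals > max_total
    return CountTable(
        [o for o, k in zip(counts.otu_ids, keep) if k],
        list(counts.sample_ids),
        counts.counts[keep, :],
    )


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # per-sample stream keyed on the id, so reordering samples cannot change draws
    return np.random.default_rng([seed, zlib.crc32(sample_id.encode())])


def rarefy(
    counts: CountTable,
    depth: int = 700,
    seed: int = 0,
    drop_small: bool = True,
) -> CountTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Each retained column is a multivariate-hypergeometric draw from its read
    multiset. Samples with fewer than ``depth`` total reads are dropped (the
    default) or kept unrarefied when ``drop_small`` is False. Deterministic
    given ``seed``; each sample uses an independent stream derived from its id.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    totals = counts.counts.sum(axis=0)
    cols: list[np.ndarray] = []
    kept: list[str] = []
    for j, sid in enumerate(counts.sample_ids):
        total = int(totals[j])
        if total < depth:
            if drop_small:
                logger.warning(
                    "sample %r has %d < %d reads; dropped", sid, total, depth
                )
                continue
            cols.append(counts.counts[:, j])
            kept.append(sid)
            continue
        if total == depth:
            cols.append(counts.counts[:, j])
        else:
            rng = _sample_rng(seed, sid)
            cols.append(
                rng.multivariate_hypergeometric(counts.counts[:, j], depth)
            )
        kept.append(sid)
    if not kept:
        raise ValueError(f"every sample is below the rarefaction depth {depth}")
    return CountTable(list(counts.otu_ids), kept, np.column_stack(cols))


def prune_low_abundance(counts: CountTable, min_reads: int = 10) -> CountTable:
    """Remove OTUs with fewer than ``min_reads`` total reads."""
    keep = counts.counts.sum(axis=1) >= min_reads
    return CountTable(
        [o for o, k in zip(counts.otu_ids, keep) if k],
        list(counts.sample_ids),
        counts.counts[keep, :],
    )


def to_incidence(counts: CountTable) -> CountTable:
    """Binary presence/absence transform: 1 where count > 0."""
    return CountTable(
        list(counts.otu_ids),
        list(counts.sample_ids),
        (counts.counts > 0).astype(np.int64),
    )


def preprocess_pipeline(
    counts: CountTable,
    max_total: int = 3,
    depth: int = 700,
    min_reads: int = 10,
    seed: int = 0,
    drop_small: bool = True,
) -> tuple[CountTable, CountTable]:
    """Full preprocessing chain; returns (rarefied counts, incidence table)."""
    rare_dropped = drop_rare_otus(counts, max_total=max_total)
    rarefied = rarefy(rare_dropped, depth=depth, seed=seed, drop_small=drop_small)
    pruned = prune_low_abundance(rarefied, min_reads=min_reads)
    return pruned, to_incidence(pruned)
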