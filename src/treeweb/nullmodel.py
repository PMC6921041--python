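"""Fixed-margin null model for count tables and the observed-vs-null
nestedness comparison.

The null model shuffles the full post-preprocessing OTU x sample count
table while keeping every row and column sum fixed (a uniform draw over
contingency tables with those margins, via the Patefield algorithm), then
the identical downstream pipeline (incidence -> webs -> NODF) is re-run on
the shuffled table.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.stats import random_table

from .io_tables import CountTable
from .stats import wilcoxon_ranksum

__all__ = ["patefield_shuffle", "null_nodf_comparison"]


def patefield_shuffle(counts: CountTable, seed: int = 0) -> CountTable:
    """Random contingency table with the input's exact row and column sums.

    Drawn uniformly over the multinomial distribution of tables with fixed
    margins (Patefield's algorithm); deterministic given ``seed``.  Zero
    rows/columns are preserved as zero.
    """
    mat = counts.counts
    rows = mat.sum(axis=1)
    cols = mat.sum(axis=0)
    if mat.size == 0 or rows.sum() == 0 or 1 in mat.shape:
        # a single row or column is fully determined by its margins
        return CountTable(list(counts.otu_ids), list(counts.sample_ids), mat.copy())
    rng = np.random.default_rng(seed)
    shuffled = random_table(rows, cols).rvs(random_state=rng, method="patefield")
    return CountTable(
        list(counts.otu_ids),
        list(counts.sample_ids),
        np.asarray(shuffled, dtype=np.int64),
    )


def _median(values: Sequence[float]) -> float:
    return float(np.median(np.asarray(values, dtype=float)))


def null_nodf_comparison(
    observed_nodf: Sequence[float], null_nodf: Sequence[float]
) -> tuple[float, float, float]:
    """Medians of the observed and null NODF samples and a two-sample
    Wilcoxon rank-sum p-value (two-sided) for their difference."""
    if len(observed_nodf) == 0 or len(null_nodf) == 0:
        raise ValueError("empty NODF sample")
    _, p = wilcoxon_ranksum(observed_nodf, null_nodf)
    return _median(observed_nodf), _median(null_nodf), p
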