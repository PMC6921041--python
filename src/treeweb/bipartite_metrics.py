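"""Threshold-based tree-fungal webs and their network statistics.

A web links a tree species to a fungal OTU when the OTU occurs in at least
``threshold`` of the five soil samples taken under that species in the
combination's plot for the relevant diversity class.  The statistics
computed here are the standard binary bipartite-network descriptors:
connectance, link-weighted fungal generality, the Stone-Roberts C score,
NODF nestedness, Barber bipartite modularity, mean shared fungal partners,
and pooled alpha diversity (richness, Shannon).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .design import DiversityClass, SubsampleCombination
from .io_tables import CountTable, SampleRecord

__all__ = [
    "Web",
    "NetworkMetrics",
    "build_sample_index",
    "build_web",
    "connectance",
    "generality",
    "c_score",
    "nodf",
    "mean_shared_partners",
    "modularity",
    "alpha_diversity",
    "compute_metrics",
]


@dataclass
class Web:
    """Binary tree x OTU co-occurrence matrix at one link threshold."""

    tree_species: list[str]
    otu_ids: list[str]
    links: np.ndarray
    threshold: int

    def __post_init__(self) -> None:
        self.links = np.asarray(self.links, dtype=np.int64)
        if self.links.shape != (len(self.tree_species), len(self.otu_ids)):
            raise ValueError("links shape does not match labels")
        if not np.isin(self.links, (0, 1)).all():
            raise ValueError("links must be binary")

    @property
    def n_links(self) -> int:
        return int(self.links.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.links.shape


@dataclass
class NetworkMetrics:
    """Per-web network statistics (one row of the long-format results)."""

    n_otus: int
    connectance: float
    generality: float
    c_score: float
    nodf: float
    modularity_q: float
    n_modules: int
    mean_shared_partners: float
    richness: int
    shannon: float

    def as_dict(self) -> dict[str, float]:
        return {
            "n_otus": self.n_otus,
            "connectance": self.connectance,
            "generality": self.generality,
            "c_score": self.c_score,
            "nodf": self.nodf,
            "modularity_q": self.modularity_q,
            "n_modules": self.n_modules,
            "mean_shared_partners": self.mean_shared_partners,
            "richness": self.richness,
            "shannon": self.shannon,
        }


def build_sample_index(
    metadata: Sequence[SampleRecord],
) -> dict[tuple[str, str], list[str]]:
    """Map (plot_id, tree_species) -> ordered sample ids."""
    index: dict[tuple[str, str], list[str]] = {}
    for rec in metadata:
        index.setdefault((rec.plot_id, rec.tree_species), []).append(rec.sample_id)
    return index


def cell_presence_matrix(
    incidence: CountTable,
    combo: SubsampleCombination,
    level: DiversityClass,
    sample_index: Mapping[tuple[str, str], Sequence[str]],
    n_samples_per_cell: int = 5,
) -> np.ndarray:
    """Per-cell presence counts: (n_cells x n_otus) matrix of 0..5 values."""
    rows = []
    for plot_id, species in combo.cells_at(level):
        sids = sample_index.get((plot_id, species), [])
        if len(sids) != n_samples_per_cell:
            raise ValueError(
                f"cell (plot {plot_id!r}, species {species!r}) has "
                f"{len(sids)} samples, expected {n_samples_per_cell}"
            )
        cols = [incidence.sample_index(s) for s in sids]
        rows.append((incidence.counts[:, cols] > 0).sum(axis=1))
    return np.array(rows)


def build_web(
    incidence: CountTable,
    combo: SubsampleCombination,
    level: DiversityClass,
    threshold: int,
    sample_index: Mapping[tuple[str, str], Sequence[str]],
) -> Web:
    """Build the tree x OTU web at one threshold; all-zero OTUs are dropped."""
    if not 1 <= threshold <= 5:
        raise ValueError("threshold must be in 1..5")
    pres = cell_presence_matrix(incidence, combo, level, sample_index)
    links = (pres >= threshold).astype(np.int64)
    keep = links.sum(axis=0) > 0
    return Web(
        tree_species=list(combo.species),
        otu_ids=[o for o, k in zip(incidence.otu_ids, keep) if k],
        links=links[:, keep],
        threshold=threshold,
    )


def connectance(web: Web) -> float:
    """Realized fraction of possible links, L / (I * J)."""
    nrow, ncol = web.shape
    if nrow == 0 or ncol == 0:
        raise ValueError("web has a zero dimension")
    return web.n_links / (nrow * ncol)


def generality(web: Web) -> float:
    """Link-weighted mean effective number of tree partners per OTU.

    For a binary web the effective partner number of an OTU is its degree,
    and weighting each OTU by its share of the links gives sum(d^2) / L.
    """
    L = web.n_links
    if L == 0:
        raise ValueError("web has no links")
    deg = web.links.sum(axis=0)
    return float((deg.astype(float) ** 2).sum() / L)


def c_score(web: Web) -> float:
    """Mean normalized checkerboard units over unordered OTU pairs.

    For columns f, g with degrees r_f, r_g sharing S trees the unit is
    (r_f - S)(r_g - S) / (r_f r_g), in [0, 1]; 1 indicates segregation.
    """
    _, ncol = web.shape
    if ncol < 2:
        raise ValueError("need at least two OTU columns")
    A = web.links.astype(float)
    r = A.sum(axis=0)
    S = A.T @ A
    num = (r[:, None] - S) * (r[None, :] - S)
    cu = num / (r[:, None] * r[None, :])
    iu = np.triu_indices(ncol, k=1)
    return float(cu[iu].mean())


def _nodf_axis(mat: np.ndarray) -> tuple[float, int]:
    """Summed paired-overlap contributions over ordered row pairs of ``mat``."""
    totals = mat.sum(axis=1)
    order = np.argsort(-totals, kind="stable")
    m = mat[order]
    t = totals[order]
    total = 0.0
    n = len(t)
    for u in range(n):
        for v in range(u + 1, n):
            if t[u] > t[v] and t[v] > 0:
                shared = int(np.minimum(m[u], m[v]).sum())
                total += 100.0 * shared / t[v]
    return total, n * (n - 1) // 2


def nodf(web: Web) -> float:
    """NODF nestedness (0 = non-nested, 100 = perfectly nested).

    Rows and columns are sorted by decreasing marginal totals; each ordered
    pair with a strict decrease contributes 100 x overlap / (smaller total),
    ties contribute 0; the result averages row-pair and column-pair
    contributions together.
    """
    nrow, ncol = web.shape
    if nrow < 2 or ncol < 2:
        raise ValueError("web must be at least 2 x 2")
    mat = web.links
    row_sum, n_row_pairs = _nodf_axis(mat)
    col_sum, n_col_pairs = _nodf_axis(mat.T)
    return (row_sum + col_sum) / (n_row_pairs + n_col_pairs)


def mean_shared_partners(web: Web) -> float:
    """Mean number of OTUs linked to both trees of an unordered tree pair."""
    nrow, _ = web.shape
    if nrow < 2:
        raise ValueError("need at least two tree rows")
    shared = web.links @ web.links.T
    iu = np.triu_indices(nrow, k=1)
    return float(shared[iu].mean())


def barber_q(web: Web, row_labels: np.ndarray, col_labels: np.ndarray) -> float:
    """Barber bipartite modularity of a given node partition.

    Q = (1/L) sum_{s,f} (A_sf - k_s d_f / L) [g_s == g_f].
    """
    A = web.links.astype(float)
    L = A.sum()
    if L == 0:
        raise ValueError("web has no links")
    k = A.sum(axis=1)
    d = A.sum(axis=0)
    same = row_labels[:, None] == col_labels[None, :]
    return float(((A - np.outer(k, d) / L) * same).sum() / L)


def _label_prop_once(
    web: Web, rng: np.random.Generator
) -> tuple[float, np.ndarray, np.ndarray]:
    """One seeded LPAwb+-style run.

    Alternates single-node label moves (each node may join any existing
    module or open a fresh singleton module, taking the move with the best
    modularity contribution) with greedy pairwise module merging, until
    neither phase improves Q.
    """
    A = web.links.astype(float)
    nrow, ncol = A.shape
    L = A.sum()
    k = A.sum(axis=1)
    d = A.sum(axis=0)
    B = A - np.outer(k, d) / L  # modularity matrix

    n = nrow + ncol
    row_labels = rng.integers(0, max(1, n // 2), size=nrow)
    col_labels = rng.integers(0, max(1, n // 2), size=ncol)

    def relabel() -> int:
        nonlocal row_labels, col_labels
        labs = np.unique(np.concatenate([row_labels, col_labels]))
        remap = {l: i for i, l in enumerate(labs)}
        row_labels = np.array([remap[l] for l in row_labels])
        col_labels = np.array([remap[l] for l in col_labels])
        return len(labs)

    def sweep() -> bool:
        # single-node moves; a fresh label contributes 0 and wins over
        # any strictly negative attachment
        changed = False
        n_lab = int(max(row_labels.max(initial=0),
                        col_labels.max(initial=0))) + 1
        for node in rng.permutation(n):
            if node < nrow:
                scores = np.zeros(n_lab + 1)
                np.add.at(scores, col_labels, B[node, :])
                scores[n_lab] = 0.0  # open a new module
                cur = row_labels[node]
                best = int(np.argmax(scores))
                if scores[best] > scores[cur] + 1e-12:
                    row_labels[node] = best
                    n_lab = max(n_lab, best + 1)
                    changed = True
            else:
                j = node - nrow
                scores = np.zeros(n_lab + 1)
                np.add.at(scores, row_labels, B[:, j])
                scores[n_lab] = 0.0
                cur = col_labels[j]
                best = int(np.argmax(scores))
                if scores[best] > scores[cur] + 1e-12:
                    col_labels[j] = best
                    n_lab = max(n_lab, best + 1)
                    changed = True
        return changed

    def merge_once() -> bool:
        nonlocal row_labels, col_labels
        n_mod = relabel()
        if n_mod < 2:
            return False
        q0 = barber_q(web, row_labels, col_labels)
        # zero-gain merges are taken too: among Q-optimal partitions we
        # report the one with fewest modules (a complete web is one module)
        best_gain, best_pair = -1e-12, None
        for a in range(n_mod):
            for b in range(a + 1, n_mod):
                rl = np.where(row_labels == b, a, row_labels)
                cl = np.where(col_labels == b, a, col_labels)
                gain = barber_q(web, rl, cl) - q0
                if gain > best_gain:
                    best_gain, best_pair = gain, (a, b)
        if best_pair is None:
            return False
        a, b = best_pair
        row_labels = np.where(row_labels == b, a, row_labels)
        col_labels = np.where(col_labels == b, a, col_labels)
        return True

    for _ in range(200):
        moved = False
        for _ in range(100):
            if not sweep():
                break
            moved = True
        merged = merge_once()
        if not moved and not merged:
            break

    relabel()
    return barber_q(web, row_labels, col_labels), row_labels, col_labels


def modularity(
    web: Web, seed: int = 0, restarts: int = 20
) -> tuple[float, int, tuple[np.ndarray, np.ndarray]]:
    """Maximize Barber bipartite modularity by seeded label propagation.

    Runs ``restarts`` independent label-propagation + greedy-agglomeration
    passes and keeps the best partition.  Returns (Q, number of modules,
    (row labels, column labels)); deterministic given ``seed``.
    """
    if web.n_links == 0:
        raise ValueError("web has no links")
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(restarts):
        q, rl, cl = _label_prop_once(web, rng)
        if best is None or q > best[0] + 1e-12:
            best = (q, rl, cl)
    q, rl, cl = best
    n_modules = len(np.unique(np.concatenate([rl, cl])))
    return q, n_modules, (rl, cl)


def alpha_diversity(
    counts: CountTable,
    combo: SubsampleCombination,
    level: DiversityClass,
    sample_index: Mapping[tuple[str, str], Sequence[str]],
) -> tuple[int, float]:
    """Pooled OTU richness and Shannon diversity over the level's samples.

    Counts are pooled across all samples of the combination's cells at the
    level (7 plots x 5 samples in pipeline use); Shannon entropy uses
    natural log on pooled relative abundances.
    """
    sids: list[str] = []
    for plot_id, species in combo.cells_at(level):
        cell = sample_index.get((plot_id, species), [])
        if not cell:
            raise ValueError(f"no samples for cell ({plot_id!r}, {species!r})")
        sids.extend(cell)
    cols = [counts.sample_index(s) for s in sids]
    pooled = counts.counts[:, cols].sum(axis=1).astype(float)
    present = pooled[pooled > 0]
    richness = int(len(present))
    p = present / present.sum()
    shannon = float(-(p * np.log(p)).sum())
    return richness, shannon


def compute_metrics(
    web: Web,
    counts: CountTable,
    combo: SubsampleCombination,
    level: DiversityClass,
    sample_index: Mapping[tuple[str, str], Sequence[str]],
    seed: int = 0,
    restarts: int = 20,
    strict: bool = True,
) -> NetworkMetrics:
    """All per-web statistics plus pooled alpha diversity, as one record.

    With ``strict=False``, metrics whose preconditions a degenerate web
    fails (e.g. a single OTU column at a high threshold) are recorded as
    NaN instead of raising.
    """

    def guarded(fn, *args):
        if strict:
            return fn(*args)
        try:
            return fn(*args)
        except ValueError:
            return float("nan")

    mod = guarded(lambda w: modularity(w, seed=seed, restarts=restarts), web)
    q, n_mod = (mod[0], mod[1]) if isinstance(mod, tuple) else (mod, 0)
    richness, shannon = alpha_diversity(counts, combo, level, sample_index)
    return NetworkMetrics(
        n_otus=web.shape[1],
        connectance=guarded(connectance, web),
        generality=guarded(generality, web),
        c_score=guarded(c_score, web),
        nodf=guarded(nodf, web),
        modularity_q=q,
        n_modules=n_mod,
        mean_shared_partners=guarded(mean_shared_partners, web),
        richness=richness,
        shannon=shannon,
    )
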