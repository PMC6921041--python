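"""Web construction and network statistics against brute-force oracles."""

import numpy as np
import pytest

from treeweb.bipartite_metrics import (
    Web,
    barber_q,
    build_sample_index,
    build_web,
    c_score,
    connectance,
    generality,
    mean_shared_partners,
    modularity,
    nodf,
    alpha_diversity,
)
from treeweb.design import DiversityClass
from treeweb.io_tables import CountTable
from treeweb.preprocess import to_incidence
from treeweb.synthetic_data import generate_counts, generate_design


def web_from(mat, threshold=1):
    mat = np.asarray(mat)
    return Web(
        [f"t{i}" for i in range(mat.shape[0])],
        [f"o{j}" for j in range(mat.shape[1])],
        mat,
        threshold,
    )


def random_webs(rng, n=200, max_rows=10, max_cols=50):
    webs = []
    while len(webs) < n:
        nr = int(rng.integers(2, max_rows + 1))
        nc = int(rng.integers(2, max_cols + 1))
        mat = (rng.random((nr, nc)) < rng.uniform(0.15, 0.7)).astype(int)
        if mat.sum() and (mat.sum(axis=0) > 0).all():
            webs.append(web_from(mat))
    return webs


# -- independent naive implementations -------------------------------------

def naive_connectance(w):
    total = links = 0
    for row in w.links:
        for v in row:
            total += 1
            links += int(v)
    return links / total


def naive_generality(w):
    per_otu = [sum(col) for col in w.links.T]
    L = sum(per_otu)
    return sum(d * d for d in per_otu) / L


def naive_c_score(w):
    cols = w.links.T
    units = []
    for f in range(len(cols)):
        for g in range(f + 1, len(cols)):
            rf, rg = sum(cols[f]), sum(cols[g])
            s = sum(int(a and b) for a, b in zip(cols[f], cols[g]))
            units.append((rf - s) * (rg - s) / (rf * rg))
    return sum(units) / len(units)


def naive_shared_partners(w):
    rows = w.links
    vals = []
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            vals.append(sum(int(a and b) for a, b in zip(rows[i], rows[j])))
    return sum(vals) / len(vals)


def naive_nodf(w):
    def axis(mat):
        totals = [sum(r) for r in mat]
        idx = sorted(range(len(mat)), key=lambda i: -totals[i])
        contribs = []
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                u, v = idx[a], idx[b]
                if totals[u] > totals[v] and totals[v] > 0:
                    shared = sum(
                        int(x and y) for x, y in zip(mat[u], mat[v])
                    )
                    contribs.append(100 * shared / totals[v])
                else:
                    contribs.append(0.0)
        return contribs

    contribs = axis([list(r) for r in w.links])
    contribs += axis([list(c) for c in w.links.T])
    return sum(contribs) / len(contribs)


def partitions_rgs(n):
    a = [0] * n
    b = [0] * n
    while True:
        yield list(a)
        j = n - 1
        while j > 0 and a[j] == b[j] + 1:
            j -= 1
        if j == 0:
            return
        a[j] += 1
        mx = max(b[j], a[j])
        for k in range(j + 1, n):
            a[k] = 0
            b[k] = mx


def exhaustive_modularity(w):
    nrow, ncol = w.shape
    best = -np.inf
    for labels in partitions_rgs(nrow + ncol):
        rl = np.array(labels[:nrow])
        cl = np.array(labels[nrow:])
        best = max(best, barber_q(w, rl, cl))
    return best


# -- frozen examples --------------------------------------------------------

class TestFrozenExamples:
    def test_connectance(self):
        assert connectance(web_from(np.ones((7, 10)))) == 1.0
        mat = np.zeros((7, 10), dtype=int)
        mat[0, :10] = 1
        mat[1, :4] = 1
        assert connectance(web_from(mat)) == 14 / 70

    def test_generality(self):
        assert generality(web_from(np.eye(3, dtype=int))) == 1.0
        mat = np.array([[1, 1, 1], [1, 1, 0]])
        assert generality(web_from(mat)) == pytest.approx((4 + 4 + 1) / 5)
        assert generality(web_from(np.ones((7, 4)))) == 7.0

    def test_c_score(self):
        assert c_score(web_from([[1, 0], [0, 1]])) == 1.0
        assert c_score(web_from([[1, 1], [1, 1]])) == 0.0
        # f on trees {1,2}, g on {2,3}
        mat = np.array([[1, 0], [1, 1], [0, 1]])
        assert c_score(web_from(mat)) == pytest.approx(0.25)

    def test_nodf(self):
        assert nodf(web_from([[1, 1, 1], [1, 1, 0], [1, 0, 0]])) == 100.0
        assert nodf(web_from([[1, 0], [0, 1]])) == 0.0
        assert nodf(web_from([[1, 1, 0], [0, 1, 1]])) == pytest.approx(50.0)

    def test_mean_shared_partners(self):
        assert mean_shared_partners(web_from([[1, 1, 1], [1, 1, 1]])) == 3.0
        assert mean_shared_partners(web_from([[1, 0], [0, 1]])) == 0.0
        mat = np.array([[1, 1, 1], [0, 1, 1], [0, 0, 1]])
        assert mean_shared_partners(web_from(mat)) == pytest.approx(4 / 3)

    def test_modularity_complete_web(self):
        q, n_mod, _ = modularity(web_from(np.ones((3, 4))), seed=0, restarts=5)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert n_mod == 1

    @pytest.mark.parametrize("m", [2, 4])
    def test_modularity_disjoint_blocks(self, m):
        mat = np.zeros((2 * m, 2 * m), dtype=int)
        for i in range(m):
            mat[2 * i : 2 * i + 2, 2 * i : 2 * i + 2] = 1
        q, n_mod, _ = modularity(web_from(mat), seed=1, restarts=10)
        assert q == pytest.approx(1 - 1 / m)
        assert n_mod == m

    def test_degenerate_webs_rejected(self):
        with pytest.raises(ValueError):
            c_score(web_from([[1], [1]]))
        with pytest.raises(ValueError):
            nodf(web_from([[1, 1]]))
        with pytest.raises(ValueError):
            mean_shared_partners(web_from([[1, 1]]))


# -- oracle agreement on random webs ----------------------------------------

class TestOracles:
    def test_metrics_match_naive_implementations(self, rng):
        for w in random_webs(rng, n=200):
            assert connectance(w) == pytest.approx(naive_connectance(w))
            assert generality(w) == pytest.approx(naive_generality(w))
            assert c_score(w) == pytest.approx(naive_c_score(w))
            assert nodf(w) == pytest.approx(naive_nodf(w))
            assert mean_shared_partners(w) == pytest.approx(
                naive_shared_partners(w)
            )

    def test_nodf_invariant_to_permutation(self, rng):
        for w in random_webs(rng, n=20, max_rows=6, max_cols=10):
            perm_r = rng.permutation(w.shape[0])
            perm_c = rng.permutation(w.shape[1])
            w2 = web_from(w.links[perm_r][:, perm_c])
            assert nodf(w) == pytest.approx(nodf(w2))

    def test_modularity_matches_exhaustive_optimum(self, rng):
        done = 0
        while done < 15:
            nr = int(rng.integers(2, 6))
            nc = int(rng.integers(2, 6))
            if nr + nc > 10:
                continue
            mat = (rng.random((nr, nc)) < 0.45).astype(int)
            if not mat.sum() or (mat.sum(axis=0) == 0).any():
                continue
            w = web_from(mat)
            q, _, _ = modularity(w, seed=done, restarts=20)
            assert q == pytest.approx(exhaustive_modularity(w), abs=1e-9)
            done += 1

    def test_modularity_deterministic_given_seed(self, rng):
        w = random_webs(rng, n=1, max_rows=7, max_cols=20)[0]
        a = modularity(w, seed=5, restarts=10)
        b = modularity(w, seed=5, restarts=10)
        assert a[0] == b[0] and a[1] == b[1]


# -- web construction -------------------------------------------------------

@pytest.fixture(scope="module")
def small_world():
    design, metadata = generate_design(16, seed=3)
    counts, _, _ = generate_counts(design, metadata, n_otus=120,
                                   depth_range=(700, 900), seed=3)
    incidence = to_incidence(counts)
    index = build_sample_index(metadata)
    return design, metadata, counts, incidence, index


class TestBuildWeb:
    def test_threshold_semantics(self):
        # one tree cell whose 5 samples contain the OTU 3 times
        from treeweb.design import SubsampleCombination

        otus = ["OTUa"]
        sids = [f"s{i}" for i in range(5)] + [f"r{i}" for i in range(5)]
        counts = np.array([[1, 1, 1, 0, 0, 1, 0, 0, 0, 0]])
        inc = CountTable(otus, sids, counts)
        combo = SubsampleCombination(
            0, ("spA", "spB"),
            {DiversityClass.MONO: (("p1", "spA"), ("p2", "spB"))},
        )
        index = {("p1", "spA"): sids[:5], ("p2", "spB"): sids[5:]}
        for t in (1, 2, 3):
            w = build_web(inc, combo, DiversityClass.MONO, t, index)
            assert w.links[0].tolist() == [1]
        for t in (4, 5):
            w = build_web(inc, combo, DiversityClass.MONO, t, index)
            assert w.shape[1] == 0 or w.links[0].tolist() == [0]

    def test_threshold_five_requires_all_samples(self, small_world):
        design, metadata, counts, incidence, index = small_world
        from treeweb.design import enumerate_combinations

        combo = enumerate_combinations(design)[0]
        w5 = build_web(incidence, combo, DiversityClass.MONO, 5, index)
        pres = {}
        for pid, sp in combo.cells_at(DiversityClass.MONO):
            cols = [incidence.sample_index(s) for s in index[(pid, sp)]]
            pres[(pid, sp)] = (incidence.counts[:, cols] > 0).sum(axis=1)
        full = set()
        for v in pres.values():
            full |= {
                incidence.otu_ids[i] for i in np.flatnonzero(v == 5)
            }
        assert set(w5.otu_ids) == full

    def test_column_count_non_increasing_in_threshold(self, small_world):
        design, metadata, counts, incidence, index = small_world
        from treeweb.design import enumerate_combinations

        combo = enumerate_combinations(design)[10]
        for level in DiversityClass:
            sizes = [
                build_web(incidence, combo, level, t, index).shape[1]
                for t in range(1, 6)
            ]
            assert sizes == sorted(sizes, reverse=True)

    def test_wrong_cell_size_errors(self, small_world):
        design, metadata, counts, incidence, index = small_world
        from treeweb.design import enumerate_combinations

        combo = enumerate_combinations(design)[0]
        broken = dict(index)
        pid, sp = combo.cells_at(DiversityClass.MONO)[0]
        broken[(pid, sp)] = broken[(pid, sp)][:4]
        with pytest.raises(ValueError, match=pid):
            build_web(incidence, combo, DiversityClass.MONO, 3, broken)


class TestAlphaDiversity:
    def test_equal_pool_entropy(self):
        from treeweb.design import SubsampleCombination

        sids = [f"s{i}" for i in range(5)]
        counts = CountTable(["A", "B"], sids,
                            np.full((2, 5), 7, dtype=int))
        combo = SubsampleCombination(
            0, ("spA",), {DiversityClass.MONO: (("p1", "spA"),)}
        )
        index = {("p1", "spA"): sids}
        richness, shannon = alpha_diversity(counts, combo,
                                            DiversityClass.MONO, index)
        assert richness == 2
        assert shannon == pytest.approx(np.log(2))

    def test_two_otu_pool(self):
        from treeweb.design import SubsampleCombination

        counts = CountTable(["A", "B"], ["s1"], np.array([[700], [300]]))
        combo = SubsampleCombination(
            0, ("spA",), {DiversityClass.MONO: (("p1", "spA"),)}
        )
        richness, shannon = alpha_diversity(
            counts, combo, DiversityClass.MONO, {("p1", "spA"): ["s1"]}
        )
        assert richness == 2
        assert shannon == pytest.approx(
            -0.7 * np.log(0.7) - 0.3 * np.log(0.3)
        )
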