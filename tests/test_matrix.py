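"""Matrix inference, complete-linkage clustering and the Mantel test."""

import io
import itertools
import statistics

import numpy as np
import pytest

import linforge as lf
from linforge.matrix import SimilarityMatrix, cut_clusters, to_newick

from conftest import write_genome


def _seed_store(store, tmp_path, assignments, seed0=100):
    """Replay a sequence of (genome, subject, ani) divergence events.

    Drives the real assignment path (allocate_number + assign_lin) with
    prescribed ANI values so inference semantics can be checked against
    hand-constructed histories.
    """
    lin20 = store.get_scheme("lin20")
    for i, (gid, subject, ani) in enumerate(assignments):
        p = write_genome(tmp_path, gid, lf.random_genome(200, seed=seed0 + i))
        store.register_genome(p)
        subject_lin = store.get_lin(subject, "lin20") if subject else None
        lin = lf.assign_lin(subject_lin, ani, lin20, store)
        store.save_lin(gid, "lin20", lin)
        if subject is not None:
            store.record_ani(gid, subject, ani)


class TestInferPairwise:
    def test_direct_record_passthrough(self, tmp_store, tmp_path):
        _seed_store(tmp_store, tmp_path, [("a", None, None), ("b", "a", 95.2)])
        assert lf.infer_pairwise("a", "b", tmp_store) == pytest.approx(95.2)
        assert lf.infer_pairwise("b", "a", tmp_store) == pytest.approx(95.2)

    def test_two_group_merging_phenomenon(self, tmp_store, tmp_path):
        """Two internally >99%-similar groups linked by one founder-to-founder
        computation of 70.75%: every cross-group pair infers exactly 70.75."""
        _seed_store(
            tmp_store,
            tmp_path,
            [
                ("a1", None, None),
                ("a2", "a1", 99.2),
                ("a3", "a2", 99.4),
                ("b1", "a1", 70.75),  # founds the second branch at the B position
                ("b2", "b1", 99.3),
                ("b3", "b1", 99.1),
            ],
        )
        m = lf.full_matrix(tmp_store)
        frame = m.to_dataframe()
        for x in ("a1", "a2", "a3"):
            for y in ("b1", "b2", "b3"):
                assert frame.loc[x, y] == pytest.approx(70.75)

    def test_third_branch_fallback_stays_in_bracket(self, tmp_store, tmp_path, lin20):
        """Branch 2's founder was measured against branch 0, so the (branch 1,
        branch 2) pair has no spanning record; the later founder's recorded
        ANI is propagated and lies inside the divergence bracket."""
        _seed_store(
            tmp_store,
            tmp_path,
            [
                ("f0", None, None),
                ("f1", "f0", 72.0),   # branch 1 at the B position
                ("f2", "f0", 73.5),   # branch 2, subject in branch 0
            ],
        )
        v = lf.infer_pairwise("f1", "f2", tmp_store)
        assert v == pytest.approx(73.5)  # later founder's recorded value
        p = 1  # all three branches diverge at the 75%-threshold position
        assert lin20.threshold(p - 1) <= v < lin20.threshold(p)

    def test_novel_branch_without_record_falls_back_to_threshold(
        self, tmp_store, tmp_path, lin20
    ):
        _seed_store(tmp_store, tmp_path, [("a", None, None)])
        # second top-level branch founded with no ANI computation at all
        lin20_scheme = tmp_store.get_scheme("lin20")
        p = write_genome(tmp_path, "b", lf.random_genome(200, seed=300))
        tmp_store.register_genome(p)
        lin = lf.assign_lin(None, None, lin20_scheme, tmp_store)
        tmp_store.save_lin("b", "lin20", lin)
        assert lf.infer_pairwise("a", "b", tmp_store) == 0.0


class TestFullMatrix:
    def test_single_genome(self, tmp_store, tmp_path):
        _seed_store(tmp_store, tmp_path, [("a", None, None)])
        m = lf.full_matrix(tmp_store)
        assert m.labels == ["a"]
        assert m.values.tolist() == [[100.0]]

    def test_counting_records_vs_cells(self, tmp_store, tmp_path):
        events = [("g0", None, None)] + [
            (f"g{i}", f"g{i - 1}", 99.0 - i * 0.5) for i in range(1, 6)
        ]
        _seed_store(tmp_store, tmp_path, events)
        m = lf.full_matrix(tmp_store)
        n = len(m.labels)
        assert len(tmp_store.ani_records()) == n - 1
        off_diag = m.values[~np.eye(n, dtype=bool)]
        assert np.all(off_diag > 0)  # every one of the n(n-1) cells inferred
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 100.0)

    def test_bracket_consistency_on_randomized_stores(self, tmp_path, lin20, rng):
        """Every inferred (non-direct) value for a pair first differing at
        position p lies in [threshold(p-1), threshold(p))."""
        for trial in range(3):
            store = lf.Store.create(tmp_path / f"s{trial}")
            events = [("g0", None, None)]
            for i in range(1, 12):
                subject = f"g{rng.integers(0, i)}"
                ani = float(rng.uniform(70.0, 99.9))
                events.append((f"g{i}", subject, ani))
            _seed_store(store, tmp_path / f"fa{trial}", events, seed0=trial * 50)
            lins = store.lins("lin20")
            direct = {
                frozenset((r.query_id, r.subject_id)) for r in store.ani_records()
            }
            m = lf.full_matrix(store)
            frame = m.to_dataframe()
            for x, y in itertools.combinations(m.labels, 2):
                if frozenset((x, y)) in direct:
                    continue
                diffs = [i for i, (a, b) in enumerate(zip(lins[x], lins[y])) if a != b]
                if not diffs:
                    continue
                p = diffs[0]
                v = frame.loc[x, y]
                lo = lin20.threshold(p - 1) if p > 0 else 0.0
                hi = lin20.threshold(p)
                assert lo <= v < hi, (x, y, p, v)
            store.close()

    def test_label_order_invariance(self, tmp_store, tmp_path):
        events = [("a", None, None), ("b", "a", 96.0), ("c", "a", 80.0), ("d", "c", 99.0)]
        _seed_store(tmp_store, tmp_path, events)
        frame = lf.full_matrix(tmp_store).to_dataframe()
        for x, y in itertools.combinations("abcd", 2):
            assert frame.loc[x, y] == frame.loc[y, x]


def _naive_complete_linkage_heights(dist: np.ndarray) -> list[float]:
    """O(n^3) agglomerative oracle: merge heights under complete linkage."""
    clusters = [{i} for i in range(dist.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            d = max(dist[a, b] for a in clusters[i] for b in clusters[j])
            if best is None or d < best[0]:
                best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[i] = clusters[i] | clusters[j]
        del clusters[j]
    return heights


class TestCompleteLinkage:
    def test_identical_matrix_single_cluster_height_zero(self):
        m = SimilarityMatrix(["a", "b", "c"], np.full((3, 3), 100.0))
        linkage, leaves = lf.complete_linkage(m)
        assert np.allclose(linkage[:, 2], 0.0)
        assert sorted(leaves) == ["a", "b", "c"]

    def test_planted_split_height_is_max_distance(self):
        values = np.full((4, 4), 80.0)
        values[:2, :2] = 99.0
        values[2:, 2:] = 99.0
        np.fill_diagonal(values, 100.0)
        m = SimilarityMatrix(list("abcd"), values)
        linkage, _ = lf.complete_linkage(m)
        assert linkage[-1, 2] == pytest.approx(20.0)  # final merge at 100 - 80
        clusters = cut_clusters(linkage, m.labels, 5.0)
        assert clusters["a"] == clusters["b"]
        assert clusters["c"] == clusters["d"]
        assert clusters["a"] != clusters["c"]

    def test_agreement_with_naive_oracle(self, rng):
        for _ in range(5):
            vals = rng.uniform(70, 100, size=(6, 6))
            vals = (vals + vals.T) / 2
            np.fill_diagonal(vals, 100.0)
            m = SimilarityMatrix([f"g{i}" for i in range(6)], vals)
            linkage, _ = lf.complete_linkage(m)
            oracle = _naive_complete_linkage_heights(100.0 - vals)
            assert np.allclose(sorted(linkage[:, 2]), sorted(oracle))

    def test_newick_round_trip(self):
        from Bio import Phylo

        values = np.full((4, 4), 85.0)
        values[:2, :2] = 98.0
        values[2:, 2:] = 97.0
        np.fill_diagonal(values, 100.0)
        m = SimilarityMatrix(["w", "x", "y", "z"], values)
        linkage, _ = lf.complete_linkage(m)
        tree = Phylo.read(io.StringIO(to_newick(linkage, m.labels)), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == ["w", "x", "y", "z"]


def _random_similarity(rng, n, lo=70, hi=100):
    vals = rng.uniform(lo, hi, size=(n, n))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 100.0)
    return SimilarityMatrix([f"g{i}" for i in range(n)], vals)


class TestMantel:
    def test_self_correlation_is_one(self, rng):
        m = _random_similarity(rng, 6)
        r, p = lf.mantel(m, m, permutations=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p <= 0.05

    def test_matches_closed_form_pearson(self, rng):
        """4x4 pair: r equals the closed-form Pearson of the 6-element upper
        triangles (computed with the stdlib, independent of numpy)."""
        m1 = _random_similarity(rng, 4)
        m2 = _random_similarity(rng, 4)
        r, _ = lf.mantel(m1, m2, permutations=9, seed=1)
        oracle = statistics.correlation(
            list(m1.upper_triangle()), list(m2.upper_triangle())
        )
        assert r == pytest.approx(oracle)

    def test_matches_skbio_statistic(self, rng):
        from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel

        m1 = _random_similarity(rng, 7)
        m2 = _random_similarity(rng, 7)
        r, _ = lf.mantel(m1, m2, permutations=9, seed=2)
        d1 = DistanceMatrix(100.0 - m1.values, ids=m1.labels)
        d2 = DistanceMatrix(100.0 - m2.values, ids=m2.labels)
        result = skbio_mantel(d1, d2, permutations=0)
        r_ref = result[0] if isinstance(result, tuple) else result.statistic
        # distances are 100 - similarity, so the correlation is identical
        assert r == pytest.approx(float(r_ref))

    def test_permutation_pvalue_matches_bruteforce_oracle(self, rng):
        """Replaying the identical seeded permutation stream through an
        independent implementation must give the identical p-value."""
        m1 = _random_similarity(rng, 5)
        m2 = _random_similarity(rng, 5)
        seed, perms = 42, 199
        r_obs, p = lf.mantel(m1, m2, permutations=perms, seed=seed)

        oracle_rng = np.random.default_rng(seed)
        tri = lambda vals: [vals[i][j] for i in range(5) for j in range(i + 1, 5)]
        v1 = tri(m1.values)
        hits = 0
        for _ in range(perms):
            perm = list(oracle_rng.permutation(5))
            shuffled = [[m2.values[perm[i]][perm[j]] for j in range(5)] for i in range(5)]
            # tolerance absorbs ulp-level disagreement between the stdlib and
            # numpy correlation when a permutation reproduces r_obs exactly
            if statistics.correlation(v1, tri(shuffled)) >= r_obs - 1e-9:
                hits += 1
        assert p == (1 + hits) / (perms + 1)

    def test_label_mismatch_rejected(self, rng):
        m1 = _random_similarity(rng, 4)
        m2 = SimilarityMatrix(list("wxyz"), m1.values)
        with pytest.raises(ValueError, match="labels"):
            lf.mantel(m1, m2)

    def test_constant_matrix_undefined(self, rng):
        m1 = _random_similarity(rng, 4)
        m2 = SimilarityMatrix(m1.labels, np.full((4, 4), 100.0))
        with pytest.warns(UserWarning, match="constant"):
            r, p = lf.mantel(m1, m2, permutations=9)
        assert np.isnan(r) and np.isnan(p)


def test_matrix_save_load_round_trip(tmp_path, rng):
    m = _random_similarity(rng, 5)
    path = tmp_path / "m.tsv"
    m.save(path)
    loaded = SimilarityMatrix.load(path)
    assert loaded.labels == m.labels
    assert np.allclose(loaded.values, m.values)


def test_matrix_validates_shape_and_symmetry():
    with pytest.raises(ValueError, match="shape"):
        SimilarityMatrix(["a"], np.zeros((2, 2)))
    with pytest.raises(ValueError, match="symmetric"):
        SimilarityMatrix(["a", "b"], np.array([[100.0, 1.0], [2.0, 100.0]]))
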