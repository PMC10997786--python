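import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from metacourse.core_data import AnnotatedExpressionMatrix, TimeGrid
from metacourse.metacells import (
    aggregate_pseudobulk,
    assign_type_and_purity,
    build_knn_graph,
    construct_rmetacells,
    construct_smetacells,
    filter_for_analysis,
    single_cell_metacells,
    target_metacell_count,
)


class TestTargetMetacellCount:
    def test_paper_ratio(self):
        assert target_metacell_count(750, ratio=75) == 10

    def test_round_to_nearest_ten(self):
        # 2480 / 75 = 33.07 -> nearest multiple of 10 is 30
        assert target_metacell_count(2480, ratio=75) == 30
        assert target_metacell_count(2700, ratio=75) == 40  # 36 -> 40

    def test_floor_at_ten(self):
        assert target_metacell_count(120, ratio=75) == 10
        assert target_metacell_count(1, ratio=75) == 10

    def test_day_override(self):
        assert target_metacell_count(750, ratio=75, day=28, day_overrides={28: 20}) == 20
        assert target_metacell_count(750, ratio=75, day=25, day_overrides={28: 20}) == 10

    def test_invalid(self):
        with pytest.raises(ValueError):
            target_metacell_count(0)


class TestKnnGraph:
    def test_equilateral_equal_weights(self):
        pts = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        W = build_knn_graph(pts, k=2).toarray()
        off = W[~np.eye(3, dtype=bool)]
        assert np.allclose(off, off[0])
        assert np.allclose(np.diag(W), 1.0)
        assert np.allclose(W, W.T)

    def test_duplicate_cell_weight_one(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [6.0, 5.0]])
        W = build_knn_graph(pts, k=2).toarray()
        assert W[0, 1] == pytest.approx(1.0)

    def test_neighbors_match_bruteforce(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(150, 4))
        k = 8
        W = build_knn_graph(pts, k)
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        for i in range(150):
            expected = set(np.argsort(d2[i], kind="stable")[:k])
            got = set(W[i].indices) - {i}
            # symmetrization may add reverse edges; all true neighbors present
            assert expected <= got

    def test_bad_k(self):
        pts = np.zeros((5, 2))
        with pytest.raises(ValueError):
            build_knn_graph(pts, 0)
        with pytest.raises(ValueError):
            build_knn_graph(pts, 5)


class TestAssignTypeAndPurity:
    def test_paper_example(self):
        types = ["plasma"] * 18 + ["NK"] * 2
        assert assign_type_and_purity(types) == ("plasma", pytest.approx(0.90))

    def test_unanimous(self):
        assert assign_type_and_purity(["B"] * 7) == ("B", 1.0)

    def test_tie_lexicographic(self):
        assert assign_type_and_purity(["B"] * 10 + ["A"] * 10) == ("A", 0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assign_type_and_purity([])


class TestSmetacells:
    def test_partition_per_day(self, embedded_sim):
        matrix, _ = embedded_sim
        mcs = construct_smetacells(matrix, seed=0)
        meta = matrix.cell_meta
        for day in matrix.time_grid:
            day_cells = set(meta.loc[meta["day"] == day, "cell_id"])
            assigned = [c for m in mcs if m.day == day for c in m.member_cell_ids]
            assert len(assigned) == len(set(assigned))  # disjoint
            assert set(assigned) == day_cells  # covering

    def test_singletons_when_count_equals_cells(self, embedded_sim):
        matrix, _ = embedded_sim
        day = matrix.time_grid.days[0]
        sub = matrix.subset_cells((matrix.cell_meta["day"] == day).to_numpy())
        n = sub.n_cells
        mcs = construct_smetacells(sub, ratio=1, day_overrides={day: n}, seed=0)
        day_mcs = [m for m in mcs if m.day == day]
        assert len(day_mcs) == n
        assert all(m.n_members == 1 and m.purity == 1.0 for m in day_mcs)

    def test_two_separated_clusters_recovered(self):
        rng = np.random.default_rng(4)
        n = 60
        counts = rng.poisson(2.0, size=(2 * n, 30))
        counts[counts.sum(axis=1) == 0, 0] = 1
        meta = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(2 * n)],
                "sample_id": "s",
                "patient_id": "p",
                "day": 3,
                "cell_type": ["A"] * n + ["B"] * n,
                "severity": "mild",
            }
        )
        m = AnnotatedExpressionMatrix(
            counts=sp.csr_matrix(counts), cell_meta=meta,
            gene_ids=[f"g{i}" for i in range(30)], time_grid=TimeGrid((3, 7)),
        )
        m.normalize()
        emb = np.vstack([rng.normal(0, 0.2, (n, 2)), rng.normal(8, 0.2, (n, 2))])
        mcs = construct_smetacells(m, embedding=emb, day_overrides={3: 2}, seed=0)
        assert len(mcs) == 2
        groups = [set(mc.member_cell_ids) for mc in mcs]
        expected = [set(meta["cell_id"][:n]), set(meta["cell_id"][n:])]
        assert groups == expected or groups == expected[::-1]
        assert all(mc.purity == 1.0 for mc in mcs)

    def test_deterministic(self, embedded_sim):
        matrix, _ = embedded_sim
        a = construct_smetacells(matrix, seed=1)
        b = construct_smetacells(matrix, seed=1)
        assert [m.member_cell_ids for m in a] == [m.member_cell_ids for m in b]

    def test_requires_embedding(self, toy_matrix):
        toy_matrix.normalize()
        with pytest.raises(ValueError, match="embedding"):
            construct_smetacells(toy_matrix)


class TestRmetacells:
    def test_exact_stratum_mean(self, embedded_sim):
        matrix, _ = embedded_sim
        meta = matrix.cell_meta
        day = matrix.time_grid.days[0]
        ctype = "type_0"
        stratum = np.flatnonzero(
            (meta["day"] == day).to_numpy() & (meta["cell_type"] == ctype).to_numpy()
        )
        n = stratum.size
        mcs = construct_rmetacells(matrix, n_per_metacell=n, n_replicates=1, seed=0)
        target = [m for m in mcs if m.day == day and m.cell_type == ctype]
        assert len(target) == 1 and target[0].n_members == n
        expected = np.asarray(matrix.normalized[stratum].mean(axis=0)).ravel()
        np.testing.assert_allclose(target[0].expression, expected, rtol=1e-12)

    def test_purity_always_one(self, embedded_sim):
        matrix, _ = embedded_sim
        mcs = construct_rmetacells(matrix, seed=5)
        assert all(m.purity == 1.0 for m in mcs)
        assert all(m.n_members == 20 for m in mcs)

    def test_small_stratum_skipped(self, embedded_sim, caplog):
        matrix, _ = embedded_sim
        n_small = matrix.cell_meta.groupby(["day", "cell_type"]).size().min()
        mcs = construct_rmetacells(matrix, n_per_metacell=n_small + 1, seed=0)
        sizes = matrix.cell_meta.groupby(["day", "cell_type"]).size()
        expected_strata = (sizes >= n_small + 1).sum()
        built = {(m.day, m.cell_type) for m in mcs}
        assert len(built) == expected_strata

    def test_unbiased_across_seeds(self, embedded_sim):
        matrix, _ = embedded_sim
        meta = matrix.cell_meta
        day, ctype = matrix.time_grid.days[0], "type_0"
        stratum = np.flatnonzero(
            (meta["day"] == day).to_numpy() & (meta["cell_type"] == ctype).to_numpy()
        )
        true_mean = np.asarray(matrix.normalized[stratum].mean(axis=0)).ravel()
        reps = []
        for seed in range(40):
            mcs = construct_rmetacells(matrix, n_per_metacell=20, n_replicates=1, seed=seed)
            m = next(x for x in mcs if x.day == day and x.cell_type == ctype)
            reps.append(m.expression)
        avg = np.mean(reps, axis=0)
        # deviation of the across-seed average shrinks well below one draw's SD
        one_draw_sd = np.std(reps, axis=0).mean()
        assert np.abs(avg - true_mean).mean() < one_draw_sd / 3


class TestPseudobulk:
    def test_single_cell_stratum_equals_renormalized_cell(self, toy_matrix):
        mcs = aggregate_pseudobulk(toy_matrix)
        m = next(x for x in mcs if x.sample_id == "s1")
        counts = np.array([0, 5.0])
        expected = np.log1p(counts / counts.sum() * 1e4)
        np.testing.assert_allclose(m.expression, expected, rtol=1e-12)

    def test_hand_formula_two_cells(self):
        counts = np.array([[1, 0], [1, 2]])
        meta = pd.DataFrame(
            {
                "cell_id": ["a", "b"],
                "sample_id": "s",
                "patient_id": "p",
                "day": 3,
                "cell_type": "T",
                "severity": "mild",
            }
        )
        m = AnnotatedExpressionMatrix(
            counts=sp.csr_matrix(counts), cell_meta=meta, gene_ids=["g0", "g1"],
            time_grid=TimeGrid((3, 7)),
        )
        mcs = aggregate_pseudobulk(m)
        assert len(mcs) == 1
        # summed counts [2, 2], total 4 -> ln(1 + 0.5 * 1e4)
        np.testing.assert_allclose(
            mcs.metacells[0].expression, np.log1p(np.array([0.5, 0.5]) * 1e4)
        )

    def test_member_conservation(self, embedded_sim):
        matrix, _ = embedded_sim
        mcs = aggregate_pseudobulk(matrix)
        total = sum(m.n_members for m in mcs)
        assert total == matrix.n_cells

    def test_all_cells_mode(self, embedded_sim):
        matrix, _ = embedded_sim
        mcs = aggregate_pseudobulk(matrix, by_cell_type=False)
        assert {m.cell_type for m in mcs} == {"all"}
        assert len(mcs) == matrix.cell_meta["sample_id"].nunique()


class TestFilterForAnalysis:
    def test_low_count_type_removed(self, embedded_sim):
        matrix, _ = embedded_sim
        mcs = single_cell_metacells(matrix)
        per_type = matrix.cell_meta.groupby("cell_type").size()
        threshold = int(per_type.max())  # all types below max+? keep only the max one(s)
        out = filter_for_analysis(mcs, min_cells_per_type=threshold)
        kept_types = {m.cell_type for m in out}
        assert kept_types == set(per_type[per_type >= threshold].index)

    def test_499_vs_500(self):
        counts = sp.csr_matrix(np.ones((499, 2), dtype=int))
        meta = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(499)],
                "sample_id": "s",
                "patient_id": "p",
                "day": 3,
                "cell_type": "rare",
                "severity": "mild",
            }
        )
        m = AnnotatedExpressionMatrix(
            counts=counts, cell_meta=meta, gene_ids=["g0", "g1"],
            time_grid=TimeGrid((3, 7)),
        )
        m.normalize()
        mcs = single_cell_metacells(m)
        with pytest.raises(ValueError, match="every metacell"):
            filter_for_analysis(mcs, min_cells_per_type=500)

    def test_purity_threshold(self, embedded_sim):
        matrix, _ = embedded_sim
        mcs = construct_smetacells(matrix, seed=0)
        for m, p in zip(mcs.metacells[:2], (0.96, 0.90)):
            m.purity = p
        out = filter_for_analysis(mcs, min_cells_per_type=0, purity_min=0.95)
        ids = {m.id for m in out}
        assert mcs.metacells[0].id in ids and mcs.metacells[1].id not in ids

    def test_empty_mask_identity(self, embedded_sim):
        matrix, _ = embedded_sim
        mcs = construct_smetacells(matrix, seed=0)
        out = filter_for_analysis(mcs, min_cells_per_type=0, day_masks={})
        assert len(out) == len(mcs)

    def test_day_mask_applied(self, embedded_sim):
        matrix, _ = embedded_sim
        mcs = construct_rmetacells(matrix, seed=0)
        out = filter_for_analysis(
            mcs, min_cells_per_type=0, day_masks={"type_0": [3, 7, 9]}
        )
        assert not any(m.cell_type == "type_0" and m.day in (3, 7, 9) for m in out)
        assert any(m.cell_type == "type_1" and m.day == 3 for m in out)


class TestVarianceDirection:
    def test_smetacell_variance_exceeds_rmetacell(self, embedded_sim):
        """With planted within-type states, similarity-based metacells keep
        more across-replicate variance than random ones."""
        matrix, _ = embedded_sim
        smc = construct_smetacells(matrix, seed=0)
        rmc = construct_rmetacells(matrix, seed=0)

        def within_type_sd(mcs):
            meta = mcs.meta_table()
            expr = mcs.expression_matrix()
            sds = []
            for (ct, day), grp in meta.groupby(["cell_type", "day"]):
                if len(grp) >= 2:
                    sds.append(expr[grp.index.to_numpy()].std(axis=0, ddof=1).mean())
            return np.mean(sds)

        assert within_type_sd(smc) > within_type_sd(rmc)

    def test_purity_high_on_separable_sim(self, embedded_sim):
        matrix, _ = embedded_sim
        mcs = construct_smetacells(matrix, seed=0)
        assert np.mean([m.purity for m in mcs]) >= 0.9
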