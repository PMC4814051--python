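"""Co-expression network: adjacency, TOM, module derivation, calibration,
merging, scale-not-center scoring, preservation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import txconcord as tx
from txconcord.network import ModuleMember, ModuleModel


def _single_gene_model(loading=1.0, sd=1.0, raw_sd=2.0):
    return ModuleModel(
        module_id="M1",
        members=[ModuleMember("g1", loading, 0.0, sd)],
        raw_score_sd=raw_sd,
        pc1_variance_fraction=1.0,
    )


class TestAdjacencyAndTOM:
    def test_perfect_and_anti_correlation_both_fully_adjacent(self):
        frame = pd.DataFrame(
            [[1.0, 2, 3, 4], [2, 4, 6, 8], [-1, -2, -3, -4]],
            index=["a", "b", "c"], columns=list("wxyz"))
        adj = tx.soft_adjacency(tx.LogFCMatrix(frame))
        assert adj.loc["a", "b"] == pytest.approx(1.0)
        assert adj.loc["a", "c"] == pytest.approx(1.0)  # unsigned convention

    def test_power_arithmetic(self, rng):
        # force pairwise correlation 0.5 analytically via constructed vectors
        x = np.array([1.0, -1, 1, -1, 1, -1, 1, -1])
        y = np.array([1.0, -1, 1, -1, -1, 1, -1, 1])
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(0.0)
        z = (x + y) / np.sqrt(2)
        frame = pd.DataFrame([x, z], index=["a", "b"], columns=[f"e{i}" for i in range(8)])
        adj = tx.soft_adjacency(tx.LogFCMatrix(frame))
        r = np.corrcoef(x, z)[0, 1]
        assert adj.loc["a", "b"] == pytest.approx(abs(r) ** 8)

    def test_tom_two_gene_full_adjacency(self):
        adj = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]], index=list("ab"), columns=list("ab"))
        tom = tx.tom_similarity(adj)
        assert tom.loc["a", "b"] == pytest.approx(1.0)

    def test_tom_isolated_genes(self):
        adj = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        tom = tx.tom_similarity(adj)
        off = tom.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.0)

    def test_tom_three_gene_hand_value(self):
        # a_ij = 0.5 everywhere: k_i = 1, shared = 0.25,
        # TOM = (0.25 + 0.5) / (1 + 1 - 0.5) = 0.5
        A = np.full((3, 3), 0.5)
        np.fill_diagonal(A, 1.0)
        adj = pd.DataFrame(A, index=list("abc"), columns=list("abc"))
        tom = tx.tom_similarity(adj)
        assert tom.loc["a", "b"] == pytest.approx(0.5)

    def test_tom_matches_brute_force_oracle(self, rng):
        n = 30
        R = np.corrcoef(rng.normal(size=(n, 40)))
        A = np.abs(R) ** 8
        np.fill_diagonal(A, 1.0)
        ids = [f"g{i}" for i in range(n)]
        tom = tx.tom_similarity(pd.DataFrame(A, index=ids, columns=ids)).to_numpy()
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                k_i = sum(A[i, u] for u in range(n) if u != i)
                k_j = sum(A[j, u] for u in range(n) if u != j)
                shared = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
                expected = (shared + A[i, j]) / (min(k_i, k_j) + 1 - A[i, j])
                assert tom[i, j] == pytest.approx(expected, abs=1e-9)


class TestDeriveModules:
    def test_planted_blocks_recovered_exactly(self, two_block_logfc):
        clusters = tx.derive_modules(two_block_logfc)
        assert sorted(map(tuple, clusters)) == [
            tuple(f"a{i}" for i in range(6)), tuple(f"b{i}" for i in range(6))]

    def test_pure_noise_recovers_nothing_planted(self, rng):
        frame = pd.DataFrame(rng.normal(size=(60, 40)),
                             index=[f"g{i:02d}" for i in range(60)],
                             columns=[f"e{i}" for i in range(40)])
        clusters = tx.derive_modules(tx.LogFCMatrix(frame))
        planted = [set(f"g{i:02d}" for i in range(k, k + 10)) for k in (0, 10, 20)]
        for c in clusters:
            for p in planted:
                jacc = len(p & set(c)) / len(p | set(c))
                assert jacc < 0.2

    def test_min_cluster_size_enforced(self, rng):
        # one strong block of 4 genes only: too small to be reported
        s = rng.normal(size=30)
        X = np.vstack([np.outer(np.ones(4), s), rng.normal(size=(20, 30))])
        frame = pd.DataFrame(X, index=[f"g{i}" for i in range(24)],
                             columns=[f"e{i}" for i in range(30)])
        clusters = tx.derive_modules(tx.LogFCMatrix(frame), min_cluster_size=5)
        block = {"g0", "g1", "g2", "g3"}
        assert not any(block <= set(c) and len(c) < 8 for c in clusters)

    def test_too_few_experiments_rejected(self):
        frame = pd.DataFrame(np.ones((10, 2)) + np.eye(10, 2),
                             index=[f"g{i}" for i in range(10)], columns=["e1", "e2"])
        with pytest.raises(ValueError, match="3 training experiments"):
            tx.derive_modules(tx.LogFCMatrix(frame))


class TestCalibration:
    def test_single_gene_module(self, rng):
        frame = pd.DataFrame(rng.normal(size=(1, 20)), index=["g1"],
                             columns=[f"e{i}" for i in range(20)])
        logfc = tx.LogFCMatrix(frame)
        model = tx.calibrate_module(["g1"], logfc, "M1")
        assert abs(model.members[0].loading) == pytest.approx(1.0)
        assert model.pc1_variance_fraction == pytest.approx(1.0)

    def test_two_identical_genes_symmetric(self, rng):
        x = rng.normal(size=25)
        frame = pd.DataFrame([x, x], index=["g1", "g2"],
                             columns=[f"e{i}" for i in range(25)])
        model = tx.calibrate_module(["g1", "g2"], tx.LogFCMatrix(frame), "M1")
        l1, l2 = (m.loading for m in model.members)
        assert l1 == pytest.approx(l2)
        assert model.pc1_variance_fraction == pytest.approx(1.0)

    def test_planted_loadings_recovered_at_zero_noise(self, rng):
        w = rng.normal(0.5, 1.0, size=10)  # mixed signs
        s = rng.normal(size=60)
        frame = pd.DataFrame(np.outer(w, s), index=[f"g{i}" for i in range(10)],
                             columns=[f"e{i}" for i in range(60)])
        model = tx.calibrate_module(list(frame.index), tx.LogFCMatrix(frame), "M1")
        loadings = np.array([m.loading for m in model.members])
        # after per-gene z-scoring the planted weights become +/- equal, so
        # recovered loadings have equal magnitude and carry the signs of w
        assert np.allclose(np.abs(loadings), 1 / np.sqrt(10), atol=1e-9)
        sign_match = np.sign(loadings) == np.sign(w)
        assert sign_match.all() or (~sign_match).all()
        assert model.pc1_variance_fraction == pytest.approx(1.0)

    def test_zero_sd_member_rejected(self):
        frame = pd.DataFrame([[1.0, 1.0, 1.0], [0.1, 0.2, 0.3]],
                             index=["flat", "ok"], columns=list("abc"))
        with pytest.raises(ValueError, match="flat"):
            tx.calibrate_module(["flat", "ok"], tx.LogFCMatrix(frame), "M1")


class TestMerging:
    def _cohort(self, group_rhos, rng, n_exp=80, genes_per_module=4):
        """Modules driven by latents; listed groups share a latent."""
        frames, modules = [], []
        gidx = 0
        for g, rho in enumerate(group_rhos):
            base = rng.normal(size=n_exp)
            for m in range(2):
                latent = rho * base + np.sqrt(1 - rho**2) * rng.normal(size=n_exp)
                w = np.abs(rng.normal(1, 0.2, size=genes_per_module))
                block = np.outer(w, latent) + rng.normal(0, 0.05, (genes_per_module, n_exp))
                ids = [f"g{gidx + i}" for i in range(genes_per_module)]
                gidx += genes_per_module
                frames.append(pd.DataFrame(block, index=ids))
                modules.append(ids)
        frame = pd.concat(frames)
        frame.columns = [f"e{i}" for i in range(n_exp)]
        return tx.LogFCMatrix(frame), modules

    def test_high_correlation_merges_low_does_not(self, rng):
        logfc, module_genes = self._cohort([0.97, 0.3], rng)
        models = [tx.calibrate_module(g, logfc, f"M{i}") for i, g in enumerate(module_genes)]
        out = tx.merge_modules(models, logfc)
        merged = [m for m in out if m.kind == "merged"]
        assert len(merged) == 1
        assert sorted(merged[0].gene_ids) == sorted(module_genes[0] + module_genes[1])
        # the uncorrelated pair stays base and unmerged
        assert all(m.is_base for m in out if m.module_id in ("M2", "M3"))
        # constituents of the merge lose base status
        assert not any(m.is_base for m in out if m.module_id in ("M0", "M1"))

    def test_transitive_chain_merges_as_one_component(self, rng):
        # a-b and b-c correlate above threshold, a-c below: single 3-way merge
        n = 100
        b = rng.normal(size=n)
        a = 0.85 * b + np.sqrt(1 - 0.85**2) * rng.normal(size=n)
        c = 0.85 * b - np.sqrt(1 - 0.85**2) * rng.normal(size=n)
        frames = []
        for name, latent in zip("abc", (a, b, c)):
            w = np.abs(rng.normal(1, 0.1, 5))
            frames.append(pd.DataFrame(
                np.outer(w, latent) + rng.normal(0, 0.02, (5, n)),
                index=[f"{name}{i}" for i in range(5)]))
        frame = pd.concat(frames)
        frame.columns = [f"e{i}" for i in range(n)]
        logfc = tx.LogFCMatrix(frame)
        models = [tx.calibrate_module([f"{nm}{i}" for i in range(5)], logfc, f"M_{nm}")
                  for nm in "abc"]
        scores = tx.training_scores(models, logfc)
        R = np.corrcoef(scores.to_numpy())
        assert R[0, 1] >= 0.8 and R[1, 2] >= 0.8 and R[0, 2] < 0.8
        out = tx.merge_modules(models, logfc)
        merged = [m for m in out if m.kind == "merged"]
        assert len(merged) == 1 and len(merged[0]) == 15

    def test_merge_bookkeeping_identity(self, small_models):
        merged = [m for m in small_models if m.kind == "merged"]
        derived = [m for m in small_models if m.kind == "unmerged"]
        n_merging = sum(len(m.constituents) for m in merged)
        n_base = sum(1 for m in small_models if m.is_base)
        # base modules = merged groups + derived modules that did not merge
        assert n_base == (len(derived) - n_merging) + len(merged)
        assert all(len(m.constituents) >= 2 for m in merged)
        assert {c for m in merged for c in m.constituents} == {
            m.module_id for m in small_models if not m.is_base}

    def test_constituent_correlates_with_merged_parent(self, rng):
        logfc, module_genes = self._cohort([0.95], rng)
        models = [tx.calibrate_module(g, logfc, f"M{i}") for i, g in enumerate(module_genes)]
        out = tx.merge_modules(models, logfc)
        scores = tx.training_scores(out, logfc)
        parent = [m.module_id for m in out if m.kind == "merged"][0]
        for child in ("M0", "M1"):
            r = np.corrcoef(scores.loc[child], scores.loc[parent])[0, 1]
            assert abs(r) >= 0.8


class TestScoring:
    def test_zero_profile_scores_exactly_zero(self, small_models):
        genes = {g for m in small_models for g in m.gene_ids}
        zero = pd.Series(0.0, index=sorted(genes))
        for model in small_models:
            assert tx.score_experiment(zero, model).score == 0.0

    def test_hand_arithmetic(self):
        model = _single_gene_model(loading=1.0, sd=1.0, raw_sd=2.0)
        profile = pd.Series({"g1": 3.0})
        assert tx.score_experiment(profile, model).score == pytest.approx(1.5)

    def test_training_scores_have_unit_sd(self, small_scores):
        sds = small_scores.std(axis=1, ddof=1)
        assert np.allclose(sds, 1.0, atol=1e-9)

    def test_scoring_training_experiment_is_consistent(self, small_cohort, small_models):
        logfc, _, _ = small_cohort
        eid = logfc.experiments[0]
        mat = tx.training_scores(small_models, logfc)
        one = tx.score_experiment(logfc.profile(eid), small_models[0])
        assert one.score == pytest.approx(mat.loc[small_models[0].module_id, eid])

    @given(alpha=st.floats(-3, 3))
    def test_linearity_in_profile(self, alpha):
        model = _single_gene_model()
        base = pd.Series({"g1": 1.7})
        s1 = tx.score_experiment(base, model).score
        s2 = tx.score_experiment(alpha * base, model).score
        assert s2 == pytest.approx(alpha * s1, abs=1e-9)

    def test_missing_members_reduce_coverage_and_flag(self):
        model = ModuleModel("M1", [ModuleMember(f"g{i}", 1.0, 0.0, 1.0) for i in range(5)],
                            raw_score_sd=1.0, pc1_variance_fraction=0.5)
        profile = pd.Series({"g0": 1.0, "g1": 1.0})
        res = tx.score_experiment(profile, model)
        assert res.coverage == pytest.approx(0.4)
        assert res.low_confidence

    def test_no_members_present_is_missing(self):
        model = _single_gene_model()
        res = tx.score_experiment(pd.Series({"other": 1.0}), model)
        assert np.isnan(res.score)

    def test_cross_system_sd_source_changes_scores_little_when_sds_agree(
            self, small_cohort, small_models):
        logfc, _, _ = small_cohort
        train_sd = logfc.frame.std(axis=1, ddof=1)
        jittered = train_sd * np.exp(np.random.default_rng(1).normal(0, 0.05, len(train_sd)))
        jittered = pd.Series(jittered, index=train_sd.index)
        base = tx.score_matrix(logfc, small_models)
        alt = tx.score_matrix(logfc, small_models, gene_sd=jittered)
        for mid in base.index:
            r = np.corrcoef(base.loc[mid], alt.loc[mid])[0, 1]
            assert r > 0.98


class TestActivity:
    def test_avg_abs_eg_cases(self, small_models):
        base_ids = [m.module_id for m in small_models if m.is_base]
        scores = pd.Series(0.0, index=[m.module_id for m in small_models])
        assert tx.avg_abs_eg(scores, small_models) == 0.0
        scores[:] = 0.0
        scores[base_ids[0]] = 1.0
        if len(base_ids) > 1:
            scores[base_ids[1]] = -1.0
            expected = 2.0 / len(base_ids)
        else:
            expected = 1.0 / len(base_ids)
        assert tx.avg_abs_eg(scores, small_models) == pytest.approx(expected)

    def test_base_restriction_matters(self, rng):
        models = [
            ModuleModel("A", [ModuleMember("g1", 1.0, 0.0, 1.0)], 1.0, 1.0, is_base=True),
            ModuleModel("B", [ModuleMember("g2", 1.0, 0.0, 1.0)], 1.0, 1.0, is_base=False),
        ]
        scores = pd.Series({"A": 1.0, "B": 5.0})
        assert tx.avg_abs_eg(scores, models) == pytest.approx(1.0)
        assert scores.abs().mean() != pytest.approx(1.0)


class TestPreservation:
    def test_planted_module_strongly_preserved(self, two_block_logfc, rng):
        noisy = tx.LogFCMatrix(two_block_logfc.frame
                               + rng.normal(0, 0.05, two_block_logfc.frame.shape))
        model = tx.calibrate_module([f"a{i}" for i in range(6)], noisy, "M1")
        z = tx.preservation_z(model, noisy, n_random=200, rng=rng)
        assert z > 5

    def test_random_selection_scores_near_zero(self, rng):
        frame = pd.DataFrame(rng.normal(size=(80, 50)),
                             index=[f"g{i}" for i in range(80)],
                             columns=[f"e{i}" for i in range(50)])
        logfc = tx.LogFCMatrix(frame)
        members = [f"g{i}" for i in range(0, 40, 5)]
        model = ModuleModel("R", [ModuleMember(g, 1.0, 0.0, 1.0) for g in members],
                            1.0, 0.5)
        z = tx.preservation_z(model, logfc, n_random=200, rng=rng)
        assert abs(z) < 3


class TestSerialization:
    def test_round_trip(self, small_models, tmp_path):
        tx.network.save_modules(small_models, tmp_path / "m.tsv", tmp_path / "m.json")
        back = tx.network.load_modules(tmp_path / "m.tsv", tmp_path / "m.json")
        assert [m.module_id for m in back] == [m.module_id for m in small_models]
        for a, b in zip(back, small_models):
            assert a.raw_score_sd == pytest.approx(b.raw_score_sd)
            assert a.is_base == b.is_base
            assert [x.gene_id for x in a.members] == [x.gene_id for x in b.members]
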