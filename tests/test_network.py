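import numpy as np
import pandas as pd
import pytest
from scipy import stats

from toxmodnet.network import (
    NetworkParams,
    adjacency,
    build_module_set,
    cluster_modules,
    compute_coreg_hub,
    compute_eigengenes,
    enrich_modules,
    merge_modules,
    pick_soft_power,
    scale_free_fit,
    tom_similarity,
)

from conftest import random_logfc


def _block_matrix(rng, blocks=(10, 10), n_bg=0, n_cond=60, noise=0.3):
    """Conditions x genes frame with planted correlated blocks."""
    cols, data, labels = [], [], []
    for b, size in enumerate(blocks, start=1):
        driver = rng.normal(0, 1, n_cond)
        for j in range(size):
            data.append(driver + rng.normal(0, noise, n_cond))
            cols.append(f"b{b}g{j:02d}")
            labels.append(b)
    for j in range(n_bg):
        data.append(rng.normal(0, 1, n_cond))
        cols.append(f"bg{j:02d}")
        labels.append(0)
    df = pd.DataFrame(np.array(data).T, columns=cols)
    return df, pd.Series(labels, index=cols)


class TestAdjacency:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(12, 5)), columns=list("abcde"))
        adj = adjacency(df, beta=3)
        assert np.allclose(np.diag(adj), 1.0)

    def test_perfect_anticorrelation_is_one_in_unsigned_network(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"up": x, "down": -x})
        for beta in (1, 3, 9):
            assert adjacency(df, beta).loc["up", "down"] == pytest.approx(1.0)

    def test_matches_elementwise_power_oracle(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(6, 10)))
        adj = adjacency(df, beta=3)
        oracle = np.abs(np.corrcoef(df.to_numpy(), rowvar=False)) ** 3
        np.fill_diagonal(oracle, 1.0)
        assert np.allclose(adj.to_numpy(), oracle)

    def test_constant_gene_named_in_error(self):
        df = pd.DataFrame({"ok": [1.0, 2, 3], "flat": [5.0, 5, 5]})
        with pytest.raises(ValueError, match="flat"):
            adjacency(df, beta=2)


class TestTOM:
    @staticmethod
    def _tom_bruteforce(A):
        n = A.shape[0]
        k = A.sum(axis=1) - 1.0
        T = np.eye(n)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                shared = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
                T[i, j] = (shared + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
        return T

    def test_two_isolated_genes_closed_form(self):
        # genes 0,1 connected only to each other with a -> t01 = a
        a = 0.6
        A = np.eye(4)
        A[0, 1] = A[1, 0] = a
        tom = tom_similarity(pd.DataFrame(A))
        assert tom.iloc[0, 1] == pytest.approx(a)

    def test_identical_rows_with_full_link_give_one(self):
        # maximal overlap: i and j fully linked and sharing every neighbor
        A = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
        tom = tom_similarity(pd.DataFrame(A))
        assert tom.iloc[0, 1] == pytest.approx(1.0)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = int(rng.integers(5, 9))
            C = rng.uniform(-1, 1, (n, n))
            A = np.abs((C + C.T) / 2) ** 2
            np.fill_diagonal(A, 1.0)
            tom = tom_similarity(pd.DataFrame(A))
            assert np.allclose(tom.to_numpy(), self._tom_bruteforce(A), atol=1e-10)

    def test_range_and_symmetry(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(30, 15)))
        tom = tom_similarity(adjacency(df, 4))
        T = tom.to_numpy()
        assert np.allclose(T, T.T)
        assert (T >= 0).all() and (T <= 1).all()
        assert np.allclose(np.diag(T), 1.0)


class TestSoftPower:
    def test_white_noise_never_reaches_target(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(60, 150)))
        with pytest.warns(UserWarning, match="argmax"):
            fit = pick_soft_power(df, target_r2=0.95)
        assert not fit.reached_target

    def test_zero_target_returns_smallest_candidate(self):
        rng = np.random.default_rng(5)
        df, _ = _block_matrix(rng, blocks=(15, 15), n_bg=20, n_cond=40)
        fit = pick_soft_power(df, target_r2=0.0)
        assert fit.beta == 1 and fit.reached_target

    def test_modular_data_matches_grid_scan_oracle(self, network_dataset):
        fit = pick_soft_power(network_dataset.logfc, target_r2=0.85)
        table = fit.table
        passing = table.loc[table["signed_r2"] >= 0.85, "power"]
        assert fit.beta == int(passing.iloc[0])

    def test_too_few_genes_for_bins(self):
        with pytest.raises(ValueError, match="bins"):
            scale_free_fit(np.array([1.0, 2.0]), n_bins=10)


class TestClustering:
    def test_two_separated_blocks_fully_recovered(self):
        rng = np.random.default_rng(6)
        df, labels = _block_matrix(rng, blocks=(25, 25), n_cond=80, noise=0.3)
        tom = tom_similarity(adjacency(df, 6))
        got = cluster_modules(tom, NetworkParams(min_module_size=5))
        # ARI == 1 against planted labels
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels.to_numpy(), got.to_numpy()) == 1.0

    def test_uncorrelated_genes_all_unassigned(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.normal(size=(80, 60)),
                          columns=[f"g{i}" for i in range(60)])
        tom = tom_similarity(adjacency(df, 6))
        got = cluster_modules(tom, NetworkParams(min_module_size=20))
        assert (got == 0).all()

    def test_fewer_genes_than_min_size_warns(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(20, 5)))
        tom = tom_similarity(adjacency(df, 2))
        with pytest.warns(UserWarning):
            got = cluster_modules(tom, NetworkParams(min_module_size=20))
        assert (got == 0).all()

    def test_module_ids_ordered_by_decreasing_size(self):
        rng = np.random.default_rng(9)
        df, _ = _block_matrix(rng, blocks=(30, 12), n_bg=20, n_cond=80)
        tom = tom_similarity(adjacency(df, 6))
        got = cluster_modules(tom, NetworkParams(min_module_size=5))
        sizes = got[got != 0].value_counts().sort_index()
        assert list(sizes) == sorted(sizes, reverse=True)


class TestEigengenes:
    def test_identical_profiles_rank_one_case(self):
        rng = np.random.default_rng(10)
        profile = rng.normal(0, 2, 40)
        df = pd.DataFrame({f"g{i}": profile * (i + 1) for i in range(5)})
        assignment = pd.Series(1, index=df.columns)
        egs, report = compute_eigengenes(df, assignment)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        r = np.corrcoef(egs[1], z)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10) and r > 0
        assert report.iloc[0]["explained_variance"] == pytest.approx(1.0)
        assert egs[1].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_equals_first_svd_component_up_to_sign(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(rng.normal(size=(30, 8)), columns=[f"g{i}" for i in range(8)])
        assignment = pd.Series(1, index=df.columns)
        egs, _ = compute_eigengenes(df, assignment)
        X = df.to_numpy()
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        U, S, Vt = np.linalg.svd(Z, full_matrices=False)
        assert abs(np.corrcoef(egs[1], U[:, 0])[0, 1]) == pytest.approx(1.0, abs=1e-10)

    def test_orientation_against_module_mean_profile(self):
        rng = np.random.default_rng(12)
        for trial in range(5):
            df = pd.DataFrame(rng.normal(size=(25, 6)), columns=[f"g{i}" for i in range(6)])
            assignment = pd.Series(1, index=df.columns)
            egs, _ = compute_eigengenes(df, assignment)
            Z = (df - df.mean()) / df.std(ddof=1)
            assert np.corrcoef(egs[1], Z.mean(axis=1))[0, 1] >= 0

    def test_single_gene_module_flagged(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame(rng.normal(size=(20, 3)), columns=["a", "b", "c"])
        assignment = pd.Series([1, 1, 2], index=df.columns)
        with pytest.warns(UserWarning, match="single-gene"):
            egs, report = compute_eigengenes(df, assignment)
        assert report.set_index("module").loc[2, "degenerate"]
        assert egs[2].std(ddof=1) == pytest.approx(1.0)

    def test_unit_variance_contract(self, network_dataset):
        assignment = network_dataset.truth_assignment
        egs, _ = compute_eigengenes(network_dataset.logfc, assignment)
        assert np.allclose(egs.std(ddof=1), 1.0, atol=1e-9)


class TestMerging:
    def test_duplicated_module_merges_to_one(self):
        rng = np.random.default_rng(14)
        df, _ = _block_matrix(rng, blocks=(20,), n_cond=50, noise=0.2)
        assignment = pd.Series([1] * 10 + [2] * 10, index=df.columns)
        merged = merge_modules(df, assignment, 0.8)
        assert merged.nunique() == 1 and set(merged) == {1}

    def test_exactly_one_merge_among_three_modules(self):
        rng = np.random.default_rng(15)
        n = 60
        d1 = rng.normal(0, 1, n)
        d2 = 0.95 * d1 + np.sqrt(1 - 0.95**2) * rng.normal(0, 1, n)  # EG cor ~0.95
        d3 = rng.normal(0, 1, n)  # independent
        cols, data, labels = [], [], []
        for b, drv in enumerate((d1, d2, d3), start=1):
            for j in range(8):
                data.append(drv + rng.normal(0, 0.15, n))
                cols.append(f"m{b}g{j}")
                labels.append(b)
        df = pd.DataFrame(np.array(data).T, columns=cols)
        assignment = pd.Series(labels, index=cols)
        egs, _ = compute_eigengenes(df, assignment)
        cor = egs.corr()
        assert cor.loc[1, 2] > 0.8 and cor.loc[1, 3] < 0.5 and cor.loc[2, 3] < 0.5
        merged = merge_modules(df, assignment, 0.8)
        assert merged.nunique() == 2

    def test_threshold_one_with_noisy_data_never_merges(self):
        rng = np.random.default_rng(16)
        df, labels = _block_matrix(rng, blocks=(10, 10), n_cond=50)
        merged = merge_modules(df, labels, 1.0)
        assert merged.nunique() == 2

    def test_merge_fixpoint_no_pair_reaches_threshold(self, network_dataset):
        from toxmodnet.network import cluster_modules, tom_similarity, adjacency

        tom = tom_similarity(adjacency(network_dataset.logfc, 6))
        assignment = cluster_modules(tom, NetworkParams(beta=6))
        merged = merge_modules(network_dataset.logfc, assignment, 0.8)
        egs, _ = compute_eigengenes(network_dataset.logfc, merged)
        cor = egs.corr().to_numpy()
        np.fill_diagonal(cor, 0.0)
        assert cor.max() < 0.8


class TestCorEGHub:
    def test_single_gene_module(self):
        rng = np.random.default_rng(17)
        df = pd.DataFrame(rng.normal(size=(20, 1)), columns=["solo"])
        assignment = pd.Series([1], index=["solo"])
        with pytest.warns(UserWarning):
            egs, _ = compute_eigengenes(df, assignment)
        coreg, hub = compute_coreg_hub(df, assignment, egs)
        assert coreg["solo"] == pytest.approx(1.0)
        assert hub[1] == "solo"

    def test_hub_has_maximal_coreg_and_matches_oracle(self):
        rng = np.random.default_rng(18)
        df, labels = _block_matrix(rng, blocks=(12,), n_cond=40)
        egs, _ = compute_eigengenes(df, labels)
        coreg, hub = compute_coreg_hub(df, labels, egs)
        oracle = {g: np.corrcoef(df[g], egs[1])[0, 1] for g in df.columns}
        for g in df.columns:
            assert coreg[g] == pytest.approx(oracle[g], abs=1e-12)
        assert coreg[hub[1]] == max(coreg)


class TestEnrichment:
    def test_exact_tail_probability_for_identical_set(self):
        genes = [f"g{i}" for i in range(20)]
        assignment = pd.Series(0, index=pd.Index(genes))
        assignment.iloc[:5] = 1
        table, annotation = enrich_modules(assignment, {"S": set(genes[:5])}, set(genes))
        from math import comb

        assert table.iloc[0]["p"] == pytest.approx(1 / comb(20, 5))
        assert annotation[1][0] == "S"

    def test_zero_overlap_gives_none(self):
        genes = [f"g{i}" for i in range(10)]
        assignment = pd.Series(0, index=pd.Index(genes))
        assignment.iloc[:4] = 1
        _, annotation = enrich_modules(assignment, {"S": set(genes[5:])}, set(genes))
        assert annotation[1] is None

    def test_matches_hypergeometric_bh_oracle(self):
        rng = np.random.default_rng(19)
        genes = [f"g{i}" for i in range(40)]
        assignment = pd.Series(0, index=pd.Index(genes))
        assignment.iloc[:10] = 1
        assignment.iloc[10:18] = 2
        sets = {f"S{k}": set(rng.choice(genes, size=8, replace=False)) for k in range(4)}
        table, _ = enrich_modules(assignment, sets, set(genes))
        from statsmodels.stats.multitest import multipletests

        ps = []
        for m in (1, 2):
            mg = set(assignment.index[assignment == m])
            for k in range(4):
                ov = len(mg & sets[f"S{k}"])
                ps.append(float(stats.hypergeom.sf(ov - 1, 40, len(sets[f"S{k}"]), len(mg))))
        expected = multipletests(np.array(ps), method="fdr_bh")[1]
        assert np.allclose(np.sort(table["padj"]), np.sort(expected))

    def test_empty_collection_warns(self):
        assignment = pd.Series([1, 1, 0], index=["a", "b", "c"])
        with pytest.warns(UserWarning, match="empty"):
            _, annotation = enrich_modules(assignment, {}, {"a", "b", "c"})
        assert annotation[1] is None


def test_permutation_equivariance():
    """Relabeling genes permutes the assignment correspondingly."""
    rng = np.random.default_rng(20)
    df, _ = _block_matrix(rng, blocks=(15, 15), n_bg=10, n_cond=60)
    tom = tom_similarity(adjacency(df, 6))
    a1 = cluster_modules(tom, NetworkParams(min_module_size=5))
    perm = list(rng.permutation(df.columns))
    tom2 = tom_similarity(adjacency(df[perm], 6))
    a2 = cluster_modules(tom2, NetworkParams(min_module_size=5))
    from sklearn.metrics import adjusted_rand_score

    assert adjusted_rand_score(a1[perm].to_numpy(), a2.to_numpy()) == 1.0


def test_build_module_set_assembles_consistent_object(network_dataset):
    ms = build_module_set(network_dataset.logfc, network_dataset.truth_assignment)
    for m in ms.module_ids:
        members = ms.genes_of(m)
        assert ms.hub[m] in members
        assert ms.coreg[ms.hub[m]] == ms.coreg[members].max()
    assert np.allclose(ms.eigengenes.std(ddof=1), 1.0, atol=1e-9)
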