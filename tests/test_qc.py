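import numpy as np
import pandas as pd
import pytest

from toxmodnet.containers import CountMatrix, LogFCMatrix
from toxmodnet.design import generate_design
from toxmodnet.qc import (
    aggregate_degs,
    call_degs,
    collapse_probes,
    compute_log2fc,
    cpm_normalize,
    filter_good_genes,
    filter_library_size,
    filter_replicate_correlation,
    qc_pipeline,
)
from toxmodnet.simulate import generate_counts, make_module_spec

from conftest import random_logfc


@pytest.fixture(scope="module")
def tiny_design():
    return generate_design({"DILI": 1}, n_dose_levels=2, time_points=(24,),
                           n_replicates=3, seed=0)


def _counts_from(values: np.ndarray, design) -> CountMatrix:
    sids = list(design.samples["sample_id"])[: values.shape[1]]
    df = pd.DataFrame(values, index=[f"p{i}" for i in range(values.shape[0])], columns=sids)
    return CountMatrix(df, design)


class TestLibraryFilter:
    def test_strictly_lower_than_threshold_removed(self, tiny_design):
        v = np.zeros((2, 3), dtype=int)
        v[:, 0] = [499_998, 1]       # 499,999 -> removed
        v[:, 1] = [250_000, 250_000]  # 500,000 -> retained
        v[:, 2] = [600_000, 1]
        counts = _counts_from(v, tiny_design)
        kept, log = filter_library_size(counts)
        assert kept.values.shape[1] == 2
        assert list(log["sample_id"]) == [counts.sample_ids[0]]

    def test_all_zero_sample_removed(self, tiny_design):
        v = np.zeros((3, 2), dtype=int)
        v[:, 1] = 300_000
        counts = _counts_from(v, tiny_design)
        kept, _ = filter_library_size(counts, min_total=100)
        assert kept.sample_ids == [counts.sample_ids[1]]

    def test_matches_column_sum_oracle_on_random_matrices(self, tiny_design):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = rng.integers(0, 200_000, size=(4, 6))
            counts = _counts_from(v, tiny_design)
            thr = int(rng.integers(1, 500_000))
            expected = {s for s in counts.sample_ids if counts.values[s].sum() >= thr}
            if not expected:
                with pytest.raises(ValueError):
                    filter_library_size(counts, thr)
                continue
            kept, _ = filter_library_size(counts, thr)
            assert set(kept.sample_ids) == expected

    def test_removing_everything_is_an_error(self, tiny_design):
        counts = _counts_from(np.ones((2, 3), dtype=int), tiny_design)
        with pytest.raises(ValueError, match="500000|500_000|every sample"):
            filter_library_size(counts)


class TestCPM:
    def test_single_nonzero_probe_takes_the_million(self, tiny_design):
        counts = _counts_from(np.array([[7], [0]]), tiny_design)
        cpm = cpm_normalize(counts)
        assert cpm.iloc[0, 0] == 1e6

    def test_uniform_counts_split_evenly(self, tiny_design):
        counts = _counts_from(np.full((8, 2), 13), tiny_design)
        cpm = cpm_normalize(counts)
        assert np.allclose(cpm.to_numpy(), 1e6 / 8)

    def test_column_sums_are_one_million(self, tiny_design):
        rng = np.random.default_rng(1)
        counts = _counts_from(rng.integers(1, 1000, size=(20, 6)), tiny_design)
        cpm = cpm_normalize(counts)
        assert np.allclose(cpm.sum(axis=0), 1e6, rtol=1e-9)

    def test_zero_total_column_is_an_error(self, tiny_design):
        counts = _counts_from(np.zeros((3, 2), dtype=int), tiny_design)
        with pytest.raises(ValueError, match="zero-total"):
            cpm_normalize(counts)


class TestReplicateCorrelation:
    def test_identical_replicates_all_kept(self, tiny_design):
        rng = np.random.default_rng(2)
        profile = rng.integers(100, 10_000, size=50)
        design = tiny_design
        sids = list(design.samples["sample_id"])
        v = np.tile(profile[:, None], (1, len(sids)))
        cpm = cpm_normalize(_counts_from(v, design))
        kept, report = filter_replicate_correlation(cpm, design)
        assert not report["removed"].any()
        assert kept.shape[1] == len(sids)

    def test_noise_replaced_replicate_removed(self):
        # six replicates: the scrambled one falls far below 0.95 while its
        # siblings' correlation to the (contaminated) condition mean survives
        design = generate_design({"DILI": 1}, n_dose_levels=1, time_points=(24,),
                                 n_replicates=6, seed=1)
        spec = make_module_spec(design, n_genes=400, module_sizes=(40,), seed=1)
        counts = generate_counts(design, spec, qc_defect_rate=0.0, seed=1)
        rng = np.random.default_rng(3)
        bad = counts.sample_ids[0]
        counts.values[bad] = rng.permutation(counts.values[bad].to_numpy())
        cpm = cpm_normalize(counts)
        _, report = filter_replicate_correlation(cpm, counts.design)
        removed = set(report.loc[report["removed"], "sample_id"])
        assert removed == {bad}

    def test_impossible_threshold_empties_conditions_and_errors(self):
        design = generate_design({"DILI": 1}, n_dose_levels=1, time_points=(24,),
                                 n_replicates=3, seed=1)
        spec = make_module_spec(design, n_genes=100, module_sizes=(20,), seed=1)
        counts = generate_counts(design, spec, seed=2)
        cpm = cpm_normalize(counts)
        with pytest.raises(ValueError, match="emptied"):
            filter_replicate_correlation(cpm, counts.design, min_r=1.0)


class TestLog2FC:
    def test_treated_identical_to_vehicle_gives_zero(self, tiny_design):
        rng = np.random.default_rng(4)
        profile = rng.integers(100, 5000, size=30).astype(float)
        design = tiny_design
        v = np.tile(profile[:, None], (1, len(design.samples)))
        cpm = cpm_normalize(_counts_from(v.astype(int), design))
        lf = compute_log2fc(cpm, design)
        assert np.allclose(lf.values.to_numpy(), 0.0)

    def test_forced_arithmetic_with_pseudocount(self):
        # vehicle mean CPM 1000, treated mean 2000 -> log2(2001/1001)
        design = generate_design({"DILI": 1}, n_dose_levels=1, time_points=(24,),
                                 n_replicates=2, seed=0)
        sids = design.samples.sort_values("category")["sample_id"]  # DILI first
        treated = [s for s in sids if not s.startswith("VEH")]
        veh = [s for s in sids if s.startswith("VEH")]
        genes = ["gA", "gB"]
        cpm = pd.DataFrame(0.0, index=genes, columns=treated + veh)
        cpm.loc["gA", treated] = 2000.0
        cpm.loc["gA", veh] = 1000.0
        cpm.loc["gB", :] = 500.0
        lf = compute_log2fc(cpm, design, pseudocount=1.0)
        assert lf.values.iloc[0]["gA"] == pytest.approx(np.log2(2001 / 1001), abs=1e-12)
        assert lf.values.iloc[0]["gB"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_recomputation(self):
        design = generate_design({"DILI": 2}, n_dose_levels=2, time_points=(8, 24),
                                 n_replicates=3, seed=6)
        spec = make_module_spec(design, n_genes=60, module_sizes=(20,), seed=6)
        counts = generate_counts(design, spec, seed=7)
        cpm = cpm_normalize(counts)
        lf = compute_log2fc(cpm, design, pseudocount=1.0)
        meta = design.samples
        for cond in lf.values.index[:4]:
            compound, dose, t = cond
            t_ids = meta.loc[
                (meta["compound"] == compound) & (meta["dose_level"] == dose)
                & (meta["time_h"] == t), "sample_id"]
            veh_name = meta.loc[meta["sample_id"] == t_ids.iloc[0], "vehicle_of"].iloc[0]
            v_ids = meta.loc[(meta["compound"] == veh_name) & (meta["time_h"] == t), "sample_id"]
            expected = np.log2((cpm[t_ids].mean(axis=1) + 1) / (cpm[v_ids].mean(axis=1) + 1))
            assert np.allclose(lf.values.loc[cond].to_numpy(), expected.to_numpy())

    def test_missing_vehicle_is_an_error(self, tiny_design):
        design = tiny_design
        treated_only = design.samples[design.samples["category"] != "vehicle"]
        cpm = pd.DataFrame(
            100.0, index=["g1"], columns=list(treated_only["sample_id"])
        )
        with pytest.raises(ValueError, match="vehicle"):
            compute_log2fc(cpm, design)


class TestCollapseProbes:
    def _logfc(self, padj_rows: dict) -> LogFCMatrix:
        idx = pd.MultiIndex.from_tuples([("c", 1, 24), ("c", 2, 24)],
                                        names=("compound", "dose_level", "time_h"))
        probes = list(padj_rows)
        values = pd.DataFrame(0.5, index=idx, columns=probes)
        padj = pd.DataFrame({p: padj_rows[p] for p in probes}, index=idx)
        return LogFCMatrix(values=values, padj=padj)

    def test_one_probe_per_gene_is_identity(self):
        lf = self._logfc({"p1": [0.5, 0.2], "p2": [0.1, 0.9]})
        out = collapse_probes(lf, {"p1": "gA", "p2": "gB"})
        assert list(out.values.columns) == ["gA", "gB"]

    def test_most_significant_probe_kept(self):
        lf = self._logfc({"p1": [0.001, 0.8], "p2": [0.01, 0.9]})
        lf.values["p1"] = 1.0
        out = collapse_probes(lf, {"p1": "gA", "p2": "gA"})
        assert list(out.values.columns) == ["gA"]
        assert (out.values["gA"] == 1.0).all()  # p1 survived

    def test_tie_broken_by_larger_mean_count_then_probe_id(self):
        lf = self._logfc({"p1": [0.1, 0.5], "p2": [0.1, 0.7]})
        out = collapse_probes(lf, {"p1": "gA", "p2": "gA"},
                              mean_counts=pd.Series({"p1": 10.0, "p2": 99.0}))
        assert out.padj["gA"].tolist() == [0.1, 0.7]  # p2 kept
        out2 = collapse_probes(lf, {"p1": "gA", "p2": "gA"})
        assert out2.padj["gA"].tolist() == [0.1, 0.5]  # lexicographic fallback

    def test_uncovered_probe_rejected(self):
        lf = self._logfc({"p1": [0.1, 0.5]})
        with pytest.raises(ValueError, match="cover"):
            collapse_probes(lf, {})


class TestGeneFilter:
    def test_constant_gene_removed_and_mild_missingness_kept(self):
        rng = np.random.default_rng(5)
        lf = random_logfc(rng, n_conditions=10, n_genes=5)
        lf.values["g00"] = 0.0                       # zero variance
        lf.values.iloc[0, 1] = np.nan                # 1/10 missing at cap 0.5
        out, removed = filter_good_genes(lf, max_missing_frac=0.5)
        assert removed == ["g00"]
        assert "g01" in out.values.columns

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            lf = random_logfc(rng, n_conditions=8, n_genes=12)
            mask = rng.random(size=lf.values.shape) < 0.2
            lf.values[mask] = np.nan
            lf.values.iloc[:, 0] = 1.23
            expected = [
                g for g in lf.values.columns
                if lf.values[g].isna().mean() > 0.3 or lf.values[g].var() < 1e-8
            ]
            _, removed = filter_good_genes(lf, max_missing_frac=0.3)
            assert removed == expected


class TestDEGs:
    def test_all_padj_one_gives_no_degs(self):
        rng = np.random.default_rng(7)
        lf = random_logfc(rng, 6, 5)
        lf.padj.iloc[:, :] = 1.0
        degs = call_degs(lf)
        assert all(len(s) == 0 for s in degs.up.values())
        assert all(len(s) == 0 for s in degs.down.values())

    def test_boundary_values_are_strict(self):
        rng = np.random.default_rng(8)
        lf = random_logfc(rng, 2, 2)
        lf.values.iloc[:, :] = 0.1   # exactly at cutoff -> not a DEG
        lf.padj.iloc[:, :] = 0.005
        degs = call_degs(lf)
        assert all(len(s) == 0 for s in degs.up.values())
        lf.values.iloc[:, :] = 0.10001
        degs = call_degs(lf)
        assert all(len(s) == 2 for s in degs.up.values())

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(9)
        lf = random_logfc(rng, 10, 20)
        lf.values.iloc[:, :] = rng.normal(0, 0.3, size=lf.values.shape)
        degs = call_degs(lf)
        for cond in lf.values.index:
            up = {g for g in lf.values.columns
                  if lf.padj.loc[cond, g] < 0.01 and lf.values.loc[cond, g] > 0.1}
            down = {g for g in lf.values.columns
                    if lf.padj.loc[cond, g] < 0.01 and lf.values.loc[cond, g] < -0.1}
            assert degs.up[cond] == up and degs.down[cond] == down

    def test_relaxing_thresholds_never_shrinks_deg_sets(self):
        rng = np.random.default_rng(10)
        lf = random_logfc(rng, 8, 15)
        strict = call_degs(lf, padj_max=0.01, min_abs_lfc=0.5)
        relaxed = call_degs(lf, padj_max=0.1, min_abs_lfc=0.2)
        for cond in lf.values.index:
            assert strict.up[cond] <= relaxed.up[cond]
            assert strict.down[cond] <= relaxed.down[cond]


class TestAggregateDEGs:
    def test_union_semantics(self):
        from toxmodnet.containers import DEGTable
        degs = DEGTable(
            up={("c", 1, 24): frozenset({"A", "B"}), ("c", 2, 24): frozenset({"B", "C"})},
            down={("c", 1, 24): frozenset(), ("c", 2, 24): frozenset({"D"})},
        )
        agg = aggregate_degs(degs)
        row = agg[(agg["compound"] == "c") & (agg["time_h"] == 24)].iloc[0]
        assert row["n_up"] == 3 and row["n_down"] == 1

    def test_identical_sets_at_every_dose_collapse(self):
        from toxmodnet.containers import DEGTable
        same = frozenset({"A", "B"})
        degs = DEGTable(up={("c", d, 8): same for d in (1, 2, 3)},
                        down={("c", d, 8): frozenset() for d in (1, 2, 3)})
        agg = aggregate_degs(degs)
        assert agg.iloc[0]["n_up"] == 2


class TestPipelineProperties:
    def test_qc_outputs_invariant_to_sample_order(self):
        design = generate_design({"DILI": 1}, n_dose_levels=2, time_points=(24,),
                                 n_replicates=3, seed=11)
        spec = make_module_spec(design, n_genes=80, module_sizes=(20,), seed=11)
        counts = generate_counts(design, spec, seed=12)
        lf1, _ = qc_pipeline(counts)
        rng = np.random.default_rng(13)
        perm = list(rng.permutation(counts.sample_ids))
        shuffled = CountMatrix(counts.values[perm], counts.design, counts.truth)
        lf2, _ = qc_pipeline(shuffled)
        pd.testing.assert_frame_equal(lf1.values, lf2.values)

    def test_pipeline_removes_exactly_corrupted_samples(self):
        design = generate_design({"DILI": 4}, n_dose_levels=3, n_replicates=3, seed=14,
                                 n_vehicle_replicates=6)
        spec = make_module_spec(design, n_genes=300, module_sizes=(40, 30), seed=14)
        counts = generate_counts(design, spec, qc_defect_rate=0.08, seed=15)
        _, report = qc_pipeline(counts)
        removed = set(report["removed_library_size"]["sample_id"]) | set(
            report["replicate_correlation"].loc[
                lambda df: df["removed"], "sample_id"]
        )
        assert removed == set(counts.truth["corrupted"])
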