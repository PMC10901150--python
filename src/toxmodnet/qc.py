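"""Sample QC, CPM normalization, log2FC computation and DEG calling.

The processing contract mirrors a targeted RNA-seq pipeline: drop samples
with library size below 500,000 counts, normalize to counts-per-million,
drop replicates whose Pearson correlation to their condition mean falls
below 0.95, compute per-condition log2 fold changes against the matched
vehicle control from the same time point and batch, and call DEGs at
adjusted p < .01 and |log2FC| > 0.1.

Differential-expression p-values come from a per-gene two-sided Welch
t-test on log2(CPM+1) replicate values (treated vs matched vehicle) with
Benjamini-Hochberg adjustment within each time point; the pseudocount in
the fold-change ratio is configurable.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CONDITION_NAMES, CountMatrix, DEGTable, LogFCMatrix, StudyDesign

DEFAULT_MIN_LIBRARY_SIZE = 500_000
DEFAULT_MIN_REPLICATE_R = 0.95
DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_DEG_PADJ = 0.01
DEFAULT_DEG_MIN_ABS_LFC = 0.1


def filter_library_size(
    counts: CountMatrix, min_total: int = DEFAULT_MIN_LIBRARY_SIZE
) -> tuple[CountMatrix, pd.DataFrame]:
    """Drop samples whose total raw count is strictly below ``min_total``.

    Returns the filtered counts and a removal log (sample_id, library_size).
    """
    if min_total <= 0:
        raise ValueError("min_total must be positive")
    totals = counts.library_sizes()
    keep = totals.index[totals >= min_total]
    removed = totals[totals < min_total]
    if len(keep) == 0:
        raise ValueError(f"library-size filter at {min_total} removed every sample")
    log = pd.DataFrame(
        {"sample_id": removed.index, "library_size": removed.to_numpy(), "reason": "library_size"}
    )
    return counts.subset_samples(keep), log.reset_index(drop=True)


def cpm_normalize(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: scale each sample (column) to a total of 1e6."""
    values = counts.values if isinstance(counts, CountMatrix) else counts
    totals = values.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(
            f"zero-total samples (remove with the library-size filter first): {list(zero)[:5]}"
        )
    return values / totals * 1e6


def _condition_groups(design: StudyDesign, sample_ids) -> pd.core.groupby.DataFrameGroupBy:
    present = design.samples[design.samples["sample_id"].isin(set(sample_ids))]
    return present.groupby(["compound", "dose_level", "time_h", "batch"], sort=True)


def filter_replicate_correlation(
    cpm: pd.DataFrame,
    design: StudyDesign,
    min_r: float = DEFAULT_MIN_REPLICATE_R,
    n_top_variable: int = 5000,
    leave_one_out: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop samples poorly correlated with their condition's mean profile.

    Pearson correlation is computed on log2(CPM+1) over the
    ``n_top_variable`` most variable probes.  By default the condition mean
    includes the candidate sample itself; ``leave_one_out`` excludes it.
    Single-replicate conditions are passed through with a warning.  An
    error is raised if the filter empties a condition (or all samples).
    """
    log_cpm = np.log2(cpm + 1)
    variances = log_cpm.var(axis=1)
    top = variances.sort_values(ascending=False).index[: min(n_top_variable, len(variances))]
    feats = log_cpm.loc[top]

    records = []
    removed: list[str] = []
    emptied: list[tuple] = []
    for cond, grp in _condition_groups(design, cpm.columns):
        sids = [s for s in grp["sample_id"] if s in feats.columns]
        if len(sids) < 2:
            for s in sids:
                records.append({"sample_id": s, "condition": cond, "r": np.nan, "removed": False,
                                "note": "single replicate, check skipped"})
            continue
        block = feats[sids].to_numpy()
        mean_all = block.mean(axis=1)
        cond_removed = []
        for j, s in enumerate(sids):
            if leave_one_out:
                ref = (mean_all * len(sids) - block[:, j]) / (len(sids) - 1)
            else:
                ref = mean_all
            r = float(np.corrcoef(block[:, j], ref)[0, 1])
            drop = r < min_r
            records.append({"sample_id": s, "condition": cond, "r": r, "removed": drop, "note": ""})
            if drop:
                cond_removed.append(s)
        removed.extend(cond_removed)
        if len(cond_removed) == len(sids):
            emptied.append(cond)
    if emptied:
        raise ValueError(
            f"replicate-correlation filter at {min_r} emptied conditions: {emptied[:5]}"
        )
    report = pd.DataFrame(records)
    if (report["note"] == "single replicate, check skipped").any():
        warnings.warn("conditions with a single replicate were not correlation-checked",
                      stacklevel=2)
    keep = [s for s in cpm.columns if s not in set(removed)]
    if not keep:
        raise ValueError("replicate-correlation filter removed every sample")
    return cpm[keep], report


def compute_log2fc(
    cpm: pd.DataFrame,
    design: StudyDesign,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> LogFCMatrix:
    """Per-condition log2FC versus the matched vehicle, with adjusted p-values.

    ``value(cond, gene) = log2((mean treated CPM + pc) / (mean vehicle CPM + pc))``
    where the vehicle group shares time point and batch with the treated
    condition.  P-values: Welch t-test per gene on log2(CPM+1) replicates,
    BH-adjusted within each time point across all genes x conditions.
    """
    present = design.samples[design.samples["sample_id"].isin(set(cpm.columns))]
    vehicles = present[present["category"] == "vehicle"]
    veh_groups = {
        key: list(grp["sample_id"])
        for key, grp in vehicles.groupby(["compound", "time_h", "batch"])
    }
    log_cpm = np.log2(cpm + 1)

    orphans = []
    rows = []
    for cond, grp in present[present["category"] != "vehicle"].groupby(
        list(CONDITION_NAMES), sort=True
    ):
        veh_name = grp["vehicle_of"].iloc[0]
        key = (veh_name, cond[2], grp["batch"].iloc[0])
        veh_ids = veh_groups.get(key, [])
        if not veh_ids:
            orphans.append(cond)
            continue
        rows.append((cond, list(grp["sample_id"]), veh_ids))
    if orphans:
        raise ValueError(f"conditions without a matched vehicle after QC: {orphans[:5]}")
    if not rows:
        raise ValueError("no treated conditions present")

    genes = cpm.index
    lfc = np.empty((len(rows), len(genes)))
    pvals = np.full((len(rows), len(genes)), np.nan)
    n_reps = []
    for i, (cond, t_ids, v_ids) in enumerate(rows):
        mt = cpm[t_ids].mean(axis=1).to_numpy()
        mv = cpm[v_ids].mean(axis=1).to_numpy()
        lfc[i] = np.log2((mt + pseudocount) / (mv + pseudocount))
        n_reps.append(len(t_ids))
        if len(t_ids) >= 2 and len(v_ids) >= 2:
            with np.errstate(invalid="ignore", divide="ignore"):
                res = stats.ttest_ind(
                    log_cpm[t_ids].to_numpy(),
                    log_cpm[v_ids].to_numpy(),
                    axis=1,
                    equal_var=False,
                )
            pvals[i] = res.pvalue
    pvals = np.where(np.isnan(pvals), 1.0, pvals)  # zero-variance / untestable genes

    index = pd.MultiIndex.from_tuples([r[0] for r in rows], names=CONDITION_NAMES)
    padj = np.empty_like(pvals)
    for t in index.get_level_values("time_h").unique():
        mask = index.get_level_values("time_h") == t
        flat = pvals[mask].ravel()
        padj[mask] = multipletests(flat, method="fdr_bh")[1].reshape(pvals[mask].shape)

    values = pd.DataFrame(lfc, index=index, columns=genes)
    padj_df = pd.DataFrame(padj, index=index, columns=genes)
    n_rep = pd.Series(n_reps, index=index, name="n_replicates")
    return LogFCMatrix(values=values, padj=padj_df, n_replicates=n_rep)


def collapse_probes(
    logfc: LogFCMatrix,
    probe_to_gene: Mapping[str, str],
    mean_counts: pd.Series | None = None,
) -> LogFCMatrix:
    """Keep one probe per gene: the one with the smallest minimum adjusted p.

    Ties are broken by larger mean raw count (when ``mean_counts`` is
    given), then by lexicographically smaller probe id, so the result is
    deterministic.  The surviving probe is renamed to its gene id.
    """
    missing = [p for p in logfc.values.columns if p not in probe_to_gene]
    if missing:
        raise ValueError(f"probe_to_gene map does not cover probes: {missing[:5]}")
    min_padj = logfc.padj.min(axis=0)
    chosen: dict[str, str] = {}
    by_gene: dict[str, list[str]] = {}
    for probe in logfc.values.columns:
        by_gene.setdefault(probe_to_gene[probe], []).append(probe)
    for gene, probes in by_gene.items():
        def sort_key(p: str):
            tie = -float(mean_counts.get(p, 0.0)) if mean_counts is not None else 0.0
            return (min_padj[p], tie, p)
        chosen[gene] = min(probes, key=sort_key)
    genes = sorted(chosen)
    keep = [chosen[g] for g in genes]
    values = logfc.values[keep].copy()
    padj = logfc.padj[keep].copy()
    values.columns = padj.columns = pd.Index(genes, name="gene")
    return LogFCMatrix(values=values, padj=padj, n_replicates=logfc.n_replicates)


def filter_good_genes(
    logfc: LogFCMatrix,
    max_missing_frac: float = 0.5,
    min_variance: float = 1e-8,
) -> tuple[LogFCMatrix, list[str]]:
    """Remove genes with too many missing entries or (near-)zero variance."""
    if not (0 <= max_missing_frac < 1) or min_variance < 0:
        raise ValueError("max_missing_frac must be in [0,1) and min_variance >= 0")
    frac_missing = logfc.values.isna().mean(axis=0)
    variance = logfc.values.var(axis=0)
    bad = (frac_missing > max_missing_frac) | (variance < min_variance)
    removed = list(logfc.values.columns[bad])
    if bad.all():
        raise ValueError("gene filter removed every gene")
    return logfc.subset_genes(logfc.values.columns[~bad]), removed


def call_degs(
    logfc: LogFCMatrix,
    padj_max: float = DEFAULT_DEG_PADJ,
    min_abs_lfc: float = DEFAULT_DEG_MIN_ABS_LFC,
) -> DEGTable:
    """DEG per condition: padj < padj_max and log2FC strictly beyond the cutoff."""
    if padj_max <= 0 or min_abs_lfc <= 0:
        raise ValueError("thresholds must be positive")
    up: dict[tuple, frozenset] = {}
    down: dict[tuple, frozenset] = {}
    sig = logfc.padj < padj_max
    genes = logfc.values.columns
    for cond in logfc.values.index:
        s = sig.loc[cond].to_numpy()
        v = logfc.values.loc[cond].to_numpy()
        up[cond] = frozenset(genes[s & (v > min_abs_lfc)])
        down[cond] = frozenset(genes[s & (v < -min_abs_lfc)])
    return DEGTable(up=up, down=down)


def aggregate_degs(degs: DEGTable) -> pd.DataFrame:
    """Unique DEG counts per compound and time point (union over dose levels)."""
    agg: dict[tuple, dict[str, set]] = {}
    for cond, genes in degs.up.items():
        compound, _dose, t = cond
        agg.setdefault((compound, t), {"up": set(), "down": set()})["up"] |= genes
    for cond, genes in degs.down.items():
        compound, _dose, t = cond
        agg.setdefault((compound, t), {"up": set(), "down": set()})["down"] |= genes
    rows = [
        {"compound": c, "time_h": t, "n_up": len(d["up"]), "n_down": len(d["down"])}
        for (c, t), d in sorted(agg.items())
    ]
    return pd.DataFrame(rows)


def qc_pipeline(
    counts: CountMatrix,
    min_library_size: int = DEFAULT_MIN_LIBRARY_SIZE,
    min_replicate_r: float = DEFAULT_MIN_REPLICATE_R,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    n_top_variable: int = 5000,
    leave_one_out: bool = False,
) -> tuple[LogFCMatrix, dict]:
    """Full QC chain: library filter -> CPM -> replicate filter -> log2FC."""
    filtered, lib_log = filter_library_size(counts, min_library_size)
    cpm = cpm_normalize(filtered)
    cpm, rep_report = filter_replicate_correlation(
        cpm, filtered.design, min_replicate_r, n_top_variable, leave_one_out
    )
    logfc = compute_log2fc(cpm, filtered.design, pseudocount)
    report = {
        "removed_library_size": lib_log,
        "replicate_correlation": rep_report,
        "n_samples_in": len(counts.sample_ids),
        "n_samples_out": cpm.shape[1],
    }
    return logfc, report
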