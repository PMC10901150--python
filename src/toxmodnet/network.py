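"""Unsigned weighted co-expression network construction and module detection.

Builds the soft-thresholded adjacency ``a_ij = |cor(x_i, x_j)|^beta`` over
the condition x gene log2FC matrix, converts it to the topological overlap
measure, clusters genes by average-linkage hierarchical clustering on
1 - TOM, cuts the dendrogram into modules, computes unit-variance eigengene
scores (first principal component of each module's z-scored member matrix),
iteratively merges modules whose eigengenes correlate at or above a
threshold, and annotates modules by hypergeometric gene-set enrichment.

The unsigned adjacency groups co-induced and co-repressed genes into one
module; the soft power is chosen as the smallest exponent reaching an
approximately scale-free degree distribution (signed R^2 of the log-log
frequency fit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .containers import LogFCMatrix, ModuleSet

DEFAULT_MERGE_THRESHOLD = 0.8
DEFAULT_MIN_MODULE_SIZE = 20
#: Soft power the original HepG2 analysis settled on; `pick_soft_power`
#: recomputes the choice for any new dataset.
REFERENCE_SOFT_POWER = 9


@dataclass
class NetworkParams:
    """Tunable parameters for network construction and module detection."""

    beta: int | None = None  # None = pick automatically
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE
    merge_threshold: float = DEFAULT_MERGE_THRESHOLD
    cut_height: float | None = None  # fraction of max merge height; None = 0.99
    cut_mode: str = "hybrid"  # "hybrid" (with TOM-based rescue) or "static"
    pam_frac: float = 0.5
    candidate_powers: tuple[int, ...] = tuple(range(1, 21))
    target_r2: float = 0.85
    merge_absolute: bool = False

    def __post_init__(self) -> None:
        if self.beta is not None and self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not (0 < self.merge_threshold <= 1):
            raise ValueError("merge_threshold must be in (0, 1]")
        if self.min_module_size < 3:
            raise ValueError("min_module_size must be >= 3")


def _corr_matrix(values: pd.DataFrame) -> np.ndarray:
    X = values.to_numpy(float)
    if np.isnan(X).any():
        return values.corr().to_numpy()  # pairwise-complete
    sd = X.std(axis=0)
    const = np.flatnonzero(sd == 0)
    if const.size:
        names = [values.columns[i] for i in const[:5]]
        raise ValueError(f"constant genes (zero variance): {names}")
    return np.corrcoef(X, rowvar=False)


def adjacency(logfc: LogFCMatrix | pd.DataFrame, beta: int) -> pd.DataFrame:
    """Unsigned soft-thresholded adjacency ``|cor|^beta`` with unit diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    values = logfc.values if isinstance(logfc, LogFCMatrix) else logfc
    cor = _corr_matrix(values)
    adj = np.abs(cor) ** beta
    np.clip(adj, 0.0, 1.0, out=adj)
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=values.columns, columns=values.columns)


def connectivity(adj: pd.DataFrame) -> pd.Series:
    """Whole-network connectivity ``k_i = sum_{u != i} a_iu``."""
    return adj.sum(axis=1) - 1.0


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed R^2 of the log10 p(k) vs log10 k regression over equal-width bins.

    Returns ``(signed_r2, slope)`` where ``signed_r2 = -sign(slope) * R^2``,
    positive only when frequency falls with connectivity (the power-law
    signature).
    """
    k = np.asarray(k, float)
    if k.size < n_bins:
        raise ValueError(f"need at least {n_bins} genes for {n_bins} connectivity bins")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0 or members.mean() <= 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / k.size))
    if len(xs) < 3:
        return 0.0, 0.0
    fit = stats.linregress(xs, ys)
    r2 = float(fit.rvalue**2)
    return -np.sign(fit.slope) * r2, float(fit.slope)


@dataclass
class PowerFit:
    beta: int
    table: pd.DataFrame
    reached_target: bool


def pick_soft_power(
    logfc: LogFCMatrix | pd.DataFrame,
    candidates=tuple(range(1, 21)),
    target_r2: float = 0.85,
    n_bins: int = 10,
    min_mean_k: float = 1.0,
) -> PowerFit:
    """Smallest candidate power with scale-free fit >= target, else the argmax.

    Powers whose mean connectivity falls below ``min_mean_k`` are ineligible:
    at extreme powers even structureless data yields a power-law-looking
    degree distribution simply because the network has dissolved (fewer than
    one neighbor per gene).  A warning is attached (``reached_target=False``)
    when no eligible candidate reaches the target.
    """
    values = logfc.values if isinstance(logfc, LogFCMatrix) else logfc
    if values.shape[0] < 20:
        warnings.warn("fewer than 20 conditions: soft-power selection is unstable", stacklevel=2)
    abs_cor = np.abs(_corr_matrix(values))
    np.fill_diagonal(abs_cor, 1.0)
    rows = []
    for power in candidates:
        a = abs_cor**power
        k = a.sum(axis=1) - 1.0
        signed_r2, slope = scale_free_fit(k, n_bins)
        rows.append(
            {"power": power, "signed_r2": signed_r2, "slope": slope,
             "mean_k": float(k.mean()), "median_k": float(np.median(k))}
        )
    table = pd.DataFrame(rows)
    eligible = table[table["mean_k"] >= min_mean_k]
    if target_r2 <= 0:  # vacuous bound: no fit requirement at all
        passing = eligible
    else:
        passing = eligible[eligible["signed_r2"] >= target_r2]
    if len(passing):
        return PowerFit(beta=int(passing["power"].iloc[0]), table=table, reached_target=True)
    pool = eligible if len(eligible) else table
    best = int(pool.loc[pool["signed_r2"].idxmax(), "power"])
    warnings.warn(
        f"no candidate power reached signed R^2 >= {target_r2}; returning argmax {best}",
        stacklevel=2,
    )
    return PowerFit(beta=best, table=table, reached_target=False)


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap: ``t_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij)``.

    The shared-neighbor sum runs over ``u not in {i, j}``; the diagonal is 1.
    """
    A = adj.to_numpy(float)
    k = A.sum(axis=1) - 1.0
    L = A @ A
    numer = L - A  # removes the u=i and u=j terms (2*a_ij), then adds back a_ij
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        T = numer / denom
    T = np.clip(np.nan_to_num(T, nan=0.0), 0.0, 1.0)
    np.fill_diagonal(T, 1.0)
    T = (T + T.T) / 2.0
    return pd.DataFrame(T, index=adj.index, columns=adj.columns)


def cluster_modules(tom: pd.DataFrame, params: NetworkParams | None = None) -> pd.Series:
    """Detect modules from the TOM by average-linkage clustering on 1 - TOM.

    The dendrogram is cut at ``cut_height`` (a fraction of the maximum merge
    height, default 0.99); clusters smaller than ``min_module_size`` fall to
    module 0.  In ``hybrid`` mode unassigned genes are then rescued into the
    module to which their mean TOM is highest, provided that mean reaches
    ``pam_frac`` of the module's internal mean TOM.  Module ids are ordered
    by decreasing size.
    """
    params = params or NetworkParams()
    genes = tom.index
    n = len(genes)
    if n < params.min_module_size:
        warnings.warn("fewer genes than min_module_size: all genes unassigned", stacklevel=2)
        return pd.Series(0, index=genes, name="module")
    D = 1.0 - tom.to_numpy(float)
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    frac = params.cut_height if params.cut_height is not None else 0.99
    height = frac * Z[:, 2].max()
    raw = hierarchy.fcluster(Z, t=height, criterion="distance")
    labels = pd.Series(raw, index=genes)
    sizes = labels.value_counts()
    small = sizes.index[sizes < params.min_module_size]
    labels[labels.isin(small)] = 0

    if params.cut_mode == "hybrid" and (labels == 0).any() and (labels != 0).any():
        T = tom.to_numpy(float)
        module_ids = [m for m in sizes.index if m not in set(small)]
        cols = {m: np.flatnonzero((labels == m).to_numpy()) for m in module_ids}
        internal = {}
        for m, idx in cols.items():
            sub = T[np.ix_(idx, idx)]
            internal[m] = (sub.sum() - len(idx)) / max(len(idx) * (len(idx) - 1), 1)
        unassigned = np.flatnonzero((labels == 0).to_numpy())
        for g in unassigned:
            best, best_val = 0, -np.inf
            for m, idx in cols.items():
                val = T[g, idx].mean()
                if val > best_val:
                    best, best_val = m, val
            if best != 0 and best_val >= params.pam_frac * internal[best]:
                labels.iloc[g] = best

    return _relabel_by_size(labels)


def _relabel_by_size(labels: pd.Series) -> pd.Series:
    sizes = labels[labels != 0].value_counts()
    order = sizes.sort_values(ascending=False).index
    mapping = {old: new for new, old in enumerate(order, start=1)}
    mapping[0] = 0
    out = labels.map(mapping).astype(int)
    out.name = "module"
    return out


def compute_eigengenes(
    logfc: LogFCMatrix | pd.DataFrame, assignment: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Unit-variance module eigengene scores per condition.

    Per module: z-score each member gene across conditions, take the first
    principal component over conditions, orient its sign so its correlation
    with the module's mean z-scored profile is non-negative, then divide by
    its standard deviation across conditions so the column SD is exactly 1.
    Returns ``(eigengenes, report)`` where the report carries explained
    variance and a flag for degenerate single-gene modules.
    """
    values = logfc.values if isinstance(logfc, LogFCMatrix) else logfc
    module_ids = sorted(m for m in assignment.unique() if m != 0)
    egs = {}
    report_rows = []
    for m in module_ids:
        genes = assignment.index[assignment == m]
        X = values[genes].to_numpy(float)
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Z = (X - mu) / sd
        if Z.shape[1] == 1:
            score = Z[:, 0]
            explained = 1.0
            degenerate = True
        else:
            U, S, _Vt = np.linalg.svd(Z, full_matrices=False)
            score = U[:, 0] * S[0]
            explained = float(S[0] ** 2 / (S**2).sum())
            degenerate = False
        mean_profile = Z.mean(axis=1)
        if np.corrcoef(score, mean_profile)[0, 1] < 0:
            score = -score
        score = score / score.std(ddof=1)
        egs[m] = score
        report_rows.append(
            {"module": m, "n_genes": len(genes), "explained_variance": explained,
             "degenerate": degenerate}
        )
    eigengenes = pd.DataFrame(egs, index=values.index)
    report = pd.DataFrame(report_rows)
    if report["degenerate"].any() if len(report) else False:
        warnings.warn("single-gene modules: eigengene equals the z-scored profile", stacklevel=2)
    return eigengenes, report


def merge_modules(
    logfc: LogFCMatrix | pd.DataFrame,
    assignment: pd.Series,
    merge_threshold: float = DEFAULT_MERGE_THRESHOLD,
    absolute: bool = False,
    max_iter: int = 50,
) -> pd.Series:
    """Iteratively merge modules whose eigengenes correlate >= threshold.

    Merging is transitive (single linkage over the >= threshold graph) and
    recomputes eigengenes after each round until no pair of module
    eigengenes reaches the threshold.  Module 0 is never merged.
    """
    if not (0 < merge_threshold <= 1):
        raise ValueError("merge_threshold must be in (0, 1]")
    labels = assignment.copy()
    for _ in range(max_iter):
        module_ids = sorted(m for m in labels.unique() if m != 0)
        if len(module_ids) < 2:
            return _relabel_by_size(labels)
        egs, _ = compute_eigengenes(logfc, labels)
        cor = egs.corr().to_numpy()
        if absolute:
            cor = np.abs(cor)
        np.fill_diagonal(cor, 0.0)
        if (cor < merge_threshold).all():
            return _relabel_by_size(labels)
        # union-find over the >= threshold graph
        parent = {m: m for m in module_ids}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ids = list(egs.columns)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if cor[i, j] >= merge_threshold:
                    ri, rj = find(ids[i]), find(ids[j])
                    if ri != rj:
                        parent[rj] = ri
        labels = labels.map(lambda m: find(m) if m != 0 else 0)
    raise RuntimeError(f"module merging did not converge within {max_iter} iterations")


def compute_coreg_hub(
    logfc: LogFCMatrix | pd.DataFrame,
    assignment: pd.Series,
    eigengenes: pd.DataFrame,
) -> tuple[pd.Series, dict[int, str]]:
    """Per-gene correlation with the parent module eigengene, and hub genes.

    ``corEG(g) = Pearson cor(log2FC profile of g, EG of g's module)``;
    the hub of a module is its corEG-maximizing member (ties broken by
    lexicographically smaller gene id).
    """
    values = logfc.values if isinstance(logfc, LogFCMatrix) else logfc
    coreg = pd.Series(np.nan, index=assignment.index, name="corEG")
    hub: dict[int, str] = {}
    for m in sorted(set(assignment.unique()) - {0}):
        genes = list(assignment.index[assignment == m])
        eg = eigengenes[m].to_numpy()
        X = values[genes].to_numpy(float)
        egc = eg - eg.mean()
        Xc = X - X.mean(axis=0)
        denom = np.sqrt((Xc**2).sum(axis=0)) * np.sqrt((egc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Xc * egc[:, None]).sum(axis=0) / denom
        coreg.loc[genes] = r
        ranked = sorted(zip(genes, r), key=lambda t: (-t[1], t[0]))
        hub[m] = ranked[0][0]
    return coreg, hub


def enrich_modules(
    assignment: pd.Series,
    gene_sets: Mapping[str, set],
    universe: set | None = None,
) -> tuple[pd.DataFrame, dict[int, tuple[str, float] | None]]:
    """Hypergeometric gene-set enrichment per module with BH adjustment.

    Each module is labeled with its minimum-adjusted-p gene set among sets
    with a non-empty overlap, or ``None``.
    """
    universe = set(universe) if universe is not None else set(assignment.index)
    module_genes = {
        m: set(assignment.index[assignment == m]) & universe
        for m in sorted(set(assignment.unique()) - {0})
    }
    missing = set(assignment.index) - universe
    if missing:
        raise ValueError(f"universe does not contain all module genes: {sorted(missing)[:5]}")
    if not gene_sets:
        warnings.warn("empty gene-set collection: all annotations are None", stacklevel=2)
        return pd.DataFrame(columns=["module", "gene_set", "overlap", "p", "padj"]), {
            m: None for m in module_genes
        }
    M = len(universe)
    rows = []
    for m, genes in module_genes.items():
        for set_id, members in gene_sets.items():
            members = set(members) & universe
            overlap = len(genes & members)
            p = float(stats.hypergeom.sf(overlap - 1, M, len(members), len(genes)))
            rows.append({"module": m, "gene_set": set_id, "overlap": overlap, "p": p})
    table = pd.DataFrame(rows)
    table["padj"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    annotation: dict[int, tuple[str, float] | None] = {}
    for m in module_genes:
        sub = table[(table["module"] == m) & (table["overlap"] > 0)]
        if sub.empty:
            annotation[m] = None
        else:
            best = sub.sort_values(["padj", "p", "gene_set"]).iloc[0]
            annotation[m] = (str(best["gene_set"]), float(best["padj"]))
    return table, annotation


def build_module_set(
    logfc: LogFCMatrix | pd.DataFrame,
    assignment: pd.Series,
    gene_sets: Mapping[str, set] | None = None,
    universe: set | None = None,
) -> ModuleSet:
    """Assemble a :class:`ModuleSet` (eigengenes, corEG, hubs, annotation)."""
    egs, report = compute_eigengenes(logfc, assignment)
    coreg, hub = compute_coreg_hub(logfc, assignment, egs)
    annotation: dict = {}
    if gene_sets:
        _, annotation = enrich_modules(assignment, gene_sets, universe)
    explained = dict(zip(report["module"], report["explained_variance"])) if len(report) else {}
    return ModuleSet(
        assignment=assignment,
        eigengenes=egs,
        coreg=coreg,
        hub=hub,
        annotation=annotation,
        explained_variance=explained,
    )
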