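"""Module preservation between a reference and a test expression system.

Quantifies whether reference-system modules retain their density and
connectivity structure in a second dataset via permutation Z statistics.
For each module the observed statistics are compared against a null built
from random same-size gene sets drawn from the shared-gene universe:

* density — mean within-module adjacency in the test system;
* connectivity — correlation of intramodular connectivity vectors between
  systems, and correlation of the vectorized within-module gene-gene
  correlation matrices.

``Zsummary = (Zdensity + Zconnectivity) / 2``; modules with Zsummary >= 2
count as moderately preserved and >= 10 as highly preserved, and a lower
median rank indicates higher preservation.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .containers import LogFCMatrix, PreservationResult

MODERATE_ZSUMMARY = 2.0
HIGH_ZSUMMARY = 10.0
DEFAULT_N_PERM = 200


def classify_preservation(zsummary: float) -> str:
    """Map a Zsummary value to {nonpreserved, moderate, high}."""
    if not np.isfinite(zsummary):
        raise ValueError("Zsummary must be finite")
    if zsummary < MODERATE_ZSUMMARY:
        return "nonpreserved"
    if zsummary < HIGH_ZSUMMARY:
        return "moderate"
    return "high"


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 3 or x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def _module_stats(
    idx: np.ndarray,
    cor_ref: np.ndarray,
    cor_test: np.ndarray,
    adj_ref: np.ndarray,
    adj_test: np.ndarray,
) -> tuple[float, float, float]:
    """(density, cor.kIM, cor.cor) for one gene-index set."""
    n = idx.size
    at = adj_test[np.ix_(idx, idx)]
    ar = adj_ref[np.ix_(idx, idx)]
    density = (at.sum() - n) / (n * (n - 1))
    kim_ref = ar.sum(axis=1) - 1.0
    kim_test = at.sum(axis=1) - 1.0
    cor_kim = _pearson(kim_ref, kim_test)
    iu = np.triu_indices(n, k=1)
    cor_cor = _pearson(cor_ref[np.ix_(idx, idx)][iu], cor_test[np.ix_(idx, idx)][iu])
    return density, cor_kim, cor_cor


def preservation_stats(
    ref_logfc: LogFCMatrix | pd.DataFrame,
    ref_assignment: pd.Series,
    test_logfc: LogFCMatrix | pd.DataFrame,
    beta: int = 6,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    min_shared_genes: int = 10,
) -> PreservationResult:
    """Permutation Zdensity/Zconnectivity/Zsummary and medianRank per module.

    Both systems' adjacencies are computed at the reference soft power
    ``beta``.  The null draws ``n_perm`` random gene sets of the module's
    size from the genes shared between the two systems, which nulls the
    module's identity while preserving each system's global correlation
    structure.  Modules with fewer than ``min_shared_genes`` shared genes
    are skipped and recorded.  Deterministic given the seed.
    """
    if n_perm < 50:
        warnings.warn(f"n_perm={n_perm} < 50: null distribution will be unstable", stacklevel=2)
    ref_values = ref_logfc.values if isinstance(ref_logfc, LogFCMatrix) else ref_logfc
    test_values = test_logfc.values if isinstance(test_logfc, LogFCMatrix) else test_logfc
    shared = sorted(set(ref_values.columns) & set(test_values.columns))
    if len(shared) < min_shared_genes:
        raise ValueError("too few genes shared between the two systems")
    rng = np.random.default_rng(seed)

    R = ref_values[shared].to_numpy(float)
    T = test_values[shared].to_numpy(float)
    cor_ref = np.corrcoef(R, rowvar=False)
    cor_test = np.corrcoef(T, rowvar=False)
    cor_ref = np.nan_to_num(cor_ref, nan=0.0)
    cor_test = np.nan_to_num(cor_test, nan=0.0)
    adj_ref = np.abs(cor_ref) ** beta
    adj_test = np.abs(cor_test) ** beta
    np.fill_diagonal(adj_ref, 1.0)
    np.fill_diagonal(adj_test, 1.0)

    pos = {g: i for i, g in enumerate(shared)}
    module_ids = sorted(m for m in ref_assignment.unique() if m != 0)
    skipped: list[str] = []
    rows = []
    n_shared_total = len(shared)
    for m in module_ids:
        genes = [g for g in ref_assignment.index[ref_assignment == m] if g in pos]
        if len(genes) < min_shared_genes:
            skipped.append(f"module {m}: only {len(genes)} shared genes (< {min_shared_genes})")
            continue
        idx = np.array([pos[g] for g in genes])
        obs = _module_stats(idx, cor_ref, cor_test, adj_ref, adj_test)
        null = np.empty((n_perm, 3))
        for p in range(n_perm):
            ridx = rng.choice(n_shared_total, size=idx.size, replace=False)
            null[p] = _module_stats(ridx, cor_ref, cor_test, adj_ref, adj_test)
        null_mean = np.nanmean(null, axis=0)
        null_sd = np.nanstd(null, axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (np.array(obs) - null_mean) / null_sd
        z_density = float(z[0])
        z_connectivity = float(np.nanmean(z[1:]))
        z_summary = (z_density + z_connectivity) / 2.0
        rows.append(
            {
                "module": m,
                "n_genes": int((ref_assignment == m).sum()),
                "n_shared": len(genes),
                "density": obs[0],
                "cor_kim": obs[1],
                "cor_cor": obs[2],
                "z_density": z_density,
                "z_connectivity": z_connectivity,
                "z_summary": z_summary,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        ranks = np.column_stack(
            [
                stats.rankdata(-table[c].to_numpy(), method="ordinal")
                for c in ("density", "cor_kim", "cor_cor")
            ]
        )
        table["median_rank"] = np.median(ranks, axis=1).astype(int)
        table["preservation_class"] = [classify_preservation(z) for z in table["z_summary"]]
    else:
        table = pd.DataFrame(
            columns=[
                "module", "n_genes", "n_shared", "density", "cor_kim", "cor_cor",
                "z_density", "z_connectivity", "z_summary", "median_rank", "preservation_class",
            ]
        )
    return PreservationResult(stats=table, skipped=skipped, n_perm=n_perm, seed=seed)
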