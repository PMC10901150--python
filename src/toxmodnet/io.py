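"""Reading and writing the pipeline's tabular artifacts.

Everything is plain text: counts as TSV (genes in rows, samples in
columns) or MatrixMarket MTX with sidecar row/column name files, sample
metadata / trait / RNAi tables as TSV, log2FC and eigengene matrices as
TSV with the condition key spread over leading columns, gene sets as GMT,
and ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from .containers import (
    CONDITION_NAMES,
    CountMatrix,
    LogFCMatrix,
    StudyDesign,
    validate_rnai_table,
    validate_trait_table,
)

# -- counts ----------------------------------------------------------------


def write_counts_tsv(counts: CountMatrix, path) -> None:
    counts.values.to_csv(path, sep="\t", index_label="gene")


def read_counts_tsv(path, design: StudyDesign) -> CountMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    bad = values.columns[~values.apply(lambda c: np.issubdtype(c.dtype, np.number))]
    if len(bad):
        raise ValueError(f"non-numeric count columns: {list(bad)[:5]}")
    if (values.to_numpy() % 1 != 0).any():
        raise ValueError("counts must be integers")
    return CountMatrix(values.astype(np.int64), design)


def write_counts_mtx(counts: CountMatrix, prefix) -> None:
    """Write counts as `<prefix>.mtx` with `.rownames` / `.colnames` sidecars."""
    prefix = Path(prefix)
    scipy_io.mmwrite(str(prefix.with_suffix(".mtx")), sparse.csr_matrix(counts.values.to_numpy()))
    prefix.with_suffix(".rownames").write_text("\n".join(counts.probe_ids) + "\n")
    prefix.with_suffix(".colnames").write_text("\n".join(counts.sample_ids) + "\n")


def read_counts_mtx(prefix, design: StudyDesign) -> CountMatrix:
    prefix = Path(prefix)
    m = scipy_io.mmread(str(prefix.with_suffix(".mtx")))
    rows = prefix.with_suffix(".rownames").read_text().splitlines()
    cols = prefix.with_suffix(".colnames").read_text().splitlines()
    values = pd.DataFrame(
        np.asarray(m.todense() if sparse.issparse(m) else m, dtype=np.int64),
        index=pd.Index(rows, name="gene"),
        columns=cols,
    )
    return CountMatrix(values, design)


# -- condition-indexed matrices (log2FC, padj, eigengenes) ------------------


def write_condition_matrix(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index = pd.MultiIndex.from_tuples(out.index, names=CONDITION_NAMES)
    out.reset_index().to_csv(path, sep="\t", index=False)


def read_condition_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(list(CONDITION_NAMES))
    df.index = pd.MultiIndex.from_tuples(df.index, names=CONDITION_NAMES)
    return df


def write_logfc(logfc: LogFCMatrix, values_path, padj_path) -> None:
    write_condition_matrix(logfc.values, values_path)
    write_condition_matrix(logfc.padj, padj_path)


def read_logfc(values_path, padj_path) -> LogFCMatrix:
    values = read_condition_matrix(values_path)
    padj = read_condition_matrix(padj_path)
    values.columns.name = padj.columns.name = "gene"
    return LogFCMatrix(values=values, padj=padj)


def write_eigengenes(egs: pd.DataFrame, path) -> None:
    out = egs.copy()
    out.columns = [f"M{m}" for m in out.columns]
    write_condition_matrix(out, path)


def read_eigengenes(path) -> pd.DataFrame:
    df = read_condition_matrix(path)
    df.columns = [int(str(c).lstrip("M")) for c in df.columns]
    return df


# -- module assignment ------------------------------------------------------


def write_modules(assignment: pd.Series, path, coreg: pd.Series | None = None,
                  hub: Mapping[int, str] | None = None) -> None:
    df = pd.DataFrame({"gene": assignment.index, "module": assignment.to_numpy()})
    if coreg is not None:
        df["corEG"] = coreg.reindex(assignment.index).to_numpy()
    if hub is not None:
        hubs = {g for g in hub.values()}
        df["is_hub"] = [g in hubs for g in df["gene"]]
    df.to_csv(path, sep="\t", index=False)


def read_modules(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["module"].to_numpy(int), index=pd.Index(df["gene"], name="gene"),
                     name="module")


# -- simple tables ----------------------------------------------------------


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_trait_table(path) -> pd.DataFrame:
    return validate_trait_table(pd.read_csv(path, sep="\t"))


def read_rnai_table(path) -> pd.DataFrame:
    return validate_rnai_table(pd.read_csv(path, sep="\t"))


# -- GMT gene sets ----------------------------------------------------------


def read_gmt(path) -> dict[str, set]:
    """Parse a GMT gene-set file: tab-separated set id, description, genes."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields (< 3)")
            set_id = fields[0]
            if set_id in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set id {set_id!r}")
            sets[set_id] = {g for g in fields[2:] if g}
    return sets


def write_gmt(gene_sets: Mapping[str, set], path, descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for set_id, genes in gene_sets.items():
            desc = (descriptions or {}).get(set_id, "na")
            fh.write("\t".join([set_id, desc, *sorted(genes)]) + "\n")


# -- ground truth -----------------------------------------------------------


def write_truth_json(truth: dict, path) -> None:
    """Serialize generator ground truth (module labels, corrupted samples, ...)."""
    payload = {}
    for key, val in truth.items():
        if isinstance(val, pd.Series):
            payload[key] = {str(k): (int(v) if isinstance(v, (int, np.integer)) else v)
                            for k, v in val.items()}
        elif isinstance(val, pd.DataFrame):
            payload[key] = {
                "index": [list(map(_plain, t)) if isinstance(t, tuple) else _plain(t)
                          for t in val.index],
                "columns": [_plain(c) for c in val.columns],
                "values": val.to_numpy().tolist(),
            }
        else:
            payload[key] = _plain(val)
    Path(path).write_text(json.dumps(payload, indent=1, default=_plain))


def _plain(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (set, frozenset, tuple)):
        return sorted(v) if isinstance(v, (set, frozenset)) else list(v)
    if isinstance(v, dict):
        return {str(k): _plain(x) for k, x in v.items()}
    return v
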