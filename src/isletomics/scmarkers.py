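"""Single-cell QC and marker-threshold cluster merging.

The dataset is a cells x genes count matrix (AnnData-backed) with per-cell
sample, condition and precomputed cluster labels; graph clustering itself
is consumed, not reproduced.  The merge step averages log-normalized marker
expression per original cluster and relabels clusters High / Mid / Low by
two thresholds applied to the cluster means (defaults 0.3 and 0.18, strict
on both sides, boundary values falling to Mid).  Normalization is
ln(1 + 1e4 * count / cell_total), the scale on which the default thresholds
are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.io import mmread

__all__ = [
    "CellDataset",
    "MarkerMergeResult",
    "qc_filter",
    "merge_clusters_by_marker",
    "cluster_condition_proportions",
    "marker_summary",
]

MERGED_LEVELS = ("High", "Mid", "Low")


@dataclass
class CellDataset:
    """Cells x genes counts with sample/condition/cluster annotations."""

    adata: ad.AnnData

    def __post_init__(self) -> None:
        obs = self.adata.obs
        for col in ("sample", "condition", "cluster"):
            if col not in obs.columns:
                raise ValueError(f"per-cell annotation {col!r} missing")
        self._recompute_metrics()

    def _recompute_metrics(self) -> None:
        x = sparse.csr_matrix(self.adata.X)
        self.adata.obs["n_counts"] = np.asarray(x.sum(axis=1)).ravel()
        self.adata.obs["n_features"] = np.asarray((x > 0).sum(axis=1)).ravel()
        mito = self.adata.var_names.str.lower().str.startswith("mt-")
        mito_counts = np.asarray(x[:, np.where(mito)[0]].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(
                self.adata.obs["n_counts"] > 0,
                mito_counts / np.maximum(self.adata.obs["n_counts"], 1),
                0.0,
            )
        self.adata.obs["mito_fraction"] = frac
        self.adata.X = x

    @property
    def n_cells(self) -> int:
        return self.adata.n_obs

    @classmethod
    def read_mtx(
        cls, mtx_path, barcodes_path, features_path, obs_path
    ) -> "CellDataset":
        """Load a genes x cells MTX triplet plus a per-cell annotation TSV
        (columns: sample, condition, cluster; index = barcode)."""
        x = sparse.csr_matrix(mmread(mtx_path).T)
        barcodes = pd.read_csv(barcodes_path, header=None, sep="\t")[0].astype(str)
        features = pd.read_csv(features_path, header=None, sep="\t")[0].astype(str)
        obs = pd.read_csv(obs_path, sep="\t", index_col=0)
        obs.index = obs.index.astype(str)
        obs = obs.loc[barcodes]
        adata = ad.AnnData(X=x, obs=obs, var=pd.DataFrame(index=features))
        return cls(adata)

    def normalized(self, gene: str) -> np.ndarray:
        """ln(1 + 1e4 * count / cell_total) for one gene across all cells."""
        if gene not in self.adata.var_names:
            raise KeyError(f"marker gene {gene!r} absent from dataset")
        j = self.adata.var_names.get_loc(gene)
        counts = np.asarray(
            sparse.csr_matrix(self.adata.X)[:, j].todense()
        ).ravel()
        totals = np.maximum(self.adata.obs["n_counts"].values, 1.0)
        return np.log1p(1e4 * counts / totals)


@dataclass
class MarkerMergeResult:
    marker: str
    hi: float
    lo: float
    cluster_means: pd.Series        # per original cluster, normalized scale
    cluster_labels: dict            # original cluster -> High/Mid/Low
    cell_labels: pd.Series = field(repr=False)  # per cell


def qc_filter(
    ds: CellDataset,
    f_min: int = 2000,
    f_max: int = 5000,
    c_min: int = 5000,
    c_max: int = 50000,
    mito_max: float = 0.10,
) -> CellDataset:
    """Keep cells inside the feature/count ranges (inclusive) with
    mitochondrial fraction strictly below ``mito_max``."""
    obs = ds.adata.obs
    keep = (
        (obs["n_features"] >= f_min)
        & (obs["n_features"] <= f_max)
        & (obs["n_counts"] >= c_min)
        & (obs["n_counts"] <= c_max)
        & (obs["mito_fraction"] < mito_max)
    )
    return CellDataset(ds.adata[keep.values].copy())


def merge_clusters_by_marker(
    ds: CellDataset, marker_gene: str, hi: float = 0.3, lo: float = 0.18
) -> MarkerMergeResult:
    """Merge original clusters into High/Mid/Low by mean normalized marker
    expression.  Thresholds are strict: a mean exactly at ``hi`` or ``lo``
    lands in Mid; per-cell labels are inherited from the cluster."""
    if hi <= lo:
        raise ValueError("need hi > lo")
    norm = ds.normalized(marker_gene)
    clusters = ds.adata.obs["cluster"].astype(str)
    means = pd.Series(norm).groupby(clusters.values).mean().sort_index()
    labels = {}
    for cl, m in means.items():
        labels[cl] = "High" if m > hi else ("Low" if m < lo else "Mid")
    cell_labels = clusters.map(labels)
    cell_labels.index = ds.adata.obs_names
    return MarkerMergeResult(marker_gene, hi, lo, means, labels, cell_labels)


def cluster_condition_proportions(
    result: MarkerMergeResult,
    ds: CellDataset,
    baseline: str = "vehicle",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample merged-cluster fractions and treatment-vs-baseline t-tests.

    Returns ``(proportions, tests)``: proportions has one row per sample
    (fractions summing to 1), tests one row per (merged cluster, condition)
    with a two-sided t-test of per-sample fractions against the baseline
    condition.  Conditions with fewer than two samples are reported with the
    test skipped and flagged.
    """
    obs = ds.adata.obs
    frame = pd.DataFrame(
        {
            "sample": obs["sample"].astype(str).values,
            "condition": obs["condition"].astype(str).values,
            "merged": result.cell_labels.values,
        }
    )
    counts = (
        frame.groupby(["sample", "merged"], observed=True).size().unstack(fill_value=0)
    )
    for level in MERGED_LEVELS:
        if level not in counts.columns:
            counts[level] = 0
    counts = counts[list(MERGED_LEVELS)]
    props = counts.div(counts.sum(axis=1), axis=0)
    sample_cond = frame.drop_duplicates("sample").set_index("sample")["condition"]
    props.insert(0, "condition", sample_cond.loc[props.index].values)

    rows = []
    conditions = [c for c in props["condition"].unique() if c != baseline]
    base = props[props["condition"] == baseline]
    for cond in conditions:
        trt = props[props["condition"] == cond]
        for level in MERGED_LEVELS:
            if len(base) < 2 or len(trt) < 2:
                rows.append(
                    {"merged": level, "condition": cond, "t": np.nan,
                     "p": np.nan, "skipped": True}
                )
                continue
            t, p = stats.ttest_ind(trt[level], base[level])
            if np.isnan(t):  # zero variance in both groups
                equal = np.isclose(trt[level].mean(), base[level].mean())
                t, p = (0.0, 1.0) if equal else (np.inf, 0.0)
            rows.append(
                {"merged": level, "condition": cond, "t": float(t),
                 "p": float(p), "skipped": False}
            )
    return props, pd.DataFrame(rows)


def marker_summary(
    ds: CellDataset, genes: list[str], cluster_key: str = "cluster"
) -> pd.DataFrame:
    """Per-cluster mean normalized expression and fraction of cells
    expressing (count > 0) each gene; unknown genes yield all-NA rows."""
    clusters = ds.adata.obs[cluster_key].astype(str)
    uniq = sorted(clusters.unique())
    rows = []
    for gene in genes:
        if gene not in ds.adata.var_names:
            for cl in uniq:
                rows.append({"gene": gene, "cluster": cl,
                             "mean_norm": np.nan, "frac_expressing": np.nan})
            continue
        norm = ds.normalized(gene)
        j = ds.adata.var_names.get_loc(gene)
        raw = np.asarray(sparse.csr_matrix(ds.adata.X)[:, j].todense()).ravel()
        for cl in uniq:
            mask = (clusters == cl).values
            rows.append(
                {
                    "gene": gene,
                    "cluster": cl,
                    "mean_norm": float(norm[mask].mean()) if mask.any() else 0.0,
                    "frac_expressing": float((raw[mask] > 0).mean())
                    if mask.any()
                    else 0.0,
                }
            )
    return pd.DataFrame(rows)
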