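"""Donor-aware differential expression on TPM tables.

Treatment effects are modelled on log2(TPM + 1) with a donor random
intercept:

    y_ij = mu + beta * treated_ij + u_i + e_ij,   u_i ~ N(0, s_d^2)

For a complete, balanced paired design (every donor contributes exactly one
control and one treated sample) the generalized-least-squares estimate of
beta is the mean of the within-donor differences and its Wald test is the
exact paired t-test; that closed form is used directly, which keeps the
genome-wide scan vectorized and reproducible.  Unbalanced designs fall back
to a numeric REML fit (statsmodels MixedLM) per gene.

Selection mirrors the source study: genes are kept when mean TPM exceeds
``tpm_min`` in either condition, and flagged as regulated on the raw
p-value at ``alpha``.  Benjamini-Hochberg q-values are reported alongside
but are not used for selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionTable",
    "LmeFit",
    "DEResult",
    "filter_expressed",
    "fit_paired_lme",
    "differential_genes",
]

CONTROL, TREATED = "control", "treated"


@dataclass
class ExpressionTable:
    """TPM matrix (genes x samples) plus donor/condition sample metadata."""

    tpm: pd.DataFrame
    design: pd.DataFrame  # index = sample ids; columns: donor, condition

    def __post_init__(self) -> None:
        missing = {"donor", "condition"} - set(self.design.columns)
        if missing:
            raise ValueError(f"design lacks columns: {sorted(missing)}")
        if list(self.tpm.columns) != list(self.design.index):
            self.design = self.design.loc[self.tpm.columns]
        bad = set(self.design["condition"]) - {CONTROL, TREATED}
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")
        if (self.tpm.values < 0).any():
            raise ValueError("TPM values must be >= 0")

    @property
    def donors(self) -> list:
        return sorted(self.design["donor"].unique())

    def samples_of(self, condition: str) -> list:
        return list(self.design.index[self.design["condition"] == condition])

    def is_balanced_paired(self) -> bool:
        counts = self.design.groupby(["donor", "condition"]).size().unstack(fill_value=0)
        return (
            set(counts.columns) == {CONTROL, TREATED}
            and (counts.values == 1).all()
        )

    @classmethod
    def read(cls, tpm_path, design_path) -> "ExpressionTable":
        tpm = pd.read_csv(tpm_path, sep="\t", index_col=0)
        design = pd.read_csv(design_path, sep="\t", index_col=0)
        return cls(tpm, design)

    def write(self, tpm_path, design_path) -> None:
        self.tpm.to_csv(tpm_path, sep="\t", float_format="%.6f")
        self.design.to_csv(design_path, sep="\t")


@dataclass
class LmeFit:
    effect: float
    se: float
    p: float
    df: float
    degenerate: bool = False
    method: str = "paired-closed-form"


@dataclass
class DEResult:
    gene_id: str
    effect: float
    se: float
    p_raw: float
    q_bh: float
    mean_tpm_control: float
    mean_tpm_treated: float
    regulated: bool
    direction: str  # up / down / none


def filter_expressed(table: ExpressionTable, tpm_min: float = 0.5) -> list[str]:
    """Genes whose mean TPM exceeds ``tpm_min`` in control OR treated (strict >)."""
    ctrl = table.tpm[table.samples_of(CONTROL)].mean(axis=1)
    trt = table.tpm[table.samples_of(TREATED)].mean(axis=1)
    keep = (ctrl > tpm_min) | (trt > tpm_min)
    return list(table.tpm.index[keep])


def _paired_differences(table: ExpressionTable, genes: list[str]) -> np.ndarray:
    """log2(TPM+1) treated-minus-control matrix, genes x donors."""
    y = np.log2(table.tpm.loc[genes].values + 1.0)
    donors = table.donors
    cols = {s: i for i, s in enumerate(table.tpm.columns)}
    d = np.empty((len(genes), len(donors)))
    for j, donor in enumerate(donors):
        sub = table.design[table.design["donor"] == donor]
        trt = sub.index[sub["condition"] == TREATED][0]
        ctl = sub.index[sub["condition"] == CONTROL][0]
        d[:, j] = y[:, cols[trt]] - y[:, cols[ctl]]
    return d


def _paired_t_rows(d: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized paired t-test on rows of a difference matrix.

    Zero-variance rows get the degenerate limit: p = 0 when the mean
    difference is non-zero, p = 1 otherwise.
    """
    n = d.shape[1]
    eff = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    se = sd / np.sqrt(n)
    degenerate = sd == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, eff / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p = np.where(degenerate, np.where(eff != 0.0, 0.0, 1.0), p)
    return eff, se, p, degenerate


def fit_paired_lme(y: np.ndarray, design: pd.DataFrame) -> LmeFit:
    """Fit the donor random-intercept model for one gene.

    ``y`` is log2(TPM + 1) per sample, aligned with ``design`` rows
    (columns ``donor`` and ``condition``).
    """
    design = design.copy()
    counts = design.groupby(["donor", "condition"]).size().unstack(fill_value=0)
    donors_both = (
        (counts.get(CONTROL, 0) > 0) & (counts.get(TREATED, 0) > 0)
    )
    if int(np.asarray(donors_both).sum()) < 2:
        raise ValueError("need >= 2 donors observed under both conditions")

    balanced = set(counts.columns) == {CONTROL, TREATED} and (counts.values == 1).all()
    if balanced:
        donors = sorted(design["donor"].unique())
        d = np.empty(len(donors))
        for j, donor in enumerate(donors):
            sub = design[design["donor"] == donor]
            it = y[design.index.get_indexer(sub.index[sub["condition"] == TREATED])][0]
            ic = y[design.index.get_indexer(sub.index[sub["condition"] == CONTROL])][0]
            d[j] = it - ic
        eff, se, p, degen = _paired_t_rows(d[None, :])
        return LmeFit(float(eff[0]), float(se[0]), float(p[0]), len(donors) - 1,
                      bool(degen[0]))

    import statsmodels.formula.api as smf

    frame = design.assign(y=y, treated=(design["condition"] == TREATED).astype(float))
    model = smf.mixedlm("y ~ treated", frame, groups=frame["donor"])
    fit = model.fit(reml=True, method="lbfgs")
    eff = float(fit.params["treated"])
    se = float(fit.bse["treated"])
    p = float(fit.pvalues["treated"])
    return LmeFit(eff, se, p, np.nan, False, "mixedlm-reml")


def differential_genes(
    table: ExpressionTable,
    alpha: float = 0.05,
    tpm_min: float = 0.5,
) -> list[DEResult]:
    """Genome-wide DE scan with the expression filter and raw-p selection."""
    counts = table.design.groupby("condition")["donor"].nunique()
    if counts.get(CONTROL, 0) < 2 or counts.get(TREATED, 0) < 2:
        raise ValueError("need >= 2 donors per condition")

    genes = filter_expressed(table, tpm_min)
    ctrl_mean = table.tpm.loc[genes, table.samples_of(CONTROL)].mean(axis=1)
    trt_mean = table.tpm.loc[genes, table.samples_of(TREATED)].mean(axis=1)

    if table.is_balanced_paired():
        d = _paired_differences(table, genes)
        eff, se, p, _ = _paired_t_rows(d)
    else:
        eff = np.empty(len(genes))
        se = np.empty(len(genes))
        p = np.empty(len(genes))
        y_all = np.log2(table.tpm.loc[genes].values + 1.0)
        for i in range(len(genes)):
            fit = fit_paired_lme(y_all[i], table.design)
            eff[i], se[i], p[i] = fit.effect, fit.se, fit.p

    q = multipletests(p, method="fdr_bh")[1] if len(genes) else np.array([])
    out = []
    for i, g in enumerate(genes):
        direction = "up" if eff[i] > 0 else ("down" if eff[i] < 0 else "none")
        out.append(
            DEResult(
                gene_id=g,
                effect=float(eff[i]),
                se=float(se[i]),
                p_raw=float(p[i]),
                q_bh=float(q[i]),
                mean_tpm_control=float(ctrl_mean.iloc[i]),
                mean_tpm_treated=float(trt_mean.iloc[i]),
                regulated=bool(p[i] < alpha),
                direction=direction,
            )
        )
    return out


def results_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "log2fc": [r.effect for r in results],
            "se": [r.se for r in results],
            "p_raw": [r.p_raw for r in results],
            "q_bh": [r.q_bh for r in results],
            "mean_tpm_control": [r.mean_tpm_control for r in results],
            "mean_tpm_treated": [r.mean_tpm_treated for r in results],
            "regulated": [r.regulated for r in results],
            "direction": [r.direction for r in results],
        }
    ).set_index("gene_id")
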