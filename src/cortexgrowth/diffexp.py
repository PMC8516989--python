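"""Postnatal-vs-prenatal differential expression screen.

Expression arrives as a genes x samples RPKM matrix.  After log2
scaling, the fold change of a gene is the difference of group means of
log2 expression (postnatal target minus prenatal control), so the linear
fold is 2**log2_fc.  Genes pass the screen when the linear fold exceeds
a threshold (default 4) AND the per-gene two-sample t-test p-value falls
below a Bonferroni-style alpha (default 5.7e-6); survivors are ranked by
descending fold change.  The per-gene test defaults to the
pooled-variance two-sample t-test on log2 values; Welch's unequal-
variance variant is selectable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger("cortexgrowth")

__all__ = [
    "ExpressionMatrix", "DifferentialExpression", "DiffExprResults",
    "to_log2", "fold_change", "per_gene_test", "select_genes",
    "export_gene_list", "read_expression", "read_sample_metadata",
]

TARGET_GROUP = "target_postnatal"
CONTROL_GROUP = "control_prenatal"
DEFAULT_FC_THRESHOLD = 4.0       # linear fold
DEFAULT_ALPHA = 5.7e-6           # Bonferroni-corrected per-gene threshold


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x samples matrix with an explicit scale flag."""

    values: pd.DataFrame
    scale: str = "linear"   # "linear" (RPKM) or "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError("scale must be 'linear' or 'log2'")
        v = self.values
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dups[:5]}")
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if self.scale == "linear" and (arr < 0).any():
            raise ValueError("linear-scale RPKM values must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


def _check_metadata(matrix: ExpressionMatrix, metadata: pd.DataFrame) -> pd.Series:
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    missing = [s for s in matrix.samples if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing[:5]}")
    groups = meta.loc[matrix.samples, "group"]
    bad = set(groups) - {TARGET_GROUP, CONTROL_GROUP}
    if bad:
        raise ValueError(f"unknown group labels {sorted(bad)}")
    for g in (TARGET_GROUP, CONTROL_GROUP):
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} needs at least 2 samples")
    return groups


def to_log2(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(RPKM + pseudocount).  Refuses to double-transform."""
    if matrix.scale == "log2":
        raise ValueError("matrix is already log2-scaled")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    vals = matrix.values + pseudocount
    if (vals.to_numpy() <= 0).any():
        raise ValueError("log2 of non-positive value; raise the pseudocount")
    return ExpressionMatrix(np.log2(vals), scale="log2")


def fold_change(matrix_log2: ExpressionMatrix, metadata: pd.DataFrame) -> pd.Series:
    """Per-gene log2 fold change: mean over target minus mean over control."""
    if matrix_log2.scale != "log2":
        raise ValueError("fold_change expects a log2-scaled matrix")
    groups = _check_metadata(matrix_log2, metadata)
    v = matrix_log2.values
    tgt = v.loc[:, groups[groups == TARGET_GROUP].index]
    ctl = v.loc[:, groups[groups == CONTROL_GROUP].index]
    return (tgt.mean(axis=1) - ctl.mean(axis=1)).rename("log2_fc")


def per_gene_test(matrix_log2: ExpressionMatrix, metadata: pd.DataFrame,
                  equal_var: bool = True) -> pd.Series:
    """Two-sided two-sample t-test per gene on log2 values.

    ``equal_var=True`` (default) pools the within-group variances
    (df = n1 + n2 - 2); ``equal_var=False`` gives Welch's test.  Genes
    with zero variance in both groups get p = 1 when the group means are
    equal and p = 0 when they differ (logged as degenerate).
    """
    if matrix_log2.scale != "log2":
        raise ValueError("per_gene_test expects a log2-scaled matrix")
    groups = _check_metadata(matrix_log2, metadata)
    v = matrix_log2.values
    tgt = v.loc[:, groups[groups == TARGET_GROUP].index].to_numpy()
    ctl = v.loc[:, groups[groups == CONTROL_GROUP].index].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(tgt, ctl, axis=1, equal_var=equal_var)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        means_equal = np.isclose(tgt.mean(axis=1), ctl.mean(axis=1))
        p[degenerate & means_equal] = 1.0
        p[degenerate & ~means_equal] = 0.0
        n_zero = int((degenerate & ~means_equal).sum())
        if n_zero:
            log.warning("%d gene(s) with zero within-group variance and unequal "
                        "means; p set to 0", n_zero)
    return pd.Series(p, index=matrix_log2.genes, name="p")


def _result_frame(log2_fc: pd.Series, p: pd.Series,
                  fc_threshold: float, alpha: float,
                  two_sided_fc: bool) -> pd.DataFrame:
    fold = np.power(2.0, log2_fc)
    crit_fold = np.abs(log2_fc).pipe(lambda x: np.power(2.0, x)) if two_sided_fc else fold
    res = pd.DataFrame({
        "log2_fc": log2_fc,
        "fold_linear": fold,
        "p": p,
        "p_bonferroni": np.minimum(p * len(p), 1.0),
        "passes_fc": crit_fold > fc_threshold,
        "passes_p": p < alpha,
    })
    order = _ranked(res)
    res["rank"] = pd.Series(np.arange(1, len(res) + 1), index=order.index)
    return res


def _ranked(frame: pd.DataFrame) -> pd.DataFrame:
    """Descending fold change; ties broken by ascending p, then symbol."""
    out = frame.sort_index(kind="mergesort")
    out = out.sort_values("p", ascending=True, kind="mergesort")
    return out.sort_values("log2_fc", ascending=False, kind="mergesort")


class DifferentialExpression:
    """Model object for the postnatal-vs-prenatal screen.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Linear RPKM or already log2-scaled expression.
    metadata : DataFrame with columns sample_id, group, region, age_label.
    pseudocount : added before log2 when the input is linear.
    equal_var : pooled (True) vs Welch (False) two-sample t-test.
    """

    def __init__(self, matrix: ExpressionMatrix, metadata: pd.DataFrame,
                 pseudocount: float = 1.0, equal_var: bool = True):
        self.matrix_log2 = (matrix if matrix.scale == "log2"
                            else to_log2(matrix, pseudocount))
        self.metadata = metadata
        self.equal_var = equal_var
        _check_metadata(self.matrix_log2, metadata)

    def fit(self) -> "DiffExprResults":
        fc = fold_change(self.matrix_log2, self.metadata)
        p = per_gene_test(self.matrix_log2, self.metadata, equal_var=self.equal_var)
        return DiffExprResults(fc, p)


class DiffExprResults:
    """Per-gene fold changes and p-values with threshold selection."""

    def __init__(self, log2_fc: pd.Series, p: pd.Series):
        self.log2_fc = log2_fc
        self.p = p

    def table(self, fc_threshold: float = DEFAULT_FC_THRESHOLD,
              alpha: float = DEFAULT_ALPHA,
              two_sided_fc: bool = False) -> pd.DataFrame:
        return _result_frame(self.log2_fc, self.p, fc_threshold, alpha, two_sided_fc)

    def select(self, fc_threshold: float = DEFAULT_FC_THRESHOLD,
               alpha: float = DEFAULT_ALPHA,
               two_sided_fc: bool = False) -> pd.DataFrame:
        """Genes passing both thresholds, ranked by descending fold change.

        By default only up-regulated (postnatal > prenatal) genes can
        pass, since fold_linear > threshold >= 1 requires log2_fc > 0;
        ``two_sided_fc=True`` applies the fold threshold to |log2_fc|.
        """
        res = self.table(fc_threshold, alpha, two_sided_fc)
        return _ranked(res[res["passes_fc"] & res["passes_p"]])

    def summary(self, fc_threshold: float = DEFAULT_FC_THRESHOLD,
                alpha: float = DEFAULT_ALPHA) -> str:
        sel = self.select(fc_threshold, alpha)
        lines = [
            "Postnatal vs prenatal differential expression",
            "=" * 48,
            f"Genes tested: {len(self.log2_fc)}",
            f"Fold-change threshold (linear): {fc_threshold}",
            f"Significance threshold: {alpha:g}",
            f"Selected genes: {len(sel)}",
        ]
        if len(sel):
            top = sel.head(10)[["log2_fc", "fold_linear", "p"]]
            lines += ["", "Top genes by fold change:",
                      top.to_string(float_format=lambda v: f"{v:.4g}")]
        return "\n".join(lines)


def select_genes(result: pd.DataFrame | DiffExprResults,
                 fc_threshold: float = DEFAULT_FC_THRESHOLD,
                 alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Threshold-and-rank selection on a results object or table."""
    if isinstance(result, DiffExprResults):
        return result.select(fc_threshold, alpha)
    return _ranked(result[(result["fold_linear"] > fc_threshold) & (result["p"] < alpha)])


def export_gene_list(selection: pd.DataFrame, path) -> None:
    """Write a ranked one-symbol-per-line list plus a stats TSV.

    The plain list (at ``path``) is suitable for external enrichment
    services; ``<path>.stats.tsv`` carries log2_fc and p per gene.
    """
    symbols = list(selection.index)
    if not symbols:
        log.warning("exporting an empty gene selection to %s", path)
    with open(path, "w") as fh:
        for s in symbols:
            fh.write(f"{s}\n")
    stats_path = f"{path}.stats.tsv"
    selection[["log2_fc", "p"]].to_csv(stats_path, sep="\t",
                                       index_label="gene", float_format="%.17g")


def read_expression(path, scale: str = "linear") -> ExpressionMatrix:
    """Read a TSV with gene symbols in the first column, samples after."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    return ExpressionMatrix(df, scale=scale)


def read_sample_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group"}
    if not required <= set(meta.columns):
        raise ValueError(f"metadata needs columns {sorted(required)}")
    return meta
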