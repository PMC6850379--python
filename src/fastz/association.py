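"""Diversity-ratio summaries and the diversity-vs-expression regression.

``diversity_ratio`` pools per-site synonymous diversity within the Z and
autosomal gene sets and reports pi_sZ / pi_sA; at neutral equilibrium with
a 1:1 sex ratio the expectation is 0.75 (three Z copies per four autosome
copies), and purifying/background selection pushes it lower.

``pin_regression`` is the gene-level ordinary least squares fit

    log pi_n ~ log pi_s + chromosome_class + log RPKM,

dropping genes where any logged quantity is zero (no polymorphism or no
expression), with the dropped count reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .counts import GeneCounts, pool_counts

__all__ = ["RegressionResult", "diversity_ratio", "pin_regression"]


@dataclass
class RegressionResult:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    n_genes_used: int
    n_genes_dropped_zero: int
    rsquared: float
    diagnostics: pd.DataFrame  # fitted vs residual per gene used


def diversity_ratio(
    genes: Sequence[GeneCounts], chrom_class: Mapping[str, str]
) -> float:
    """Pooled pi_sZ / pi_sA over the two chromosome classes."""
    z = [g for g in genes if chrom_class.get(g.gene_id) == "Z"]
    a = [g for g in genes if chrom_class.get(g.gene_id) == "autosome"]
    if not z or not a:
        raise ValueError("both chromosome classes must be represented")
    return pool_counts(z).pi_s / pool_counts(a).pi_s


def pin_regression(
    table: pd.DataFrame,
    rpkm_column: str = "mean_rpkm",
) -> RegressionResult:
    """OLS of log pi_n on log pi_s, chromosome class, and log RPKM.

    ``table`` needs columns pi_n, pi_s, chrom_class and ``rpkm_column``.
    Natural logarithms; genes with pi_n, pi_s or RPKM equal to zero (or
    missing) are excluded and counted.
    """
    required = {"pi_n", "pi_s", "chrom_class", rpkm_column}
    if not required <= set(table.columns):
        raise ValueError(f"missing columns: {sorted(required - set(table.columns))}")
    n_input = len(table)
    ok = (
        (table["pi_n"] > 0)
        & (table["pi_s"] > 0)
        & (table[rpkm_column] > 0)
        & table["chrom_class"].notna()
    )
    sub = table.loc[ok]
    n_used = len(sub)
    if n_used < 10:
        raise ValueError(f"only {n_used} genes usable after zero exclusions (need >= 10)")
    if sub["chrom_class"].nunique() < 2:
        raise ValueError("design is rank deficient: single chromosome class (chrom_class)")

    X = pd.DataFrame(
        {
            "log_pi_s": np.log(sub["pi_s"]),
            "Z": (sub["chrom_class"] == "Z").astype(float),
            "log_rpkm": np.log(sub[rpkm_column]),
        },
        index=sub.index,
    )
    X = sm.add_constant(X)
    y = np.log(sub["pi_n"])
    fit = sm.OLS(y, X).fit()
    diagnostics = pd.DataFrame(
        {"fitted": fit.fittedvalues, "residual": fit.resid}, index=sub.index
    )
    return RegressionResult(
        params=fit.params,
        bse=fit.bse,
        pvalues=fit.pvalues,
        n_genes_used=n_used,
        n_genes_dropped_zero=n_input - n_used,
        rsquared=float(fit.rsquared),
        diagnostics=diagnostics,
    )
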