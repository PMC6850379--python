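"""Expression levels and sex-/tissue-bias classification.

RPKM = N_c * 1e9 / (N_tot * L_c) per gene and sample; the per-gene level
is the unweighted mean across the relevant samples.  Sex bias follows the
fold-change rule on mean RPKM ratios: RPKM_f/RPKM_m > 1.5 -> female
biased, < 0.66 -> male biased, otherwise unbiased (boundary values are
unbiased: the rule uses strict inequalities).  Tissue bias thresholds an
externally produced ovary-vs-gut differential-expression table at
adjusted p < 0.05 and |log2 fold change| > 1.5.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneAnnot",
    "rpkm",
    "rpkm_matrix",
    "mean_rpkm_by_sex",
    "classify_sex_bias",
    "classify_tissue_bias",
    "enrichment_test",
    "annotate_genes",
]

FEMALE_RATIO = 1.5
MALE_RATIO = 0.66


@dataclass
class GeneAnnot:
    gene_id: str
    chrom_class: str
    rpkm_f: float
    rpkm_m: float
    bias: str  # "female" | "male" | "unbiased"
    tissue_bias: str = "none"  # "ovary" | "gut" | "none"
    mean_rpkm: float = np.nan
    unexpressed: bool = False


def rpkm(counts_column: np.ndarray, gene_lengths: np.ndarray) -> np.ndarray:
    """RPKM_i = N_c * 1e9 / (N_tot * L_c) for one sample's count column."""
    counts_column = np.asarray(counts_column, dtype=float)
    gene_lengths = np.asarray(gene_lengths, dtype=float)
    if np.any(counts_column < 0):
        raise ValueError("negative read counts")
    if np.any(gene_lengths <= 0):
        raise ValueError("gene lengths must be > 0")
    n_tot = counts_column.sum()
    if n_tot <= 0:
        raise ValueError("zero library size")
    return counts_column * 1.0e9 / (n_tot * gene_lengths)


def rpkm_matrix(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Column-wise RPKM of a genes x samples count matrix."""
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][:3].tolist()
        raise ValueError(f"gene lengths missing for {missing} ...")
    return counts.apply(lambda col: rpkm(col.to_numpy(), lengths.to_numpy()), axis=0)


def mean_rpkm_by_sex(
    counts: pd.DataFrame, gene_lengths: pd.Series, samples: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene mean RPKM for female and male samples (columns f, m, all)."""
    r = rpkm_matrix(counts, gene_lengths)
    sex = samples.loc[r.columns, "sex"]
    return pd.DataFrame(
        {
            "rpkm_f": r.loc[:, sex == "female"].mean(axis=1),
            "rpkm_m": r.loc[:, sex == "male"].mean(axis=1),
            "mean_rpkm": r.mean(axis=1),
        }
    )


def classify_sex_bias(rpkm_f: float, rpkm_m: float) -> tuple[str, bool]:
    """(bias label, unexpressed flag) from mean female/male RPKM.

    A gene expressed in females only is female biased (infinite ratio);
    one expressed in neither sex is unbiased and flagged unexpressed.
    """
    if rpkm_f < 0 or rpkm_m < 0:
        raise ValueError("RPKM values must be >= 0")
    if rpkm_f == 0 and rpkm_m == 0:
        return "unbiased", True
    if rpkm_m == 0:
        return "female", False
    ratio = rpkm_f / rpkm_m
    if ratio > FEMALE_RATIO:
        return "female", False
    if ratio < MALE_RATIO:
        return "male", False
    return "unbiased", False


def classify_tissue_bias(
    de_table: pd.DataFrame,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 1.5,
) -> pd.Series:
    """Ovary/gut/none labels from a DE table (log2FC ovary vs gut, padj)."""
    if "log2FC" not in de_table or "padj" not in de_table:
        raise ValueError("DE table needs columns 'log2FC' and 'padj'")
    missing = de_table["padj"].isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} genes lack adjusted p; skipped")
    table = de_table.loc[~missing]
    labels = pd.Series("none", index=table.index, name="tissue_bias")
    sig = table["padj"] < fdr_threshold
    labels[sig & (table["log2FC"] > lfc_threshold)] = "ovary"
    labels[sig & (table["log2FC"] < -lfc_threshold)] = "gut"
    return labels


def enrichment_test(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 contingency table -> (statistic, p).

    Warns when any expected count is below 5 (asymptotic p unreliable).
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or np.any(table < 0) or np.any(table != np.round(table)):
        raise ValueError("need a 2x2 table of nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    if np.any(expected < 5):
        warnings.warn("expected count below 5: chi-square p-value is approximate")
    return float(chi2), float(p)


def annotate_genes(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    samples: pd.DataFrame,
    chrom_class: pd.Series,
    de_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full per-gene annotation: expression levels plus bias categories."""
    levels = mean_rpkm_by_sex(counts, gene_lengths, samples)
    bias = []
    unexpressed = []
    for f, m in zip(levels["rpkm_f"], levels["rpkm_m"]):
        b, u = classify_sex_bias(f, m)
        bias.append(b)
        unexpressed.append(u)
    annot = levels.assign(
        bias=bias,
        unexpressed=unexpressed,
        chrom_class=chrom_class.reindex(levels.index),
        tissue_bias="none",
    )
    if de_table is not None:
        labels = classify_tissue_bias(de_table)
        annot.loc[labels.index, "tissue_bias"] = labels
    annot.index.name = "gene_id"
    return annot
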