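"""Per-gene polymorphism/divergence containers and pooling.

``GeneCounts`` is the central record of the toolkit: segregating-site and
fixed-difference counts split into synonymous and nonsynonymous
compartments, the Nei-Gojobori site totals that normalize them, and the
site frequency spectra that the DFE model consumes.  Ratio statistics
(dN, dS, pi_n, pi_s) are derived on demand; pooling across genes sums the
raw counts and recomputes ratios from the pooled sums (ratio-of-sums,
never mean-of-ratios).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["GeneCounts", "pool_counts", "pool_groups", "counts_to_frame"]


@dataclass
class GeneCounts:
    """Polymorphism, divergence, site and SFS summaries for one gene.

    ``sfs_s``/``sfs_n`` have length ``n_alleles - 1`` when unfolded
    (index i-1 holds the count of sites at derived-allele count i) or
    ``n_alleles // 2`` when folded (minor-allele count bins).
    """

    gene_id: str
    n_alleles: int
    L_n: float
    L_s: float
    D_n: float
    D_s: float
    sfs_s: np.ndarray
    sfs_n: np.ndarray
    codons_used: int = 0
    folded: bool = False
    usable: bool = True
    n_unpolarized: int = 0  # SFS entries binned by minor allele (no polarization)

    def __post_init__(self) -> None:
        self.sfs_s = np.asarray(self.sfs_s, dtype=float)
        self.sfs_n = np.asarray(self.sfs_n, dtype=float)
        expected = self.n_alleles // 2 if self.folded else self.n_alleles - 1
        if self.sfs_s.shape != (expected,) or self.sfs_n.shape != (expected,):
            raise ValueError(
                f"gene {self.gene_id}: SFS length {self.sfs_s.shape[0]} "
                f"inconsistent with n_alleles={self.n_alleles}, folded={self.folded}"
            )

    @property
    def P_s(self) -> float:
        return float(self.sfs_s.sum())

    @property
    def P_n(self) -> float:
        return float(self.sfs_n.sum())

    @property
    def dN(self) -> float:
        return self.D_n / self.L_n if self.L_n > 0 else np.nan

    @property
    def dS(self) -> float:
        return self.D_s / self.L_s if self.L_s > 0 else np.nan

    def _pi_weights(self) -> np.ndarray:
        """Per-bin heterozygosity weight 2 i (n-i) / (n (n-1)).

        Valid for folded bins too: a site at minor count i contributes the
        same pairwise-difference mass as one at n-i.
        """
        n = self.n_alleles
        if self.folded:
            i = np.arange(1, n // 2 + 1)
        else:
            i = np.arange(1, n)
        return 2.0 * i * (n - i) / (n * (n - 1.0))

    @property
    def pi_s(self) -> float:
        if self.L_s <= 0:
            return np.nan
        return float(self.sfs_s @ self._pi_weights()) / self.L_s

    @property
    def pi_n(self) -> float:
        if self.L_n <= 0:
            return np.nan
        return float(self.sfs_n @ self._pi_weights()) / self.L_n

    def fold(self) -> "GeneCounts":
        """Collapse derived-count bins i and n-i into minor-allele bins."""
        if self.folded:
            return self
        n = self.n_alleles
        nf = n // 2
        folded_s = np.zeros(nf)
        folded_n = np.zeros(nf)
        for i in range(1, n):
            j = min(i, n - i) - 1
            folded_s[j] += self.sfs_s[i - 1]
            folded_n[j] += self.sfs_n[i - 1]
        return replace(self, sfs_s=folded_s, sfs_n=folded_n, folded=True)


def pool_counts(genes: Sequence[GeneCounts], gene_id: str = "pooled") -> GeneCounts:
    """Element-wise sum of counts and sites across genes.

    All genes must share ``n_alleles`` and folding mode; ratio statistics of
    the result are ratios of the pooled sums.
    """
    genes = [g for g in genes if g.usable]
    if not genes:
        raise ValueError("cannot pool an empty or fully unusable gene set")
    n_alleles = {g.n_alleles for g in genes}
    if len(n_alleles) != 1:
        raise ValueError(f"mixed n_alleles in pool: {sorted(n_alleles)}")
    folded = {g.folded for g in genes}
    if len(folded) != 1:
        raise ValueError("cannot pool folded with unfolded genes")
    return GeneCounts(
        gene_id=gene_id,
        n_alleles=genes[0].n_alleles,
        L_n=sum(g.L_n for g in genes),
        L_s=sum(g.L_s for g in genes),
        D_n=sum(g.D_n for g in genes),
        D_s=sum(g.D_s for g in genes),
        sfs_s=np.sum([g.sfs_s for g in genes], axis=0),
        sfs_n=np.sum([g.sfs_n for g in genes], axis=0),
        codons_used=sum(g.codons_used for g in genes),
        folded=genes[0].folded,
        n_unpolarized=sum(g.n_unpolarized for g in genes),
    )


def pool_groups(
    genes: Sequence[GeneCounts], grouping: Mapping[str, str]
) -> dict[str, GeneCounts]:
    """Pool genes by the group label ``grouping[gene_id]`` assigns them.

    Genes absent from ``grouping`` are skipped; empty groups are omitted.
    """
    by_group: dict[str, list[GeneCounts]] = {}
    for g in genes:
        label = grouping.get(g.gene_id)
        if label is not None:
            by_group.setdefault(label, []).append(g)
    return {label: pool_counts(gs, gene_id=label) for label, gs in by_group.items()}


def counts_to_frame(genes: Iterable[GeneCounts]) -> pd.DataFrame:
    """One row per gene with all scalar GeneCounts fields."""
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "n_alleles": g.n_alleles,
                "P_n": g.P_n,
                "P_s": g.P_s,
                "D_n": g.D_n,
                "D_s": g.D_s,
                "L_n": g.L_n,
                "L_s": g.L_s,
                "dN": g.dN,
                "dS": g.dS,
                "pi_n": g.pi_n,
                "pi_s": g.pi_s,
                "codons_used": g.codons_used,
                "folded": g.folded,
                "usable": g.usable,
            }
        )
    return pd.DataFrame(rows)
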