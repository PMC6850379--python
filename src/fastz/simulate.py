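"""Synthetic polymorphism, divergence, alignment and expression generator.

The generator draws per-gene counts directly from the Poisson-random-field
expectations the downstream DFE fitter assumes: synonymous SFS entries are
Poisson with mean theta*L_s/i, nonsynonymous entries are Poisson with mean
theta*L_n*E[H(S,i,n)] over a gamma distribution of deleterious effects, and
divergence counts are Poisson with rates set by the relative fixation rate
of the DFE plus an adaptive fraction.  Z-linked genes have their
polymorphism scaled by the Z/autosome effective-size ratio; divergence is
left unscaled because the neutral substitution rate is independent of Ne
(an optional per-class divergence multiplier models male-biased mutation).

Ground truth is recorded on every gene, so parameter-recovery tests are
exact-model tests.  ``emit_alignments`` additionally realizes each gene as
a codon alignment (ingroup haplotypes plus one outgroup) whose re-counted
statistics reproduce the simulated totals exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .codon import CODON_TO_AA, CodonAlignment, STOP_CODONS
from .prf import gamma_dfe_sfs

__all__ = [
    "SimTruth",
    "SimGene",
    "omega_na_true",
    "simulate_counts",
    "genes_to_counts",
    "emit_alignments",
    "simulate_expression",
    "simulate_de_table",
]

_BASES = "ACGT"
_SENSE_CODONS = sorted(c for c in CODON_TO_AA if c not in STOP_CODONS)


@dataclass
class SimTruth:
    """Ground-truth parameters of a simulated dataset.

    Defaults emulate the Heliconius-like regime the toolkit targets:
    ~2.5% synonymous diversity, 15% synonymous divergence, 20 sampled
    haplotypes, a leptokurtic (shape 0.4) strongly deleterious DFE and
    about half of amino-acid substitutions adaptive.
    """

    n_genes: int = 2000
    n_alleles: int = 20
    theta_s: float = 0.025
    gamma_shape: float = 0.4
    gamma_mean_S: float = -2000.0
    p_adaptive: float = 0.5
    ne_ratio_Z: float = 0.75
    div_s: float = 0.15
    seed: int = 0
    # composition of the gene set
    z_fraction: float = 0.1
    frac_female_biased: float = 0.165
    frac_male_biased: float = 0.165
    mean_codons: float = 450.0
    # optional per-class divergence multiplier for Z (male-biased mutation)
    div_multiplier_Z: float = 1.0
    # fraction of nonsynonymous *polymorphism* drawn from the neutral
    # spectrum rather than the DFE (default 0: all under the DFE)
    neutral_poly_fraction: float = 0.0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_alleles < 4:
            raise ValueError("n_alleles must be >= 4")
        if not self.theta_s > 0:
            raise ValueError("theta_s must be > 0")
        if not self.gamma_shape > 0:
            raise ValueError("gamma_shape must be > 0")
        if self.gamma_mean_S > 0:
            raise ValueError("gamma_mean_S must be <= 0")
        if not 0.0 <= self.p_adaptive < 1.0:
            raise ValueError("p_adaptive must be in [0, 1)")
        if not 0.0 < self.ne_ratio_Z <= 1.0:
            raise ValueError("ne_ratio_Z must be in (0, 1]")
        if not self.div_s > 0:
            raise ValueError("div_s must be > 0")
        if not 0.0 <= self.z_fraction <= 1.0:
            raise ValueError("z_fraction must be in [0, 1]")
        if self.frac_female_biased + self.frac_male_biased > 1.0:
            raise ValueError("frac_female_biased + frac_male_biased must be <= 1")
        if self.div_multiplier_Z <= 0:
            raise ValueError("div_multiplier_Z must be > 0")
        if not 0.0 <= self.neutral_poly_fraction <= 1.0:
            raise ValueError("neutral_poly_fraction must be in [0, 1]")


@dataclass
class SimGene:
    """One simulated gene with its recorded ground truth."""

    gene_id: str
    chrom_class: str  # "Z" or "autosome"
    L_s: float
    L_n: float
    sfs_s: np.ndarray
    sfs_n: np.ndarray
    D_s: int
    D_n: int
    true_bias: str  # "female" | "male" | "unbiased"
    base_expression: float  # unbiased-state mean RPKM
    rpkm_f: float = 0.0
    rpkm_m: float = 0.0
    true_tissue: str = "none"


def omega_na_true(shape: float, mean_S: float) -> float:
    """Expected nonadaptive dN/dS, E[S/(1-e^{-S})] over the gamma DFE.

    Adaptive quadrature (relative tolerance 1e-8) over t = -S in (0, inf);
    independent of the Gauss-Laguerre rule the fitter uses.
    """
    if mean_S > 0:
        raise ValueError("gamma_mean_S must be <= 0")
    mean_t = -float(mean_S)
    if mean_t < 1e-12:
        return 1.0
    dist = stats.gamma(shape, scale=mean_t / shape)

    def integrand(t: float) -> float:
        # t/(e^t - 1), written with negative exponents only
        if t < 1e-8:
            return dist.pdf(t) * (1.0 - t / 2.0)
        return dist.pdf(t) * t * math.exp(-t) / (1.0 - math.exp(-t))

    val, _ = integrate.quad(
        integrand, 0.0, np.inf, epsrel=1e-8, epsabs=0.0, limit=500
    )
    return val


def simulate_counts(truth: SimTruth) -> list[SimGene]:
    """Draw per-gene SFS and divergence counts under the PRF model."""
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    n = truth.n_alleles
    i_arr = np.arange(1, n)

    neutral_shape = 1.0 / i_arr
    dfe_shape_vec = gamma_dfe_sfs(truth.gamma_shape, truth.gamma_mean_S, n)
    poly_shape_n = (
        (1.0 - truth.neutral_poly_fraction) * dfe_shape_vec
        + truth.neutral_poly_fraction * neutral_shape
    )

    w_na = omega_na_true(truth.gamma_shape, truth.gamma_mean_S)
    w_a = truth.p_adaptive / (1.0 - truth.p_adaptive) * w_na
    omega_total = w_na + w_a

    n_z = int(round(truth.z_fraction * truth.n_genes))
    chrom = np.array(["Z"] * n_z + ["autosome"] * (truth.n_genes - n_z))
    rng.shuffle(chrom)

    bias = rng.choice(
        ["female", "male", "unbiased"],
        size=truth.n_genes,
        p=[
            truth.frac_female_biased,
            truth.frac_male_biased,
            1.0 - truth.frac_female_biased - truth.frac_male_biased,
        ],
    )

    codons = np.maximum(
        rng.lognormal(np.log(truth.mean_codons), 0.35, truth.n_genes), 120
    ).astype(int)
    base_expr = rng.lognormal(np.log(20.0), 1.0, truth.n_genes)

    genes: list[SimGene] = []
    for g in range(truth.n_genes):
        # nominal Nei-Gojobori split of a typical coding sequence
        L_tot = 3.0 * codons[g]
        L_s = 0.24 * L_tot
        L_n = L_tot - L_s
        theta = truth.theta_s
        if chrom[g] == "Z":
            theta = theta * truth.ne_ratio_Z
        div = truth.div_s * (truth.div_multiplier_Z if chrom[g] == "Z" else 1.0)
        sfs_s = rng.poisson(theta * L_s * neutral_shape)
        sfs_n = rng.poisson(theta * L_n * poly_shape_n)
        D_s = int(rng.poisson(L_s * div))
        D_n = int(rng.poisson(L_n * div * omega_total))
        genes.append(
            SimGene(
                gene_id=f"g{g:05d}",
                chrom_class=str(chrom[g]),
                L_s=L_s,
                L_n=L_n,
                sfs_s=sfs_s,
                sfs_n=sfs_n,
                D_s=D_s,
                D_n=D_n,
                true_bias=str(bias[g]),
                base_expression=float(base_expr[g]),
            )
        )
    return genes


def genes_to_counts(genes: Sequence[SimGene], folded: bool = False) -> list["GeneCounts"]:
    """Wrap simulated genes as GeneCounts records (counts-only path).

    Skips the alignment round trip; nominal site totals stand in for
    Nei-Gojobori recounts.
    """
    from .counts import GeneCounts

    out = []
    for g in genes:
        n = len(g.sfs_s) + 1
        gc = GeneCounts(
            gene_id=g.gene_id,
            n_alleles=n,
            L_n=g.L_n,
            L_s=g.L_s,
            D_n=g.D_n,
            D_s=g.D_s,
            sfs_s=np.asarray(g.sfs_s, dtype=float),
            sfs_n=np.asarray(g.sfs_n, dtype=float),
            codons_used=int(round((g.L_s + g.L_n) / 3)),
        )
        out.append(gc.fold() if folded else gc)
    return out


def _enumerate_changes(codon: str, synonymous: bool) -> list[tuple[int, str]]:
    """(position, alt base) single-nucleotide changes of the required class.

    Changes to or through stop codons are never offered.
    """
    aa = CODON_TO_AA[codon]
    out = []
    for pos in range(3):
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            new = codon[:pos] + alt + codon[pos + 1 :]
            if new in STOP_CODONS:
                continue
            if (CODON_TO_AA[new] == aa) == synonymous:
                out.append((pos, alt))
    return out


def emit_alignments(
    genes: Sequence[SimGene],
    truth: SimTruth,
    seed: int | None = None,
    max_retries: int = 8,
) -> dict[str, CodonAlignment]:
    """Realize each simulated gene as a codon alignment.

    Each polymorphism or fixed difference occupies its own codon (one
    variant per codon), so Nei-Gojobori re-counting recovers the simulated
    totals exactly.  The outgroup carries the ancestral allele at every
    polymorphic site, making outgroup polarization unambiguous.
    """
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    n = truth.n_alleles
    alignments: dict[str, CodonAlignment] = {}
    for gene in genes:
        variants: list[tuple[str, bool, int]] = []  # kind, synonymous, derived count
        for i, c in enumerate(np.asarray(gene.sfs_s, dtype=int)):
            variants += [("poly", True, i + 1)] * int(c)
        for i, c in enumerate(np.asarray(gene.sfs_n, dtype=int)):
            variants += [("poly", False, i + 1)] * int(c)
        variants += [("fixed", True, 0)] * int(gene.D_s)
        variants += [("fixed", False, 0)] * int(gene.D_n)

        n_codons = max(int(round((gene.L_s + gene.L_n) / 3)), len(variants) + 10)
        aln = None
        for attempt in range(max_retries):
            aln = _try_emit(gene, variants, n_codons, n, rng)
            if aln is not None:
                break
            n_codons = int(n_codons * 1.5) + 10  # too many placement misses
        if aln is None:
            raise RuntimeError(
                f"gene {gene.gene_id}: could not place {len(variants)} variants "
                f"after {max_retries} attempts"
            )
        alignments[gene.gene_id] = aln
    return alignments


def _try_emit(
    gene: SimGene,
    variants: list[tuple[str, bool, int]],
    n_codons: int,
    n: int,
    rng: np.random.Generator,
) -> CodonAlignment | None:
    codon_idx = rng.integers(0, len(_SENSE_CODONS), n_codons)
    base = [_SENSE_CODONS[k] for k in codon_idx]
    free = list(rng.permutation(n_codons))
    ingroup = [list(base) for _ in range(n)]
    outgroup = list(base)

    for kind, syn, count in variants:
        placed = False
        for slot in range(len(free)):
            c = free[slot]
            options = _enumerate_changes(base[c], syn)
            if not options:
                continue
            pos, alt = options[rng.integers(0, len(options))]
            new = base[c][:pos] + alt + base[c][pos + 1 :]
            if kind == "poly":
                carriers = rng.choice(n, size=count, replace=False)
                for h in carriers:
                    ingroup[h][c] = new
            else:
                outgroup[c] = new
            free.pop(slot)
            placed = True
            break
        if not placed:
            return None

    return CodonAlignment(
        gene_id=gene.gene_id,
        ingroup_seqs=["".join(h) for h in ingroup],
        outgroup_seq="".join(outgroup),
    )


def simulate_expression(
    genes: Sequence[SimGene],
    truth: SimTruth,
    n_samples_per_sex: int = 5,
    bias_fold: float = 4.0,
    dispersion: float = 0.1,
    mean_libsize: float = 3.0e7,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial abdomen count matrix plus its sample sheet.

    Genes with true_bias="female" have their female-sample expression
    multiplied by ``bias_fold`` (male-biased genes mirrored).  True mean
    RPKM per sex is recorded on each gene.  Returns (counts, samples):
    counts is genes x samples (integers), samples has sex/tissue/treatment.
    """
    if bias_fold < 1.0:
        raise ValueError("bias_fold must be >= 1")
    if n_samples_per_sex < 2:
        raise ValueError("n_samples_per_sex must be >= 2")
    rng = np.random.default_rng(truth.seed + 2 if seed is None else seed)

    sample_ids = [f"F{j+1}" for j in range(n_samples_per_sex)] + [
        f"M{j+1}" for j in range(n_samples_per_sex)
    ]
    sexes = ["female"] * n_samples_per_sex + ["male"] * n_samples_per_sex
    libsizes = mean_libsize * rng.lognormal(0.0, 0.2, 2 * n_samples_per_sex)

    lengths = np.array([g.L_s + g.L_n for g in genes])
    expr = np.empty((len(genes), 2))  # column 0: female mean RPKM, 1: male
    for k, g in enumerate(genes):
        f = m = g.base_expression
        if g.true_bias == "female":
            f *= bias_fold
        elif g.true_bias == "male":
            m *= bias_fold
        g.rpkm_f, g.rpkm_m = f, m
        expr[k] = (f, m)

    mu = (
        expr[:, [0] * n_samples_per_sex + [1] * n_samples_per_sex]
        * lengths[:, None]
        * libsizes[None, :]
        / 1.0e9
    )
    if dispersion > 0:
        size = 1.0 / dispersion
        counts = rng.negative_binomial(size, size / (size + mu))
    else:
        counts = rng.poisson(mu)

    counts_df = pd.DataFrame(
        counts, index=[g.gene_id for g in genes], columns=sample_ids
    )
    counts_df.index.name = "gene_id"
    samples_df = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "sex": sexes,
            "tissue": "abdomen",
            "treatment": "adult",
        }
    ).set_index("sample_id")
    return counts_df, samples_df


def simulate_de_table(
    genes: Sequence[SimGene],
    truth: SimTruth,
    frac_ovary: float = 0.005,
    frac_gut: float = 0.02,
    seed: int | None = None,
) -> pd.DataFrame:
    """Synthetic ovary-vs-gut differential-expression result table.

    Stand-in for an externally produced DE table (gene, log2FC, padj):
    a small fraction of genes get large fold changes and small adjusted
    p-values; the rest are null.  True tissue labels are recorded on genes.
    """
    rng = np.random.default_rng(truth.seed + 3 if seed is None else seed)
    rows = []
    for g in genes:
        u = rng.random()
        if u < frac_ovary:
            g.true_tissue = "ovary"
            lfc = rng.uniform(2.0, 6.0)
            padj = rng.uniform(0.0, 0.04)
        elif u < frac_ovary + frac_gut:
            g.true_tissue = "gut"
            lfc = -rng.uniform(2.0, 6.0)
            padj = rng.uniform(0.0, 0.04)
        else:
            g.true_tissue = "none"
            lfc = rng.normal(0.0, 0.3)
            padj = rng.uniform(0.1, 1.0)
        rows.append({"gene_id": g.gene_id, "log2FC": lfc, "padj": padj})
    return pd.DataFrame(rows).set_index("gene_id")
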