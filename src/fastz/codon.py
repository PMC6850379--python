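"""Nei-Gojobori codon statistics from ingroup + outgroup alignments.

Per-gene polymorphism (P_n, P_s), fixed divergence (D_n, D_s),
synonymous/nonsynonymous site totals (L_n, L_s), pairwise diversity and
site frequency spectra are computed from a codon alignment of n ingroup
haplotypes plus one outgroup sequence.

Counting scheme (equal-weight Nei-Gojobori):

* a codon column is usable only if every sequence carries an unambiguous,
  non-stop codon there (complete-case exclusion of N/gap/stop codons);
* each position of the ingroup consensus codon contributes f = (#synonymous
  single-nucleotide changes)/3 synonymous sites and 1-f nonsynonymous
  sites, so L_n + L_s = 3 x codons_used exactly;
* a site with >=2 segregating ingroup alleles is polymorphism; a site where
  the monomorphic ingroup differs from the outgroup is a fixed difference;
  a site that is both counts as polymorphism only;
* variants are classified by amino-acid effect in the majority-background
  codon context; codons with multiple fixed differences are resolved by
  averaging over minimal mutational pathways that avoid stop codons;
* SFS bins are derived-allele counts polarized by the outgroup when it
  matches one segregating allele, otherwise the minor-allele (folded) bin.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .counts import GeneCounts, pool_counts

__all__ = [
    "CODON_TO_AA",
    "STOP_CODONS",
    "CodonAlignment",
    "count_sites",
    "count_polymorphism_divergence",
    "pairwise_diversity",
    "jukes_cantor",
    "pool_counts",
]

STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in STOP_CODONS:
    CODON_TO_AA[_stop] = "*"

_VALID = set("ACGT")
_ALPHABET = set("ACGTN-")
_BASES = "ACGT"


@dataclass
class CodonAlignment:
    """Aligned coding sequences: n ingroup haplotypes plus one outgroup."""

    gene_id: str
    ingroup_seqs: list[str]
    outgroup_seq: str

    def __post_init__(self) -> None:
        self.ingroup_seqs = [s.upper() for s in self.ingroup_seqs]
        self.outgroup_seq = self.outgroup_seq.upper()
        lengths = {len(s) for s in self.ingroup_seqs} | {len(self.outgroup_seq)}
        if len(lengths) != 1:
            raise ValueError(f"gene {self.gene_id}: unequal sequence lengths")
        (length,) = lengths
        if length % 3 != 0:
            raise ValueError(f"gene {self.gene_id}: length {length} not divisible by 3")
        for s in self.ingroup_seqs + [self.outgroup_seq]:
            bad = set(s) - _ALPHABET
            if bad:
                raise ValueError(f"gene {self.gene_id}: invalid characters {bad}")

    @property
    def length(self) -> int:
        return len(self.outgroup_seq)

    @property
    def n_ingroup(self) -> int:
        return len(self.ingroup_seqs)

    def codon_column(self, j: int) -> tuple[list[str], str]:
        sl = slice(3 * j, 3 * j + 3)
        return [s[sl] for s in self.ingroup_seqs], self.outgroup_seq[sl]


def _usable(codons: list[str], out_codon: str) -> bool:
    for c in codons + [out_codon]:
        if not set(c) <= _VALID or c in STOP_CODONS:
            return False
    return True


def _consensus(codons: list[str]) -> str:
    cons = []
    for pos in range(3):
        counter = Counter(c[pos] for c in codons)
        top = max(counter.values())
        # deterministic tie-break: alphabetical among the most common
        cons.append(min(b for b, k in counter.items() if k == top))
    return "".join(cons)


def _syn_fraction(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    Every one of the 9 single-nucleotide changes counts; changes creating a
    stop codon are treated as nonsynonymous, which preserves the exact
    identity L_n + L_s = 3 per codon.
    """
    aa = CODON_TO_AA[codon]
    syn = 0
    for pos in range(3):
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            new = codon[:pos] + alt + codon[pos + 1 :]
            if new not in STOP_CODONS and CODON_TO_AA[new] == aa:
                syn += 1
    L_s = syn / 3.0
    return L_s, 3.0 - L_s


def _is_synonymous(codon_a: str, codon_b: str) -> bool | None:
    """Amino-acid effect of a single-position change; None if a stop is hit."""
    if codon_a in STOP_CODONS or codon_b in STOP_CODONS:
        return None
    return CODON_TO_AA[codon_a] == CODON_TO_AA[codon_b]


def count_sites(alignment: CodonAlignment) -> tuple[float, float, int]:
    """Nei-Gojobori (L_n, L_s, codons_used) over usable codon columns."""
    L_n = L_s = 0.0
    used = 0
    for j in range(alignment.length // 3):
        codons, out_codon = alignment.codon_column(j)
        if not _usable(codons, out_codon):
            continue
        s, n = _syn_fraction(_consensus(codons))
        L_s += s
        L_n += n
        used += 1
    return L_n, L_s, used


def _pathway_divergence(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(D_s, D_n) between two codons, averaged over minimal pathways.

    Pathways passing through a stop codon are discarded; if every pathway
    does, each differing position is classified independently instead.
    """
    diff = [p for p in range(3) if codon_a[p] != codon_b[p]]
    if not diff:
        return 0.0, 0.0
    if len(diff) == 1:
        syn = _is_synonymous(codon_a, codon_b)
        if syn is None:
            return 0.0, 0.0
        return (1.0, 0.0) if syn else (0.0, 1.0)
    path_counts = []
    for order in permutations(diff):
        cur = codon_a
        d_s = d_n = 0
        ok = True
        for p in order:
            nxt = cur[:p] + codon_b[p] + cur[p + 1 :]
            syn = _is_synonymous(cur, nxt)
            if syn is None:
                ok = False
                break
            d_s += syn
            d_n += not syn
            cur = nxt
        if ok:
            path_counts.append((d_s, d_n))
    if not path_counts:  # all pathways hit stops: classify positions one by one
        d_s = d_n = 0.0
        for p in diff:
            syn = _is_synonymous(codon_a, codon_a[:p] + codon_b[p] + codon_a[p + 1 :])
            if syn is not None:
                d_s += syn
                d_n += not syn
        return d_s, d_n
    arr = np.array(path_counts, dtype=float)
    return float(arr[:, 0].mean()), float(arr[:, 1].mean())


def count_polymorphism_divergence(
    alignment: CodonAlignment,
    folded: bool = False,
    min_ingroup: int = 4,
) -> GeneCounts:
    """Full per-gene counts: sites, polymorphism, divergence and SFS.

    ``min_ingroup`` guards against spectra too short for downstream DFE
    fitting; pass 2 to allow minimal pairwise comparisons.
    """
    n = alignment.n_ingroup
    if n < 2:
        raise ValueError(f"gene {alignment.gene_id}: need >= 2 ingroup sequences")
    if n < min_ingroup:
        raise ValueError(
            f"gene {alignment.gene_id}: {n} ingroup sequences < min_ingroup="
            f"{min_ingroup} (SFS too short for DFE fitting)"
        )
    n_bins = n // 2 if folded else n - 1
    sfs_s = np.zeros(n_bins)
    sfs_n = np.zeros(n_bins)
    L_n_tot = L_s_tot = 0.0
    D_s_tot = D_n_tot = 0.0
    codons_used = 0
    n_unpolarized = 0

    for j in range(alignment.length // 3):
        codons, out_codon = alignment.codon_column(j)
        if not _usable(codons, out_codon):
            continue
        cons = _consensus(codons)
        s_sites, n_sites = _syn_fraction(cons)
        L_s_tot += s_sites
        L_n_tot += n_sites
        codons_used += 1

        fixed_positions: list[int] = []
        for pos in range(3):
            bases = [c[pos] for c in codons]
            counter = Counter(bases)
            if len(counter) == 1:
                if bases[0] != out_codon[pos]:
                    fixed_positions.append(pos)
                continue
            # polymorphic site: classify each non-major allele on the
            # majority background; outgroup polarizes when it matches a
            # segregating allele (polymorphism-only: no divergence counted)
            major = cons[pos]
            for allele, count in counter.items():
                if allele == major:
                    continue
                codon_major = cons
                codon_minor = cons[:pos] + allele + cons[pos + 1 :]
                syn = _is_synonymous(codon_major, codon_minor)
                if syn is None:
                    continue
                out_base = out_codon[pos]
                if len(counter) == 2 and out_base in counter:
                    derived = count if out_base == major else n - count
                    bin_idx = (min(derived, n - derived) if folded else derived) - 1
                else:
                    n_unpolarized += 1
                    bin_idx = min(count, n - count) - 1
                if syn:
                    sfs_s[bin_idx] += 1
                else:
                    sfs_n[bin_idx] += 1

        if fixed_positions:
            target = list(cons)
            for pos in fixed_positions:
                target[pos] = out_codon[pos]
            d_s, d_n = _pathway_divergence(cons, "".join(target))
            D_s_tot += d_s
            D_n_tot += d_n

    counts = GeneCounts(
        gene_id=alignment.gene_id,
        n_alleles=n,
        L_n=L_n_tot,
        L_s=L_s_tot,
        D_n=D_n_tot,
        D_s=D_s_tot,
        sfs_s=sfs_s,
        sfs_n=sfs_n,
        codons_used=codons_used,
        folded=folded,
        usable=codons_used > 0,
        n_unpolarized=n_unpolarized,
    )
    return counts


def pairwise_diversity(alignment: CodonAlignment) -> tuple[float, float]:
    """(pi_n, pi_s): per-site pairwise diversity by compartment.

    Equals the average over all ingroup sequence pairs of per-site
    differences: each segregating site contributes its heterozygosity
    2 p (1-p) n/(n-1) (bi-allelic case), normalized by L of its class.
    """
    counts = count_polymorphism_divergence(alignment, min_ingroup=2)
    return counts.pi_n, counts.pi_s


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor multiple-hit correction of a per-site divergence."""
    if p >= 0.75:
        return np.inf
    return -0.75 * np.log1p(-4.0 * p / 3.0)
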