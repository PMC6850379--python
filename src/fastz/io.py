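"""Reading and writing the toolkit's file formats.

Per-gene FASTA alignments (ingroup haplotypes plus one record whose id is
suffixed ``_outgroup``) via Bio.SeqIO; everything tabular is
tab-separated with a single header row.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codon import CodonAlignment
from .counts import GeneCounts
from .simulate import SimGene, SimTruth

__all__ = [
    "write_alignment",
    "read_alignment",
    "write_alignments",
    "read_alignment_dir",
    "write_sim_tables",
    "read_tsv",
    "write_tsv",
    "sfs_frame",
]

OUTGROUP_SUFFIX = "_outgroup"


def write_alignment(aln: CodonAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=f"{aln.gene_id}_hap{i}", description="")
        for i, s in enumerate(aln.ingroup_seqs)
    ]
    records.append(
        SeqRecord(Seq(aln.outgroup_seq), id=f"{aln.gene_id}{OUTGROUP_SUFFIX}", description="")
    )
    SeqIO.write(records, str(path), "fasta")


def read_alignment(path: str | Path, gene_id: str | None = None) -> CodonAlignment:
    """One gene's FASTA: the ``*_outgroup`` record is split off as outgroup."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    ingroup, outgroup = [], []
    for rec in records:
        (outgroup if rec.id.endswith(OUTGROUP_SUFFIX) else ingroup).append(rec)
    if len(outgroup) != 1:
        raise ValueError(
            f"{path}: expected exactly one '{OUTGROUP_SUFFIX}' record, "
            f"found {len(outgroup)}"
        )
    if gene_id is None:
        gene_id = outgroup[0].id[: -len(OUTGROUP_SUFFIX)]
    return CodonAlignment(
        gene_id=gene_id,
        ingroup_seqs=[str(r.seq) for r in ingroup],
        outgroup_seq=str(outgroup[0].seq),
    )


def write_alignments(
    alignments: Mapping[str, CodonAlignment], out_dir: str | Path
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for gene_id, aln in alignments.items():
        write_alignment(aln, out_dir / f"{gene_id}.fasta")


def read_alignment_dir(aln_dir: str | Path) -> dict[str, CodonAlignment]:
    aln_dir = Path(aln_dir)
    paths = sorted(aln_dir.glob("*.fasta")) + sorted(aln_dir.glob("*.fa"))
    if not paths:
        raise FileNotFoundError(f"no FASTA files in {aln_dir}")
    return {p.stem: read_alignment(p) for p in paths}


def write_tsv(frame: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, index_col: int | str | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def sfs_frame(genes: Iterable[GeneCounts]) -> pd.DataFrame:
    """Gene x frequency-class matrix for both compartments (long header)."""
    rows = {}
    for g in genes:
        row = {f"s_{i+1}": v for i, v in enumerate(g.sfs_s)}
        row.update({f"n_{i+1}": v for i, v in enumerate(g.sfs_n)})
        rows[g.gene_id] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene_id"
    return out


def write_sim_tables(
    genes: Sequence[SimGene],
    truth: SimTruth,
    out_dir: str | Path,
    counts: pd.DataFrame | None = None,
    samples: pd.DataFrame | None = None,
) -> None:
    """genes.tsv, truth.tsv and (when given) counts.tsv / samples.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genes_df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom_class": [g.chrom_class for g in genes],
            "L_s": [g.L_s for g in genes],
            "L_n": [g.L_n for g in genes],
            "D_s": [g.D_s for g in genes],
            "D_n": [g.D_n for g in genes],
            "P_s": [int(np.sum(g.sfs_s)) for g in genes],
            "P_n": [int(np.sum(g.sfs_n)) for g in genes],
            "true_bias": [g.true_bias for g in genes],
            "base_expression": [g.base_expression for g in genes],
        }
    ).set_index("gene_id")
    write_tsv(genes_df, out_dir / "genes.tsv")
    truth_df = pd.DataFrame([vars(truth)])
    write_tsv(truth_df, out_dir / "truth.tsv", index=False)
    if counts is not None:
        write_tsv(counts, out_dir / "counts.tsv")
    if samples is not None:
        write_tsv(samples, out_dir / "samples.tsv")
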