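"""End-to-end orchestration: counts -> classification -> selection tables.

``run_pipeline`` executes the full chain (codon statistics or simulated
counts, expression classification, stratification by chromosome class and
sex-bias category, classic MK and DFE-model estimates, gene bootstrap,
diversity ratio and the diversity regression) and writes the master
report: one row per statistic {pi_n/pi_s, dN/dS, alpha classic, alpha
model, omega_a, omega_na, #genes} x columns {All, female, male, unbiased}
x {autosome, Z}, each cell with a 95% gene-bootstrap interval, plus a
synonymous-diversity report and a structured run log.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import diversity_ratio, pin_regression
from .codon import count_polymorphism_divergence
from .counts import GeneCounts, counts_to_frame, pool_counts
from .dfe import fit_dfe
from .expression import annotate_genes, enrichment_test
from .io import read_alignment_dir, read_tsv, sfs_frame, write_sim_tables, write_tsv
from .mk import classic_alpha
from .resample import bootstrap_stat
from .simulate import SimTruth, genes_to_counts, simulate_counts, simulate_expression

__all__ = ["RunConfig", "run_pipeline", "stratum_table"]

STAT_ROWS = ["pi_n/pi_s", "dN/dS", "alpha_classic", "alpha_model", "omega_a", "omega_na"]
BIAS_COLUMNS = ["All", "female", "male", "unbiased"]
CHROM_CLASSES = ["autosome", "Z"]


@dataclass
class RunConfig:
    mode: str = "simulate"  # "simulate" | "real"
    out_dir: str = "fastz_run"
    seed: int = 0
    n_bootstrap: int = 1000
    folded: bool = False
    # simulate mode
    truth: SimTruth | None = None
    bias_fold: float = 4.0
    n_samples_per_sex: int = 5
    # real mode inputs
    alignments_dir: str | None = None
    genes_tsv: str | None = None
    counts_tsv: str | None = None
    samples_tsv: str | None = None
    de_results_tsv: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        truth_kwargs = raw.pop("truth", None)
        cfg = cls(**raw)
        if truth_kwargs:
            cfg.truth = SimTruth(**truth_kwargs)
        return cfg

    def validate(self) -> None:
        if self.mode not in ("simulate", "real"):
            raise ValueError(f"unknown mode '{self.mode}'")
        if self.mode == "real":
            for name in ("alignments_dir", "genes_tsv", "counts_tsv", "samples_tsv"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"real mode requires {name}")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p} does not exist")


def _all_stats(pooled: GeneCounts, warm: tuple[float, float] | None) -> dict[str, float]:
    """Every reported statistic of one pooled gene set (one DFE fit)."""
    out = {
        "pi_n/pi_s": pooled.pi_n / pooled.pi_s if pooled.pi_s > 0 else np.nan,
        "dN/dS": pooled.dN / pooled.dS if pooled.D_s > 0 else np.nan,
        "alpha_classic": classic_alpha(pooled).alpha,
    }
    try:
        fit = fit_dfe(pooled, start=warm, n_starts=3)
        out["alpha_model"] = fit.alpha
        out["omega_a"] = fit.omega_a
        out["omega_na"] = fit.omega_na
    except (ValueError, RuntimeError):
        out["alpha_model"] = out["omega_a"] = out["omega_na"] = np.nan
    return out


def _bootstrap_all_stats(
    members: Sequence[GeneCounts],
    warm: tuple[float, float] | None,
    n_replicates: int,
    seed: int,
) -> dict[str, dict]:
    """Joint gene bootstrap of all stratum statistics (one DFE refit per
    replicate, warm-started at the point estimate)."""
    rng = np.random.default_rng(seed)
    draws: dict[str, list[float]] = {s: [] for s in STAT_ROWS}
    for _ in range(n_replicates):
        idx = rng.integers(0, len(members), len(members))
        rep = _all_stats(pool_counts([members[i] for i in idx]), warm)
        for s, v in rep.items():
            if np.isfinite(v):
                draws[s].append(v)
    out = {}
    for s, values in draws.items():
        if values:
            lo, hi = np.percentile(values, [2.5, 97.5])
        else:
            lo = hi = np.nan
        out[s] = {"lower": float(lo), "upper": float(hi), "n_valid": len(values)}
    return out


def stratum_table(
    genes: Sequence[GeneCounts],
    annot: pd.DataFrame,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Master (Table-1-shaped) and synonymous-diversity (Table-2-shaped) reports.

    Empty strata produce empty cells, not dropped rows.
    """
    by_id = {g.gene_id: g for g in genes}
    rows = []
    pi_s_rows = []
    for chrom in CHROM_CLASSES:
        for bias in BIAS_COLUMNS:
            ids = annot.index[
                (annot["chrom_class"] == chrom)
                & ((annot["bias"] == bias) if bias != "All" else True)
            ]
            members = [by_id[i] for i in ids if i in by_id]
            # stable across processes (str hash() is salted)
            cell_seed = zlib.crc32(f"{chrom}|{bias}|{seed}".encode()) % (2**31)
            if not members:
                for stat in STAT_ROWS:
                    rows.append(
                        dict(statistic=stat, chrom_class=chrom, bias=bias,
                             estimate=np.nan, lower=np.nan, upper=np.nan, n_valid=0)
                    )
                rows.append(
                    dict(statistic="#genes", chrom_class=chrom, bias=bias,
                         estimate=0, lower=np.nan, upper=np.nan, n_valid=0)
                )
                pi_s_rows.append(
                    dict(statistic="pi_s", chrom_class=chrom, bias=bias,
                         estimate=np.nan, lower=np.nan, upper=np.nan)
                )
                continue
            pooled = pool_counts(members, gene_id=f"{chrom}|{bias}")
            point_fit = fit_dfe(pooled, label=pooled.gene_id)
            warm = (point_fit.shape, point_fit.mean_S)
            points = _all_stats(pooled, warm)
            cis = _bootstrap_all_stats(members, warm, n_bootstrap, cell_seed)
            for stat in STAT_ROWS:
                rows.append(
                    dict(statistic=stat, chrom_class=chrom, bias=bias,
                         estimate=points[stat], lower=cis[stat]["lower"],
                         upper=cis[stat]["upper"], n_valid=cis[stat]["n_valid"])
                )
            rows.append(
                dict(statistic="#genes", chrom_class=chrom, bias=bias,
                     estimate=len(members), lower=np.nan, upper=np.nan,
                     n_valid=n_bootstrap)
            )
            pi_ci = bootstrap_stat(
                members, lambda g: g.pi_s, n_replicates=n_bootstrap,
                seed=cell_seed + 1, statistic="pi_s",
            )
            pi_s_rows.append(
                dict(statistic="pi_s", chrom_class=chrom, bias=bias,
                     estimate=pi_ci.point, lower=pi_ci.lower, upper=pi_ci.upper)
            )
    return pd.DataFrame(rows), pd.DataFrame(pi_s_rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write all result tables under out_dir."""
    t0 = time.time()
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "fastz_version": __version__,
        "mode": config.mode,
        "seed": config.seed,
        "n_bootstrap": config.n_bootstrap,
        "stages": [],
    }

    if config.mode == "simulate":
        truth = config.truth or SimTruth(seed=config.seed)
        gene_records = simulate_counts(truth)
        genes = genes_to_counts(gene_records, folded=config.folded)
        expr_counts, samples = simulate_expression(
            gene_records, truth,
            n_samples_per_sex=config.n_samples_per_sex,
            bias_fold=config.bias_fold,
        )
        lengths = pd.Series(
            {g.gene_id: g.L_s + g.L_n for g in gene_records}, name="length"
        )
        chrom = pd.Series(
            {g.gene_id: g.chrom_class for g in gene_records}, name="chrom_class"
        )
        de_table = None
        write_sim_tables(gene_records, truth, out_dir, expr_counts, samples)
        log["stages"].append("simulate")
    else:
        alignments = read_alignment_dir(config.alignments_dir)
        genes = [
            count_polymorphism_divergence(a, folded=config.folded)
            for a in alignments.values()
        ]
        genes_meta = read_tsv(config.genes_tsv)
        chrom = genes_meta["chrom_class"]
        expr_counts = read_tsv(config.counts_tsv)
        samples = read_tsv(config.samples_tsv)
        lengths = genes_meta["L_s"] + genes_meta["L_n"] if "L_s" in genes_meta else (
            genes_meta["length"]
        )
        de_table = (
            read_tsv(config.de_results_tsv) if config.de_results_tsv else None
        )
        log["stages"].append("codon_stats")

    write_tsv(counts_to_frame(genes).set_index("gene_id"), out_dir / "gene_counts.tsv")
    write_tsv(sfs_frame(genes), out_dir / "sfs.tsv")

    annot = annotate_genes(expr_counts, lengths, samples, chrom, de_table)
    write_tsv(annot, out_dir / "annot.tsv")
    log["stages"].append("expression")
    log["n_unexpressed"] = int(annot["unexpressed"].sum())

    master, pi_s_report = stratum_table(
        genes, annot, n_bootstrap=config.n_bootstrap, seed=config.seed
    )
    write_tsv(master, out_dir / "master_table.tsv", index=False)
    write_tsv(pi_s_report, out_dir / "pi_s_table.tsv", index=False)
    log["stages"].append("strata")

    ratio = diversity_ratio(genes, chrom.to_dict())
    log["pi_sZ_over_pi_sA"] = float(ratio)

    counts_frame = counts_to_frame(genes).set_index("gene_id")
    reg_table = counts_frame[["pi_n", "pi_s"]].join(
        annot[["chrom_class", "mean_rpkm"]]
    )
    try:
        reg = pin_regression(reg_table)
        coef = pd.DataFrame(
            {"coef": reg.params, "se": reg.bse, "p": reg.pvalues}
        )
        write_tsv(coef, out_dir / "regression.tsv")
        write_tsv(reg.diagnostics, out_dir / "diagnostics.tsv")
        log["regression_n_used"] = reg.n_genes_used
        log["regression_n_dropped_zero"] = reg.n_genes_dropped_zero
        log["stages"].append("regression")
    except ValueError as err:
        log["regression_error"] = str(err)

    if de_table is not None or (
        config.mode == "real" and config.de_results_tsv
    ):
        tb = annot["tissue_bias"]
        table = np.array(
            [
                [int(((annot["chrom_class"] == "Z") & (tb == t)).sum()) for t in ("gut", "ovary")],
                [int(((annot["chrom_class"] == "autosome") & (tb == t)).sum()) for t in ("gut", "ovary")],
            ]
        )
        if (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
            chi2, p = enrichment_test(table)
            log["tissue_enrichment"] = {"chi2": chi2, "p": p, "table": table.tolist()}

    log["runtime_s"] = round(time.time() - t0, 2)
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return log
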