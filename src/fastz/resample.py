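"""Gene-level bootstrap confidence intervals.

Genes are resampled with replacement to the original count, the pooled
statistic is recomputed on each replicate, and the 2.5th/97.5th
percentiles form the interval (percentile bootstrap, 1000 replicates by
default).  Replicates where the statistic is undefined (e.g. a pooled MK
alpha with no synonymous polymorphism) are dropped and counted.
Significance between strata follows the interval-overlap rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .counts import GeneCounts, pool_counts

__all__ = ["BootstrapCI", "bootstrap_stat", "compare_strata"]


@dataclass
class BootstrapCI:
    statistic: str
    point: float
    lower: float
    upper: float
    n_replicates: int
    n_valid: int
    seed: int | None = None

    @property
    def contains_point(self) -> bool:
        return self.lower <= self.point <= self.upper


def bootstrap_stat(
    genes: Sequence[GeneCounts],
    stat_fn: Callable[[GeneCounts], float],
    n_replicates: int = 1000,
    seed: int | None = None,
    statistic: str = "stat",
) -> BootstrapCI:
    """95% percentile CI of ``stat_fn`` applied to pooled resampled genes."""
    genes = list(genes)
    if not genes:
        raise ValueError("need at least one gene to bootstrap")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    point = float(stat_fn(pool_counts(genes)))
    values = []
    for _ in range(n_replicates):
        idx = rng.integers(0, len(genes), len(genes))
        v = float(stat_fn(pool_counts([genes[i] for i in idx])))
        if np.isfinite(v):
            values.append(v)
    if not values:
        raise ValueError(f"statistic '{statistic}' undefined in every replicate")
    lower, upper = np.percentile(values, [2.5, 97.5])
    return BootstrapCI(
        statistic=statistic,
        point=point,
        lower=float(lower),
        upper=float(upper),
        n_replicates=n_replicates,
        n_valid=len(values),
        seed=seed,
    )


def compare_strata(ci_a: BootstrapCI, ci_b: BootstrapCI) -> dict:
    """Interval-overlap verdict for the same statistic in two strata."""
    if ci_a.statistic != ci_b.statistic:
        raise ValueError(
            f"mismatched statistics: '{ci_a.statistic}' vs '{ci_b.statistic}'"
        )
    overlap = ci_a.lower <= ci_b.upper and ci_b.lower <= ci_a.upper
    return {
        "statistic": ci_a.statistic,
        "overlap": overlap,
        "significant": not overlap,
        "difference": ci_b.point - ci_a.point,
    }
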