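"""Classic McDonald-Kreitman estimate of the adaptive proportion.

alpha = 1 - (dS * p_n) / (dN * p_s): the proportion of nonsynonymous
substitutions driven by positive selection, assuming nonsynonymous
mutations are adaptive, neutral, or strongly deleterious.  Both ratios
compare like with like: dN, dS are per-site divergences and p_n, p_s are
per-site polymorphism levels (P_n/L_n, P_s/L_s), so the site totals
cancel and the formula reduces to the raw-count form
1 - (D_s * P_n)/(D_n * P_s).  alpha = 0 is the neutral null
(dN/dS = p_n/p_s); alpha < 0 indicates segregating weakly deleterious
variants; alpha is bounded above by 1 (equality only when P_n = 0).
Best computed on pooled strata: single genes are noisy and frequently
undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .counts import GeneCounts

__all__ = ["MKResult", "classic_alpha"]


@dataclass
class MKResult:
    label: str
    alpha: float  # NaN when undefined
    P_n: float
    P_s: float
    D_n: float
    D_s: float
    dN: float
    dS: float
    reason: str = ""  # why alpha is undefined, when it is

    @property
    def defined(self) -> bool:
        return np.isfinite(self.alpha)


def classic_alpha(counts: GeneCounts, label: str | None = None) -> MKResult:
    """alpha = 1 - (dS * p_n)/(dN * p_s) from (pooled) gene counts.

    p_n, p_s are per-site polymorphism levels P_n/L_n and P_s/L_s, so the
    estimate equals the raw-count form 1 - (D_s*P_n)/(D_n*P_s).  Undefined
    (NaN, with a reason) when P_s = 0 or dN = 0 — expected for single
    low-polymorphism genes; pool before calling.
    """
    P_n, P_s = counts.P_n, counts.P_s
    dN, dS = counts.dN, counts.dS
    reason = ""
    if P_s == 0:
        alpha, reason = np.nan, "P_s = 0 (no synonymous polymorphism)"
    elif not np.isfinite(dN) or dN == 0:
        alpha, reason = np.nan, "dN = 0 (no nonsynonymous divergence)"
    else:
        p_n = P_n / counts.L_n
        p_s = P_s / counts.L_s
        alpha = 1.0 - (dS * p_n) / (dN * p_s)
    return MKResult(
        label=label or counts.gene_id,
        alpha=float(alpha),
        P_n=P_n,
        P_s=P_s,
        D_n=counts.D_n,
        D_s=counts.D_s,
        dN=dN,
        dS=dS,
        reason=reason,
    )
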