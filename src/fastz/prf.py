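"""Poisson random field machinery for selected and neutral polymorphism.

The stationary density of derived-allele frequency x for a mutation with
population-scaled selection coefficient S (= 4*Ne*s, negative for
deleterious) is

    f(x; S) = [theta / (x (1 - x))] * (1 - exp(-S (1 - x))) / (1 - exp(-S)),

which reduces to theta / x as S -> 0.  Binomial sampling of n alleles gives
the expected number of sites with derived count i,

    H(S, i, n) = integral_0^1 f-kernel(x; S) * C(n, i) x^i (1-x)^(n-i) dx,

with the neutral limit H(0, i, n) = 1/i.  The relative fixation rate of a
mutation with effect S is S / (1 - exp(-S)).

Deleterious effects are modelled as a gamma distribution over t = -S with
shape ``shape`` and mean ``-mean_S``.  Expectations over the DFE use
generalized Gauss-Laguerre quadrature in t (exact weight for the gamma
density) and split Gauss-Legendre quadrature in x (the kernel concentrates
near x = 0 for strong selection, so the x grid is split at ~20/t).
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammainc, gammaln, roots_legendre

__all__ = [
    "selection_kernel_ratio",
    "fixation_rate",
    "sfs_single_S",
    "neutral_sfs_shape",
    "gamma_dfe_sfs",
    "gamma_dfe_omega_na",
]

# x integral: split Gauss-Legendre, 32 nodes per half.  S integral:
# composite 16-point Gauss-Legendre panels of width 2 in log t plus an
# analytic mass term below t = 1e-8 (where every integrand is neutral);
# the log grid resolves the near-neutral power-law tail of the gamma that
# a Laguerre-type rule misses when |mean S| is large.
_N_X_NODES = 32  # per half of the split x grid
_T_FLOOR = 1e-8
_PANEL_WIDTH = 2.0
_PANEL_NODES, _PANEL_WEIGHTS = roots_legendre(16)

_LEG_NODES, _LEG_WEIGHTS = roots_legendre(_N_X_NODES)


def selection_kernel_ratio(t: np.ndarray, one_minus_x: np.ndarray) -> np.ndarray:
    """(1 - e^{-S(1-x)}) / (1 - e^{-S}) for S = -t, t >= 0, overflow-safe.

    For S = -t the ratio is expm1(t(1-x))/expm1(t); rewritten with
    negative exponents only so arbitrarily large t is safe.
    """
    t = np.asarray(t, dtype=float)
    omx = np.asarray(one_minus_x, dtype=float)
    small = t < 1e-8
    t_safe = np.where(small, 1.0, t)
    with np.errstate(over="ignore"):
        ratio = (
            np.exp(-t_safe * (1.0 - omx))
            * (-np.expm1(-t_safe * omx))
            / (-np.expm1(-t_safe))
        )
    # S -> 0 limit: ratio -> 1 - x
    return np.where(small, omx, ratio)


def fixation_rate(S: np.ndarray) -> np.ndarray:
    """Relative fixation rate S / (1 - e^{-S}), stable for any sign of S."""
    S = np.asarray(S, dtype=float)
    out = np.empty_like(S)
    small = np.abs(S) < 1e-8
    out[small] = 1.0 + S[small] / 2.0
    Sp = S[~small]
    with np.errstate(over="ignore", under="ignore"):
        # S/(1-e^{-S}) = S e^{-max(S,0)} / (e^{-max(S,0)} - e^{-S-max(S,0)})
        m = np.maximum(Sp, 0.0)
        out[~small] = Sp * np.exp(-m) / (np.exp(-m) - np.exp(-Sp - m))
    return out


def _x_nodes_for_t(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split Gauss-Legendre grid on (0,1), breakpoint ~20/t per DFE node.

    Returns (x, w) of shape (len(t), 2*_N_X_NODES).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    brk = np.clip(20.0 / np.maximum(t, 1.0), 1e-12, 0.5)
    u = 0.5 * (_LEG_NODES + 1.0)  # nodes on (0,1)
    w = 0.5 * _LEG_WEIGHTS
    lo_x = brk[:, None] * u[None, :]
    lo_w = brk[:, None] * w[None, :]
    hi_x = brk[:, None] + (1.0 - brk[:, None]) * u[None, :]
    hi_w = (1.0 - brk[:, None]) * w[None, :]
    return np.concatenate([lo_x, hi_x], axis=1), np.concatenate([lo_w, hi_w], axis=1)


def _binom_pmf_matrix(x: np.ndarray, n: int) -> np.ndarray:
    """C(n,i) x^i (1-x)^(n-i) / (x(1-x)) for i = 1..n-1; shape (n-1, *x.shape).

    The 1/(x(1-x)) factor of the frequency kernel is folded in here, so the
    exponents are i-1 and n-i-1 (both >= 0: no singularity).
    """
    i = np.arange(1, n)
    logc = gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)
    with np.errstate(divide="ignore"):
        logx = np.log(x)
        log1mx = np.log1p(-x)
    out = np.exp(
        logc.reshape((-1,) + (1,) * x.ndim)
        + (i - 1).reshape((-1,) + (1,) * x.ndim) * logx[None]
        + (n - i - 1).reshape((-1,) + (1,) * x.ndim) * log1mx[None]
    )
    return np.nan_to_num(out, nan=0.0, posinf=0.0)


def sfs_single_S(S: float, n: int) -> np.ndarray:
    """Expected SFS shape H(S, i, n) for i = 1..n-1 at a single S (theta = 1)."""
    t = -float(S)
    if t < 0:
        raise ValueError("sfs_single_S expects S <= 0 (deleterious or neutral)")
    if t < 1e-10:
        return neutral_sfs_shape(n)
    x, w = _x_nodes_for_t(np.array([t]))
    kernel = selection_kernel_ratio(np.array([t])[:, None], 1.0 - x)
    pmf = _binom_pmf_matrix(x, n)  # (n-1, 1, nx)
    return np.einsum("jk,ijk->i", kernel * w, pmf)


def neutral_sfs_shape(n: int) -> np.ndarray:
    """H(0, i, n) = 1/i for i = 1..n-1."""
    return 1.0 / np.arange(1, n)


def _gamma_nodes(shape: float, mean_t: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Quadrature for E_gamma[f(t)], t ~ Gamma(shape, scale=mean_t/shape).

    Returns (t nodes, weights incl. the gamma density, mass below 1e-8).
    Composite Gauss-Legendre in y = log t from 1e-8 up to 60x the gamma
    scale (the density beyond is negligible); f is treated as its t -> 0
    limit on the analytic mass term.
    """
    scale = mean_t / shape
    y_lo = np.log(_T_FLOOR)
    y_hi = np.log(scale) + np.log(60.0)
    if y_hi <= y_lo:  # pathologically small mean: everything is neutral
        return np.array([]), np.array([]), 1.0
    n_panels = int(np.ceil((y_hi - y_lo) / _PANEL_WIDTH))
    edges = np.linspace(y_lo, y_hi, n_panels + 1)
    half = 0.5 * (edges[1:] - edges[:-1])
    mid = 0.5 * (edges[1:] + edges[:-1])
    y = (mid[:, None] + half[:, None] * _PANEL_NODES[None, :]).ravel()
    wy = (half[:, None] * _PANEL_WEIGHTS[None, :]).ravel()
    t = np.exp(y)
    # gamma pdf times Jacobian dt = t dy
    log_pdf_t = (shape - 1.0) * y - t / scale - gammaln(shape) - shape * np.log(scale)
    w = np.exp(log_pdf_t + y) * wy
    mass0 = float(gammainc(shape, _T_FLOOR / scale))
    return t, w, mass0


def gamma_dfe_sfs(shape: float, mean_S: float, n: int) -> np.ndarray:
    """E over the gamma DFE of H(S, i, n), i = 1..n-1 (theta = 1).

    ``mean_S`` <= 0 is the mean population-scaled effect; mean_S = 0 is the
    neutral point mass.
    """
    if shape <= 0:
        raise ValueError("gamma shape must be > 0")
    if mean_S > 0:
        raise ValueError("mean_S must be <= 0")
    mean_t = -float(mean_S)
    if mean_t < 1e-12:
        return neutral_sfs_shape(n)
    t, wt, mass0 = _gamma_nodes(shape, mean_t)
    neutral = neutral_sfs_shape(n)
    if t.size == 0:
        return neutral
    x, wx = _x_nodes_for_t(t)
    kernel = selection_kernel_ratio(t[:, None], 1.0 - x)
    pmf = _binom_pmf_matrix(x, n)  # (n-1, nt, nx)
    h_per_t = np.einsum("jk,ijk->ij", kernel * wx, pmf)  # (n-1, nt)
    return h_per_t @ wt + mass0 * neutral


def gamma_dfe_omega_na(shape: float, mean_S: float) -> float:
    """E over the gamma DFE of the relative fixation rate S/(1-e^{-S}).

    This is the expected dN/dS contributed by nonadaptive (deleterious or
    neutral) mutations under the fitted DFE.
    """
    if shape <= 0:
        raise ValueError("gamma shape must be > 0")
    if mean_S > 0:
        raise ValueError("mean_S must be <= 0")
    mean_t = -float(mean_S)
    if mean_t < 1e-12:
        return 1.0
    t, wt, mass0 = _gamma_nodes(shape, mean_t)
    if t.size == 0:
        return 1.0
    return float(fixation_rate(-t) @ wt) + mass0
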