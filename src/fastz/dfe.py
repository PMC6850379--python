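"""Gamma-DFE fitting to site frequency spectra (the "modelling" MK test).

The synonymous SFS is neutral; the nonsynonymous SFS is shaped by a gamma
distribution of deleterious population-scaled effects S.  Counts in every
frequency class of both compartments are independent Poisson variables:

    E[s_i] = theta * L_s * r_i * (1/i)
    E[n_i] = theta * L_n * r_i * E_phi[H(S, i, n)]

with a shared per-class nuisance factor r_i (r_1 = 1) absorbing demography
and ascertainment.  Because theta*r_i enters both compartments linearly,
its per-bin MLE is available in closed form given the DFE parameters, so
the likelihood is profiled down to two parameters (gamma shape, mean S)
and maximized by bounded quasi-Newton from several dispersed starts.

From the fitted DFE the expected dN/dS under near-neutrality is
E_phi[S/(1-e^{-S})]; the excess of observed over expected dN/dS gives the
adaptive proportion alpha = 1 - expected/observed, the per-mutation
adaptive rate omega_a = alpha * dN/dS and the nonadaptive rate
omega_na = (1 - alpha) * dN/dS (so omega_a + omega_na = dN/dS exactly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .counts import GeneCounts
from .prf import gamma_dfe_omega_na, gamma_dfe_sfs, neutral_sfs_shape

__all__ = ["SFSPair", "DFEFit", "expected_sfs", "fit_dfe"]

# an SFSPair is a (pooled) GeneCounts record: both spectra, site totals,
# divergence counts, n_alleles and the folded flag
SFSPair = GeneCounts

_LOG_SHAPE_BOUNDS = (np.log(0.01), np.log(20.0))
_LOG_MEANT_BOUNDS = (np.log(1e-4), np.log(1e7))
_STARTS = [(0.4, 1e3), (0.2, 10.0), (1.0, 100.0), (0.15, 1e5), (2.0, 1.0)]


@dataclass
class DFEFit:
    shape: float
    mean_S: float
    theta_hat: float
    r: np.ndarray  # per-frequency-class nuisance factors, r[0] == 1
    loglik: float
    expected_dnds_neutral: float
    alpha: float
    omega_a: float
    omega_na: float
    dnds_obs: float
    converged: bool
    at_bound: bool
    n_starts_converged: int = 0
    label: str = ""
    ci: dict = field(default_factory=dict)


def _fold_vector(v: np.ndarray, n: int) -> np.ndarray:
    """Collapse unfolded bins i and n-i into minor-allele bins."""
    nf = n // 2
    out = np.zeros(nf)
    for i in range(1, n):
        out[min(i, n - i) - 1] += v[i - 1]
    return out


def _bin_shapes(
    shape: float, mean_S: float, n: int, folded: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin neutral (1/i) and DFE-averaged SFS shapes, folded on request."""
    h = neutral_sfs_shape(n)
    g = gamma_dfe_sfs(shape, mean_S, n)
    if folded:
        return _fold_vector(h, n), _fold_vector(g, n)
    return h, g


def expected_sfs(
    shape: float,
    mean_S: float,
    theta: float,
    L: float,
    r: np.ndarray,
    n_alleles: int,
    folded: bool = False,
) -> np.ndarray:
    """Expected SFS counts theta * L * r_i * E_phi[H(S, i, n)] per bin.

    ``mean_S = 0`` gives the neutral spectrum theta*L*r_i/i (unfolded).
    """
    _, g = _bin_shapes(shape, mean_S, n_alleles, folded)
    r = np.asarray(r, dtype=float)
    if r.shape != g.shape:
        raise ValueError(f"r has length {r.shape[0]}, expected {g.shape[0]}")
    return theta * L * r * g


def _profile_loglik(
    shape: float,
    mean_t: float,
    data: GeneCounts,
) -> tuple[float, np.ndarray]:
    """Log-likelihood with per-bin scales lambda_i profiled out.

    Returns (loglik, lambda_hat).  lambda_i = theta * r_i maximizes the
    two-compartment Poisson likelihood at (s_i + n_i)/(L_s h_i + L_n g_i).
    """
    h, g = _bin_shapes(shape, -mean_t, data.n_alleles, data.folded)
    a = data.L_s * h
    b = data.L_n * g
    s = data.sfs_s
    nn = data.sfs_n
    denom = a + b
    lam = (s + nn) / denom
    with np.errstate(divide="ignore", invalid="ignore"):
        term_s = np.where(s > 0, s * np.log(lam * a), 0.0)
        term_n = np.where(nn > 0, nn * np.log(lam * b), 0.0)
    ll = float(np.sum(term_s + term_n - lam * denom))
    if not np.isfinite(ll):
        ll = -np.inf
    return ll, lam


def fit_dfe(
    data: SFSPair,
    n_starts: int = 5,
    start: tuple[float, float] | None = None,
    label: str | None = None,
    tol: float = 1e-8,
) -> DFEFit:
    """Maximum-likelihood gamma DFE fit plus alpha / omega_a / omega_na.

    ``start`` (shape, mean_S) warm-starts a single optimization — used by
    bootstrap replicates; otherwise ``n_starts`` dispersed starts are run
    and the best optimum kept.
    """
    if data.sfs_s.sum() <= 0:
        raise ValueError("empty synonymous SFS: theta is unidentifiable")
    if data.n_alleles < 4:
        raise ValueError("need n_alleles >= 4")

    def objective(p: np.ndarray) -> float:
        ll, _ = _profile_loglik(np.exp(p[0]), np.exp(p[1]), data)
        return -ll

    if start is not None:
        starts = [(start[0], max(-start[1], 1e-4))]
    else:
        starts = _STARTS[: max(n_starts, 1)]
    bounds = [_LOG_SHAPE_BOUNDS, _LOG_MEANT_BOUNDS]
    best = None
    n_ok = 0
    for s0, t0 in starts:
        p0 = np.array([np.log(s0), np.log(t0)])
        res = minimize(
            objective, p0, method="L-BFGS-B", bounds=bounds, options={"ftol": tol}
        )
        n_ok += bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or (n_ok == 0 and not np.isfinite(best.fun)):
        raise RuntimeError("DFE optimization failed from every start")

    shape = float(np.exp(best.x[0]))
    mean_t = float(np.exp(best.x[1]))
    mean_S = -mean_t
    ll, lam = _profile_loglik(shape, mean_t, data)
    theta_hat = float(lam[0])
    r = lam / theta_hat if theta_hat > 0 else np.full_like(lam, np.nan)

    at_bound = bool(
        np.isclose(best.x[0], _LOG_SHAPE_BOUNDS, atol=1e-6).any()
        or np.isclose(best.x[1], _LOG_MEANT_BOUNDS, atol=1e-6).any()
    )

    expected_neutral = gamma_dfe_omega_na(shape, mean_S)
    dnds_obs = data.dN / data.dS if (data.D_s > 0 and data.L_s > 0) else np.nan
    if np.isfinite(dnds_obs) and dnds_obs > 0:
        alpha = 1.0 - expected_neutral / dnds_obs
        omega_a = alpha * dnds_obs
        omega_na = dnds_obs - omega_a
    else:
        alpha = omega_a = omega_na = np.nan

    return DFEFit(
        shape=shape,
        mean_S=mean_S,
        theta_hat=theta_hat,
        r=r,
        loglik=ll,
        expected_dnds_neutral=expected_neutral,
        alpha=float(alpha),
        omega_a=float(omega_a),
        omega_na=float(omega_na),
        dnds_obs=float(dnds_obs),
        converged=bool(best.success),
        at_bound=at_bound,
        n_starts_converged=n_ok,
        label=label or data.gene_id,
    )
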