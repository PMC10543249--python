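"""SNP-set association tests on per-gene GWAS summary Z-scores.

Given a gene's harmonized Z-vector z (length m) with LD correlation
matrix R, and assuming z ~ MVN(0, R) under the null:

* Sum test (burden-type):        B = sum_j z_j,     B^2/(1'R1) ~ chi2(1)
* Squared-sum test (SKAT-type):  Q = sum_j z_j^2 ~ sum_k lambda_k chi2_k(1),
  with lambda the eigenvalues of R
* Adaptive test: T = min over rho in [0,1] of the p-value of
  Q_rho = (1-rho) Q + rho B^2, whose null is the weighted chi-square with
  weights eig(A_rho^{1/2} R A_rho^{1/2}), A_rho = (1-rho) I + rho J.
  The min-p null probability p_AT = P(min_rho p_rho <= T) is evaluated by
  one-dimensional numerical integration conditioning on the standardized
  burden component u = 1'z / sqrt(1'R1), with the residual quadratic form
  moment-matched — the same decomposition used by optimal unified
  kernel-association tests — and cross-checked by a Monte-Carlo
  estimator in the Q_rho domain.

Weighted-chi-square survival probabilities are computed by numerical
inversion of the characteristic function (Imhof-type integration) with a
moment-matching fallback (Liu-type noncentral-chi-square approximation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy import integrate
from scipy.stats import chi2, ncx2, norm

from .ld_panel import GeneSnpSet

__all__ = [
    "DEFAULT_RHO_GRID",
    "QuadFormNull",
    "GeneTestResult",
    "GeneScanResult",
    "quadform_sf",
    "sum_test",
    "squared_sum_test",
    "adaptive_test",
    "gene_scan",
]

#: rho grid for the adaptive test: squares of an even grid on [0, 1],
#: denser near 0 where the optimum usually lies for SKAT-type signals.
DEFAULT_RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.36, 0.49, 0.64, 0.81, 1.0)

_P_FLOOR = 1e-300  # p-values are reported in (0, 1]; never exactly 0
_LIU_SWITCH_P = 1e-12  # below this, CF inversion accuracy is exhausted


class NumericalError(ArithmeticError):
    pass


def _clean_weights(weights: Sequence[float], neg_tol: float = 1e-8) -> np.ndarray:
    """Validate, clip at zero and drop numerically-null eigenvalues."""
    lam = np.asarray(weights, dtype=float).ravel()
    if lam.size == 0:
        raise ValueError("empty weight vector")
    scale = max(lam.max(), 1.0)
    if lam.min() < -neg_tol * scale:
        raise ValueError(f"negative weight beyond tolerance: {lam.min()}")
    lam = np.clip(lam, 0.0, None)
    lam = lam[lam > 1e-12 * scale]
    return np.sort(lam)[::-1]


# ---------------------------------------------------------------------------
# Liu-type moment matching: match skewness/kurtosis of sum(lam*chi2_1) to a
# scaled noncentral chi-square.
# ---------------------------------------------------------------------------


def _liu_params(lam: np.ndarray) -> tuple[float, float, float, float, float, float]:
    c1 = lam.sum()
    c2 = (lam**2).sum()
    c3 = (lam**3).sum()
    c4 = (lam**4).sum()
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
    mu_x = df + delta
    sigma_x = np.sqrt(2 * (df + 2 * delta))
    return c1, np.sqrt(2 * c2), df, delta, mu_x, sigma_x


def _liu_sf(q: float, lam: np.ndarray) -> float:
    c1, sigma_q, df, delta, mu_x, sigma_x = _liu_params(lam)
    x = (q - c1) / sigma_q * sigma_x + mu_x
    return float(ncx2.sf(max(x, 0.0), df, delta))


def _liu_quantile(p: float, lam: np.ndarray) -> float:
    """q with sf(q) = p under the moment-matched approximation."""
    c1, sigma_q, df, delta, mu_x, sigma_x = _liu_params(lam)
    x = ncx2.isf(min(max(p, _P_FLOOR), 1.0), df, delta)
    return float((x - mu_x) / sigma_x * sigma_q + c1)


# ---------------------------------------------------------------------------
# Imhof-type characteristic-function inversion.
#
#   P(Q > q) = 1/2 + (1/pi) * int_0^inf sin(theta(t)) / (t * rho(t)) dt
#   theta(t) = 0.5 * sum_k arctan(lam_k t) - 0.5 q t
#   rho(t)   = prod_k (1 + lam_k^2 t^2)^(1/4)
#
# The integral is split at U0: an adaptive quadrature on [0, U0], then the
# oscillatory tail via QUADPACK's Fourier-weighted integration with the
# asymptotic frequency q/2 (for large t, theta(t) -> m*pi/4 - q*t/2).
# ---------------------------------------------------------------------------


def _imhof_sf(q: float, lam: np.ndarray, acc: float = 1e-9) -> tuple[float, bool]:
    """Return (sf, converged). lam cleaned and positive; q > 0."""
    lmax = lam[0]
    lam = lam / lmax
    q = q / lmax
    w = q / 2.0

    def theta0(t: float) -> float:
        return 0.5 * np.arctan(lam * t).sum()

    def inv_trho(t: float) -> float:
        return np.exp(-0.25 * np.log1p((lam * t) ** 2).sum()) / t

    def f_main(t: float) -> float:
        return np.sin(theta0(t) - w * t) * inv_trho(t)

    def g_sin(t: float) -> float:
        return np.sin(theta0(t)) * inv_trho(t)

    def g_cos(t: float) -> float:
        return np.cos(theta0(t)) * inv_trho(t)

    U0 = 3.0
    ok = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", integrate.IntegrationWarning)
        try:
            i0, e0 = integrate.quad(f_main, 0.0, U0, epsabs=acc / 3, epsrel=1e-10, limit=400)
            # sin(theta0 - wt) = sin(theta0) cos(wt) - cos(theta0) sin(wt)
            i1, e1 = integrate.quad(
                g_sin, U0, np.inf, weight="cos", wvar=w, epsabs=acc / 3, limlst=200, limit=200
            )
            i2, e2 = integrate.quad(
                g_cos, U0, np.inf, weight="sin", wvar=w, epsabs=acc / 3, limlst=200, limit=200
            )
        except (integrate.IntegrationWarning, Exception):
            return np.nan, False
    total_err = e0 + e1 + e2
    p = 0.5 + (i0 + i1 - i2) / np.pi
    if not np.isfinite(p) or total_err > max(10 * acc, 1e-6):
        ok = False
    return p, ok


def quadform_sf(
    q: float,
    weights: Sequence[float],
    acc: float = 1e-9,
    return_method: bool = False,
):
    """Survival function of sum_k lambda_k chi2_k(1) at q.

    Computed by CF inversion (Imhof-type) at absolute error ``acc``; falls
    back to the Liu moment-matching approximation when the inversion fails
    to converge or returns p below 1e-12 (beyond inversion resolution).
    With ``return_method=True`` also returns ``"cf_inversion"`` or
    ``"moment_match"``.
    """
    lam = _clean_weights(weights)
    q = float(q)
    if q <= 0:
        return (1.0, "cf_inversion") if return_method else 1.0
    # exact closed forms for degenerate weight patterns
    if lam.size == 1 or np.allclose(lam, lam[0], rtol=1e-12):
        p = float(chi2.sf(q / lam[0], df=lam.size))
        p = max(p, _P_FLOOR)
        return (p, "cf_inversion") if return_method else p

    p, ok = _imhof_sf(q, lam, acc=acc)
    method = "cf_inversion"
    if not ok or not np.isfinite(p) or p < _LIU_SWITCH_P:
        p = _liu_sf(q, lam)
        method = "moment_match"
    p = float(min(max(p, _P_FLOOR), 1.0))
    return (p, method) if return_method else p


def _imhof_sf_batch(
    qs: np.ndarray,
    lam: np.ndarray,
    acc: float = 1e-6,
    max_nodes: int = 1 << 17,
    refine_tiny: bool = True,
) -> np.ndarray:
    """Vectorized sf at many quantiles for one shared weight vector.

    Midpoint-rule CF inversion with node-doubling and truncation-extension
    checks; entries that fail to stabilize are recomputed by the scalar
    routine. Intended for the inner CDF evaluations of the adaptive-test
    integral, where thousands of quantiles share one weight vector.
    """
    lam = _clean_weights(lam)
    qs = np.asarray(qs, dtype=float)
    out = np.ones_like(qs)
    pos = qs > 0
    if not pos.any():
        return out
    if lam.size == 1 or np.allclose(lam, lam[0], rtol=1e-12):
        out[pos] = chi2.sf(qs[pos] / lam[0], df=lam.size)
        return np.clip(out, _P_FLOOR, 1.0)

    lmax = lam[0]
    lam_n = lam / lmax
    q = qs[pos] / lmax
    mu = lam_n.sum()
    sd = np.sqrt(2 * (lam_n**2).sum())

    def midpoint(U: float, K: int) -> np.ndarray:
        t = (np.arange(K) + 0.5) * (U / K)
        th0 = 0.5 * np.arctan(np.outer(lam_n, t)).sum(axis=0)
        base = np.exp(-0.25 * np.log1p(np.outer(lam_n, t) ** 2).sum(axis=0)) / t
        phase = th0[None, :] - 0.5 * q[:, None] * t[None, :]
        integral = (np.sin(phase) * base).sum(axis=1) * (U / K)
        # two-term integration-by-parts correction for the truncated
        # oscillatory tail:
        #   int_U^inf h sin(phi) dt
        #     ~ (h/phi') cos(phi) - ((h' phi' - h phi'') / phi'^3) sin(phi)
        # evaluated at U, with phi = theta0 - (q/2) t
        th0_U = 0.5 * np.arctan(lam_n * U).sum()
        h_U = np.exp(-0.25 * np.log1p((lam_n * U) ** 2).sum()) / U
        dh_U = h_U * (-1.0 / U - 0.5 * (lam_n**2 * U / (1.0 + (lam_n * U) ** 2)).sum())
        dth0_U = 0.5 * (lam_n / (1.0 + (lam_n * U) ** 2)).sum()
        d2th0_U = -(lam_n**3 * U / (1.0 + (lam_n * U) ** 2) ** 2).sum()
        dphi = dth0_U - 0.5 * q
        phi_U = th0_U - 0.5 * q * U
        safe = np.abs(dphi) > 1e-3
        with np.errstate(divide="ignore", invalid="ignore"):
            tail = np.where(
                safe,
                h_U * np.cos(phi_U) / dphi
                - (dh_U * dphi - h_U * d2th0_U) / dphi**3 * np.sin(phi_U),
                0.0,
            )
        return 0.5 + (integral + tail) / np.pi

    span = 0.5 * (q.max() + mu) + 6 * sd
    # few eigenvalues -> slow envelope decay t^-(1+m/2); push truncation out
    U = 150.0 if lam_n.size < 5 else 40.0
    K = int(min(max(256, 8 * U * span / np.pi), max_nodes))
    p1 = midpoint(U, K)
    p2 = midpoint(U, 2 * K if 2 * K <= max_nodes else K)
    p3 = midpoint(1.6 * U, int(min(1.6 * 2 * K, max_nodes)))
    stable = (np.abs(p1 - p2) < acc) & (np.abs(p2 - p3) < acc)
    res = p3.copy()
    if not stable.all():
        idx = np.nonzero(~stable)[0]
        for i in idx:
            res[i] = quadform_sf(q[i] * lmax, lam, acc=acc)
    res = np.clip(res, _P_FLOOR, 1.0)
    if refine_tiny:
        # far-tail entries below midpoint resolution: scalar/fallback path
        for i in np.nonzero(res < 1e-10)[0]:
            res[i] = quadform_sf(q[i] * lmax, lam)
    out[pos] = res
    return out


@dataclass
class QuadFormNull:
    """Eigenvalue weights of a quadratic-form null and the method used."""

    weights: np.ndarray
    method: str = "cf_inversion"

    def __post_init__(self) -> None:
        self.weights = _clean_weights(self.weights)

    def sf(self, q: float, acc: float = 1e-9) -> float:
        p, method = quadform_sf(q, self.weights, acc=acc, return_method=True)
        self.method = method
        return p


# ---------------------------------------------------------------------------
# The three gene-level tests.
# ---------------------------------------------------------------------------


def _as_zR(z: Sequence[float], R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    z = np.asarray(z, dtype=float).ravel()
    R = np.asarray(R, dtype=float)
    if R.shape != (z.size, z.size):
        raise ValueError(f"shape mismatch: z has {z.size} entries, R is {R.shape}")
    return z, (R + R.T) / 2


def sum_test(z: Sequence[float], R: np.ndarray) -> tuple[float, float]:
    """Burden-type sum test: B = sum(z); B ~ N(0, 1'R1) under the null.

    Returns (B, two-sided p) with the p-value taken as the chi2(1) tail of
    B^2/(1'R1).
    """
    z, R = _as_zR(z, R)
    B = float(z.sum())
    v = float(R.sum())
    if v <= 1e-12:
        raise NumericalError(f"1'R1 = {v} is not positive; invalid LD matrix")
    p = float(chi2.sf(B * B / v, df=1))
    return B, max(p, _P_FLOOR)


def squared_sum_test(z: Sequence[float], R: np.ndarray) -> tuple[float, float]:
    """SKAT-type squared-sum test: Q = sum(z^2), null weights = eig(R)."""
    z, R = _as_zR(z, R)
    Q = float((z**2).sum())
    lam = np.linalg.eigvalsh(R)
    p = quadform_sf(Q, lam)
    return Q, p


@dataclass
class GeneTestResult:
    """Per-gene statistics and p-values for ST, S2T and AT."""

    gene_id: str
    m: int
    B: float
    Q: float
    p_st: float
    p_s2t: float
    T: float
    p_at: float
    rho_grid: tuple[float, ...]
    p_rho: tuple[float, ...]
    at_method: str = "integration"
    mc_draws: int | None = None
    chrom: str | None = None
    qf_method: str = "cf_inversion"


class _AdaptiveNull:
    """Precomputed null structure of the rho family for one LD matrix R.

    Caches the per-rho eigenvalues of A_rho^{1/2} R A_rho^{1/2} and the
    conditioning decomposition used for the min-p integral, so scans over
    many Z-vectors sharing one R pay the eigendecompositions once.
    """

    def __init__(self, R: np.ndarray, rho_grid: Sequence[float] = DEFAULT_RHO_GRID):
        R = np.asarray(R, dtype=float)
        R = (R + R.T) / 2
        m = R.shape[0]
        rho = np.asarray(rho_grid, dtype=float)
        if rho.size == 0 or rho.min() < 0 or rho.max() > 1:
            raise ValueError("rho grid must be non-empty within [0, 1]")
        self.R = R
        self.m = m
        self.rho = rho
        ones = np.ones(m)
        self.s2 = float(ones @ R @ ones)
        if self.s2 <= 1e-12:
            raise NumericalError("1'R1 is not positive; invalid LD matrix")
        # per-rho weights via the closed-form square root of A_rho:
        # sqrt(A_rho) = sqrt(1-rho) (I - J/m) + sqrt(1-rho+rho m) J/m
        self.lam_rho: list[np.ndarray] = []
        J = np.full((m, m), 1.0 / m)
        for r in rho:
            alpha = np.sqrt(1.0 - r)
            beta = np.sqrt(1.0 - r + r * m)
            Asq = alpha * (np.eye(m) - J) + beta * J
            S = Asq @ R @ Asq
            self.lam_rho.append(_clean_weights(np.linalg.eigvalsh((S + S.T) / 2)))
        # conditioning on the standardized burden u = 1'z / sqrt(1'R1):
        # z = a u + w with a = R1/sqrt(s2), w ~ MVN(0, R - a a') independent
        a = (R @ ones) / np.sqrt(self.s2)
        Sw = R - np.outer(a, a)
        self.lam_w = _clean_weights(np.linalg.eigvalsh((Sw + Sw.T) / 2))
        self.mu_kappa = float(self.lam_w.sum())
        self.var_remain = float(4.0 * a @ Sw @ a)
        self.var_kappa = float(2.0 * (self.lam_w**2).sum() + self.var_remain)
        self.tau = rho * self.s2 + (1.0 - rho) * float(a @ a)

    def stats(self, z: np.ndarray) -> tuple[float, float, np.ndarray]:
        B = float(z.sum())
        Q = float((z**2).sum())
        q_rho = (1.0 - self.rho) * Q + self.rho * B * B
        return B, Q, q_rho

    def per_rho_p(self, q_rho: np.ndarray) -> np.ndarray:
        # vectorized inverter per rho (scalar-quadrature fallback inside)
        return np.array(
            [
                float(_imhof_sf_batch(np.array([q]), lam, acc=1e-7)[0])
                for q, lam in zip(q_rho, self.lam_rho)
            ],
            dtype=float,
        )

    def thresholds(self, T: float) -> np.ndarray:
        """Per-rho quantiles q with sf(q) = T (moment-matched, as in
        optimal unified kernel tests)."""
        return np.array([_liu_quantile(T, lam) for lam in self.lam_rho], dtype=float)

    def minp_tail_integration(self, qmin: np.ndarray, n_nodes: int = 96) -> float:
        """P(exists rho: Q_rho >= qmin[rho]) under z ~ MVN(0, R).

        One-dimensional integral over the 1-df density of u^2 of the
        survival of the moment-matched residual quadratic form.
        """
        rho = self.rho
        is_one = rho > 1.0 - 1e-12
        # rho = 1 contributes a hard cap on u^2 = B^2/s2
        if is_one.any():
            x_up = float((qmin[is_one] / self.tau[is_one]).min())
        else:
            x_up = float(chi2.isf(1e-16, df=1))
        if x_up <= 0:
            return 1.0
        rest = ~is_one
        u_nodes, u_wts = leggauss(n_nodes)
        u_up = np.sqrt(x_up)
        u = 0.5 * u_up * (u_nodes + 1.0)
        wts = 0.5 * u_up * u_wts
        x = u**2
        if rest.any():
            delta = np.min(
                (qmin[rest][None, :] - np.outer(x, self.tau[rest])) / (1.0 - rho[rest])[None, :],
                axis=1,
            )
        else:
            delta = np.full_like(x, np.inf)
        F = np.zeros_like(x)
        shrink = np.sqrt(max(self.var_kappa - self.var_remain, 0.0) / self.var_kappa)
        finite = np.isfinite(delta) & (delta > 0)
        huge = delta > self.mu_kappa * 1e4
        F[huge] = 1.0
        eval_idx = finite & ~huge
        if eval_idx.any():
            t_std = (delta[eval_idx] - self.mu_kappa) * shrink + self.mu_kappa
            # tiny survival values mean F ~= 1; no need to resolve them
            sf_vals = _imhof_sf_batch(t_std, self.lam_w, acc=1e-7, refine_tiny=False)
            F[eval_idx] = 1.0 - sf_vals
        F[delta <= 0] = 0.0
        F[~np.isfinite(delta)] = 1.0
        survive = float((wts * F * 2.0 * norm.pdf(u)).sum())
        return 1.0 - survive

    def minp_tail_mc(
        self, qmin: np.ndarray, n_draws: int, seed: int | np.random.Generator
    ) -> float:
        """Monte-Carlo estimate of the same tail probability.

        Draws z* ~ MVN(0, R) via a square-root factorization with diagonal
        jitter up to 1e-8 and counts draws where any Q_rho* reaches its
        threshold; the estimate is (1 + hits) / (N + 1).
        """
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        L = _chol_with_jitter(self.R)
        hits = 0
        chunk = 200_000
        remaining = n_draws
        while remaining > 0:
            n = min(chunk, remaining)
            zs = rng.standard_normal((n, self.m)) @ L.T
            Qs = (zs**2).sum(axis=1)
            Bs = zs.sum(axis=1)
            q_mat = np.outer(Qs, 1.0 - self.rho) + np.outer(Bs**2, self.rho)
            hits += int((q_mat >= qmin[None, :]).any(axis=1).sum())
            remaining -= n
        return (1 + hits) / (n_draws + 1)


def _chol_with_jitter(R: np.ndarray, max_jitter: float = 1e-8) -> np.ndarray:
    jitter = 0.0
    for _ in range(6):
        try:
            return np.linalg.cholesky(R + jitter * np.eye(R.shape[0]))
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-12)
            if jitter > max_jitter:
                break
    # PSD fallback: symmetric eigendecomposition square root
    w, V = np.linalg.eigh((R + R.T) / 2)
    if w.min() < -1e-8:
        raise NumericalError(f"R is not PSD beyond jitter tolerance (min eig {w.min()})")
    return V * np.sqrt(np.clip(w, 0.0, None))


def adaptive_test(
    z: Sequence[float],
    R: np.ndarray,
    rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
    method: str = "integration",
    mc_draws: int = 200_000,
    seed: int | np.random.Generator = 0,
    gene_id: str = "",
    null: "_AdaptiveNull | None" = None,
) -> GeneTestResult:
    """Adaptive min-p combination of the sum and squared-sum tests.

    Computes Q_rho = (1-rho) Q + rho B^2 over the rho grid, the per-rho
    weighted-chi-square p-values, T = min p, and the adjusted p_AT that
    accounts for the minimization. ``method`` is ``"integration"``
    (default; one-dimensional conditioning integral) or ``"monte_carlo"``.
    Monte Carlo is also the automatic fallback when integration
    diagnostics fail. The result always satisfies the min-p sandwich
    T <= p_AT <= min(1, len(grid) * T).
    """
    z, R = _as_zR(z, R)
    m = z.size
    if m == 1:
        # all three statistics coincide with the single-variant chi-square
        p = float(max(chi2.sf(z[0] ** 2 / R[0, 0], df=1), _P_FLOOR))
        return GeneTestResult(
            gene_id=gene_id, m=1, B=float(z[0]), Q=float(z[0] ** 2),
            p_st=p, p_s2t=p, T=p, p_at=p,
            rho_grid=tuple(rho_grid), p_rho=tuple([p] * len(tuple(rho_grid))),
            at_method="closed_form",
        )

    if null is None:
        null = _AdaptiveNull(R, rho_grid)
    B, Q, q_rho = null.stats(z)
    p_rho = null.per_rho_p(q_rho)
    T = float(p_rho.min())
    qmin = null.thresholds(T)

    at_method = method
    used_draws: int | None = None
    if method == "integration":
        p_at = null.minp_tail_integration(qmin)
        if not np.isfinite(p_at) or p_at < -1e-6 or p_at > 1 + 1e-6:
            warnings.warn(
                f"adaptive-test integration diagnostics failed for gene "
                f"{gene_id or '<unnamed>'}; falling back to Monte Carlo",
                RuntimeWarning,
            )
            p_at = null.minp_tail_mc(qmin, mc_draws, seed)
            at_method = "monte_carlo"
            used_draws = mc_draws
    elif method == "monte_carlo":
        p_at = null.minp_tail_mc(qmin, mc_draws, seed)
        used_draws = mc_draws
    else:
        raise ValueError(f"unknown adaptive-test method: {method!r}")

    # min-p sandwich: the adjusted p can never beat the raw minimum nor
    # exceed its Bonferroni bound over the grid
    p_at = float(min(max(p_at, T), min(1.0, len(null.rho) * T)))

    _, p_st = sum_test(z, R)
    p_s2t = float(p_rho[np.argmin(np.abs(null.rho - 0.0))]) if 0.0 in set(null.rho) else squared_sum_test(z, R)[1]
    # definitional endpoints: rho=0 is S2T, rho=1 is ST
    return GeneTestResult(
        gene_id=gene_id, m=m, B=B, Q=Q,
        p_st=p_st, p_s2t=p_s2t, T=T, p_at=p_at,
        rho_grid=tuple(float(r) for r in null.rho),
        p_rho=tuple(float(p) for p in p_rho),
        at_method=at_method, mc_draws=used_draws,
    )


@dataclass
class GeneScanResult:
    """Genome-scan output: per-gene table, threshold, Manhattan table."""

    results: pd.DataFrame
    threshold: float
    manhattan: pd.DataFrame
    n_tested: int

    def significant(self) -> pd.DataFrame:
        return self.results[self.results["significant"]]


def gene_scan(
    gene_sets: Iterable[GeneSnpSet] | str | Path,
    alpha_fw: float = 0.05,
    n_tests: int | None = None,
    rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
    method: str = "integration",
    mc_draws: int = 200_000,
    seed: int = 0,
) -> GeneScanResult:
    """Run the adaptive test over every gene and apply a Bonferroni
    family-wise threshold alpha_fw / n_tests.

    ``gene_sets`` is an iterable of :class:`GeneSnpSet` or a bundle
    directory path. ``n_tests`` overrides the family size (by default the
    number of genes actually tested, e.g. 20,000 genes at alpha 0.05 give
    2.5e-6).
    """
    if isinstance(gene_sets, (str, Path)):
        from .ld_panel import read_bundles

        gene_sets = read_bundles(gene_sets)
    gene_sets = list(gene_sets)
    if not gene_sets:
        raise ValueError("empty gene-set collection: nothing to scan")

    rows = []
    for i, gs in enumerate(gene_sets):
        res = adaptive_test(
            gs.z, gs.ld.r, rho_grid=rho_grid, method=method,
            mc_draws=mc_draws, seed=seed + i, gene_id=gs.gene_id,
        )
        rows.append(
            {
                "gene_id": gs.gene_id,
                "chrom": gs.chrom,
                "midpoint": gs.midpoint,
                "m": res.m,
                "B": res.B,
                "Q": res.Q,
                "p_st": res.p_st,
                "p_s2t": res.p_s2t,
                "T": res.T,
                "p_at": res.p_at,
                "method": res.at_method,
            }
        )
    results = pd.DataFrame(rows)
    n = n_tests if n_tests is not None else len(results)
    threshold = alpha_fw / n
    results["significant"] = results["p_at"] < threshold
    manhattan = results[["gene_id", "chrom", "midpoint", "p_at"]].copy()
    manhattan["neg_log10_p"] = -np.log10(manhattan["p_at"])
    return GeneScanResult(
        results=results, threshold=threshold, manhattan=manhattan, n_tested=len(results)
    )
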