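"""Variance-component (kernel) and optimal unified set tests.

The kernel statistic is Q = r' G W W' G' r with r the null-model residuals
and W = diag(Beta-density MAF weights); its null distribution is the
mixture sum_i lambda_i chi2_1 with lambda_i the eigenvalues of the weighted
kernel projected by the residual covariance V = D - D X (X'DX)^-1 X'D,
D = diag(mu(1-mu)).

The optimal unified test evaluates Q_rho = (1-rho) Q_kernel + rho Q_burden
over a rho grid, takes the minimum p, and converts it to a single p-value
by one-dimensional integration over the conditional null distribution of
the minimum-p statistic (the burden direction factors out as an independent
1-df chi-square).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ..errors import ConfigError, DataError, DegenerateSetError
from .null import NullModel
from .quadform import MIN_P, QuadFormSpec, liu_quantile, pvalue_quadform

__all__ = [
    "DEFAULT_RHO_GRID",
    "SkatOConfig",
    "SkatOResult",
    "impute_missing",
    "skat_q",
    "skat_p",
    "skato_p",
    "select_a2",
    "tune_a2",
]

#: Grid of the original optimal unified test publication.
DEFAULT_RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)

# 64 Gauss-Legendre nodes on t in [0, 8] for the min-p combination integral
# (after x = t^2: exp(-t^2/2) weight; the omitted tail is < 1e-14)
_COMB_T_MAX = 8.0
_n, _w = np.polynomial.legendre.leggauss(64)
_COMB_NODES = (0.5 * _COMB_T_MAX * (_n + 1.0), 0.5 * _COMB_T_MAX * _w)
del _n, _w


def _liu_sf_vec(t: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Vectorised moment-matching survival function for the remainder term."""
    from .quadform import _liu_params

    mu_q, sigma_q, ell, delta, sigma_x = _liu_params(lambdas)
    mu_x = ell + delta
    z = (t - mu_q) / sigma_q * sigma_x + mu_x
    if delta > 0:
        return stats.ncx2.sf(z, ell, delta)
    return stats.chi2.sf(z, ell)


@dataclass(frozen=True)
class SkatOConfig:
    rho_grid: tuple[float, ...] = DEFAULT_RHO_GRID

    def __post_init__(self) -> None:
        grid = tuple(self.rho_grid)
        if any(not 0.0 <= r <= 1.0 for r in grid):
            raise ConfigError("rho grid values must lie in [0, 1]")
        if len(grid) > 1 and not (0.0 in grid and 1.0 in grid):
            raise ConfigError("multi-point rho grid must contain 0 and 1")
        object.__setattr__(self, "rho_grid", grid)


@dataclass
class SkatOResult:
    p: float
    rho_min: float
    p_per_rho: dict[float, float] = field(default_factory=dict)
    fallback: bool = False
    q_rho_min: float = float("nan")  # observed statistic at the selected rho


def impute_missing(G: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages per variant (kernel-test convention)."""
    G = np.array(G, dtype=float)
    means = np.nanmean(np.where(np.isnan(G), np.nan, G), axis=0)
    means = np.where(np.isnan(means), 0.0, means)
    idx = np.where(np.isnan(G))
    G[idx] = means[idx[1]]
    return G


def _projected_weighted(
    G: np.ndarray, w: np.ndarray, null: NullModel
) -> tuple[np.ndarray, np.ndarray]:
    """Return (Z1, s): the V^{1/2}-projected weighted genotypes and scores.

    Z1 = V^{1/2} G W (so Z1'Z1 = W G' V G W) and s = W G' r.
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    if G.ndim != 2:
        raise DataError("G must be a samples x variants matrix")
    n = null.mu_hat.size
    if G.shape[0] != n:
        raise DataError(f"G has {G.shape[0]} rows but null model has {n} samples")
    if np.isnan(G).any():
        G = impute_missing(G)
    w = np.asarray(w, dtype=float)
    if w.size != G.shape[1]:
        raise DataError("one weight per variant required")
    Z = G * w[None, :]
    d = null.variance_weights
    sd = np.sqrt(d)
    X = null.X
    DX = X * d[:, None]
    XtDX = X.T @ DX
    # V^{1/2} z = sqrt(D) z - sqrt(D) X (X'DX)^-1 X'D z
    coef = np.linalg.solve(XtDX, DX.T @ Z)
    Z1 = sd[:, None] * Z - sd[:, None] * (X @ coef)
    s = Z.T @ null.residuals
    return Z1, s


def _kernel_lambdas(K: np.ndarray) -> np.ndarray:
    lam = np.linalg.eigvalsh((K + K.T) / 2.0)
    lam = lam[lam > max(lam.max(), 0.0) * 1e-12]
    return np.sort(lam)[::-1]


def skat_q(G: np.ndarray, w: np.ndarray, null: NullModel) -> QuadFormSpec:
    """Observed kernel statistic and its null mixture eigenvalues."""
    G = np.atleast_2d(np.asarray(G, dtype=float))
    if G.size and np.nanmax(G, axis=0).max() == 0.0:
        raise DegenerateSetError("all retained dosages are zero for this set")
    Z1, s = _projected_weighted(G, w, null)
    q = float(s @ s)
    K = Z1.T @ Z1
    if not np.any(np.diag(K) > 0):
        # all-zero weights: Q = 0 by convention
        return QuadFormSpec(lambdas=np.array([1.0]), q=0.0)
    lam = _kernel_lambdas(K)
    if lam.size == 0:
        raise DegenerateSetError("zero-variance kernel for this variant set")
    return QuadFormSpec(lambdas=lam, q=q)


def skat_p(G: np.ndarray, w: np.ndarray, null: NullModel) -> tuple[float, bool]:
    """Plain kernel-test p-value (rho = 0)."""
    spec = skat_q(G, w, null)
    if spec.q == 0.0:
        return 1.0, False
    return pvalue_quadform(spec)


def _rho_sqrt(m: int, rho: float) -> np.ndarray:
    """Matrix square root of R_rho = (1-rho) I + rho 11'."""
    a = np.sqrt(1.0 - rho)
    b = (np.sqrt(1.0 - rho + m * rho) - a) / m
    return a * np.eye(m) + b * np.ones((m, m))


def _per_rho_pvalues(
    K: np.ndarray, s: np.ndarray, rhos: tuple[float, ...]
) -> tuple[dict[float, float], dict[float, np.ndarray], dict[float, float], bool]:
    m = K.shape[0]
    ss = float(s @ s)
    sb = float(s.sum()) ** 2
    pvals: dict[float, float] = {}
    lambdas: dict[float, np.ndarray] = {}
    qs: dict[float, float] = {}
    fallback = False
    for rho in rhos:
        q_rho = (1.0 - rho) * ss + rho * sb
        R2 = _rho_sqrt(m, rho)
        lam = _kernel_lambdas(R2 @ K @ R2)
        if lam.size == 0:
            raise DegenerateSetError("zero-variance kernel for this variant set")
        p, fb = pvalue_quadform(QuadFormSpec(lambdas=lam, q=q_rho))
        fallback = fallback or fb
        pvals[rho] = p
        lambdas[rho] = lam
        qs[rho] = q_rho
    return pvals, lambdas, qs, fallback


def _minp_combination(
    Z1: np.ndarray,
    rhos: tuple[float, ...],
    pvals: dict[float, float],
    lambdas: dict[float, np.ndarray],
) -> float:
    """Combine the grid's minimum p into a single p-value.

    Conditional on the squared burden-direction score (a 1-df chi-square
    eta0), each Q_rho threshold becomes a bound on the common remainder
    kappa; the combined p integrates P(kappa below all bounds) over eta0.
    """
    n, m = Z1.shape
    pmin = min(pvals.values())
    z_bar = Z1.mean(axis=1)
    zb2 = float(z_bar @ z_bar)
    if zb2 <= 0:
        return pmin
    cof = (z_bar @ Z1) / zb2
    Z_orth = Z1 - np.outer(z_bar, cof)
    K_orth = Z_orth.T @ Z_orth
    lam_k = np.linalg.eigvalsh((K_orth + K_orth.T) / 2.0)
    lam_k = lam_k[lam_k > max(lam_k.max(), 0.0) * 1e-12]
    if lam_k.size == 0:
        # burden direction carries everything: all rho statistics coincide
        return pmin
    mu_q = lam_k.sum()
    # 4 * tr[(Z_par'Z_par)(Z_orth'Z_orth)] with Z_par = z_bar cof'
    var_remain = 4.0 * zb2 * float(np.sum((Z_orth @ cof) ** 2))
    var_q = 2.0 * float((lam_k**2).sum()) + var_remain
    sd1 = np.sqrt(max(var_q - var_remain, 0.0)) / np.sqrt(var_q)

    taus = np.array(
        [(m**2 * rho + (1.0 - rho) * float(cof @ cof)) * zb2 for rho in rhos]
    )
    qmins = np.array([liu_quantile(pmin, lambdas[rho]) for rho in rhos])
    rhos_c = np.minimum(np.asarray(rhos, dtype=float), 0.999)

    # integrate E[ P(kappa < min bound | eta0 = x) ] over the 1-df chi-square
    # eta0; substituting x = t^2 absorbs the density's x^{-1/2} singularity
    # into a Gaussian weight, so fixed Gauss-Legendre nodes suffice.
    t_nodes, t_weights = _COMB_NODES
    x = t_nodes**2
    bounds = np.min(
        (qmins[:, None] - taus[:, None] * x[None, :]) / (1.0 - rhos_c)[:, None],
        axis=0,
    )
    t_std = (bounds - mu_q) * sd1 + mu_q
    cdf = np.where(
        bounds <= 0, 0.0, 1.0 - np.clip(_liu_sf_vec(t_std, lam_k), 0.0, 1.0)
    )
    gauss = 2.0 * np.exp(-0.5 * t_nodes**2) / np.sqrt(2.0 * np.pi)
    val = float(np.sum(t_weights * cdf * gauss))
    p = 1.0 - val
    # numerical guards: the combined p cannot beat Bonferroni over the grid
    # and cannot be smaller than the best single-rho p
    p = max(p, pmin)
    p = min(p, pmin * len(rhos), 1.0)
    return max(p, MIN_P)


def skato_p(
    G: np.ndarray,
    w: np.ndarray,
    null: NullModel,
    config: SkatOConfig = SkatOConfig(),
) -> SkatOResult:
    """Optimal unified test p-value and the argmin rho of the grid."""
    rhos = config.rho_grid
    Z1, s = _projected_weighted(G, w, null)
    K = Z1.T @ Z1
    if not np.any(np.diag(K) > 0):
        raise DegenerateSetError("zero-variance kernel for this variant set")
    pvals, lambdas, qs, fallback = _per_rho_pvalues(K, s, rhos)
    rho_min = min(rhos, key=lambda r: (pvals[r], r))
    if len(rhos) == 1:
        return SkatOResult(
            p=pvals[rhos[0]],
            rho_min=rhos[0],
            p_per_rho=dict(pvals),
            fallback=fallback,
            q_rho_min=qs[rhos[0]],
        )
    p = _minp_combination(Z1, rhos, pvals, lambdas)
    return SkatOResult(
        p=p,
        rho_min=rho_min,
        p_per_rho=dict(pvals),
        fallback=fallback,
        q_rho_min=qs[rho_min],
    )


def select_a2(table: dict[float, float]) -> float:
    """Pick the a2 with the smallest p; ties break to the smallest a2."""
    if not table:
        raise ConfigError("empty tuning table")
    return min(sorted(table), key=lambda a: (table[a], a))


def tune_a2(
    G: np.ndarray,
    null: NullModel,
    mafs: np.ndarray,
    grid: tuple[float, ...] = (25.0, 250.0, 2500.0),
    a1: float = 1.0,
    config: SkatOConfig = SkatOConfig(),
) -> tuple[float, dict[float, float]]:
    """Select the Beta shape a2 minimising the positive-control set's p.

    Ties break toward the smallest a2. Returns (a2*, {a2: p}).
    """
    from .weights import beta_weight

    if not grid:
        raise ConfigError("a2 grid must be nonempty")
    G = np.atleast_2d(np.asarray(G, dtype=float))
    if G.shape[1] == 0:
        raise DegenerateSetError("positive-control set has no variants")
    table: dict[float, float] = {}
    for a2 in grid:
        w = beta_weight(np.asarray(mafs, dtype=float), a1, a2)
        table[a2] = skato_p(G, w, null, config).p
    return select_a2(table), table
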