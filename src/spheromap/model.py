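"""Per-gene probabilistic inference of spatial regulation in spheroids.

A gene's expression along the core-periphery axis is summarized by its
*spatial regulation function* f(r): the fraction of a cell's transcriptome
contributed by the gene at radial position r (0 = core, 1 = periphery).
f is modelled as a second-order polynomial

    f(r) = a + b*r + c*r**2,    f(r) > 0 on [0, 1],

where a is the fractional abundance at the core and b, c are the linear and
quadratic trends. Observed UMI counts are treated as noisy measurements:
for cell c with radial position r_c and sequencing depth N_c (total UMIs),

    n_c ~ NegativeBinomial(mean = f(r_c) * N_c, size = theta),

with a gene-specific size parameter theta (variance = mu + mu**2/theta;
theta -> inf recovers Poisson). MAP estimates of (a, b, c, log theta)
maximize the likelihood plus weak priors: a soft log-barrier keeping
min f above a depth-implied floor (the likelihood is flat in arbitrarily
small a, which would otherwise ill-condition the Hessian), and zero-mean
Gaussian "no trend" priors on b and c with large scale. Standard errors
come from a Laplace (Gauss) approximation: the inverse Hessian of the
negative log posterior at the MAP.

The public surface is statsmodels-like: build a :class:`GeneRegulationModel`
from data, call :meth:`~GeneRegulationModel.fit`, inspect the returned
:class:`GeneRegulationResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import scipy.optimize
from scipy.special import digamma, expit, gammaln
from scipy.stats import chi2, norm

from .io import CellProfile, SpheromapError

_LOG_THETA_BOUNDS = (np.log(0.01), np.log(1e4))
_BARRIER_GRID = np.linspace(0.0, 1.0, 21)

__all__ = [
    "RegulationFunction",
    "RegulationPriors",
    "GeneRegulationModel",
    "GeneRegulationResults",
    "nb_logpmf",
    "gene_log_posterior",
    "init_params",
    "fit_gene",
    "test_spatial",
    "regulation_magnitude",
]


# ---------------------------------------------------------------------------
# Regulation function
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegulationFunction:
    """Second-order polynomial spatial regulation f(r) = a + b*r + c*r**2."""

    a: float
    b: float
    c: float

    def __call__(self, r) -> np.ndarray | float:
        r = np.asarray(r, dtype=float) if np.ndim(r) else float(r)
        return self.a + self.b * r + self.c * r * r

    def evaluate(self, r: float) -> float:
        """Evaluate f at r in [0, 1], enforcing the positivity domain."""
        if not 0.0 <= r <= 1.0:
            raise SpheromapError(f"radial position {r} outside [0, 1]")
        val = float(self(r))
        if val <= 0:
            raise SpheromapError(
                f"regulation function non-positive at r={r}: f={val}"
            )
        return val

    def extrema(self) -> tuple[float, float]:
        """(min, max) of f over [0, 1], from the analytic extremum set.

        Candidates are the boundary values f(0), f(1) plus the interior
        vertex f(r*) at r* = -b/(2c) when it falls inside (0, 1).
        """
        candidates = [self.a, self.a + self.b + self.c]
        if self.c != 0:
            r_star = -self.b / (2.0 * self.c)
            if 0.0 < r_star < 1.0:
                candidates.append(float(self(r_star)))
        return min(candidates), max(candidates)

    @property
    def magnitude(self) -> float:
        """Regulation magnitude: 1 - min f / max f over [0, 1]."""
        lo, hi = self.extrema()
        if lo <= 0:
            raise SpheromapError(
                f"regulation function not positive on [0, 1] (min={lo})"
            )
        return 1.0 - lo / hi

    def vertex(self) -> float | None:
        """Interior stationary point r* = -b/(2c), or None if c == 0."""
        if self.c == 0:
            return None
        return -self.b / (2.0 * self.c)


def eval_regulation(f: RegulationFunction, r: float) -> float:
    """Functional alias for :meth:`RegulationFunction.evaluate`."""
    return f.evaluate(r)


def regulation_magnitude(f: RegulationFunction) -> float:
    """Relative dynamic range of f over [0, 1]: 1 - min f / max f."""
    return f.magnitude


# ---------------------------------------------------------------------------
# Negative binomial log pmf
# ---------------------------------------------------------------------------


def nb_logpmf(n, mu, theta) -> np.ndarray | float:
    """Log pmf of NB with mean ``mu`` and size ``theta``.

    Variance is mu + mu**2/theta; theta -> inf recovers Poisson(mu).
    mu = 0 is the degenerate point mass at zero: logpmf 0 at n = 0 and
    -inf for n > 0.
    """
    n_arr = np.asarray(n)
    scalar = n_arr.ndim == 0 and np.ndim(mu) == 0 and np.ndim(theta) == 0
    n_arr = np.atleast_1d(n_arr).astype(float)
    mu_arr = np.broadcast_to(np.atleast_1d(np.asarray(mu, dtype=float)), n_arr.shape
                             ) if np.ndim(mu) else np.full_like(n_arr, float(mu))
    theta_arr = (np.broadcast_to(np.atleast_1d(np.asarray(theta, dtype=float)),
                                 n_arr.shape)
                 if np.ndim(theta) else np.full_like(n_arr, float(theta)))
    if (n_arr < 0).any():
        raise SpheromapError("negative counts")
    if not np.allclose(n_arr, np.round(n_arr)):
        raise SpheromapError("counts must be integral")
    if (mu_arr < 0).any() or (theta_arr <= 0).any():
        raise SpheromapError("require mu >= 0 and theta > 0")
    out = np.empty_like(n_arr)
    zero_mu = mu_arr == 0
    out[zero_mu] = np.where(n_arr[zero_mu] == 0, 0.0, -np.inf)
    ok = ~zero_mu
    nn, mm, tt = n_arr[ok], mu_arr[ok], theta_arr[ok]
    out[ok] = (
        gammaln(nn + tt)
        - gammaln(tt)
        - gammaln(nn + 1.0)
        + tt * (np.log(tt) - np.log(tt + mm))
        + nn * (np.log(mm) - np.log(tt + mm))
    )
    return float(out[0]) if scalar else out


def _nb_dll_dmu(n, mu, theta):
    return n / mu - (n + theta) / (theta + mu)


def _nb_dll_dtheta(n, mu, theta):
    return (
        digamma(n + theta)
        - digamma(theta)
        + np.log(theta)
        - np.log(theta + mu)
        + 1.0
        - (n + theta) / (theta + mu)
    )


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegulationPriors:
    """Weak priors regularizing the per-gene MAP fit.

    floor : float
        Minimal fractional abundance the barrier defends, typically
        ``floor_eps / median depth`` — below this, a single extra UMI is
        undetectable and the likelihood is flat in a.
    trend_sigma : float
        Scale of the zero-mean Gaussian "no trend" priors on b and c.
    """

    floor: float
    trend_sigma: float

    @classmethod
    def from_data(
        cls,
        depths: np.ndarray,
        abundance_scale: float,
        floor_eps: float = 0.1,
        trend_sigma_scale: float = 100.0,
    ) -> "RegulationPriors":
        floor = floor_eps / float(np.median(depths))
        sigma = trend_sigma_scale * max(abundance_scale, floor)
        return cls(floor=floor, trend_sigma=sigma)

    def log_prior(self, a: float, b: float, c: float) -> float:
        """Unnormalized log prior density at (a, b, c)."""
        f_grid = a + b * _BARRIER_GRID + c * _BARRIER_GRID**2
        w = 0.5 * self.floor
        barrier = -np.logaddexp(0.0, (self.floor - f_grid) / w).sum()
        gauss = -(b * b + c * c) / (2.0 * self.trend_sigma**2)
        return float(barrier + gauss)


def _safe_abundance(f: np.ndarray, floor: float) -> tuple[np.ndarray, np.ndarray]:
    """Softplus-smoothed floor on f; returns (g, dg/df).

    g = floor + w*softplus((f - floor)/w) with w = floor/2 keeps the NB mean
    strictly positive for any polynomial coefficients (never NaN), while
    g ~= f whenever f is comfortably above the floor.
    """
    w = 0.5 * floor
    z = (f - floor) / w
    g = floor + w * np.logaddexp(0.0, z)
    return g, expit(z)


# ---------------------------------------------------------------------------
# Log posterior (functional surface)
# ---------------------------------------------------------------------------


def _split_cells(cells) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(cells, tuple):
        r, N = cells
        return np.asarray(r, dtype=float), np.asarray(N, dtype=float)
    r = np.array([c.radial_position for c in cells], dtype=float)
    N = np.array([c.depth for c in cells], dtype=float)
    return r, N


def gene_log_posterior(
    counts,
    cells,
    a: float,
    b: float,
    c: float,
    theta: float,
    priors: RegulationPriors | None = None,
) -> float:
    """Log posterior of one gene's parameters given its spatial UMI counts.

    ``cells`` is either a sequence of :class:`~spheromap.io.CellProfile` or a
    ``(radial_position, depth)`` array pair. With ``priors=None`` the value
    is the pure log likelihood (no floor smoothing, no trend priors).
    """
    n = np.asarray(counts, dtype=float)
    r, N = _split_cells(cells)
    if n.shape != r.shape:
        raise SpheromapError("counts not aligned with cells")
    f = a + b * r + c * r * r
    if priors is None:
        if (f <= 0).any():
            raise SpheromapError("regulation function non-positive at a cell")
        return float(nb_logpmf(n, f * N, theta).sum())
    g, _ = _safe_abundance(f, priors.floor)
    ll = nb_logpmf(n, g * N, theta).sum()
    return float(ll + priors.log_prior(a, b, c))


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class GeneRegulationModel:
    """NB model of one gene's UMI counts along the core-periphery axis.

    Parameters
    ----------
    counts : array-like of int
        UMI counts of the gene, one per cell.
    cells : sequence of CellProfile, or (radial_position, depth) arrays
        Cell positions r in [0, 1] and sequencing depths N.
    priors : RegulationPriors, optional
        Defaults to :meth:`RegulationPriors.from_data` on the cells.
    gene_id : str, optional
        Carried through to results and summaries.

    Examples
    --------
    >>> model = GeneRegulationModel(counts, (r, depths), gene_id="VIM")
    >>> res = model.fit()
    >>> res.params.a, res.params.b, res.theta
    """

    def __init__(self, counts, cells, priors=None, gene_id: str | None = None):
        self.endog = np.asarray(counts, dtype=float)
        self.radial, self.depth = _split_cells(cells)
        if self.endog.shape != self.radial.shape:
            raise SpheromapError("counts not aligned with cells")
        if (self.radial < 0).any() or (self.radial > 1).any():
            raise SpheromapError("radial positions outside [0, 1]")
        if (self.depth < 1).any():
            raise SpheromapError("depths must be >= 1")
        self.gene_id = gene_id
        # depth-weighted mean abundance: natural parameter scale for the gene
        self._scale = max(
            float(self.endog.sum() / self.depth.sum()),
            0.1 / float(np.median(self.depth)),
        )
        self.priors = priors if priors is not None else RegulationPriors.from_data(
            self.depth, self._scale
        )
        self._design = np.column_stack(
            [np.ones_like(self.radial), self.radial, self.radial**2]
        )
        self._barrier_design = np.column_stack(
            [np.ones_like(_BARRIER_GRID), _BARRIER_GRID, _BARRIER_GRID**2]
        )

    # -- objective ----------------------------------------------------------

    def _neg_log_posterior(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        """Negative log posterior and its gradient in scaled coordinates.

        x = (x0, x1, x2, t): f(r) = scale*(x0 + x1 r + x2 r^2), theta = e^t.
        """
        s = self._scale
        theta = np.exp(x[3])
        f = s * (self._design @ x[:3])
        g, dg_df = _safe_abundance(f, self.priors.floor)
        mu = g * self.depth
        n = self.endog

        ll = nb_logpmf(n, mu, theta).sum()
        dll_dmu = _nb_dll_dmu(n, mu, theta)
        grad_poly = self._design.T @ (dll_dmu * self.depth * dg_df) * s
        grad_t = theta * _nb_dll_dtheta(n, mu, theta).sum()

        # barrier: -sum softplus((floor - f)/w) on a fixed grid over [0, 1]
        w = 0.5 * self.priors.floor
        f_grid = s * (self._barrier_design @ x[:3])
        u = (self.priors.floor - f_grid) / w
        lp = -np.logaddexp(0.0, u).sum()
        grad_poly += (s / w) * (self._barrier_design.T @ expit(u))

        sig2 = self.priors.trend_sigma**2
        b_val, c_val = s * x[1], s * x[2]
        lp += -(b_val**2 + c_val**2) / (2.0 * sig2)
        grad_poly[1] += -(b_val / sig2) * s
        grad_poly[2] += -(c_val / sig2) * s

        grad = np.concatenate([grad_poly, [grad_t]])
        return -(ll + lp), -grad

    # -- initialization -----------------------------------------------------

    def init_params(self) -> np.ndarray:
        """Staged starting point (a, b, c, theta) for the optimizer.

        Stage 1 assumes no spatial trend: a0 is the pooled abundance
        sum(n)/sum(N) and theta is estimated analytically by the method of
        moments, clipped to [0.01, 1e4]. Stage 2 refits (a, b) with c and
        theta held fixed, so the full optimization starts from a reasonable
        linear trend.
        """
        n, N = self.endog, self.depth
        if n.size < 10:
            raise SpheromapError("need at least 10 cells to initialize")
        if n.sum() <= 0:
            raise SpheromapError("all-zero gene; filter before fitting")
        a0 = float(n.sum() / N.sum())
        mu = a0 * N
        denom = max(float(((n - mu) ** 2 - mu).sum()), 1e-12)
        theta0 = float(np.clip((mu**2).sum() / denom, 0.01, 1e4))

        # stage 2: optimize (x0, x1) only, c = 0, theta fixed
        s = self._scale
        t0 = np.log(theta0)

        def obj2(x2d):
            x = np.array([x2d[0], x2d[1], 0.0, t0])
            val, grad = self._neg_log_posterior(x)
            return val, grad[:2]

        res = scipy.optimize.minimize(
            obj2, np.array([a0 / s, 0.0]), jac=True, method="L-BFGS-B",
            options={"maxiter": 200},
        )
        a1, b1 = s * res.x[0], s * res.x[1]
        return np.array([a1, b1, 0.0, theta0])


def init_params(counts, cells) -> np.ndarray:
    """Functional alias: staged (a, b, c, theta) start for one gene."""
    return GeneRegulationModel(counts, cells).init_params()


class GeneRegulationResults:
    """MAP fit of a gene's spatial regulation function.

    Attributes
    ----------
    params : RegulationFunction
        MAP estimates (a, b, c).
    theta : float
        NB size (overdispersion) estimate.
    bse : dict
        Laplace standard errors for a, b, c and log theta (NaN when the
        Hessian at the optimum is not positive definite).
    llf : float
        Log likelihood at the MAP (priors excluded).
    logpost : float
        Log posterior at the MAP.
    converged : bool
        Optimizer success and finite estimates.
    """

    def __init__(self, model, params, theta, bse, llf, logpost, converged,
                 message="", cov_params=None):
        self.model = model
        self.params = params
        self.theta = theta
        self.bse = bse
        self.llf = llf
        self.logpost = logpost
        self.converged = converged
        self.message = message
        self.n_cells_used = model.endog.size
        self.gene_id = model.gene_id
        #: Laplace covariance of (a, b, c, log theta) at the MAP, or None
        self.cov_params = cov_params

    @property
    def se_a(self) -> float:
        return self.bse["a"]

    @property
    def se_b(self) -> float:
        return self.bse["b"]

    @property
    def se_c(self) -> float:
        return self.bse["c"]

    @property
    def se_log_theta(self) -> float:
        return self.bse["log_theta"]

    @property
    def has_se(self) -> bool:
        return bool(
            np.isfinite([self.se_a, self.se_b, self.se_c]).all()
            and self.se_b > 0
            and self.se_c > 0
        )

    @property
    def magnitude(self) -> float:
        return self.params.magnitude

    def predict(self, r) -> np.ndarray:
        """Fitted fractional abundance f(r)."""
        return self.params(r)

    def predicted_mean(self, r=None, depth=None) -> np.ndarray:
        """Expected UMI counts f(r) * N at the model's (or given) cells."""
        r = self.model.radial if r is None else np.asarray(r, dtype=float)
        depth = self.model.depth if depth is None else np.asarray(depth, dtype=float)
        return self.params(r) * depth

    def wald_test(self, method: str = "wald_joint") -> tuple[float, float, float]:
        """Two-sided Wald p-values for the b and c trends (see test_spatial)."""
        return test_spatial(self, method=method)

    def simulate(self, seed=None, cells=None) -> np.ndarray:
        """Posterior-predictive UMI counts at the observed (r, N) pairs.

        Draws NB(f(r_c)*N_c, theta) counts via the Gamma-Poisson mixture;
        overlaying these on the observed counts is the model's goodness-of-
        fit check.
        """
        if not self.converged:
            raise SpheromapError("cannot simulate from an unconverged fit")
        rng = np.random.default_rng(seed)
        if cells is None:
            r, N = self.model.radial, self.model.depth
        else:
            r, N = _split_cells(cells)
        mu = self.params(r) * N
        lam = rng.gamma(shape=self.theta, scale=mu / self.theta)
        return rng.poisson(lam)

    def summary(self) -> str:
        """Human-readable fit summary table."""
        p_b, p_c, p_gene = (np.nan, np.nan, np.nan)
        if self.converged and self.has_se:
            p_b, p_c, p_gene = self.wald_test()
        gid = self.gene_id or "<gene>"
        lines = [
            f"Spatial regulation fit: {gid}",
            "=" * 46,
            f"{'cells used':<22}{self.n_cells_used:>24}",
            f"{'converged':<22}{str(self.converged):>24}",
            f"{'log likelihood':<22}{self.llf:>24.2f}",
            "-" * 46,
            f"{'':<12}{'estimate':>12}{'std err':>11}{'p':>11}",
            f"{'a (core)':<12}{self.params.a:>12.4g}{self.se_a:>11.3g}{'':>11}",
            f"{'b (linear)':<12}{self.params.b:>12.4g}{self.se_b:>11.3g}{p_b:>11.3g}",
            f"{'c (quad.)':<12}{self.params.c:>12.4g}{self.se_c:>11.3g}{p_c:>11.3g}",
            f"{'theta (NB size)':<24}{self.theta:>22.4g}",
            f"{'magnitude':<24}{self.magnitude:>22.3f}",
            "=" * 46,
        ]
        return "\n".join(lines)


def _fit_impl(model: GeneRegulationModel, tol: float, maxiter: int
              ) -> GeneRegulationResults:
    s = model._scale
    start = model.init_params()
    x0 = np.array([start[0] / s, start[1] / s, start[2] / s, np.log(start[3])])
    bounds = [(None, None)] * 3 + [_LOG_THETA_BOUNDS]
    opt = scipy.optimize.minimize(
        model._neg_log_posterior,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-10},
    )
    x = opt.x
    a, b, c = s * x[0], s * x[1], s * x[2]
    theta = float(np.exp(x[3]))
    converged = bool(opt.success and np.isfinite(opt.fun))

    bse = {k: np.nan for k in ("a", "b", "c", "log_theta")}
    cov_params = None
    if converged:
        hess = _hessian_fd(model._neg_log_posterior, x)
        try:
            eigvals = np.linalg.eigvalsh(hess)
            if np.all(eigvals > 0):
                cov_x = np.linalg.inv(hess)
                scale_vec = np.array([s, s, s, 1.0])
                cov = cov_x * np.outer(scale_vec, scale_vec)
                var = np.diag(cov)
                if (var > 0).all():
                    cov_params = cov
                    se = np.sqrt(var)
                    bse = dict(zip(("a", "b", "c", "log_theta"), se))
        except np.linalg.LinAlgError:
            pass

    fn = RegulationFunction(a, b, c)
    llf = np.nan
    logpost = -float(opt.fun)
    if converged:
        g, _ = _safe_abundance(fn(model.radial), model.priors.floor)
        llf = float(nb_logpmf(model.endog, g * model.depth, theta).sum())
    return GeneRegulationResults(
        model, fn, theta, bse, llf, logpost, converged,
        message=str(opt.message), cov_params=cov_params,
    )


def _hessian_fd(fun_and_grad, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Hessian by central differences of the analytic gradient."""
    k = x.size
    hess = np.empty((k, k))
    for i in range(k):
        step = eps * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += step
        xm[i] -= step
        _, gp = fun_and_grad(xp)
        _, gm = fun_and_grad(xm)
        hess[i] = (gp - gm) / (2.0 * step)
    return 0.5 * (hess + hess.T)


def _model_fit(self, tol: float = 1e-8, maxiter: int = 500
               ) -> GeneRegulationResults:
    """MAP fit over (a, b, c, log theta) from the staged start.

    Never raises on non-convergence: the results carry ``converged=False``
    plus the optimizer message, and standard errors are NaN when the
    Hessian is not positive definite (such genes are excluded from spatial
    calling downstream).
    """
    try:
        return _fit_impl(self, tol, maxiter)
    except SpheromapError:
        raise
    except Exception as exc:  # noqa: BLE001 - diagnostics, not crash
        fn = RegulationFunction(self._scale, 0.0, 0.0)
        bse = {k: np.nan for k in ("a", "b", "c", "log_theta")}
        return GeneRegulationResults(
            self, fn, 1.0, bse, np.nan, np.nan, False, message=repr(exc)
        )


GeneRegulationModel.fit = _model_fit  # results class is defined below the model


def fit_gene(counts, cells, priors=None, gene_id=None, tol: float = 1e-8,
             maxiter: int = 500) -> GeneRegulationResults:
    """One-call per-gene fit (builds the model and fits it)."""
    return GeneRegulationModel(counts, cells, priors=priors, gene_id=gene_id).fit(
        tol=tol, maxiter=maxiter
    )


def test_spatial(
    fit: GeneRegulationResults, method: str = "wald_joint"
) -> tuple[float, float, float]:
    """Wald tests of the linear and quadratic trends.

    Returns (p_b, p_c, p_gene). p_b and p_c are the marginal two-sided
    Wald p-values p = 2*Phi(-|coef|/se). The gene-level p combines them:

    * ``"wald_joint"`` (default): 2-df Wald chi-square of (b, c) = (0, 0)
      using the Laplace covariance block. Because cells pile up near the
      periphery (density ~ r^2), r and r^2 are strongly collinear and the
      marginal SEs of b and c are inflated even when the spatial trend
      itself is sharply determined; the joint test restores that power.
    * ``"bonferroni"``: p_gene = min(1, 2*min(p_b, p_c)) — conservative by
      construction, never anti-conservative under the null.
    """
    if not fit.converged:
        raise SpheromapError("spatial test requires a converged fit")
    if not np.isfinite(fit.se_b) or not np.isfinite(fit.se_c):
        raise SpheromapError("standard errors unavailable (ill-conditioned Hessian)")
    if fit.se_b == 0 or fit.se_c == 0:
        raise SpheromapError("degenerate fit: zero standard error")
    p_b = float(2.0 * norm.sf(abs(fit.params.b) / fit.se_b))
    p_c = float(2.0 * norm.sf(abs(fit.params.c) / fit.se_c))
    if method == "bonferroni":
        p_gene = min(1.0, 2.0 * min(p_b, p_c))
    elif method == "wald_joint":
        if fit.cov_params is None:
            raise SpheromapError("covariance unavailable for the joint test")
        bc = np.array([fit.params.b, fit.params.c])
        cov_bc = fit.cov_params[1:3, 1:3]
        try:
            stat = float(bc @ np.linalg.solve(cov_bc, bc))
        except np.linalg.LinAlgError:
            raise SpheromapError("singular (b, c) covariance") from None
        p_gene = float(chi2.sf(stat, df=2))
    else:
        raise SpheromapError(f"unknown gene-level test {method!r}")
    return p_b, p_c, p_gene
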