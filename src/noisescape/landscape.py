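"""Reconstruction of continuous mean-noise fitness landscapes.

Fitness of promoter-gene strains is scattered irregularly in (log2 mean
expression, log2 noise CV) space, each observation carrying measurement
error in all three dimensions. A smooth landscape is recovered on a regular
grid by error-aware bivariate Gaussian smoothing: the weight of strain i at
grid point (x, y) is

    w = (1 / sigma_f_i**2) * integral N((mu,eta); (x,y), C_kernel)
                                    * N((mu,eta); (mu_i,eta_i), C_i) dmu deta

where C_kernel = diag(scale_mu**2, scale_eta**2) is the smoothing kernel and
C_i = diag(err_mu_i**2, err_eta_i**2) is the promoter's position-likelihood
covariance. The fitness at each grid point is the weight-averaged strain
fitness. Two weight evaluators are provided: the lattice Riemann sum on a
21 x 21 auxiliary grid with a 1% kernel-density cutoff (the default, for
fidelity to the original numerical scheme) and the exact closed form from
the Gaussian product identity (the fast option and the test oracle).

Kernel bandwidths are chosen by ten-fold cross-validation, minimising the
RMSE between held-out strain fitness and the landscape built from the
remaining strains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "Grid", "SmoothingKernel", "FitnessLandscape", "make_grid",
    "promoter_weight", "promoter_weights", "smooth_landscape",
    "landscape_uncertainty", "optimize_kernel", "LandscapeSmoother",
]

# grid points with summed weight below this are reported as undefined
MIN_TOTAL_WEIGHT = 1e-300

_EPS_LATTICE = 1e-9  # promoter errors below this collapse to a delta


@dataclass(frozen=True)
class Grid:
    """Regular rectangular grid over mean-noise space.

    ``mu`` and ``eta`` are the strictly increasing axis coordinates;
    ``wt_mu`` is the wild-type mean-expression anchor and always coincides
    with a grid column.
    """

    mu: np.ndarray
    eta: np.ndarray
    wt_mu: float

    def __post_init__(self):
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        object.__setattr__(self, "eta", np.asarray(self.eta, dtype=float))
        if np.any(np.diff(self.mu) <= 0) or np.any(np.diff(self.eta) <= 0):
            raise ValueError("grid axes must be strictly increasing")
        if np.min(np.abs(self.mu - self.wt_mu)) > 1e-9:
            raise ValueError("wt_mu must coincide with a grid column")

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.mu), len(self.eta)

    @property
    def n_points(self) -> int:
        return len(self.mu) * len(self.eta)

    @property
    def wt_index(self) -> int:
        return int(np.argmin(np.abs(self.mu - self.wt_mu)))


def make_grid(wt_mu: float, mean_halfwidth: float = 1.5,
              mean_step: float = 0.05, noise_lo: float = -3.0,
              noise_hi: float = -1.0, noise_step: float = 0.025) -> Grid:
    """Build the analysis grid around a gene's wild-type expression.

    The mean axis spans ``wt_mu +- mean_halfwidth`` and the noise axis
    ``[noise_lo, noise_hi]``, both with inclusive endpoints. Steps must
    divide the extents evenly; the standard parameters give 61 x 81 = 4941
    grid points.
    """
    def _steps(extent: float, step: float, what: str) -> int:
        k = extent / step
        if abs(k - round(k)) > 1e-9 * max(1.0, abs(k)):
            raise ValueError(f"{what} step {step} does not evenly divide "
                             f"extent {extent}")
        return int(round(k))

    k_mu = _steps(2.0 * mean_halfwidth, mean_step, "mean")
    k_eta = _steps(noise_hi - noise_lo, noise_step, "noise")
    mu = wt_mu - mean_halfwidth + mean_step * np.arange(k_mu + 1)
    eta = noise_lo + noise_step * np.arange(k_eta + 1)
    return Grid(mu=mu, eta=eta, wt_mu=wt_mu)


@dataclass(frozen=True)
class SmoothingKernel:
    """Bivariate Gaussian smoothing kernel, zero covariance.

    ``scale_mu`` and ``scale_eta`` are standard deviations in the mean and
    noise directions; the defaults are the cross-validation optima of the
    original study (0.602 and 0.361 log2 units).
    """

    scale_mu: float = 0.602
    scale_eta: float = 0.361

    def __post_init__(self):
        if self.scale_mu <= 0 or self.scale_eta <= 0:
            raise ValueError("kernel scales must be > 0")

    @property
    def var_mu(self) -> float:
        return self.scale_mu ** 2

    @property
    def var_eta(self) -> float:
        return self.scale_eta ** 2


@dataclass
class FitnessLandscape:
    """A smoothed fitness surface on a regular mean-noise grid.

    ``f`` has shape ``grid.shape``; entries are NaN wherever the summed
    smoothing weight fell below the representable floor. ``se`` (optional)
    is the weighted standard error of the mean fitness at each grid point.
    """

    grid: Grid
    f: np.ndarray
    total_weight: np.ndarray
    gene: str | None = None
    se: np.ndarray | None = None

    def __post_init__(self):
        self.f = np.asarray(self.f, dtype=float)
        if self.f.shape != self.grid.shape:
            raise ValueError("fitness array does not match grid shape")

    @property
    def wt_mu(self) -> float:
        return self.grid.wt_mu

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: gene, mu, eta, fitness, weight, se."""
        mm, ee = np.meshgrid(self.grid.mu, self.grid.eta, indexing="ij")
        out = pd.DataFrame({
            "gene": self.gene, "mu": mm.ravel(), "eta": ee.ravel(),
            "fitness": self.f.ravel(),
            "weight": self.total_weight.ravel(),
        })
        out["se"] = self.se.ravel() if self.se is not None else np.nan
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, wt_mu: float) -> "FitnessLandscape":
        mu = np.unique(frame["mu"].to_numpy())
        eta = np.unique(frame["eta"].to_numpy())
        grid = Grid(mu=mu, eta=eta, wt_mu=wt_mu)
        order = frame.sort_values(["mu", "eta"])
        f = order["fitness"].to_numpy().reshape(grid.shape)
        w = order["weight"].to_numpy().reshape(grid.shape)
        se = order["se"].to_numpy().reshape(grid.shape)
        gene = frame["gene"].iloc[0] if "gene" in frame else None
        return cls(grid=grid, f=f, total_weight=w, gene=gene, se=se)


# -- weights ---------------------------------------------------------------

def _norm_pdf(x: np.ndarray, var: np.ndarray | float) -> np.ndarray:
    return np.exp(-0.5 * x * x / var) / np.sqrt(2.0 * np.pi * var)


def _as_arrays(*vals) -> list[np.ndarray]:
    return [np.atleast_1d(np.asarray(v, dtype=float)) for v in vals]


def _closed_form_weights(mu, eta, err_mu, err_eta, sigma_f,
                         qmu: np.ndarray, qeta: np.ndarray,
                         kernel: SmoothingKernel) -> np.ndarray:
    """Exact integral weights at all (qmu x qeta) grid points.

    The integral of the product of two axis-aligned Gaussians is the normal
    density of their offset with summed covariance, which is separable per
    axis. Returns shape (n_strains, len(qmu), len(qeta)).
    """
    wmu = _norm_pdf(mu[:, None] - qmu[None, :],
                    kernel.var_mu + err_mu[:, None] ** 2)
    weta = _norm_pdf(eta[:, None] - qeta[None, :],
                     kernel.var_eta + err_eta[:, None] ** 2)
    return (wmu[:, :, None] * weta[:, None, :]
            / (sigma_f ** 2)[:, None, None])


def _aux_lattice(kernel: SmoothingKernel):
    """Masked auxiliary lattice offsets and kernel densities.

    21 x 21 lattice centred on the grid point with spacing
    0.3*sqrt(scale_mu) / 0.3*sqrt(scale_eta), keeping only offsets where the
    kernel density exceeds 1% of its central value.
    """
    step_mu = 0.3 * np.sqrt(kernel.scale_mu)
    step_eta = 0.3 * np.sqrt(kernel.scale_eta)
    idx = np.arange(-10, 11)
    dmu, deta = np.meshgrid(idx * step_mu, idx * step_eta, indexing="ij")
    q = dmu ** 2 / kernel.var_mu + deta ** 2 / kernel.var_eta
    keep = np.exp(-0.5 * q) > 0.01
    kdens = (np.exp(-0.5 * q[keep])
             / (2.0 * np.pi * kernel.scale_mu * kernel.scale_eta))
    return dmu[keep], deta[keep], kdens, step_mu * step_eta


def _auxiliary_weights(mu, eta, err_mu, err_eta, sigma_f,
                       qmu: np.ndarray, qeta: np.ndarray,
                       kernel: SmoothingKernel) -> np.ndarray:
    """Riemann-sum weights on the masked auxiliary lattice.

    Strains whose position errors are (numerically) zero are collapsed
    analytically — a delta likelihood cannot be resolved by a fixed lattice.
    """
    mu, eta, err_mu, err_eta, sigma_f = _as_arrays(
        mu, eta, err_mu, err_eta, sigma_f)
    dmu, deta, kdens, cell = _aux_lattice(kernel)
    n_s, n_x, n_y = len(mu), len(qmu), len(qeta)
    w = np.zeros((n_s, n_x, n_y))

    degenerate = (err_mu < _EPS_LATTICE) | (err_eta < _EPS_LATTICE)
    live = ~degenerate
    if np.any(live):
        ml, el = mu[live], eta[live]
        vmu, veta = err_mu[live] ** 2, err_eta[live] ** 2
        acc = np.zeros((live.sum(), n_x, n_y))
        for off_m, off_e, kd in zip(dmu, deta, kdens):
            a = _norm_pdf(qmu[None, :] + off_m - ml[:, None], vmu[:, None])
            b = _norm_pdf(qeta[None, :] + off_e - el[:, None], veta[:, None])
            acc += kd * a[:, :, None] * b[:, None, :]
        w[live] = acc * cell
    if np.any(degenerate):
        # delta-function likelihood: kernel density at the promoter offset
        dm = mu[degenerate][:, None] - qmu[None, :]
        de = eta[degenerate][:, None] - qeta[None, :]
        w[degenerate] = (_norm_pdf(dm, kernel.var_mu)[:, :, None]
                         * _norm_pdf(de, kernel.var_eta)[:, None, :])
    return w / (sigma_f ** 2)[:, None, None]


def promoter_weights(mu, eta, err_mu, err_eta, sigma_f, grid: Grid,
                     kernel: SmoothingKernel,
                     method: Literal["auxiliary", "closed_form"] = "auxiliary",
                     ) -> np.ndarray:
    """Smoothing weights of each strain at every grid point.

    Returns shape (n_strains, n_mu, n_eta). ``sigma_f`` must be strictly
    positive and position errors non-negative.
    """
    mu, eta, err_mu, err_eta, sigma_f = _as_arrays(
        mu, eta, err_mu, err_eta, sigma_f)
    if np.any(sigma_f <= 0):
        raise ValueError("fitness errors sigma_f must be > 0")
    if np.any(err_mu < 0) or np.any(err_eta < 0):
        raise ValueError("promoter position errors must be >= 0")
    if method == "closed_form":
        return _closed_form_weights(mu, eta, err_mu, err_eta, sigma_f,
                                    grid.mu, grid.eta, kernel)
    if method == "auxiliary":
        return _auxiliary_weights(mu, eta, err_mu, err_eta, sigma_f,
                                  grid.mu, grid.eta, kernel)
    raise ValueError(f"unknown weight method {method!r}")


def promoter_weight(mu: float, eta: float, err_mu: float, err_eta: float,
                    sigma_f: float, gridpoint: tuple[float, float],
                    kernel: SmoothingKernel,
                    method: Literal["auxiliary", "closed_form"] = "auxiliary",
                    ) -> float:
    """Weight of a single strain at a single grid point."""
    x, y = gridpoint
    fn = (_closed_form_weights if method == "closed_form"
          else _auxiliary_weights)
    if method not in ("auxiliary", "closed_form"):
        raise ValueError(f"unknown weight method {method!r}")
    mu_, eta_, emu, eeta, sf = _as_arrays(mu, eta, err_mu, err_eta, sigma_f)
    if np.any(sf <= 0):
        raise ValueError("fitness errors sigma_f must be > 0")
    return float(fn(mu_, eta_, emu, eeta, sf,
                    np.array([x]), np.array([y]), kernel)[0, 0, 0])


# -- smoothing -------------------------------------------------------------

def smooth_landscape(mu, eta, err_mu, err_eta, sigma_f, fitness,
                     grid: Grid, kernel: SmoothingKernel | None = None,
                     method: Literal["auxiliary", "closed_form"] = "auxiliary",
                     gene: str | None = None,
                     with_uncertainty: bool = False) -> FitnessLandscape:
    """Weighted-average fitness landscape over the grid.

    ``f(x, y) = sum_i f_i w_i(x, y) / sum_i w_i(x, y)``. Grid points whose
    total weight underflows are set to NaN.
    """
    kernel = kernel or SmoothingKernel()
    fitness = np.atleast_1d(np.asarray(fitness, dtype=float))
    if fitness.size < 1:
        raise ValueError("at least one strain is required")
    w = promoter_weights(mu, eta, err_mu, err_eta, sigma_f, grid, kernel,
                         method)
    tw = w.sum(axis=0)
    defined = tw > MIN_TOTAL_WEIGHT
    f = np.full(grid.shape, np.nan)
    f[defined] = np.tensordot(fitness, w, axes=(0, 0))[defined] / tw[defined]
    se = None
    if with_uncertainty:
        sf = np.atleast_1d(np.asarray(sigma_f, dtype=float))
        se = np.full(grid.shape, np.nan)
        num = np.sqrt(np.tensordot(sf ** 2, w ** 2, axes=(0, 0))[defined])
        se[defined] = num / tw[defined]
    return FitnessLandscape(grid=grid, f=f, total_weight=tw, gene=gene, se=se)


def landscape_uncertainty(mu, eta, err_mu, err_eta, sigma_f, grid: Grid,
                          kernel: SmoothingKernel | None = None,
                          method: Literal["auxiliary", "closed_form"] = "auxiliary",
                          ) -> np.ndarray:
    """Weighted standard error of the landscape: sqrt(sum w^2 s^2)/sum w."""
    kernel = kernel or SmoothingKernel()
    w = promoter_weights(mu, eta, err_mu, err_eta, sigma_f, grid, kernel,
                         method)
    sf = np.atleast_1d(np.asarray(sigma_f, dtype=float))
    tw = w.sum(axis=0)
    out = np.full(grid.shape, np.nan)
    defined = tw > MIN_TOTAL_WEIGHT
    out[defined] = (np.sqrt(np.tensordot(sf ** 2, w ** 2, axes=(0, 0)))[defined]
                    / tw[defined])
    return out


# -- kernel cross-validation ----------------------------------------------

def _predict_at_points(train_idx, qmu, qeta, mu, eta, err_mu, err_eta,
                       sigma_f, fitness, kernel) -> np.ndarray:
    """Closed-form landscape prediction at arbitrary query points."""
    wmu = _norm_pdf(mu[train_idx][:, None] - qmu[None, :],
                    kernel.var_mu + err_mu[train_idx][:, None] ** 2)
    weta = _norm_pdf(eta[train_idx][:, None] - qeta[None, :],
                     kernel.var_eta + err_eta[train_idx][:, None] ** 2)
    w = wmu * weta / (sigma_f[train_idx] ** 2)[:, None]
    tw = w.sum(axis=0)
    pred = np.full(len(qmu), np.nan)
    ok = tw > MIN_TOTAL_WEIGHT
    pred[ok] = (fitness[train_idx] @ w)[ok] / tw[ok]
    return pred


def _cv_rmse(scale_mu, scale_eta, folds_idx, mu, eta, err_mu, err_eta,
             sigma_f, fitness, grid) -> float:
    kernel = SmoothingKernel(scale_mu=scale_mu, scale_eta=scale_eta)
    sq, n = 0.0, 0
    for held in folds_idx:
        train = np.setdiff1d(np.arange(len(mu)), held, assume_unique=True)
        # evaluate at the nearest grid point to each held-out promoter
        snap = np.abs(mu[held][:, None] - grid.mu[None, :]).argmin(axis=1)
        qmu = grid.mu[snap]
        snap_e = np.abs(eta[held][:, None] - grid.eta[None, :]).argmin(axis=1)
        qeta = grid.eta[snap_e]
        pred = _predict_at_points(train, qmu, qeta, mu, eta, err_mu, err_eta,
                                  sigma_f, fitness, kernel)
        ok = np.isfinite(pred)
        sq += float(np.sum((pred[ok] - fitness[held][ok]) ** 2))
        n += int(ok.sum())
    if n == 0:
        return np.nan
    return np.sqrt(sq / n)


def optimize_kernel(mu, eta, err_mu, err_eta, sigma_f, fitness, grid: Grid,
                    folds: int = 10, seed: int = 0,
                    scale_mu_grid: Sequence[float] | None = None,
                    scale_eta_grid: Sequence[float] | None = None,
                    refine: int = 2) -> tuple[SmoothingKernel, pd.DataFrame]:
    """Choose kernel bandwidths by k-fold cross-validation.

    A log-spaced grid over (scale_mu, scale_eta) is scanned and the best
    point refined by two rounds of local log-space search. Held-out strain
    fitness is predicted from the landscape built on the remaining strains,
    evaluated at the held-out promoter's nearest grid point. Ties break
    toward smaller bandwidths. Returns the optimum and the full CV-RMSE
    profile.
    """
    mu, eta, err_mu, err_eta, sigma_f, fitness = _as_arrays(
        mu, eta, err_mu, err_eta, sigma_f, fitness)
    n = len(mu)
    if n < folds:
        raise ValueError("need at least as many strains as folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds_idx = np.array_split(perm, folds)

    if scale_mu_grid is None:
        scale_mu_grid = np.geomspace(0.08, 1.6, 6)
    if scale_eta_grid is None:
        scale_eta_grid = np.geomspace(0.05, 1.0, 6)

    records: list[tuple[float, float, float]] = []

    def _eval(sm: float, se: float) -> float:
        for pm, pe, r in records:
            if abs(pm - sm) < 1e-12 and abs(pe - se) < 1e-12:
                return r
        r = _cv_rmse(sm, se, folds_idx, mu, eta, err_mu, err_eta, sigma_f,
                     fitness, grid)
        records.append((sm, se, r))
        return r

    for sm in scale_mu_grid:
        for se in scale_eta_grid:
            _eval(float(sm), float(se))

    def _best() -> tuple[float, float, float]:
        finite = [r for r in records if np.isfinite(r[2])]
        if not finite:
            raise ValueError("all kernel candidates produced undefined "
                             "predictions")
        return min(finite, key=lambda r: (r[2], r[0], r[1]))

    for _ in range(refine):
        bm, be, _ = _best()
        for sm in bm * np.array([0.7, 0.85, 1.0, 1.18, 1.43]):
            for se in be * np.array([0.7, 0.85, 1.0, 1.18, 1.43]):
                _eval(float(sm), float(se))

    bm, be, _ = _best()
    profile = pd.DataFrame(records,
                           columns=["scale_mu", "scale_eta", "cv_rmse"])
    return SmoothingKernel(scale_mu=bm, scale_eta=be), profile


# -- sklearn-style estimator ----------------------------------------------

class LandscapeSmoother(BaseEstimator, RegressorMixin):
    """Error-aware Gaussian kernel smoother as a scikit-learn regressor.

    Training samples are strains: ``X`` has columns
    ``(mu, eta, err_mu, err_eta, sigma_f)`` and ``y`` is measured fitness.
    ``predict`` evaluates the smoothed surface at query positions (columns
    ``mu, eta``) using the closed-form weights; ``to_landscape`` renders a
    full :class:`FitnessLandscape` on a grid with the configured weight
    method.

    Parameters
    ----------
    scale_mu, scale_eta : float
        Kernel standard deviations (log2 units).
    method : {"auxiliary", "closed_form"}
        Weight evaluator used by :meth:`to_landscape`.
    """

    def __init__(self, scale_mu: float = 0.602, scale_eta: float = 0.361,
                 method: str = "auxiliary"):
        self.scale_mu = scale_mu
        self.scale_eta = scale_eta
        self.method = method

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 5:
            raise ValueError("X must have columns "
                             "(mu, eta, err_mu, err_eta, sigma_f)")
        if len(X) != len(y):
            raise ValueError("X and y have different lengths")
        if np.any(X[:, 4] <= 0):
            raise ValueError("sigma_f column must be > 0")
        self.X_ = X
        self.y_ = y
        self.kernel_ = SmoothingKernel(scale_mu=self.scale_mu,
                                       scale_eta=self.scale_eta)
        return self

    def predict(self, X):
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "X_")
        X = np.asarray(X, dtype=float)
        mu, eta, err_mu, err_eta, sigma_f = self.X_.T
        return _predict_at_points(np.arange(len(self.y_)), X[:, 0], X[:, 1],
                                  mu, eta, err_mu, err_eta, sigma_f,
                                  self.y_, self.kernel_)

    def to_landscape(self, grid: Grid, gene: str | None = None,
                     with_uncertainty: bool = False) -> FitnessLandscape:
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "X_")
        mu, eta, err_mu, err_eta, sigma_f = self.X_.T
        return smooth_landscape(mu, eta, err_mu, err_eta, sigma_f, self.y_,
                                grid, self.kernel_, method=self.method,
                                gene=gene, with_uncertainty=with_uncertainty)
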