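"""Expression sensitivity, noise intolerance and their statistics.

Two slope metrics summarise each gene's landscape:

* expression sensitivity — the mean absolute slope of fitness along the
  mean-expression axis at minimal noise (log2 CV = -3), i.e. the average
  fitness loss per two-fold change of mean expression;
* noise intolerance — minus the mean slope of fitness along the noise axis
  at wild-type mean expression, i.e. the average fitness loss per two-fold
  increase of noise (negative when noise is beneficial; never clipped).

Significance is assessed by permuting fitness values across a gene's
strains, rebuilding the landscape with the same smoothing weights, and
taking the fraction of permuted metrics >= the observed one; q-values come
from the Benjamini-Hochberg step-up. Alternative estimates (partial
correlations on the raw strain data, the 5%-fitness-drop curvature
distance) and the comparison against endogenous noise (running-median DM
correction, one-sided Spearman permutation tests aggregated with Fisher's
method) live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .landscape import (FitnessLandscape, Grid, SmoothingKernel,
                        MIN_TOTAL_WEIGHT, _norm_pdf, _as_arrays)

MIN_PERMUTATIONS = 100


# -- slope metrics ---------------------------------------------------------

def _slope_metric_rows(rows: np.ndarray, axis_coords: np.ndarray,
                       kind: str) -> np.ndarray:
    grad = np.gradient(rows, axis_coords, axis=-1)
    if kind == "sensitivity":
        return np.mean(np.abs(grad), axis=-1)
    return -np.mean(grad, axis=-1)


def expression_sensitivity(landscape: FitnessLandscape) -> float:
    """Mean |df/dmu| along the minimal-noise row, per two-fold change."""
    row = landscape.f[:, 0]
    if not np.all(np.isfinite(row)):
        raise ValueError("landscape undefined along the minimal-noise row")
    return float(_slope_metric_rows(row[None, :], landscape.grid.mu,
                                    "sensitivity")[0])


def noise_intolerance(landscape: FitnessLandscape) -> float:
    """Minus the mean df/deta along the wild-type column, per two-fold."""
    col = landscape.f[landscape.grid.wt_index, :]
    if not np.all(np.isfinite(col)):
        raise ValueError("landscape undefined along the wild-type column")
    return float(_slope_metric_rows(col[None, :], landscape.grid.eta,
                                    "intolerance")[0])


# -- permutation machinery -------------------------------------------------

@dataclass
class LineWeights:
    """Closed-form smoothing weights restricted to the two metric lines.

    Permuting fitness labels leaves the weights (and hence the denominators)
    unchanged, so landscapes for thousands of randomizations reduce to
    matrix products against these two small weight matrices.
    """

    w_row: np.ndarray   # (n_strains, n_mu)   at eta = noise floor
    w_col: np.ndarray   # (n_strains, n_eta)  at mu = wild type
    mu: np.ndarray
    eta: np.ndarray

    @classmethod
    def build(cls, mu, eta, err_mu, err_eta, sigma_f, grid: Grid,
              kernel: SmoothingKernel) -> "LineWeights":
        mu, eta, err_mu, err_eta, sigma_f = _as_arrays(
            mu, eta, err_mu, err_eta, sigma_f)
        vmu = kernel.var_mu + err_mu[:, None] ** 2
        veta = kernel.var_eta + err_eta[:, None] ** 2
        wmu = _norm_pdf(mu[:, None] - grid.mu[None, :], vmu)
        weta = _norm_pdf(eta[:, None] - grid.eta[None, :], veta)
        inv_var_f = 1.0 / sigma_f ** 2
        w_row = wmu * (weta[:, [0]]) * inv_var_f[:, None]
        w_col = weta * (wmu[:, [grid.wt_index]]) * inv_var_f[:, None]
        return cls(w_row=w_row, w_col=w_col, mu=grid.mu, eta=grid.eta)

    def metrics(self, fitness: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(sensitivity, intolerance) for one or many fitness vectors.

        ``fitness`` has shape (n_strains,) or (n_sets, n_strains).
        """
        f = np.atleast_2d(np.asarray(fitness, dtype=float))
        tw_row = self.w_row.sum(axis=0)
        tw_col = self.w_col.sum(axis=0)
        if np.any(tw_row <= MIN_TOTAL_WEIGHT) or np.any(tw_col <= MIN_TOTAL_WEIGHT):
            raise ValueError("metric lines undefined: zero smoothing weight")
        rows = f @ self.w_row / tw_row
        cols = f @ self.w_col / tw_col
        sens = _slope_metric_rows(rows, self.mu, "sensitivity")
        intol = _slope_metric_rows(cols, self.eta, "intolerance")
        if np.ndim(fitness) == 1:
            return float(sens[0]), float(intol[0])
        return sens, intol


def permutation_pvalue(observed: float, permuted: np.ndarray) -> float:
    """Fraction of permuted values >= observed (no smoothing, floor 1/n)."""
    permuted = np.asarray(permuted, dtype=float)
    return float(np.mean(permuted >= observed))


def permutation_null(fitness, line_weights: LineWeights,
                     n: int = 10_000, seed: int = 0) -> dict:
    """Permutation test of both slope metrics for one gene.

    Fitness values are shuffled across the gene's strains ``n`` times; the
    landscape (restricted to the two metric lines) is rebuilt with the
    unchanged weights and both metrics recomputed. p-values are the
    fractions of permuted metrics >= observed.
    """
    fitness = np.asarray(fitness, dtype=float)
    if len(fitness) < 2:
        raise ValueError("need >= 2 strains to permute")
    if n < MIN_PERMUTATIONS:
        raise ValueError(f"n must be >= {MIN_PERMUTATIONS} for any "
                         "p-value resolution")
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(fitness, (n, 1)), axis=1)
    sens_obs, intol_obs = line_weights.metrics(fitness)
    sens_perm, intol_perm = line_weights.metrics(perms)
    return {
        "sensitivity": sens_obs,
        "intolerance": intol_obs,
        "p_sens": permutation_pvalue(sens_obs, sens_perm),
        "p_noise": permutation_pvalue(intol_obs, intol_perm),
        "perm_sens": sens_perm,
        "perm_noise": intol_perm,
        "n_permutations": n,
    }


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def metric_correlation_test(sens, intol, perm_sens: np.ndarray,
                            perm_intol: np.ndarray) -> tuple[float, float]:
    """Cross-gene Pearson correlation of the two metrics, permutation p.

    ``perm_sens``/``perm_intol`` have shape (n_genes, n_runs): the per-gene
    permuted metrics from the same randomization runs. p is the fraction of
    runs whose cross-gene correlation >= the observed one.
    """
    sens = np.asarray(sens, dtype=float)
    intol = np.asarray(intol, dtype=float)
    if len(sens) < 3:
        raise ValueError("need >= 3 genes")
    r_obs = float(np.corrcoef(sens, intol)[0, 1])
    ps = np.asarray(perm_sens, dtype=float)
    pi = np.asarray(perm_intol, dtype=float)
    ps_c = ps - ps.mean(axis=0)
    pi_c = pi - pi.mean(axis=0)
    denom = np.sqrt((ps_c ** 2).sum(axis=0) * (pi_c ** 2).sum(axis=0))
    r_perm = (ps_c * pi_c).sum(axis=0) / denom
    return r_obs, float(np.mean(r_perm >= r_obs))


# -- partial correlations on raw strain data -------------------------------

def _residuals(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    slope, intercept = np.polyfit(x, y, 1)
    return y - (slope * x + intercept)


def partial_correlation_metrics(mu, eta, fitness) -> dict:
    """First-order Pearson partial correlations of fitness with mean/noise.

    ``r_mean`` controls for noise, ``r_noise`` for mean, both via the
    residual method; two-sided p from the t transform with n - 3 degrees of
    freedom. Degenerate inputs (no variance left) are reported as r = 0,
    p = 1 with ``degenerate=True`` so cross-gene FDR stays well defined.
    """
    mu, eta, f = _as_arrays(mu, eta, fitness)
    n = len(f)
    if n < 4:
        raise ValueError("need >= 4 strains for a partial correlation")

    def _partial(target: np.ndarray, control: np.ndarray
                 ) -> tuple[float, float, bool]:
        if np.ptp(control) == 0 or np.ptp(target) == 0 or np.ptp(f) == 0:
            return 0.0, 1.0, True
        rf = _residuals(f, control)
        rt = _residuals(target, control)
        sf, st = rf.std(), rt.std()
        # residuals at numerical-noise level mean the controlled variable
        # explains everything: report as degenerate, not as spurious r
        if sf < 1e-10 * f.std() or st < 1e-10 * target.std():
            return 0.0, 1.0, True
        r = float(np.corrcoef(rf, rt)[0, 1])
        r = np.clip(r, -1.0, 1.0)
        if abs(r) == 1.0:
            return r, 0.0, False
        t = r * np.sqrt((n - 3) / (1.0 - r ** 2))
        p = 2.0 * stats.t.sf(abs(t), df=n - 3)
        return r, float(p), False

    r_mean, p_mean, d1 = _partial(mu, eta)
    r_noise, p_noise, d2 = _partial(eta, mu)
    return {"r_mean": r_mean, "p_mean": p_mean,
            "r_noise": r_noise, "p_noise": p_noise,
            "degenerate": d1 or d2}


# -- curvature metric ------------------------------------------------------

def expression_curvature(mu_axis, curve, wt_mu: float,
                         drop: float = 0.05) -> float:
    """Minimal |mu - wt| at which fitness drops ``drop`` below wild type.

    Returns +inf when the drop is never reached (flat or shallow curves).
    """
    mu_axis = np.asarray(mu_axis, dtype=float)
    curve = np.asarray(curve, dtype=float)
    idx = int(np.argmin(np.abs(mu_axis - wt_mu)))
    if abs(mu_axis[idx] - wt_mu) > 1e-9:
        raise ValueError("curve is not defined at wild-type expression")
    below = curve <= curve[idx] - drop + 1e-12
    if not np.any(below):
        return float("inf")
    return float(np.min(np.abs(mu_axis[below] - wt_mu)))


# -- endogenous-noise comparison -------------------------------------------

def dm_correct(noise, expression, window_fraction: float = 0.5) -> np.ndarray:
    """Distance-from-median noise: remove the mean-noise trend.

    Subtracts from each gene's noise the running median of noise over an
    expression-rank window (odd-sized, fraction of all points, truncated at
    the edges).
    """
    noise = np.asarray(noise, dtype=float)
    expression = np.asarray(expression, dtype=float)
    n = len(noise)
    if n < 5:
        raise ValueError("need >= 5 points for a running median")
    w = max(3, int(round(window_fraction * n)))
    if w % 2 == 0:
        w += 1
    half = w // 2
    order = np.argsort(expression, kind="stable")
    sorted_noise = noise[order]
    med = np.empty(n)
    for k in range(n):
        lo, hi = max(0, k - half), min(n, k + half + 1)
        med[k] = np.median(sorted_noise[lo:hi])
    dm = np.empty(n)
    dm[order] = sorted_noise - med
    return dm


@dataclass
class EndogenousNoiseComparison:
    """Spearman comparison of a landscape metric to endogenous noise."""

    rho: dict[str, float] = field(default_factory=dict)
    p: dict[str, float] = field(default_factory=dict)
    fisher_stat: float = float("nan")
    fisher_p: float = float("nan")
    df: int = 0


def endogenous_comparison(datasets: dict[str, tuple[np.ndarray, np.ndarray]],
                          n_perm: int = 10_000,
                          seed: int = 0) -> EndogenousNoiseComparison:
    """Test whether a metric anti-correlates with endogenous noise.

    ``datasets`` maps a dataset name to the aligned pair (metric values,
    DM-corrected noise) over the genes shared with that dataset. For each
    dataset the Spearman rho and a one-sided permutation p (alternative
    rho < 0, with add-one smoothing so Fisher's method stays finite) are
    computed; the per-dataset p-values are aggregated as -2*sum(ln p)
    against chi-square with 2k degrees of freedom.
    """
    rng = np.random.default_rng(seed)
    out = EndogenousNoiseComparison()
    for name, (metric, dm) in datasets.items():
        metric = np.asarray(metric, dtype=float)
        dm = np.asarray(dm, dtype=float)
        if len(metric) < 5:
            raise ValueError(f"dataset {name!r}: need >= 5 overlapping genes")
        rho = stats.spearmanr(metric, dm).statistic
        perm_rho = np.empty(n_perm)
        for k in range(n_perm):
            perm_rho[k] = stats.spearmanr(rng.permutation(metric),
                                          dm).statistic
        p = (np.sum(perm_rho <= rho) + 1.0) / (n_perm + 1.0)
        out.rho[name] = float(rho)
        out.p[name] = float(p)
    k = len(datasets)
    out.fisher_stat = float(-2.0 * np.sum(np.log(list(out.p.values()))))
    out.df = 2 * k
    out.fisher_p = float(stats.chi2.sf(out.fisher_stat, out.df))
    return out


# -- per-gene driver -------------------------------------------------------

def gene_metrics_table(per_gene: dict[str, dict]) -> pd.DataFrame:
    """Assemble the cross-gene metrics table and add BH q-values.

    ``per_gene`` maps gene -> dict with at least ``sensitivity``,
    ``intolerance``, ``p_sens``, ``p_noise`` (e.g. from
    :func:`permutation_null`), optionally ``curvature``, ``partial_r_mean``
    and ``partial_r_noise``.
    """
    genes = list(per_gene)
    rows = pd.DataFrame({
        "gene": genes,
        "sensitivity": [per_gene[g]["sensitivity"] for g in genes],
        "intolerance": [per_gene[g]["intolerance"] for g in genes],
        "p_sens": [per_gene[g]["p_sens"] for g in genes],
        "p_noise": [per_gene[g]["p_noise"] for g in genes],
    })
    rows["q_sens"] = bh_fdr(rows["p_sens"])
    rows["q_noise"] = bh_fdr(rows["p_noise"])
    for extra in ("curvature", "partial_r_mean", "partial_r_noise"):
        if all(extra in per_gene[g] for g in genes):
            rows[extra] = [per_gene[g][extra] for g in genes]
    return rows
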