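"""Synthetic study generator.

Fabricates the three ingredients of a pooled promoter-swap competition study
so that every downstream stage of the analysis can be exercised without any
external download:

* a panel of synthetic promoters positioned in (log2 mean expression,
  log2 noise CV) space, with negatively coupled noise and per-promoter
  measurement errors;
* gene-specific ground-truth fitness landscapes, built as the expectation of
  a per-cell fitness function over a log-normal protein-abundance
  distribution — so that noise intolerance follows from concavity (Jensen)
  rather than being assumed;
* read-count tables from deterministic exponential competitive growth with
  Poisson sequencing noise.

The defaults emulate the study conditions: ~120 promoters spanning a 16-fold
expression range (2-6 log2 units) and a ~4-fold noise range (log2 CV in
[-3, -1]), wild-type noise mid-range, and competitive growth sampled at 0,
23 and 35 h with ~10 generations elapsed by 23 h.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.interpolate import RegularGridInterpolator

from .landscape import Grid

WILDTYPE_GENE = "WT"

# log2 CV domain of the analysis grid; generated panels are clipped to it
NOISE_LO = -3.0
NOISE_HI = -1.0

_GH_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gh_nodes(order: int) -> tuple[np.ndarray, np.ndarray]:
    if order not in _GH_CACHE:
        _GH_CACHE[order] = hermgauss(order)
    return _GH_CACHE[order]


class QuadratureError(RuntimeError):
    """Raised when the Gauss-Hermite expectation has not converged."""


@dataclass(frozen=True)
class GroundTruthLandscape:
    """Ground-truth population fitness over mean-noise expression space.

    Per-cell fitness of a cell with protein abundance ``x`` (linear scale,
    ``x = 2**mu`` at zero noise)::

        w(x) = baseline - lam_shortage / (1 + (x/K)**h)
                        - lam_surplus * (x/S)**g / (1 + (x/S)**g)

    with shortage half-saturation ``K`` and Hill coefficient ``h``, and
    surplus half-saturation ``S`` and Hill coefficient ``g``. The shortage
    term is a saturating penalty for too little protein, the surplus term a
    saturating penalty for too much; both weights >= 0 give a peaked
    per-cell optimum. With sharp (Hill-type) saturation ``w`` is concave
    around typical abundances, so the expectation over a wider distribution
    -- population fitness, defined as E[w(X)] for log-normal X with mean
    ``2**mu`` and coefficient of variation ``2**eta`` -- decreases with
    noise (Jensen), which is what makes these truths noise-intolerant.
    """

    wt_log2_mean: float
    shortage_halfsat: float = 12.0
    shortage_hill: float = 8.0
    surplus_halfsat: float = 20.0
    surplus_hill: float = 8.0
    lam_shortage: float = 0.09
    lam_surplus: float = 0.0
    wt_log2_cv: float = -2.0
    baseline: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.wt_log2_mean, self.shortage_halfsat, self.shortage_hill,
                self.surplus_halfsat, self.surplus_hill, self.lam_shortage,
                self.lam_surplus, self.wt_log2_cv, self.baseline)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("ground-truth parameters must be finite")
        if self.lam_shortage < 0:
            raise ValueError("shortage weight must be >= 0")

    # -- per-cell fitness -------------------------------------------------
    def percell_fitness(self, x: np.ndarray | float) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        shortage = self.lam_shortage / (
            1.0 + (x / self.shortage_halfsat) ** self.shortage_hill)
        u = (x / self.surplus_halfsat) ** self.surplus_hill
        surplus = self.lam_surplus * u / (1.0 + u)
        return self.baseline - shortage - surplus

    # -- population fitness ----------------------------------------------
    def population_fitness(self, mu, eta, order: int = 120,
                           rtol: float = 1e-6) -> np.ndarray:
        """Expectation of per-cell fitness over the log-normal distribution.

        Computed by Gauss-Hermite quadrature in log-abundance space; the
        result is checked against a doubled-order rule and a
        :class:`QuadratureError` is raised if the relative difference
        exceeds ``rtol``.
        """
        mu = np.asarray(mu, dtype=float)
        eta = np.asarray(eta, dtype=float)
        if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(eta))):
            raise ValueError("mu and eta must be finite")
        lo = self._quad(mu, eta, order)
        hi = self._quad(mu, eta, 2 * order)
        # mixed criterion: fitness is O(1), so near-zero relative values are
        # compared on an absolute floor
        scale = np.maximum(np.abs(hi), 1e-3)
        if np.any(np.abs(hi - lo) / scale > rtol):
            raise QuadratureError(
                "Gauss-Hermite expectation did not converge; "
                "increase the quadrature order")
        return hi

    def _quad(self, mu: np.ndarray, eta: np.ndarray, order: int) -> np.ndarray:
        z, w = _gh_nodes(order)
        cv2 = np.exp2(2.0 * eta)
        s2 = np.log1p(cv2)
        a = mu * np.log(2.0) - s2 / 2.0
        # X = exp(a + s*Z), Z ~ N(0,1); E[w(X)] = sum_i w_i f(sqrt(2) z_i)/sqrt(pi)
        log_x = a[..., None] + np.sqrt(2.0 * s2)[..., None] * z
        vals = self.percell_fitness(np.exp(log_x))
        return vals @ w / np.sqrt(np.pi)

    def relative_fitness(self, mu, eta) -> np.ndarray:
        """Population fitness relative to the wild-type promoter position."""
        wt = self.population_fitness(self.wt_log2_mean, self.wt_log2_cv)
        return self.population_fitness(mu, eta) - wt

    def surface(self, grid: Grid, relative: bool = True) -> np.ndarray:
        """Evaluate the landscape on a grid; shape (n_mu, n_eta)."""
        mm, ee = np.meshgrid(grid.mu, grid.eta, indexing="ij")
        f = self.relative_fitness if relative else self.population_fitness
        return np.asarray(f(mm, ee))


def landscape_fitness(truth: GroundTruthLandscape, mu: float, eta: float) -> float:
    """Population fitness of a ground truth at one mean-noise position."""
    return float(truth.population_fitness(mu, eta))


# convenience archetypes -------------------------------------------------

def shortage_truth(wt_log2_mean: float = 4.0, lam: float = 0.09,
                   **kw) -> GroundTruthLandscape:
    """Pure protein-shortage sensitivity (monotone increasing in mean)."""
    return GroundTruthLandscape(wt_log2_mean, lam_shortage=lam,
                                lam_surplus=0.0, **kw)


def surplus_truth(wt_log2_mean: float = 4.0, lam: float = 0.07,
                  **kw) -> GroundTruthLandscape:
    """Pure protein-surplus sensitivity (monotone decreasing in mean)."""
    return GroundTruthLandscape(wt_log2_mean, lam_shortage=0.0,
                                lam_surplus=lam, **kw)


def peaked_truth(wt_log2_mean: float = 4.0, lam_shortage: float = 0.09,
                 lam_surplus: float = 0.07, **kw) -> GroundTruthLandscape:
    """Sensitivity to both shortage and surplus: an interior optimum."""
    return GroundTruthLandscape(wt_log2_mean, lam_shortage=lam_shortage,
                                lam_surplus=lam_surplus, **kw)


# -- promoter panel -------------------------------------------------------

@dataclass(frozen=True)
class SyntheticPanelConfig:
    """Conditions for the synthetic promoter panel.

    ``noise_coupling_slope`` is the change in log2 CV per log2-mean unit
    (negative: burst-frequency-dominated promoter variation couples higher
    expression to lower noise). The intercept is anchored so that a promoter
    at the centre of ``mean_range`` sits at log2 CV = -2, the middle of the
    analysis noise range. ``error_sds`` are the baseline measurement error
    s.d. for (mean, noise, fitness); per-promoter error estimates scatter
    log-normally around the first two.
    """

    n_promoters: int = 120
    mean_range: tuple[float, float] = (2.0, 6.0)
    noise_coupling_slope: float = -0.3
    noise_scatter_sd: float = 0.58
    error_sds: tuple[float, float, float] = (0.2, 0.15, 0.01)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.mean_range
        nums = (lo, hi, self.noise_coupling_slope, self.noise_scatter_sd,
                *self.error_sds)
        if not all(np.isfinite(v) for v in nums):
            raise ValueError("panel configuration values must be finite")
        if self.n_promoters < 1:
            raise ValueError("n_promoters must be >= 1")
        if not lo < hi:
            raise ValueError("mean_range must satisfy low < high")
        if any(s < 0 for s in self.error_sds):
            raise ValueError("error s.d. values must be >= 0")


def generate_promoter_panel(config: SyntheticPanelConfig) -> pd.DataFrame:
    """Draw a promoter panel in mean-noise space.

    Returns a frame with the measured coordinates (``log2_mean``,
    ``log2_cv``), their per-promoter error estimates (``err_mean``,
    ``err_cv``) and, for testing against ground truth, the latent true
    coordinates (``true_log2_mean``, ``true_log2_cv``). Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.mean_range
    n = config.n_promoters
    centre = 0.5 * (lo + hi)
    intercept = -2.0 - config.noise_coupling_slope * centre

    true_mu = rng.uniform(lo, hi, size=n)
    # bounded scatter (uniform with matching s.d.): the analysis window is
    # the region the promoter panel populates homogeneously, so promoters
    # cover the full noise range at every mean rather than a thin ridge
    half = np.sqrt(3.0) * config.noise_scatter_sd
    true_eta = (intercept + config.noise_coupling_slope * true_mu
                + rng.uniform(-half, half, size=n))
    true_eta = np.clip(true_eta, NOISE_LO, NOISE_HI)

    # bounded scatter: the analysis consumes loess-smoothed error
    # estimates, whose dynamic range across promoters is limited
    s_mu, s_eta, _ = config.error_sds
    err_mu = s_mu * rng.uniform(0.7, 1.5, size=n)
    err_eta = s_eta * rng.uniform(0.7, 1.5, size=n)

    mu = np.clip(true_mu + rng.normal(0.0, 1.0, size=n) * err_mu, lo, hi)
    eta = np.clip(true_eta + rng.normal(0.0, 1.0, size=n) * err_eta,
                  NOISE_LO, NOISE_HI)

    ids = [f"P{i + 1:03d}" for i in range(n)]
    return pd.DataFrame({
        "promoter_id": ids,
        "log2_mean": mu,
        "log2_cv": eta,
        "err_mean": err_mu,
        "err_cv": err_eta,
        "true_log2_mean": true_mu,
        "true_log2_cv": true_eta,
    })


# -- strain fitness and read counts ---------------------------------------

def generate_strain_fitness(panel: pd.DataFrame,
                            truths: Mapping[str, GroundTruthLandscape],
                            sigma_f: float = 0.01,
                            seed: int = 0) -> pd.DataFrame:
    """Per-strain measured fitness directly from the ground truths.

    Bypasses the read-count layer: the true fitness of promoter i driving
    gene j is the truth landscape evaluated at the promoter's *true*
    position, and the measurement adds Gaussian noise with a per-strain
    error that scatters log-normally around ``sigma_f``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gene, truth in truths.items():
        true_f = np.asarray(truth.relative_fitness(
            panel["true_log2_mean"].to_numpy(),
            panel["true_log2_cv"].to_numpy()))
        err = sigma_f * np.exp(rng.normal(0.0, 0.3, size=len(panel)))
        meas = true_f + rng.normal(0.0, 1.0, size=len(panel)) * err
        rows.append(pd.DataFrame({
            "strain_id": [f"{p}:{gene}" for p in panel["promoter_id"]],
            "promoter_id": panel["promoter_id"].to_numpy(),
            "gene": gene,
            "fitness": meas,
            "sigma_f": err,
            "true_fitness": true_f,
        }))
    return pd.concat(rows, ignore_index=True)


def generate_read_counts(panel: pd.DataFrame,
                         truths: Mapping[str, GroundTruthLandscape],
                         depth: float = 1e6,
                         timepoints: Sequence[float] = (0.0, 23.0, 35.0),
                         generation_rate: float = 10.0 / 23.0,
                         seed: int = 0) -> pd.DataFrame:
    """Simulate pooled-competition sequencing counts.

    Lineage frequencies follow deterministic exponential growth,
    ``p_i(t) proportional to p_i(0) * 2**(f_i * g(t))`` with ``g(t) =
    generation_rate * t`` generations elapsed, and counts at each timepoint
    are Poisson-sampled to a total of about ``depth`` reads. A wild-type
    lineage (gene ``"WT"``, fitness 0) is always included as the reference.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if len(timepoints) != 3:
        raise ValueError("exactly three timepoints (t0, t23, t35) expected")
    rng = np.random.default_rng(seed)

    strain_id = [f"{p}:{g}" for g in truths for p in panel["promoter_id"]]
    promoter = list(panel["promoter_id"]) * len(truths)
    gene = [g for g in truths for _ in range(len(panel))]
    fitness = np.concatenate([
        np.asarray(t.relative_fitness(panel["true_log2_mean"].to_numpy(),
                                      panel["true_log2_cv"].to_numpy()))
        for t in truths.values()])

    strain_id.append(WILDTYPE_GENE)
    promoter.append(WILDTYPE_GENE)
    gene.append(WILDTYPE_GENE)
    fitness = np.append(fitness, 0.0)

    n = len(fitness)
    p0 = np.full(n, 1.0 / n)
    if p0[-1] <= 0:
        raise ValueError("wild-type lineage has zero starting frequency")

    out = {"strain_id": strain_id, "promoter_id": promoter, "gene": gene}
    for label, t in zip(("t0_reads", "t23_reads", "t35_reads"), timepoints):
        g = generation_rate * t
        p = p0 * np.exp2(fitness * g)
        p /= p.sum()
        counts = rng.poisson(depth * p)
        if counts[-1] == 0:
            raise ValueError(
                "wild-type lineage received zero reads; increase depth")
        out[label] = counts
    return pd.DataFrame(out)


# -- rank-2 topology ensembles --------------------------------------------

class PrincipalTopologyBasis:
    """Two orthogonal topology surfaces in mean-noise space.

    T1 is shortage-shaped (fitness rises with mean expression, falls with
    noise), T2 surplus-shaped, built from the expectation construction and
    then centred, orthonormalised over a reference window and rescaled so
    each has the requested expression sensitivity. Because both surfaces are
    affine combinations of two expectation surfaces, they can be evaluated
    consistently on any grid (e.g. an extended grid for strain sampling and
    the standard analysis window for PCA).
    """

    def __init__(self, window_grid: Grid,
                 sensitivity_scale: float = 0.0112):
        self._h1 = GroundTruthLandscape(window_grid.wt_mu, lam_shortage=1.0,
                                        lam_surplus=0.0, baseline=0.0)
        self._h2 = GroundTruthLandscape(window_grid.wt_mu, lam_shortage=0.0,
                                        lam_surplus=1.0, baseline=0.0)
        # raw penalty surfaces on the reference window (negated baselines)
        h1 = -self._h1.surface(window_grid, relative=False)
        h2 = -self._h2.surface(window_grid, relative=False)
        self._m1 = h1.mean()
        self._m2 = h2.mean()
        c1 = h1 - self._m1
        c2 = h2 - self._m2
        self._n1 = np.linalg.norm(c1)
        u1 = c1 / self._n1
        self._gamma = float((c2 * u1).sum())
        r2 = c2 - self._gamma * u1
        self._n2 = np.linalg.norm(r2)
        u2 = r2 / self._n2

        def _sens(t: np.ndarray) -> float:
            return float(np.mean(np.abs(np.gradient(t[:, 0], window_grid.mu))))

        # orientation: T1 shortage-like (low fitness at low mean), T2 opposite
        s1 = 1.0 if u1[-1, 0] > u1[0, 0] else -1.0
        s2 = 1.0 if u2[0, 0] > u2[-1, 0] else -1.0
        self._a1 = s1 * sensitivity_scale / _sens(u1)
        self._a2 = s2 * sensitivity_scale / _sens(u2)
        self.window_grid = window_grid

    def evaluate(self, grid: Grid) -> tuple[np.ndarray, np.ndarray]:
        """(T1, T2) surfaces on an arbitrary grid, shapes (n_mu, n_eta)."""
        h1 = -self._h1.surface(grid, relative=False)
        h2 = -self._h2.surface(grid, relative=False)
        u1 = (h1 - self._m1) / self._n1
        u2 = ((h2 - self._m2) - self._gamma * u1) / self._n2
        return self._a1 * u1, self._a2 * u2


def rank2_gene_ensemble(basis: PrincipalTopologyBasis, grid: Grid,
                        n_genes: int = 30,
                        loading_mean: tuple[float, float] = (1.25, 0.05),
                        loading_sd: tuple[float, float] = (0.45, 0.3),
                        seed: int = 0) -> tuple[pd.DataFrame, np.ndarray]:
    """Gene truth surfaces built as a_g*T1 + b_g*T2.

    Shortage loadings ``a`` are truncated to stay positive (every gene is at
    least neutrally shortage sensitive); surplus loadings ``b`` straddle
    zero. Returns the generative loadings and the stacked truth surfaces,
    shape (n_genes, n_mu, n_eta).
    """
    rng = np.random.default_rng(seed)
    t1, t2 = basis.evaluate(grid)
    a = np.maximum(rng.normal(loading_mean[0], loading_sd[0], size=n_genes),
                   0.2)
    b = rng.normal(loading_mean[1], loading_sd[1], size=n_genes)
    surfaces = a[:, None, None] * t1 + b[:, None, None] * t2
    genes = [f"G{i + 1:02d}" for i in range(n_genes)]
    loadings = pd.DataFrame({"gene": genes, "a": a, "b": b})
    return loadings, surfaces


def sample_strains_from_surface(surface: np.ndarray, grid: Grid,
                                panel: pd.DataFrame, gene: str,
                                sigma_f: float = 0.01,
                                seed: int = 0) -> pd.DataFrame:
    """Measured strain fitness for one gene from a truth surface.

    True fitness is the surface bilinearly interpolated at the promoter's
    true position (clipped to the grid extent); measurement noise as in
    :func:`generate_strain_fitness`.
    """
    rng = np.random.default_rng(seed)
    interp = RegularGridInterpolator((grid.mu, grid.eta), surface)
    pts = np.column_stack([
        np.clip(panel["true_log2_mean"].to_numpy(), grid.mu[0], grid.mu[-1]),
        np.clip(panel["true_log2_cv"].to_numpy(), grid.eta[0], grid.eta[-1]),
    ])
    true_f = interp(pts)
    err = sigma_f * np.exp(rng.normal(0.0, 0.3, size=len(panel)))
    meas = true_f + rng.normal(0.0, 1.0, size=len(panel)) * err
    return pd.DataFrame({
        "strain_id": [f"{p}:{gene}" for p in panel["promoter_id"]],
        "promoter_id": panel["promoter_id"].to_numpy(),
        "gene": gene,
        "fitness": meas,
        "sigma_f": err,
        "true_fitness": true_f,
    })


def rank2_recovery_study(n_panels: int = 300, n_genes: int = 30,
                         n_promoters: int = 80, seed: int = 0,
                         sigma_f: float = 0.01) -> dict:
    """Monte-Carlo recovery of the slope metrics on rank-2 ensembles.

    Fixes one set of rank-2 gene truths, then repeatedly redraws the shared
    promoter panel and measurement noise, reconstructs each gene's metric
    lines with an error-matched kernel (bandwidths = the panel's median
    position errors) and compares the Monte-Carlo mean expression
    sensitivity and noise intolerance against the truths' analytic values.

    A single shared panel induces large design noise on the ensemble-mean
    noise intolerance (the same ~dozen promoters inform every gene's
    wild-type column), so recovery is a property of the estimator's mean
    over panels, not of one draw.
    """
    from .landscape import SmoothingKernel, make_grid
    from .metrics import LineWeights, expression_sensitivity, noise_intolerance
    from .landscape import FitnessLandscape

    win = make_grid(4.0)
    ext = make_grid(4.0, mean_halfwidth=2.0)
    basis = PrincipalTopologyBasis(win)
    loadings, surf_ext = rank2_gene_ensemble(basis, ext, n_genes=n_genes,
                                             seed=seed)
    _, surf_win = rank2_gene_ensemble(basis, win, n_genes=n_genes, seed=seed)
    ones = np.ones(win.shape)
    tru_s = float(np.mean([expression_sensitivity(
        FitnessLandscape(grid=win, f=surf_win[i], total_weight=ones))
        for i in range(n_genes)]))
    tru_i = float(np.mean([noise_intolerance(
        FitnessLandscape(grid=win, f=surf_win[i], total_weight=ones))
        for i in range(n_genes)]))

    sens_all, intol_all = [], []
    for k in range(n_panels):
        pseed = (seed + 1009 * (k + 1)) % (2 ** 31)
        panel = generate_promoter_panel(SyntheticPanelConfig(
            n_promoters=n_promoters, seed=pseed))
        mu = panel["log2_mean"].to_numpy()
        eta = panel["log2_cv"].to_numpy()
        emu = panel["err_mean"].to_numpy()
        eeta = panel["err_cv"].to_numpy()
        kern = SmoothingKernel(float(np.median(emu)), float(np.median(eeta)))
        for i, g in enumerate(loadings["gene"]):
            s = sample_strains_from_surface(surf_ext[i], ext, panel, g,
                                            sigma_f=sigma_f,
                                            seed=(pseed * 97 + i) % (2 ** 31))
            lw = LineWeights.build(mu, eta, emu, eeta,
                                   s["sigma_f"].to_numpy(), win, kern)
            se_, it_ = lw.metrics(s["fitness"].to_numpy())
            sens_all.append(se_)
            intol_all.append(it_)
    sens_mc = float(np.mean(sens_all))
    intol_mc = float(np.mean(intol_all))
    return {
        "truth_sensitivity": tru_s, "truth_intolerance": tru_i,
        "mc_sensitivity": sens_mc, "mc_intolerance": intol_mc,
        "sensitivity_rel_err": abs(sens_mc - tru_s) / tru_s,
        "intolerance_rel_err": abs(intol_mc - tru_i) / abs(tru_i),
        "n_panels": n_panels,
    }


# -- I/O -------------------------------------------------------------------

PANEL_COLUMNS = ["promoter_id", "log2_mean", "log2_cv", "err_mean", "err_cv"]
COUNT_COLUMNS = ["strain_id", "promoter_id", "gene",
                 "t0_reads", "t23_reads", "t35_reads"]


def write_panel(panel: pd.DataFrame, path) -> None:
    panel[PANEL_COLUMNS].to_csv(path, sep="\t", index=False)


def write_read_counts(counts: pd.DataFrame, path) -> None:
    counts[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)
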