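"""Principal topologies of expression-fitness landscapes.

The set of per-gene landscapes (each normalized to its fitness at wild-type
mean expression and minimal noise) is decomposed by PCA with grid points as
observations and genes as variables. The component score surfaces are the
principal topologies — empirically, a shortage-sensitivity surface (PT1:
fitness falls at low mean or high noise) and a surplus-sensitivity surface
(PT2: fitness falls at high mean or high noise) — and the per-gene
coefficients are the topology loadings.

Loadings are reported on an absolute scale by correcting for the mean
landscape: the centred loading (the gene's projection after subtracting the
cross-gene mean surface) plus the mean landscape's own projection onto each
component, so a gene identical to the mean landscape reports exactly the
mean's loadings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .landscape import FitnessLandscape, Grid

_RANK_TOL = 1e-12   # minimal explained-variance ratio for a real component


def normalize_landscape(landscape: FitnessLandscape) -> FitnessLandscape:
    """Fitness relative to the (wild-type mean, minimal-noise) anchor."""
    anchor = landscape.f[landscape.grid.wt_index, 0]
    if not np.isfinite(anchor):
        raise ValueError("landscape undefined at the wild-type/low-noise "
                         "anchor")
    return FitnessLandscape(grid=landscape.grid, f=landscape.f - anchor,
                            total_weight=landscape.total_weight,
                            gene=landscape.gene, se=landscape.se)


@dataclass
class TopologyDecomposition:
    """PCA of a set of gene landscapes on a shared grid.

    ``topologies`` are the component score surfaces (n_components, n_mu,
    n_eta), mutually orthogonal; ``loadings`` are the mean-landscape-
    corrected per-gene coefficients; ``gene_offsets`` are the per-gene
    scalar offsets (gene grid-mean minus grand mean) needed for exact
    reconstruction.
    """

    topologies: np.ndarray
    loadings: pd.DataFrame
    centred_loadings: pd.DataFrame
    variance_explained: np.ndarray
    mean_landscape: np.ndarray
    mean_landscape_loadings: np.ndarray
    gene_offsets: pd.Series
    grid: Grid

    @property
    def genes(self) -> list[str]:
        return list(self.loadings.index)

    @property
    def n_components(self) -> int:
        return self.topologies.shape[0]


def _orient(scores: np.ndarray, loadings: np.ndarray, grid: Grid
            ) -> tuple[np.ndarray, np.ndarray]:
    """Fix component signs.

    PT1 is oriented as a shortage penalty (lower fitness at the low-mean,
    low-noise corner than at the high-mean, low-noise corner), PT2 the
    opposite; any further components keep the largest-|loading| gene
    positive.
    """
    n_mu = len(grid.mu)
    for k in range(scores.shape[1]):
        surf = scores[:, k].reshape(n_mu, -1)
        low, high = surf[0, 0], surf[-1, 0]
        if k == 0:
            flip = low > high
        elif k == 1:
            flip = low < high
        else:
            flip = loadings[np.argmax(np.abs(loadings[:, k])), k] < 0
        if flip:
            scores[:, k] *= -1.0
            loadings[:, k] *= -1.0
    return scores, loadings


def pca_landscapes(landscapes: dict[str, FitnessLandscape],
                   n_components: int = 2) -> TopologyDecomposition:
    """Decompose gene landscapes into principal topologies.

    Landscapes must share the grid shape and relative axes (each gene's
    grid is centred on its own wild-type expression; positions are compared
    in wild-type-relative coordinates). Fitness on each grid point is an
    observation and each gene a variable; columns are centred.
    """
    genes = list(landscapes)
    if len(genes) < 2:
        raise ValueError("need >= 2 genes for a decomposition")
    ref = landscapes[genes[0]].grid
    rel_mu = ref.mu - ref.wt_mu
    for g in genes[1:]:
        grid = landscapes[g].grid
        if (grid.shape != ref.shape
                or not np.allclose(grid.mu - grid.wt_mu, rel_mu)
                or not np.allclose(grid.eta, ref.eta)):
            raise ValueError(f"landscape grid of gene {g!r} does not match")

    x = np.column_stack([landscapes[g].f.ravel() for g in genes])
    if not np.all(np.isfinite(x)):
        raise ValueError("landscapes contain undefined grid points")

    max_rank = min(x.shape[1], x.shape[0])
    pca = PCA(n_components=min(n_components, max_rank))
    scores = pca.fit_transform(x)             # (n_points, k) surfaces
    loadings = pca.components_.T.copy()       # (genes, k)

    # drop numerically-null components
    keep = pca.explained_variance_ratio_ > _RANK_TOL
    scores, loadings = scores[:, keep], loadings[:, keep]
    var_exp = pca.explained_variance_ratio_[keep]

    scores, loadings = _orient(scores, loadings, ref)

    # the mean landscape's projection equals the gene-average loading
    m = loadings.mean(axis=0)
    centred = loadings - m
    mean_landscape = x.mean(axis=1).reshape(ref.shape)
    col_means = x.mean(axis=0)
    offsets = pd.Series(col_means - col_means.mean(), index=genes,
                        name="offset")

    k = scores.shape[1]
    cols = [f"pt{i + 1}" for i in range(k)]
    return TopologyDecomposition(
        topologies=scores.T.reshape(k, *ref.shape),
        loadings=pd.DataFrame(centred + m, index=genes, columns=cols),
        centred_loadings=pd.DataFrame(centred, index=genes, columns=cols),
        variance_explained=var_exp,
        mean_landscape=mean_landscape,
        mean_landscape_loadings=m,
        gene_offsets=offsets,
        grid=ref,
    )


def correct_loadings(centred_loadings: np.ndarray,
                     mean_landscape_loadings: np.ndarray) -> np.ndarray:
    """Report loadings on an absolute scale.

    Adds the mean landscape's projection coefficients to the centred
    (deviation-from-mean-landscape) loadings, so a gene equal to the mean
    landscape reports the mean's loadings and a mean landscape orthogonal
    to the components leaves loadings unchanged.
    """
    return np.asarray(centred_loadings, dtype=float) + np.asarray(
        mean_landscape_loadings, dtype=float)


def reconstruct(decomposition: TopologyDecomposition, gene: str,
                k: int | None = None) -> np.ndarray:
    """Rebuild a gene's landscape from its first ``k`` topologies.

    mean landscape + gene offset + sum of centred loading * topology; with
    all components the reconstruction is exact, with k = 0 it is the mean
    landscape shifted by the gene's scalar offset.
    """
    if k is None:
        k = decomposition.n_components
    if k > decomposition.n_components:
        raise ValueError("more components requested than available")
    out = decomposition.mean_landscape + decomposition.gene_offsets[gene]
    for j in range(k):
        out = out + (decomposition.centred_loadings.loc[gene].iloc[j]
                     * decomposition.topologies[j])
    return out


def classify_peaked(loadings: pd.DataFrame,
                    pt1_threshold: float = 0.0,
                    pt2_threshold: float = 0.0) -> pd.Series:
    """Label landscape shapes from corrected (PT1, PT2) loadings.

    Loadings above both thresholds -> "peaked"; above only the shortage
    (PT1) threshold -> "shortage"; only the surplus (PT2) threshold ->
    "surplus"; otherwise "flat".
    """
    pt1 = loadings.iloc[:, 0] > pt1_threshold
    pt2 = loadings.iloc[:, 1] > pt2_threshold
    labels = np.where(pt1 & pt2, "peaked",
                      np.where(pt1, "shortage",
                               np.where(pt2, "surplus", "flat")))
    return pd.Series(labels, index=loadings.index, name="topology_class")


def decomposition_frames(decomposition: TopologyDecomposition
                         ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Long-format topology surfaces, loadings table and JSON metadata."""
    grid = decomposition.grid
    mm, ee = np.meshgrid(grid.mu - grid.wt_mu, grid.eta, indexing="ij")
    rows = []
    for j in range(decomposition.n_components):
        rows.append(pd.DataFrame({
            "component": f"pt{j + 1}",
            "rel_mu": mm.ravel(), "eta": ee.ravel(),
            "value": decomposition.topologies[j].ravel(),
        }))
    surfaces = pd.concat(rows, ignore_index=True)
    loadings = decomposition.loadings.reset_index(names="gene")
    meta = {
        "variance_explained": decomposition.variance_explained.tolist(),
        "mean_landscape_loadings":
            decomposition.mean_landscape_loadings.tolist(),
        "sign_convention": "pt1 shortage-oriented, pt2 surplus-oriented",
    }
    return surfaces, loadings, meta


class PrincipalTopologies(BaseEstimator, TransformerMixin):
    """Landscape PCA as a scikit-learn transformer.

    ``fit`` takes ``X`` of shape (n_genes, n_grid_points) — one flattened,
    normalized landscape per row — and stores the topology surfaces;
    ``transform`` returns corrected loadings for (possibly new) landscapes
    by projection onto the fitted components.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("X must be (n_genes >= 2, n_points)")
        pca = PCA(n_components=min(self.n_components, *X.shape))
        scores = pca.fit_transform(X.T)
        loadings = pca.components_.T.copy()
        keep = pca.explained_variance_ratio_ > _RANK_TOL
        self.topologies_ = scores[:, keep]
        self.mean_loadings_ = loadings[:, keep].mean(axis=0)
        self.variance_explained_ = pca.explained_variance_ratio_[keep]
        self.mean_landscape_ = X.mean(axis=0)
        return self

    def transform(self, X):
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "topologies_")
        X = np.asarray(X, dtype=float)
        dev = X - self.mean_landscape_
        norms = (self.topologies_ ** 2).sum(axis=0)
        centred = dev @ self.topologies_ / norms
        return centred + self.mean_loadings_
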