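"""Spherical-variogram estimation and ordinary kriging of well observations.

Groundwater attributes (table depth in m, salinity in g/l) are observed at
irregular well locations and interpolated to the analysis grid by ordinary
kriging: the best linear unbiased predictor with weights constrained to sum
to one, driven by a spherical semivariogram

    gamma(h) = nugget + psill * (1.5 h/r - 0.5 (h/r)^3)   for h <= r
    gamma(h) = nugget + psill                             for h >  r

fitted to the binned method-of-moments empirical semivariogram by weighted
least squares (bin pair counts as weights).  The kriging system uses the
exact-interpolation convention gamma(0) = 0, so a nugget-0 model reproduces
well values at well locations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, RegressorMixin

from .geodata import Grid, GridSpec

__all__ = [
    "VariogramModel",
    "empirical_variogram",
    "fit_spherical_variogram",
    "OrdinaryKriging",
    "krige_spherical",
    "dedupe_wells",
]


@dataclass(frozen=True)
class VariogramModel:
    """Spherical semivariogram parameters (nugget, partial sill, range in m)."""

    nugget: float
    partial_sill: float
    range_: float
    kind: str = "spherical"

    def __post_init__(self) -> None:
        if self.nugget < 0 or self.partial_sill < 0 or self.range_ <= 0:
            raise ValueError("nugget, partial_sill >= 0 and range > 0 required")

    def __call__(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        hr = np.minimum(h / self.range_, 1.0)
        gamma = self.nugget + self.partial_sill * (1.5 * hr - 0.5 * hr ** 3)
        return np.where(h > 0, gamma, 0.0)


def dedupe_wells(wells: pd.DataFrame) -> pd.DataFrame:
    """Average the values of wells sharing an identical location."""
    return wells.groupby(["x", "y"], as_index=False)["value"].mean()


def empirical_variogram(coords: np.ndarray, values: np.ndarray, n_lags: int,
                        max_dist: float) -> pd.DataFrame:
    """Method-of-moments semivariogram on equal-width distance bins.

    Returns a frame with lag bin centers, semivariance gamma (mean of half
    squared differences) and pair counts; empty bins are dropped.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    iu = np.triu_indices(len(values), k=1)
    dist = d[iu]
    sq = 0.5 * (values[iu[0]] - values[iu[1]]) ** 2
    keep = (dist > 0) & (dist <= max_dist)
    dist, sq = dist[keep], sq[keep]
    edges = np.linspace(0.0, max_dist, n_lags + 1)
    which = np.clip(np.digitize(dist, edges) - 1, 0, n_lags - 1)
    rows = []
    for b in range(n_lags):
        sel = which == b
        if sel.any():
            rows.append({"lag": 0.5 * (edges[b] + edges[b + 1]),
                         "gamma": float(sq[sel].mean()), "count": int(sel.sum())})
    return pd.DataFrame(rows)


def fit_spherical_variogram(wells: pd.DataFrame, n_lags: int = 15,
                            max_dist: float | None = None) -> VariogramModel:
    """Fit a spherical model to the empirical semivariogram of a well set.

    Wells at duplicated locations are averaged first.  An all-constant field
    degenerates to the flat model (nugget 0, partial sill 0, range max_dist).
    """
    wells = dedupe_wells(wells)
    if len(wells) < 10:
        raise ValueError("need at least 10 distinct wells to fit a variogram")
    coords = wells[["x", "y"]].to_numpy()
    values = wells["value"].to_numpy()
    if max_dist is None:
        span = coords.max(axis=0) - coords.min(axis=0)
        max_dist = 0.5 * float(np.hypot(*span))
    if np.allclose(values, values[0]):
        return VariogramModel(0.0, 0.0, float(max_dist))
    emp = empirical_variogram(coords, values, n_lags, max_dist)
    lags = emp["lag"].to_numpy()
    gam = emp["gamma"].to_numpy()
    wts = np.sqrt(emp["count"].to_numpy(dtype=float))

    def resid(theta):
        nugget, psill, rng = theta
        model = VariogramModel(max(nugget, 0.0), max(psill, 0.0), max(rng, 1e-6))
        return wts * (model(lags) - gam)

    var0 = float(values.var())
    x0 = np.array([min(gam[0], var0) * 0.5, max(var0 - gam[0] * 0.5, 1e-6), max_dist / 2.0])
    sol = least_squares(resid, x0, bounds=([0.0, 0.0, 1e-6],
                                           [np.inf, np.inf, 10.0 * max_dist]))
    nugget, psill, rng = sol.x
    return VariogramModel(float(nugget), float(psill), float(rng))


class OrdinaryKriging(BaseEstimator, RegressorMixin):
    """Ordinary kriging regressor over 2D map coordinates.

    Parameters
    ----------
    variogram : VariogramModel or None
        Semivariogram driving the weights; fitted from the training wells
        when None.
    neighborhood : int
        Number of nearest wells entering each prediction (moving
        neighborhood); bounded by the number of distinct wells.

    Attributes
    ----------
    coords_ : ndarray of shape (n_wells, 2)
        Deduplicated training locations.
    values_ : ndarray of shape (n_wells,)
        Training values (location duplicates averaged).
    variogram_ : VariogramModel
        The model actually used for prediction.
    """

    def __init__(self, variogram: VariogramModel | None = None, neighborhood: int = 16):
        self.variogram = variogram
        self.neighborhood = neighborhood

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_samples, 2) map coordinates")
        if self.neighborhood < 1:
            raise ValueError("neighborhood must be >= 1")
        wells = dedupe_wells(pd.DataFrame({"x": X[:, 0], "y": X[:, 1], "value": y}))
        self.coords_ = wells[["x", "y"]].to_numpy()
        self.values_ = wells["value"].to_numpy()
        if self.variogram is not None:
            self.variogram_ = self.variogram
        else:
            self.variogram_ = fit_spherical_variogram(wells)
        self._tree = cKDTree(self.coords_)
        return self

    def predict(self, X, return_weights: bool = False):
        X = np.asarray(X, dtype=float)
        gamma = self.variogram_
        n_wells = len(self.values_)
        nb = min(self.neighborhood, n_wells)
        if n_wells == 1:
            pred = np.full(len(X), self.values_[0])
            return (pred, np.ones((len(X), 1))) if return_weights else pred
        _, nn = self._tree.query(X, k=nb)
        nn = np.asarray(nn).reshape(len(X), nb)
        # batched OK systems: [gamma(h_ij) 1; 1 0] lambda = [gamma(h_i0); 1]
        pair = np.sqrt(((self.coords_[:, None, :] - self.coords_[None, :, :]) ** 2).sum(-1))
        G = gamma(pair)
        K = np.zeros((len(X), nb + 1, nb + 1))
        K[:, :nb, :nb] = G[nn[:, :, None], nn[:, None, :]]
        K[:, nb, :nb] = 1.0
        K[:, :nb, nb] = 1.0
        d0 = np.sqrt(((self.coords_[nn] - X[:, None, :]) ** 2).sum(-1))
        rhs = np.empty((len(X), nb + 1))
        rhs[:, :nb] = gamma(d0)
        rhs[:, nb] = 1.0
        try:
            lam = np.linalg.solve(K, rhs[..., None])[..., 0]
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular kriging system (coincident wells after deduplication)") from exc
        w = lam[:, :nb]
        pred = (w * self.values_[nn]).sum(axis=1)
        if return_weights:
            return pred, w
        return pred


def krige_spherical(wells: pd.DataFrame, model: VariogramModel, spec: GridSpec,
                    neighborhood: int = 16) -> Grid:
    """Ordinary-kriging prediction of a well set at every cell center of a grid."""
    ok = OrdinaryKriging(variogram=model, neighborhood=neighborhood)
    ok.fit(wells[["x", "y"]].to_numpy(), wells["value"].to_numpy())
    X, Y = spec.cell_centers()
    pts = np.column_stack([X.ravel(), Y.ravel()])
    pred = ok.predict(pts)
    return Grid(spec, pred.reshape(spec.shape))
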