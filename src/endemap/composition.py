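"""The composition-break pipeline.

Six steps turn a gridded presence/absence matrix into a continuous map of
species composition: (1) the matrix itself, (2) a cell-to-cell Bray-Curtis
dissimilarity matrix (on binary data this equals Sorensen dissimilarity),
(3) non-metric multidimensional scaling into three axes, (4) a Moran's I
check that each axis is spatially autocorrelated (the premise of step 5),
(5) ordinary kriging of the axis scores onto a fine raster, and (6) an RGB
composite with one colour channel per axis. Total beta diversity is also
partitioned into its turnover (species replacement) and nestedness
(richness-difference) components, each of which can be pushed through the
same ordination-interpolation steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from .core_data import PresenceAbsenceMatrix, haversine_km
from .raster import KernelSurface, RasterGeometry


@dataclass
class DissimilarityMatrix:
    cell_ids: np.ndarray
    d: np.ndarray
    flavor: str  # total | turnover | nestedness
    mode: str = "binary"

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.cell_ids)
        if self.d.shape != (n, n):
            raise ValueError("dissimilarity matrix must be square over cell_ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("dissimilarity matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.cell_ids)


def _abc_counts(m: np.ndarray):
    """Pairwise shared (a) and unique (b, c) presence counts for binary rows."""
    m = m.astype(np.int64)
    a = m @ m.T
    s = m.sum(axis=1)
    b = s[:, None] - a
    c = s[None, :] - a
    return a, b, c


def bray_curtis_matrix(pam: PresenceAbsenceMatrix, mode: str = "binary") -> DissimilarityMatrix:
    """Cell-to-cell Bray-Curtis dissimilarity.

    ``mode="binary"`` (default) uses presences, where Bray-Curtis reduces to
    Sorensen: d = (b + c) / (2a + b + c). ``mode="counts"`` uses per-cell
    record counts (classic abundance Bray-Curtis).
    """
    if pam.n_cells < 2:
        raise ValueError("need at least 2 cells")
    if mode == "binary":
        a, b, c = _abc_counts(pam.matrix)
        denom = 2 * a + b + c
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(denom > 0, (b + c) / np.maximum(denom, 1), 0.0)
    elif mode == "counts":
        x = (pam.matrix.astype(float) * pam.record_counts[:, None] / np.maximum(
            pam.matrix.sum(axis=1, keepdims=True), 1))
        num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
        den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    else:
        raise ValueError("mode must be 'binary' or 'counts'")
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(np.asarray(pam.cells), d, "total", mode)


def partition_beta(pam: PresenceAbsenceMatrix):
    """Additive partition of pairwise beta diversity (binary data).

    turnover  = min(b, c) / (a + min(b, c))       (Simpson dissimilarity)
    nestedness = total - turnover
    so total Sorensen = turnover + nestedness exactly, pair by pair.
    """
    a, b, c = _abc_counts(pam.matrix)
    mn = np.minimum(b, c)
    with np.errstate(invalid="ignore", divide="ignore"):
        turn = np.where(a + mn > 0, mn / np.maximum(a + mn, 1), 0.0)
        denom = 2 * a + b + c
        total = np.where(denom > 0, (b + c) / np.maximum(denom, 1), 0.0)
    nest = total - turn
    np.fill_diagonal(turn, 0.0)
    np.fill_diagonal(nest, 0.0)
    cells = np.asarray(pam.cells)
    return (
        DissimilarityMatrix(cells, turn, "turnover"),
        DissimilarityMatrix(cells, nest, "nestedness"),
    )


# ---------------------------------------------------------------------------
# NMDS

@dataclass
class OrdinationResult:
    scores: np.ndarray  # n x k, centered per axis
    stress: float  # Kruskal stress-1
    linear_R2: float
    n_starts: int
    best_start_seed: int
    cell_ids: np.ndarray | None = None

    @property
    def nonmetric_R2(self) -> float:
        return 1.0 - self.stress**2


def nmds(
    dmat: DissimilarityMatrix, k: int = 3, n_starts: int = 100, seed: int = 0,
    max_iter: int = 500, eps: float = 1e-9,
) -> OrdinationResult:
    """Kruskal non-metric MDS, best of *n_starts* random starts by stress-1.

    SMACOF with isotonic regression (scikit-learn backend); the reported stress
    is Kruskal's stress-1, the non-metric R^2 is 1 - stress^2, and the linear
    R^2 is the squared Pearson correlation between the monotone-fitted
    disparities and the ordination distances.
    """
    d = dmat.d
    n = d.shape[0]
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} cells for k={k}")
    best = None
    rng = np.random.default_rng(seed)
    start_seeds = rng.integers(0, 2**31 - 1, size=n_starts)

    # one deterministic start from classical scaling (PCoA) in addition to the
    # random starts: nested across k, it keeps stress monotone in k
    j = np.eye(n) - np.ones((n, n)) / n
    bmat = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(bmat)
    idx = np.argsort(evals)[::-1][:k]
    pcoa = evecs[:, idx] * np.sqrt(np.maximum(evals[idx], 1e-12))

    inits = [("pcoa", pcoa)] + [(int(s), None) for s in start_seeds]
    for tag, init in inits:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            emb, stress_val = smacof(
                d, metric=False, n_components=k, init=init,
                n_init=1, max_iter=max_iter, eps=eps,
                random_state=tag if isinstance(tag, int) else 0,
                normalized_stress=True,
            )
        if not np.isfinite(stress_val):
            continue
        if best is None or stress_val < best[0]:
            best = (float(stress_val), emb, -1 if tag == "pcoa" else tag)
    if best is None:
        raise RuntimeError("NMDS failed to converge in every start")
    stress, emb, best_seed = best
    emb = emb - emb.mean(axis=0, keepdims=True)

    iu = np.triu_indices(n, 1)
    dist = np.sqrt(((emb[:, None, :] - emb[None, :, :]) ** 2).sum(-1))[iu]
    order = np.argsort(d[iu], kind="stable")
    iso = IsotonicRegression(increasing=True)
    disparities = np.empty_like(dist)
    disparities[order] = iso.fit_transform(np.arange(len(order)), dist[order])
    if disparities.std() == 0 or dist.std() == 0:
        lin_r2 = 0.0
    else:
        lin_r2 = float(np.corrcoef(disparities, dist)[0, 1] ** 2)
    return OrdinationResult(
        scores=emb, stress=stress, linear_R2=lin_r2,
        n_starts=n_starts, best_start_seed=best_seed,
        cell_ids=np.asarray(dmat.cell_ids),
    )


# ---------------------------------------------------------------------------
# Moran's I

@dataclass
class MoranResult:
    axis: int
    I: float
    expected_I: float
    p_value: float
    n_perm: int


def cell_adjacency_weights(pam: PresenceAbsenceMatrix, scheme: str = "queen") -> np.ndarray:
    """Row-standardized spatial weights between occupied cells on the pam grid."""
    cells = np.asarray(pam.cells)
    rows, cols = np.divmod(cells, pam.grid.n_cols)
    dr = np.abs(rows[:, None] - rows[None, :])
    dc = np.abs(cols[:, None] - cols[None, :])
    if scheme == "queen":
        adj = (dr <= 1) & (dc <= 1)
    elif scheme == "rook":
        adj = ((dr == 1) & (dc == 0)) | ((dr == 0) & (dc == 1))
    else:
        raise ValueError("scheme must be 'queen' or 'rook'")
    w = adj.astype(float)
    np.fill_diagonal(w, 0.0)
    rs = w.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(rs > 0, w / np.maximum(rs, 1e-300), 0.0)
    return w


def morans_i(
    values, weights: np.ndarray, n_perm: int = 999, seed: int = 0, axis: int = 0
) -> MoranResult:
    """Moran's I with a two-sided permutation test.

    *weights* should be row-standardized (see :func:`cell_adjacency_weights`);
    the permutation p-value compares |I - E[I]| against values from random
    relabelings of the cells.
    """
    z = np.asarray(values, dtype=float)
    n = z.size
    if n < 3:
        raise ValueError("need at least 3 cells")
    if z.std() == 0:
        raise ValueError("zero variance")
    w_sum = weights.sum()

    def stat(v):
        vc = v - v.mean()
        return n / w_sum * float(vc @ weights @ vc) / float(vc @ vc)

    i_obs = stat(z)
    e_i = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        i_p = stat(rng.permutation(z))
        if abs(i_p - e_i) >= abs(i_obs - e_i) - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return MoranResult(axis=axis, I=float(i_obs), expected_I=e_i, p_value=float(p), n_perm=n_perm)


# ---------------------------------------------------------------------------
# ordinary kriging

def _exp_variogram(h, nugget, psill, rng_):
    return nugget + psill * (1.0 - np.exp(-h / np.maximum(rng_, 1e-12)))


def _lin_variogram(h, nugget, slope):
    return nugget + slope * h


@dataclass
class KrigingResult:
    prediction: KernelSurface
    variance: KernelSurface
    variogram: dict = field(default_factory=dict)


class OrdinaryKriging:
    """Ordinary kriging with a WLS-fitted exponential variogram.

    The empirical semivariogram is binned up to half the maximum pairwise
    distance and an exponential model fitted by weighted least squares
    (Cressie weights ~ N(h)/gamma^2); on fit failure a linear variogram is
    used with a warning. With gamma(0) = 0 on the system diagonal, ordinary
    kriging reproduces the observations exactly at the data points, and
    predictions far beyond the variogram range tend to the (kriging) mean.
    """

    def __init__(self, coords, values, n_lags: int = 15):
        coords = np.asarray(coords, dtype=float)
        z = np.asarray(values, dtype=float)
        npts = len(z)
        if npts < 10:
            raise ValueError("need at least 10 points to krige")
        self.coords = coords
        self.z = z

        dmat = haversine_km(
            coords[:, None, 0], coords[:, None, 1], coords[None, :, 0], coords[None, :, 1]
        )
        iu = np.triu_indices(npts, 1)
        h = dmat[iu]
        gamma = 0.5 * (z[iu[0]] - z[iu[1]]) ** 2
        hmax = h.max() / 2.0
        edges = np.linspace(0, hmax, n_lags + 1)
        hc, ge, cnt = [], [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            m = (h > lo) & (h <= hi)
            if m.sum() > 0:
                hc.append(h[m].mean())
                ge.append(gamma[m].mean())
                cnt.append(m.sum())
        hc, ge, cnt = map(np.asarray, (hc, ge, cnt))

        var_z = max(z.var(), 1e-12)
        if var_z <= 1e-12 or len(hc) < 3:
            # constant (or near-constant) field: weights reduce to the mean
            self.variogram = {"model": "linear", "nugget": 0.0, "slope": 1e-12}
            self._gfun = lambda hh: _lin_variogram(hh, 0.0, 1e-12)
        else:
            try:
                def resid(p):
                    gm = _exp_variogram(hc, *p)
                    return np.sqrt(cnt) * (ge - gm) / np.maximum(gm, 1e-9)

                fit = optimize.least_squares(
                    resid, x0=[1e-6, var_z, max(hmax / 3.0, 1.0)],
                    bounds=([0, 1e-12, 1e-6],
                            [var_z * 10 + 1e-9, var_z * 10 + 1e-9, hmax * 10]),
                    max_nfev=2000,
                )
                if not fit.success:
                    raise RuntimeError(fit.message)
                nug, ps, rg = fit.x
                self.variogram = {"model": "exponential", "nugget": float(nug),
                                  "psill": float(ps), "range": float(rg)}
                self._gfun = lambda hh: _exp_variogram(hh, nug, ps, rg)
            except Exception as exc:
                warnings.warn(f"exponential variogram fit failed ({exc}); falling back to linear")
                slope = max(float(np.polyfit(hc, ge, 1)[0]), 1e-12)
                self.variogram = {"model": "linear", "nugget": 0.0, "slope": slope}
                self._gfun = lambda hh: _lin_variogram(hh, 0.0, slope)

        a_mat = np.empty((npts + 1, npts + 1))
        g_dd = self._gfun(dmat)
        np.fill_diagonal(g_dd, 0.0)
        a_mat[:npts, :npts] = g_dd
        a_mat[npts, :] = 1.0
        a_mat[:, npts] = 1.0
        a_mat[npts, npts] = 0.0
        self._lu = linalg.lu_factor(a_mat)

    def predict(self, lons, lats):
        """Prediction and kriging variance at arbitrary locations."""
        lons = np.atleast_1d(np.asarray(lons, dtype=float))
        lats = np.atleast_1d(np.asarray(lats, dtype=float))
        npts = len(self.z)
        d0 = haversine_km(
            self.coords[:, 0][:, None], self.coords[:, 1][:, None],
            lons[None, :], lats[None, :],
        )
        g0 = self._gfun(d0)
        g0[d0 == 0] = 0.0
        rhs = np.vstack([g0, np.ones((1, len(lons)))])
        lam = linalg.lu_solve(self._lu, rhs)
        pred = lam[:npts].T @ self.z
        var = np.maximum(np.sum(lam[:npts] * g0, axis=0) + lam[npts], 0.0)
        return pred, var

    def predict_raster(self, geometry: RasterGeometry) -> KrigingResult:
        glons = geometry.lons()
        pred = np.empty((geometry.ny, geometry.nx))
        pvar = np.empty((geometry.ny, geometry.nx))
        for i, lat in enumerate(geometry.lats()):
            p, v = self.predict(glons, np.full_like(glons, lat))
            pred[i] = p
            pvar[i] = v
        return KrigingResult(
            prediction=KernelSurface(geometry, pred),
            variance=KernelSurface(geometry, pvar),
            variogram=dict(self.variogram),
        )


def krige_axis(
    coords: np.ndarray, values: np.ndarray, geometry: RasterGeometry,
    n_lags: int = 15,
) -> KrigingResult:
    """Ordinary kriging of NMDS axis scores from cell centroids onto a raster.

    Convenience wrapper around :class:`OrdinaryKriging`; returns the predicted
    surface, the kriging-variance surface and the fitted variogram parameters.
    """
    return OrdinaryKriging(coords, values, n_lags=n_lags).predict_raster(geometry)


def rgb_composite(s1: KernelSurface, s2: KernelSurface, s3: KernelSurface) -> np.ndarray:
    """Min-max rescale three axis surfaces to [0, 255] bands (R, G, B)."""
    if not (s1.geometry == s2.geometry == s3.geometry):
        raise ValueError("surfaces must share a raster geometry")
    bands = []
    for s in (s1, s2, s3):
        v = s.values
        rngv = v.max() - v.min()
        if rngv == 0:
            warnings.warn("constant axis surface mapped to mid-gray")
            bands.append(np.full_like(v, 128.0))
        else:
            bands.append((v - v.min()) / rngv * 255.0)
    return np.stack(bands, axis=-1).astype(np.uint8)
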