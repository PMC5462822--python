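"""Unsupervised ML classification of composition rasters and discriminant tests.

The GIS-style unsupervised "Maximum Likelihood" classifier is a Gaussian
mixture fitted by EM on per-pixel axis vectors; a model is fitted for each
group count in a range (default 2-11) and reported with its BIC. Candidate
region schemes (e.g. interfluve polygons) are tested with a linear
discriminant model on axis scores sampled at random points inside each region,
reporting resubstitution and leave-one-out hit percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.mixture import GaussianMixture

from .raster import KernelSurface


def _stack_pixels(surfaces: list[KernelSurface]):
    g = surfaces[0].geometry
    for s in surfaces[1:]:
        if s.geometry != g:
            raise ValueError("surfaces must share a raster geometry")
    x = np.stack([s.values.ravel() for s in surfaces], axis=1)
    valid = np.isfinite(x).all(axis=1)
    return x, valid, g


@dataclass
class ClassificationResult:
    n_groups: int
    class_raster: np.ndarray  # int labels 1..n_groups, 0 = invalid pixel
    means: np.ndarray
    covariances: np.ndarray
    loglik: float
    bic: float
    loglik_trace: list[float] = field(default_factory=list)


def ml_classify(
    surfaces: list[KernelSurface], n_groups=range(2, 12), seed: int = 0,
    max_iter: int = 200, tol: float = 1e-4, reg_covar: float = 1e-6,
) -> list[ClassificationResult]:
    """Gaussian-mixture classification of stacked axis rasters, one result per
    group count.

    EM is stepped one iteration at a time so the log-likelihood trace can be
    recorded; monotonicity of the trace is asserted during fitting (the EM
    guarantee). Initialization is k-means from *seed*; full covariances with a
    small ridge against degeneracy.
    """
    counts = [int(k) for k in (n_groups if np.iterable(n_groups) else [n_groups])]
    if any(k < 2 or k > 11 for k in counts):
        raise ValueError("n_groups must lie in 2..11")
    x, valid, g = _stack_pixels(surfaces)
    xv = x[valid]
    results = []
    for k in counts:
        if len(xv) < 10 * k:
            raise ValueError(f"need at least {10 * k} valid pixels for {k} groups")
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(xv)
        gm = GaussianMixture(
            n_components=k, covariance_type="full", reg_covar=reg_covar,
            max_iter=1, warm_start=True, init_params="kmeans",
            means_init=km.cluster_centers_, random_state=seed, tol=0.0,
        )
        trace: list[float] = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(max_iter):
                gm.fit(xv)
                ll = float(gm.score(xv) * len(xv))
                if trace and ll < trace[-1] - 1e-6 * max(1.0, abs(trace[-1])):
                    raise AssertionError("EM log-likelihood decreased")
                if trace and abs(ll - trace[-1]) < tol:
                    trace.append(ll)
                    break
                trace.append(ll)
        labels = np.zeros(x.shape[0], dtype=int)
        labels[valid] = gm.predict(xv) + 1
        results.append(
            ClassificationResult(
                n_groups=k,
                class_raster=labels.reshape(g.ny, g.nx),
                means=gm.means_.copy(),
                covariances=gm.covariances_.copy(),
                loglik=trace[-1],
                bic=float(gm.bic(xv)),
                loglik_trace=trace,
            )
        )
    return results


@dataclass
class DiscriminantReport:
    region_names: list[str]
    confusion: np.ndarray  # rows = true region, cols = predicted
    hit_pct: dict[str, float]
    overall_hit_pct: float
    cv_hit_pct: float  # leave-one-out
    n_points_per_region: int
    skipped_regions: list[str] = field(default_factory=list)


def discriminant_test(
    surfaces: list[KernelSurface], regions: dict, n_points: int = 100, seed: int = 0,
) -> DiscriminantReport:
    """Linear discriminant test of a candidate region scheme.

    *n_points* pixels (without replacement, pixel centres inside the polygon)
    are sampled per region; a linear discriminant model on the stacked axis
    values gives a confusion matrix, per-region and overall resubstitution hit
    percentages, and a leave-one-out cross-validated hit percentage. Regions
    must not overlap.
    """
    x, valid, g = _stack_pixels(surfaces)
    lons = np.tile(g.lons(), g.ny)
    lats = np.repeat(g.lats(), g.nx)

    names = list(regions)
    geoms = [regions[n] for n in names]
    for i in range(len(geoms)):
        for j in range(i + 1, len(geoms)):
            if geoms[i].intersection(geoms[j]).area > 1e-12:
                raise ValueError(f"overlapping regions: {names[i]!r} and {names[j]!r}")

    rng = np.random.default_rng(seed)
    xs, ys, kept, skipped = [], [], [], []
    for name, geom in zip(names, geoms):
        inside = shapely.contains_xy(geom, lons, lats) & valid
        idx = np.nonzero(inside)[0]
        if len(idx) < n_points:
            warnings.warn(f"region {name!r} has {len(idx)} < {n_points} samplable pixels; skipped")
            skipped.append(name)
            continue
        pick = rng.choice(idx, size=n_points, replace=False)
        xs.append(x[pick])
        ys.append(np.full(n_points, len(kept)))
        kept.append(name)
    if len(kept) < 2:
        raise ValueError("need at least 2 samplable regions")
    X = np.concatenate(xs)
    y = np.concatenate(ys)

    lda = LinearDiscriminantAnalysis().fit(X, y)
    pred = lda.predict(X)
    k = len(kept)
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(y, pred):
        confusion[t, p] += 1
    hit = {kept[i]: 100.0 * confusion[i, i] / n_points for i in range(k)}
    overall = 100.0 * np.trace(confusion) / len(y)

    # leave-one-out
    loo_hits = 0
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        m = LinearDiscriminantAnalysis().fit(X[mask], y[mask])
        loo_hits += int(m.predict(X[i : i + 1])[0] == y[i])
    cv = 100.0 * loo_hits / len(y)
    return DiscriminantReport(
        region_names=kept, confusion=confusion, hit_pct=hit,
        overall_hit_pct=float(overall), cv_hit_pct=float(cv),
        n_points_per_region=n_points, skipped_regions=skipped,
    )
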