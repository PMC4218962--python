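"""Population-affinity PCA with per-sample Procrustes projection.

A canonical PCA of modern reference genotypes is computed with
Patterson-style normalization (each site centered at its mean dosage and
scaled by sqrt((mu/2)(1-mu/2))).  Each ancient sample is then placed by a
joint PCA of the moderns plus that one sample, restricted to the sample's
non-missing sites; the joint configuration's modern coordinates are mapped
onto the canonical modern coordinates by a full Procrustes transform
(translation, scaling, rotation and reflection) and the fitted transform
carries the ancient sample into the canonical frame.  This combines
per-sample plots into one panel without letting any single ancient
sample's missingness distort the modern reference space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg


@dataclass
class PCAModel:
    """Canonical reference PCA (Patterson normalization).

    ``coords`` holds the modern sample coordinates on the top ``n_components``
    axes; ``kept_sites`` indexes the polymorphic sites that entered the
    decomposition (monomorphic sites are dropped and recorded).
    """

    mean: np.ndarray
    scale: np.ndarray
    axes: np.ndarray  # (n_components, n_kept_sites), orthonormal rows
    coords: np.ndarray  # (n_samples, n_components)
    kept_sites: np.ndarray
    dropped_sites: np.ndarray
    n_components: int


@dataclass
class ProcrustesFit:
    """Similarity transform T(Y) = scale * (Y - y_mean) @ rotation + translation."""

    rotation: np.ndarray
    scale: float
    translation: np.ndarray
    y_mean: np.ndarray
    disparity: float

    def apply(self, Y: np.ndarray) -> np.ndarray:
        return self.scale * (np.atleast_2d(Y) - self.y_mean) @ self.rotation \
            + self.translation


def _normalized_matrix(genotypes: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Mean-impute, center and Patterson-normalize a dosage matrix."""
    G = np.array(genotypes, dtype=float)
    mu = np.nanmean(G, axis=0)
    inds = np.where(np.isnan(G))
    G[inds] = np.take(mu, inds[1])
    p = mu / 2.0
    keep = (p > 0) & (p < 1)
    scale = np.zeros_like(p)
    scale[keep] = 1.0 / np.sqrt(p[keep] * (1 - p[keep]))
    Z = (G[:, keep] - mu[keep]) * scale[keep]
    return Z, mu, scale, keep


def reference_pca(modern_genotypes: np.ndarray,
                  n_components: int = 2) -> PCAModel:
    """PCA of a modern dosage matrix (samples x sites, {0,1,2}, NaN missing)."""
    G = np.asarray(modern_genotypes, dtype=float)
    if G.ndim != 2 or G.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 samples")
    Z, mu, scale, keep = _normalized_matrix(G)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 polymorphic sites")
    U, S, Vt = linalg.svd(Z, full_matrices=False)
    D = min(n_components, S.size)
    return PCAModel(mean=mu, scale=scale, axes=Vt[:D],
                    coords=U[:, :D] * S[:D],
                    kept_sites=np.flatnonzero(keep),
                    dropped_sites=np.flatnonzero(~keep),
                    n_components=D)


def procrustes_fit(X: np.ndarray, Y: np.ndarray) -> ProcrustesFit:
    """Least-squares similarity transform mapping configuration Y onto X.

    Allows reflection (PCA axes carry arbitrary sign).  Disparity is the
    residual sum of squares normalized by the total centered variance of X.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.shape[0] < 3:
        raise ValueError("configurations must match with >= 3 rows")
    xm, ym = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - xm, Y - ym
    norm_y = (Yc ** 2).sum()
    norm_x = (Xc ** 2).sum()
    if norm_y == 0:
        raise ValueError("degenerate (zero-variance) source configuration")
    U, S, Vt = linalg.svd(Yc.T @ Xc)
    R = U @ Vt
    s = S.sum() / norm_y
    t = xm
    resid = norm_x - S.sum() ** 2 / norm_y
    disparity = max(0.0, resid) / norm_x if norm_x > 0 else 0.0
    return ProcrustesFit(rotation=R, scale=float(s), translation=t,
                         y_mean=ym, disparity=float(disparity))


def project_sample(model: PCAModel, dosages: np.ndarray) -> np.ndarray:
    """Passively project one dosage vector onto a fitted model's axes."""
    d = np.asarray(dosages, dtype=float)
    keep = model.kept_sites
    z = (d[keep] - model.mean[keep]) * model.scale[keep]
    z[~np.isfinite(z)] = 0.0  # missing sites contribute nothing
    return z @ model.axes.T


def cosample_project(modern_genotypes: np.ndarray, ancient_sample: np.ndarray,
                     model: PCAModel, n_min_sites: int = 10) -> np.ndarray:
    """Place one ancient sample in the canonical PCA frame.

    ``ancient_sample`` is a dosage vector over the same site set as the
    modern matrix, NaN where missing.  A per-sample PCA of the moderns
    restricted to the sample's non-missing sites defines axes the ancient
    sample is passively projected onto (so the low-coverage sample never
    drives the axes); the restricted modern coordinates are then
    Procrustes-fitted onto the canonical modern coordinates and the fitted
    transform carries the ancient projection into the canonical frame.
    """
    G = np.asarray(modern_genotypes, dtype=float)
    a = np.asarray(ancient_sample, dtype=float)
    if a.shape[0] != G.shape[1]:
        raise ValueError("ancient sample and modern matrix site sets differ")
    shared = ~np.isnan(a)
    if shared.sum() < n_min_sites:
        raise ValueError(
            f"insufficient overlap ({int(shared.sum())} < {n_min_sites} sites)")
    sub = reference_pca(G[:, shared], n_components=model.n_components)
    anc = project_sample(sub, a[shared])
    fit = procrustes_fit(model.coords, sub.coords)
    return fit.apply(anc)[0]
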