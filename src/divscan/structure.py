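"""Population structure: IBS similarity, principal coordinates analysis,
K-means/BIC cluster-number inference and discriminant analysis of
principal components (DAPC).

PCoA follows the classical MDS recipe: allele-sharing similarities are
turned into squared Euclidean distances D2 = 2(1 - s), double-centered
(Gower), and eigendecomposed; coordinates are eigenvectors scaled by the
square roots of the positive eigenvalues. DAPC runs a linear discriminant
step on a retained number of principal components, with the retained count
chosen by stratified 90/10 cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.model_selection import StratifiedShuffleSplit

from .datatypes import MISSING, GenotypeDataset


# ---------------------------------------------------------------------------
# Similarity and PCoA
# ---------------------------------------------------------------------------

def ibs_similarity(ds: GenotypeDataset) -> np.ndarray:
    """Pairwise allele-sharing (IBS) similarity matrix.

    s_ij = 1 - sum_m |g_im - g_jm| / (2 m_complete), averaged over markers
    called in both samples; the diagonal is 1. Raises if any pair shares no
    called marker.
    """
    g = ds.genotypes
    called = (g != MISSING)
    ind = [(g == d) & called for d in (0, 1, 2)]
    f = [m.astype(np.float64) for m in ind]
    # |a-b| decomposed over dosage classes
    diff1 = f[0] @ f[1].T + f[1] @ f[0].T + f[1] @ f[2].T + f[2] @ f[1].T
    diff2 = f[0] @ f[2].T + f[2] @ f[0].T
    m_complete = called.astype(np.float64) @ called.astype(np.float64).T
    if np.any(m_complete == 0):
        raise ValueError("a sample pair shares no called marker")
    s = 1.0 - (diff1 + 2.0 * diff2) / (2.0 * m_complete)
    np.fill_diagonal(s, 1.0)
    return s


@dataclass
class PcoaResult:
    eigenvalues: np.ndarray          # all eigenvalues of B, descending
    coordinates: np.ndarray          # n x k, axes for positive eigenvalues
    variance_explained: np.ndarray   # fractions over positive eigenvalues


def pcoa(similarity: np.ndarray, eps: float = 1e-9) -> PcoaResult:
    """Classical MDS of a unit-diagonal similarity matrix.

    D2 = 2 (1 - s) is Gower double-centered, B = -1/2 J D2 J; negative
    eigenvalues are reported but dropped from the coordinates and from the
    variance-fraction denominator.
    """
    s = np.asarray(similarity, dtype=float)
    if s.shape[0] != s.shape[1] or not np.allclose(s, s.T, atol=1e-8):
        raise ValueError("similarity must be a symmetric square matrix")
    n = s.shape[0]
    d2 = 2.0 * (1.0 - s)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > eps * max(evals.max(), 1.0)
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    var_exp = evals[pos] / evals[pos].sum() if pos.any() else np.empty(0)
    return PcoaResult(evals, coords, var_exp)


# ---------------------------------------------------------------------------
# Dosage -> PC helper
# ---------------------------------------------------------------------------

def _centered_dosages(g: np.ndarray, col_mean: np.ndarray | None = None):
    """Mean-impute missing dosages and center columns."""
    x = g.astype(np.float64)
    miss = g == MISSING
    if col_mean is None:
        x_masked = np.where(miss, np.nan, x)
        col_mean = np.nanmean(x_masked, axis=0)
        col_mean = np.nan_to_num(col_mean, nan=0.0)
    x = np.where(miss, col_mean[None, :], x)
    return x - col_mean[None, :], col_mean


def _pca(x: np.ndarray, n_pcs: int):
    """Thin SVD principal components of an already-centered matrix."""
    u, sing, vt = np.linalg.svd(x, full_matrices=False)
    n_pcs = min(n_pcs, sing.size)
    return u[:, :n_pcs] * sing[:n_pcs], vt[:n_pcs].T  # scores, loadings


# ---------------------------------------------------------------------------
# Cluster number by K-means BIC
# ---------------------------------------------------------------------------

def find_clusters_bic(
    ds: GenotypeDataset,
    k_max: int = 5,
    n_pcs_kept: int = 50,
    seed: int = 0,
    n_init: int = 10,
) -> tuple[pd.DataFrame, np.ndarray]:
    """K-means over retained PCs for K = 1..k_max with a BIC table.

    BIC(K) = n ln(WSS_K / n) + K ln(n); the table flags the argmin and the
    returned assignments are those of the best K. Deterministic for a
    fixed seed.
    """
    n = ds.n_samples
    if k_max >= n:
        raise ValueError("k_max must be smaller than the number of samples")
    x, _ = _centered_dosages(ds.genotypes)
    scores, _ = _pca(x, min(n_pcs_kept, n - 1))
    rows = []
    best = (np.inf, None, None)
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(scores)
        wss = float(km.inertia_)
        bic = n * np.log(wss / n) + k * np.log(n)
        rows.append({"k": k, "wss": wss, "bic": bic})
        if bic < best[0]:
            best = (bic, k, km.labels_.copy())
    table = pd.DataFrame(rows)
    table["best"] = table["k"] == best[1]
    return table, best[2]


# ---------------------------------------------------------------------------
# DAPC
# ---------------------------------------------------------------------------

@dataclass
class DapcModel:
    """Fitted DAPC: PCA step + linear discriminant step.

    Posterior membership uses Gaussian class-conditional densities with
    pooled within-group variance on the discriminant axes and uniform
    priors.
    """

    classes: np.ndarray
    n_pcs_retained: int
    col_mean: np.ndarray                 # dosage centering vector
    pc_loadings: np.ndarray              # m x n_pcs
    discriminant_loadings: np.ndarray    # n_pcs x (g-1)
    group_centroids: np.ndarray          # g x (g-1), on discriminant axes
    pooled_var: np.ndarray               # (g-1,), within-group
    bic_table: pd.DataFrame | None = None
    cv_table: pd.DataFrame | None = None

    def transform(self, genotypes: np.ndarray) -> np.ndarray:
        x, _ = _centered_dosages(genotypes, self.col_mean)
        return (x @ self.pc_loadings) @ self.discriminant_loadings

    def posteriors(self, genotypes: np.ndarray) -> np.ndarray:
        """Membership probabilities, one row per sample (rows sum to 1)."""
        d = self.transform(genotypes)
        log_density = np.empty((d.shape[0], len(self.classes)))
        for j, mu in enumerate(self.group_centroids):
            log_density[:, j] = -0.5 * (
                ((d - mu) ** 2) / self.pooled_var[None, :]
            ).sum(axis=1)
        log_density -= log_density.max(axis=1, keepdims=True)
        post = np.exp(log_density)
        return post / post.sum(axis=1, keepdims=True)

    def predict(self, genotypes: np.ndarray) -> np.ndarray:
        return self.classes[self.posteriors(genotypes).argmax(axis=1)]


def dapc_fit(
    ds_or_genotypes,
    labels,
    n_pcs: int,
) -> DapcModel:
    """Fit DAPC: PCA on centered dosages, then Fisher discriminant axes.

    Requires >= 2 groups with >= 2 members each; keeps g - 1 discriminant
    axes maximizing the between/within variance ratio on the retained PCs.
    """
    g = (
        ds_or_genotypes.genotypes
        if isinstance(ds_or_genotypes, GenotypeDataset)
        else np.asarray(ds_or_genotypes)
    )
    labels = np.asarray(labels)
    classes, y = np.unique(labels, return_inverse=True)
    if len(classes) < 2 or np.bincount(y).min() < 2:
        raise ValueError("need >= 2 groups with >= 2 members each")
    x, col_mean = _centered_dosages(g)
    n = x.shape[0]
    rank = min(n - 1, x.shape[1])
    if n_pcs > rank:
        raise ValueError(f"n_pcs={n_pcs} exceeds available rank {rank}")
    scores, loadings = _pca(x, n_pcs)

    # Fisher LDA on PC scores
    overall = scores.mean(axis=0)
    n_axes = len(classes) - 1
    sw = np.zeros((n_pcs, n_pcs))
    sb = np.zeros((n_pcs, n_pcs))
    for j in range(len(classes)):
        grp = scores[y == j]
        mu = grp.mean(axis=0)
        cen = grp - mu
        sw += cen.T @ cen
        dm = (mu - overall)[:, None]
        sb += grp.shape[0] * (dm @ dm.T)
    sw += np.eye(n_pcs) * 1e-8 * np.trace(sw) / n_pcs  # ridge for safety
    evals, evecs = np.linalg.eig(np.linalg.solve(sw, sb))
    order = np.argsort(evals.real)[::-1][:n_axes]
    w = evecs[:, order].real
    w /= np.linalg.norm(w, axis=0, keepdims=True)

    d = scores @ w
    centroids = np.vstack([d[y == j].mean(axis=0) for j in range(len(classes))])
    resid = d - centroids[y]
    pooled = (resid**2).sum(axis=0) / max(n - len(classes), 1)
    pooled = np.maximum(pooled, 1e-12)
    return DapcModel(
        classes=classes,
        n_pcs_retained=n_pcs,
        col_mean=col_mean,
        pc_loadings=loadings,
        discriminant_loadings=w,
        group_centroids=centroids,
        pooled_var=pooled,
    )


def dapc_crossvalidate(
    ds_or_genotypes,
    labels,
    pcs_grid,
    n_rep: int = 30,
    holdout: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, int]:
    """Choose the retained PC count by stratified 90/10 cross-validation.

    For each candidate, ``n_rep`` stratified splits are scored by the mean
    proportion of held-out samples assigned to their true group, and
    RMSE = sqrt(mean (1 - proportion_correct)^2); the chosen count
    maximizes mean assignment with ties broken by lower RMSE.
    """
    g = (
        ds_or_genotypes.genotypes
        if isinstance(ds_or_genotypes, GenotypeDataset)
        else np.asarray(ds_or_genotypes)
    )
    labels = np.asarray(labels)
    splitter = StratifiedShuffleSplit(
        n_splits=n_rep, test_size=holdout, random_state=seed
    )
    splits = list(splitter.split(g, labels))
    rows = []
    for n_pcs in pcs_grid:
        correct = []
        for train, test in splits:
            max_rank = min(len(train) - 1, g.shape[1])
            model = dapc_fit(g[train], labels[train], min(n_pcs, max_rank))
            pred = model.predict(g[test])
            correct.append(float(np.mean(pred == labels[test])))
        correct = np.asarray(correct)
        rows.append(
            {
                "n_pcs": int(n_pcs),
                "mean_assignment": float(correct.mean()),
                "rmse": float(np.sqrt(np.mean((1.0 - correct) ** 2))),
                "n_replicates": len(splits),
            }
        )
    table = pd.DataFrame(rows)
    best = table.sort_values(
        ["mean_assignment", "rmse", "n_pcs"], ascending=[False, True, True]
    ).iloc[0]
    return table, int(best["n_pcs"])
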