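"""Two-population cell classification on the marker panel.

The classifier follows the published recipe: natural-log transform of the
TPM matrix, PCA on the (centered, unscaled) log expression of the ten-gene
marker panel, and a two-component full-covariance Gaussian mixture fitted by
EM on the first two principal-component scores. Cells are hard-assigned by
maximum responsibility and the component with the higher Runx1 expression is
labelled haematopoietic.

The EM fitter is implemented here (multiple k-means++-style restarts, ridge
covariance regularisation, monotone log-likelihood); no external mixture
implementation is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp

from .io_model import ExpressionMatrix, MarkerPanel

logger = logging.getLogger("ehtmark")

LABEL_HAEM = "haematopoietic"
LABEL_ENDO = "endothelial"


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Replace every value x by ln(x + 1)."""
    return matrix.with_values(np.log1p(matrix.values))


@dataclass
class PCAResult:
    panel_genes_used: list[str]
    component_loadings: np.ndarray  # 2 x p
    explained_variance: np.ndarray  # length 2, non-increasing
    scores: np.ndarray  # cells x 2
    centering_means: np.ndarray  # length p


def marker_pca(log_matrix: ExpressionMatrix, panel: MarkerPanel) -> PCAResult:
    """Top-2 PCA of the centered (unscaled) panel sub-matrix.

    Loadings are the leading eigenvectors of the sample covariance of the
    centered log-expression over panel genes; panel genes absent from the
    matrix are dropped with a warning. Signs are fixed so each loading
    vector's largest-magnitude entry is positive, making the result
    deterministic.
    """
    present = [g for g in panel.gene_symbols if g in log_matrix.gene_ids]
    missing = [g for g in panel.gene_symbols if g not in present]
    if missing:
        logger.warning("panel genes missing from matrix, dropped: %s", missing)
    if len(present) < 2:
        raise ValueError("need at least 2 usable panel genes for PCA")
    if log_matrix.n_cells < 3:
        raise ValueError("need at least 3 cells for PCA")

    idx = [log_matrix.gene_index(g) for g in present]
    X = log_matrix.values[:, idx]
    means = X.mean(axis=0)
    Xc = X - means
    # SVD of the centered matrix; eigenvalues of the covariance follow from
    # the singular values with the n-1 denominator.
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if s[0] == 0:
        raise ValueError("panel sub-matrix has zero total variance")
    n = X.shape[0]
    loadings = Vt[:2]
    explained = (s[:2] ** 2) / (n - 1)
    signs = np.sign(loadings[np.arange(loadings.shape[0]), np.abs(loadings).argmax(axis=1)])
    signs[signs == 0] = 1.0
    loadings = loadings * signs[:, None]
    scores = Xc @ loadings.T
    return PCAResult(
        panel_genes_used=present,
        component_loadings=loadings,
        explained_variance=explained,
        scores=scores,
        centering_means=means,
    )


@dataclass
class MixtureFit:
    weights: np.ndarray  # length 2
    means: np.ndarray  # 2 x d
    covariances: np.ndarray  # 2 x d x d
    responsibilities: np.ndarray  # n x 2, rows sum to 1
    loglik_trace: list[float]
    n_init: int
    seed: int
    degenerate: bool = False

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]

    def hard_labels(self) -> np.ndarray:
        return self.responsibilities.argmax(axis=1)


def _log_gaussian_chol(X: np.ndarray, mean: np.ndarray, chol: np.ndarray, d: int) -> np.ndarray:
    sol = solve_triangular(chol, (X - mean).T, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + np.sum(sol**2, axis=0))


def _kmeanspp_means(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Two k-means++-style seed points: first uniform, second ~ squared distance."""
    n = X.shape[0]
    first = rng.integers(n)
    d2 = np.sum((X - X[first]) ** 2, axis=1)
    if d2.sum() == 0:
        second = rng.integers(n)
    else:
        second = rng.choice(n, p=d2 / d2.sum())
    return np.vstack([X[first], X[second]])


def _em_run(
    X: np.ndarray,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    ridge: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[float]]:
    n, d = X.shape
    centers = _kmeanspp_means(X, rng)
    assign = np.argmin(
        ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2), axis=1
    )
    resp = np.zeros((n, 2))
    resp[np.arange(n), assign] = 1.0
    # guard against an empty initial component
    if resp[:, 0].sum() == 0 or resp[:, 1].sum() == 0:
        resp[:] = 0.5

    trace: list[float] = []
    weights = means = covs = None
    for _ in range(max_iter):
        # M step
        nk = resp.sum(axis=0)
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        covs = np.empty((2, d, d))
        for k in range(2):
            diff = X - means[k]
            covs[k] = (resp[:, k, None] * diff).T @ diff / nk[k]
            covs[k][np.diag_indices(d)] += ridge
        # E step
        log_prob = np.empty((n, 2))
        for k in range(2):
            chol = np.linalg.cholesky(covs[k])
            log_prob[:, k] = np.log(weights[k]) + _log_gaussian_chol(
                X, means[k], chol, d
            )
        norm = logsumexp(log_prob, axis=1)
        resp = np.exp(log_prob - norm[:, None])
        ll = float(norm.sum())
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * (1.0 + abs(ll)):
            break
    return weights, means, covs, resp, trace


def fit_gmm2(
    scores: np.ndarray,
    n_init: int = 10,
    max_iter: int = 500,
    tol: float = 1e-7,
    seed: int = 0,
) -> MixtureFit:
    """Fit a 2-component full-covariance Gaussian mixture by restarted EM.

    ``n_init`` restarts are seeded k-means++-style from the given generator
    seed; the restart with the highest final log-likelihood wins. Component
    covariances carry a ridge of 1e-6 x the mean score variance on their
    diagonals. A fit in which a component collects fewer than 2/n of the
    cells is returned flagged ``degenerate`` rather than silently.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2:
        raise ValueError("scores must be a 2-D array")
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 cells to fit a 2-component mixture")
    if not np.all(np.isfinite(X)):
        raise ValueError("scores must be finite")

    ridge = 1e-6 * float(np.mean(np.var(X, axis=0)))
    ridge = max(ridge, 1e-12)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(n_init, 1)):
        run = _em_run(X, rng, max_iter=max_iter, tol=tol, ridge=ridge)
        if best is None or run[4][-1] > best[4][-1]:
            best = run
    weights, means, covs, resp, trace = best
    degenerate = bool(weights.min() < 2.0 / n)
    if degenerate:
        logger.warning("degenerate mixture fit: component weights %s", weights)
    return MixtureFit(
        weights=weights,
        means=means,
        covariances=covs,
        responsibilities=resp,
        loglik_trace=trace,
        n_init=n_init,
        seed=seed,
        degenerate=degenerate,
    )


@dataclass
class CellLabelSet:
    labels: dict[str, str]  # cell_id -> endothelial | haematopoietic
    component_map: dict[int, str] = field(default_factory=dict)
    annotation_statistic: dict[int, float] = field(default_factory=dict)
    responsibility: dict[str, float] = field(default_factory=dict)

    def cells_with_label(self, label: str) -> list[str]:
        return [c for c, lab in self.labels.items() if lab == label]

    def binary_vector(self, cell_ids: list[str]) -> np.ndarray:
        """1 for haematopoietic, 0 for endothelial, in the given cell order."""
        return np.array([self.labels[c] == LABEL_HAEM for c in cell_ids], dtype=int)


def annotate_components(
    fit: MixtureFit,
    log_matrix: ExpressionMatrix,
    panel: MarkerPanel,
) -> CellLabelSet:
    """Hard-assign cells and name the high-Runx1 component haematopoietic.

    The annotation statistic of a component is the responsibility-weighted
    mean log expression of the annotation gene; the component with the
    strictly larger statistic is haematopoietic. An exact tie is raised to
    the caller rather than broken arbitrarily.
    """
    gene = panel.annotation_gene
    x = log_matrix.values[:, log_matrix.gene_index(gene)]
    if fit.responsibilities.shape[0] != log_matrix.n_cells:
        raise ValueError("mixture fit and matrix disagree on cell count")
    weights = fit.responsibilities.sum(axis=0)
    stats = (fit.responsibilities * x[:, None]).sum(axis=0) / weights
    if stats[0] == stats[1]:
        raise ValueError(
            f"annotation statistic tie for {gene!r}; cannot orient components"
        )
    haem_comp = int(np.argmax(stats))
    component_map = {
        haem_comp: LABEL_HAEM,
        1 - haem_comp: LABEL_ENDO,
    }
    hard = fit.hard_labels()
    labels = {
        cell: component_map[int(k)] for cell, k in zip(log_matrix.cell_ids, hard)
    }
    resp = {
        cell: float(fit.responsibilities[i, hard[i]])
        for i, cell in enumerate(log_matrix.cell_ids)
    }
    return CellLabelSet(
        labels=labels,
        component_map=component_map,
        annotation_statistic={k: float(v) for k, v in enumerate(stats)},
        responsibility=resp,
    )
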