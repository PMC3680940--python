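"""Feature-table management: missingness filtering, imputation, PCA.

The per-image feature vectors contain NaN slots (empty size classes, failed
passes).  Following the pipeline's design, columns with too many NaNs are
dropped, the remainder are zero-imputed, and principal components computed on
the *training* images reduce the collinear feature set to the components
capturing a requested fraction (default 90%) of total variance.  Test images
are always projected onto the training basis, never refit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["filter_missing", "PCABasis", "fit_pca", "project"]


def filter_missing(matrix: pd.DataFrame, max_nan: int | None = 200,
                   max_nan_frac: float | None = None):
    """Drop columns with ``max_nan`` or more NaNs, then zero-impute the rest.

    ``max_nan`` is an absolute count (columns kept when their NaN count is
    strictly below it); ``max_nan_frac`` expresses the same cut as a fraction
    of rows for cohorts of different size.  Returns ``(filtered, dropped)``
    where ``dropped`` lists removed column names.
    """
    if max_nan_frac is not None:
        max_nan = int(np.ceil(max_nan_frac * len(matrix)))
    if max_nan is None or max_nan < 0:
        raise ValueError("max_nan must be a non-negative count")
    nan_counts = matrix.isna().sum(axis=0)
    keep = nan_counts.index[nan_counts < max_nan]
    dropped = [c for c in matrix.columns if c not in set(keep)]
    if len(keep) == 0:
        raise ValueError("all columns dropped by the missingness filter")
    filtered = matrix[list(keep)].fillna(0.0)
    return filtered, dropped


@dataclass(frozen=True)
class PCABasis:
    """Principal-component basis fitted on training rows.

    ``components`` is (k, p) with orthonormal rows; ``variance_fractions`` is
    the full non-increasing spectrum (sums to 1 over all components, not just
    the retained k).
    """

    columns: tuple
    means: np.ndarray
    components: np.ndarray
    variance_fractions: np.ndarray
    k: int
    scales: np.ndarray | None = None

    @property
    def cumulative_variance(self) -> float:
        return float(self.variance_fractions[: self.k].sum())

    def to_json(self, path) -> None:
        payload = {
            "columns": list(self.columns),
            "means": self.means.tolist(),
            "components": self.components.tolist(),
            "variance_fractions": self.variance_fractions.tolist(),
            "k": self.k,
            "scales": None if self.scales is None else self.scales.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PCABasis":
        with open(path) as fh:
            payload = json.load(fh)
        scales = payload.get("scales")
        return cls(columns=tuple(payload["columns"]),
                   means=np.asarray(payload["means"]),
                   components=np.asarray(payload["components"]),
                   variance_fractions=np.asarray(payload["variance_fractions"]),
                   k=int(payload["k"]),
                   scales=None if scales is None else np.asarray(scales))


def fit_pca(train: pd.DataFrame, var_frac: float = 0.9,
            scale: bool = False) -> PCABasis:
    """Fit a PCA basis on the training matrix (covariance PCA on centered,
    unscaled features by default; ``scale=True`` standardizes columns first).

    ``k`` is the smallest component count whose cumulative variance fraction
    reaches ``var_frac``.  Sign convention: within each component the
    largest-magnitude loading is made positive, so the basis is deterministic.
    """
    if not (0.0 < var_frac <= 1.0):
        raise ValueError("var_frac must be in (0, 1]")
    X = train.to_numpy(dtype=np.float64)
    if np.isnan(X).any():
        raise ValueError("matrix contains NaNs; run filter_missing first")
    means = X.mean(axis=0)
    Xc = X - means
    scales = None
    if scale:
        scales = Xc.std(axis=0, ddof=1)
        scales[scales == 0] = 1.0
        Xc = Xc / scales
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2
    total = var.sum()
    if total <= 0:
        raise ValueError("zero-variance matrix: PCA undefined")
    fractions = var / total
    cum = np.cumsum(fractions)
    k = int(np.searchsorted(cum, var_frac - 1e-12) + 1)
    k = min(k, len(fractions))
    # deterministic sign: largest-magnitude loading positive per component
    for i in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
    return PCABasis(columns=tuple(train.columns), means=means,
                    components=Vt, variance_fractions=fractions, k=k,
                    scales=scales)


def project(matrix: pd.DataFrame, basis: PCABasis, k: int | None = None
            ) -> pd.DataFrame:
    """Project rows onto the retained components of a fitted basis.

    Centers by the *training* means and multiplies by the loadings; never
    refits.  Raises if any basis column is missing from ``matrix``.
    """
    missing = [c for c in basis.columns if c not in matrix.columns]
    if missing:
        raise KeyError(f"matrix lacks {len(missing)} basis columns, "
                       f"e.g. {missing[:3]}")
    k = basis.k if k is None else k
    X = matrix[list(basis.columns)].to_numpy(dtype=np.float64)
    Xc = X - basis.means
    if basis.scales is not None:
        Xc = Xc / basis.scales
    scores = Xc @ basis.components[:k].T
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(scores, index=matrix.index, columns=cols)
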