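"""Divergence-time regression of per-genome alignment counts, and PCA of the
conservation matrix.

Regression is ordinary least squares on raw counts; R^2 = 1 - SS_res/SS_tot
and the p-value is the two-sided t test on the slope with n - 2 degrees of
freedom. PCA mean-centers columns (no variance scaling: entries share the
[0, 1] fraction scale) and fixes signs by making each loading column's
largest-magnitude entry positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import stats

from .chains import ConservationMatrix
from .classify import _as_fraction


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


@dataclass
class OrdinationResult:
    scores: np.ndarray                    # REs x components
    loadings: np.ndarray                  # genomes x components, orthonormal columns
    explained_variance_ratio: np.ndarray  # non-increasing, sums to <= 1
    column_means: np.ndarray


def count_by_genome(matrix: ConservationMatrix, mode: str = "high",
                    hi=0.9, lo=0.1) -> dict[str, int]:
    """Per genome: number of REs with fraction >= hi (high) or <= lo (low)."""
    if mode not in ("high", "low"):
        raise ValueError(f"mode must be 'high' or 'low', got {mode!r}")
    n_res, _ = matrix.shape
    if n_res == 0:
        raise ValueError("empty conservation matrix")
    threshold = Fraction(_as_fraction(hi if mode == "high" else lo))
    counts = {}
    for j, genome in enumerate(matrix.genome_names):
        col = (row[j] for row in matrix.exact)
        if mode == "high":
            counts[genome] = sum(1 for f in col if f >= threshold)
        else:
            counts[genome] = sum(1 for f in col if f <= threshold)
    return counts


def fit_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """OLS of y on x with slope t-test p-value; requires n >= 3, non-constant x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 points, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")
    fit = stats.linregress(x, y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    y_hat = fit.intercept + fit.slope * x
    ss_res = float(np.sum((y - y_hat) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return RegressionResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=r_squared, p_value=float(fit.pvalue), n=n,
    )


def run_pca(matrix: ConservationMatrix | np.ndarray, n_components: int) -> OrdinationResult:
    """PCA via SVD of the column-centered matrix; deterministic sign."""
    X = matrix.values() if isinstance(matrix, ConservationMatrix) else np.asarray(matrix, dtype=float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("matrix must have >= 2 rows and >= 2 columns")
    if not (1 <= n_components <= min(n, p)):
        raise ValueError(f"n_components={n_components} outside [1, {min(n, p)}]")
    means = X.mean(axis=0)
    Xc = X - means
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = Vt[:n_components].T            # p x k
    scores = U[:, :n_components] * S[:n_components]
    # sign convention: largest-|entry| of each loading column positive
    for k in range(n_components):
        col = loadings[:, k]
        pivot = int(np.argmax(np.abs(col)))
        if col[pivot] < 0:
            loadings[:, k] = -col
            scores[:, k] = -scores[:, k]
    total_var = float(np.sum(Xc ** 2))
    # mean-subtraction roundoff leaves ~eps^2-scale residue on constant columns
    var_floor = (np.finfo(float).eps * max(1.0, float(np.abs(X).max()))) ** 2 * X.size
    if total_var <= var_floor:
        Xc = np.zeros_like(Xc)
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        loadings = Vt[:n_components].T
        scores = U[:, :n_components] * S[:n_components]
        total_var = 0.0
    if total_var > 0:
        evr = (S[:n_components] ** 2) / total_var
    else:
        evr = np.zeros(n_components)
    return OrdinationResult(scores, loadings, evr, means)


def write_trends_tsv(high: RegressionResult, low: RegressionResult, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("mode\tslope\tintercept\tr_squared\tp_value\tn\n")
        for mode, r in (("high", high), ("low", low)):
            fh.write(f"{mode}\t{r.slope:.6g}\t{r.intercept:.6g}\t{r.r_squared:.6g}\t"
                     f"{r.p_value:.6g}\t{r.n}\n")


def write_pca_tsv(matrix_names: Sequence[str], result: OrdinationResult, path) -> None:
    k = result.scores.shape[1]
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("re_name\t" + "\t".join(f"PC{i+1}" for i in range(k)) + "\n")
        for name, row in zip(matrix_names, result.scores):
            fh.write(name + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
        fh.write("#explained_variance_ratio\t"
                 + "\t".join(f"{v:.6g}" for v in result.explained_variance_ratio) + "\n")
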