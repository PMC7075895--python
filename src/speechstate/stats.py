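"""Group-level structure: paired tests, FDR, partial correlations, MDS.

Condition effects on single features are assessed with paired Wilcoxon
signed-rank tests per task, corrected across features by Benjamini-Hochberg
FDR at q < 0.05.  The joint structure of the surviving features is
summarized by partial correlations from the inverse of a shrinkage-
regularized correlation matrix, and the per-(condition, task) partial-
correlation matrices are projected to two dimensions with classical
(Torgerson) multidimensional scaling on their pairwise Frobenius distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

WILCOXON_EXACT_MAX_N = 25


@dataclass
class PairedTestResult:
    feature: str
    task: str
    contrast: tuple[str, str]
    statistic: float           # W = sum of positive-difference ranks
    p_value: float
    q_value: float = np.nan
    reject: bool = False
    degenerate: bool = False


def wilcoxon_paired(values_a: np.ndarray, values_b: np.ndarray,
                    feature: str = "", task: str = "",
                    contrast: tuple[str, str] = ("A", "B")
                    ) -> PairedTestResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped (Wilcoxon's convention); the exact null
    distribution is used for n <= 25 non-zero pairs, the normal
    approximation with continuity correction above.  All-zero differences
    give p = 1 and are flagged degenerate.
    """
    d = np.asarray(values_a, float) - np.asarray(values_b, float)
    d = d[np.isfinite(d)]
    nz = d[d != 0]
    if len(nz) == 0:
        log.info("all paired differences are zero for %s", feature or "<feature>")
        return PairedTestResult(feature, task, contrast, statistic=0.0,
                                p_value=1.0, degenerate=True)
    method = "exact" if len(nz) <= WILCOXON_EXACT_MAX_N else "approx"
    res = sstats.wilcoxon(nz, zero_method="wilcox",
                          correction=(method == "approx"),
                          alternative="two-sided", method=method)
    ranks = sstats.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    return PairedTestResult(feature, task, contrast, statistic=w_plus,
                            p_value=float(res.pvalue))


def bh_fdr(p_values: np.ndarray, q: float = 0.05
           ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Returns (reject flags, adjusted q-values).
    """
    p = np.asarray(p_values, dtype=float)
    if len(p) < 1:
        raise ValueError("at least one p-value required")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q_adj = multipletests(p, alpha=q, method="fdr_bh")[:2]
    return reject, q_adj


def paired_feature_tests(table: pd.DataFrame, condition_a: str,
                         condition_b: str, task: str,
                         feature_columns: list[str] | None = None,
                         q: float = 0.05) -> pd.DataFrame:
    """Wilcoxon tests for every feature of one contrast/task, BH-corrected.

    Returns a tidy frame (feature, task, contrast, W, p, q, reject).
    """
    cols = feature_columns or [c for c in table.columns
                               if c.split("-")[0] in ("A", "S", "P")]
    sub = table[table["task"] == task]
    a = sub[sub["condition"] == condition_a].set_index("subject_id")
    b = sub[sub["condition"] == condition_b].set_index("subject_id")
    common = sorted(set(a.index) & set(b.index))
    results = [wilcoxon_paired(a.loc[common, c].to_numpy(),
                               b.loc[common, c].to_numpy(),
                               feature=c, task=task,
                               contrast=(condition_a, condition_b))
               for c in cols]
    p = np.array([r.p_value for r in results])
    reject, q_adj = bh_fdr(p, q=q)
    rows = []
    for r, rej, qv in zip(results, reject, q_adj):
        r.q_value, r.reject = float(qv), bool(rej)
        rows.append({"feature": r.feature, "task": r.task,
                     "contrast": f"{condition_a}:{condition_b}",
                     "W": r.statistic, "p": r.p_value, "q": r.q_value,
                     "reject": r.reject, "degenerate": r.degenerate})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# partial correlations
# ---------------------------------------------------------------------------

def _analytic_shrinkage(Z: np.ndarray) -> float:
    """Analytic risk-minimizing shrinkage intensity toward the identity,
    computed on standardized data (Schafer-Strimmer style)."""
    n, p = Z.shape
    R = (Z.T @ Z) / (n - 1)
    W = Z[:, :, None] * Z[:, None, :]          # n x p x p products
    var_r = W.var(axis=0, ddof=1) * n / (n - 1) ** 2
    off = ~np.eye(p, dtype=bool)
    denom = float((R[off] ** 2).sum())
    if denom <= 0:
        return 1.0
    return float(np.clip(var_r[off].sum() / denom, 0.0, 1.0))


def partial_correlations(data: np.ndarray, shrinkage: float | None = None,
                         feature_names: list[str] | None = None
                         ) -> pd.DataFrame:
    """Partial correlations from the inverse regularized correlation matrix.

    The sample correlation matrix R is shrunk linearly toward the identity,
    R* = (1 - lam) R + lam I, with ``lam`` chosen by the analytic
    risk-minimizing formula when not given.  Partial correlations are
    rho_ij = -Theta_ij / sqrt(Theta_ii Theta_jj) with Theta = inv(R*).
    Working on the correlation scale makes the result invariant to
    per-feature affine rescaling.
    """
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    if n < 3 or p < 2:
        raise ValueError("need at least 3 observations and 2 features")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance feature: remove it first")
    Z = (X - X.mean(axis=0)) / sd
    R = (Z.T @ Z) / (n - 1)
    lam = _analytic_shrinkage(Z) if shrinkage is None else float(shrinkage)
    if not 0 <= lam <= 1:
        raise ValueError("shrinkage must lie in [0, 1]")
    R_star = (1 - lam) * R + lam * np.eye(p)
    if lam == 0 and n <= p:
        raise ValueError("correlation matrix is singular with n <= p; "
                         "use shrinkage > 0")
    try:
        theta = np.linalg.inv(R_star)
    except np.linalg.LinAlgError as err:
        raise ValueError("regularized matrix is singular; increase "
                         "shrinkage") from err
    d = np.sqrt(np.diag(theta))
    rho = -theta / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    rho = np.clip((rho + rho.T) / 2, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    names = feature_names or [f"f{i:04d}" for i in range(p)]
    return pd.DataFrame(rho, index=names, columns=names)


# ---------------------------------------------------------------------------
# classical MDS of correlation matrices
# ---------------------------------------------------------------------------

@dataclass
class MDSEmbedding:
    labels: list[str]
    coordinates: np.ndarray     # (n, 2), centered at the origin
    stress: float
    eigenvalues: np.ndarray


def mds_embed(matrices: list[pd.DataFrame],
              labels: list[str] | None = None) -> MDSEmbedding:
    """Classical (Torgerson) MDS of partial-correlation matrices.

    Pairwise distance is the Frobenius norm of the matrix difference.  The
    orientation is fixed by forcing the largest-magnitude coordinate on
    each axis positive.
    """
    if len(matrices) < 3:
        raise ValueError("at least 3 matrices required")
    ref = list(matrices[0].index)
    for m in matrices[1:]:
        if list(m.index) != ref or list(m.columns) != ref:
            raise ValueError("all matrices must share one feature list")
    n = len(matrices)
    labels = labels or [f"m{i}" for i in range(n)]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = np.linalg.norm(
                matrices[i].to_numpy() - matrices[j].to_numpy(), "fro")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    coords = np.zeros((n, 2))
    for axis in range(2):
        if evals[axis] > 1e-12:
            v = evecs[:, axis] * np.sqrt(evals[axis])
            if v[np.abs(v).argmax()] < 0:
                v = -v
            coords[:, axis] = v
    D_hat = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    denom = (D ** 2).sum()
    stress = float(np.sqrt(((D - D_hat) ** 2).sum() / denom)) if denom > 0 else 0.0
    return MDSEmbedding(labels=list(labels), coordinates=coords,
                        stress=stress, eigenvalues=evals)
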