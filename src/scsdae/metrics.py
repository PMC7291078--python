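"""Evaluation statistics for imputation quality.

Covers recovery of correlation structure (CMD, per-sample Pearson against
ground truth), false-signal analysis (Spearman gene-gene detection with
Bonferroni control, FDR/TPR against the known DE structure),
differential-expression power (Kruskal-Wallis with Benjamini-Hochberg),
spike-in accuracy (per-group MAE) and clustering agreement (ARI).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from math import comb

import numpy as np
import scipy.stats
from sklearn.metrics import adjusted_rand_score


@dataclass
class EvalReport:
    """Bundle of the metric values a benchmark run produces."""

    cmd: float | None = None
    mean_pairwise_pearson: float | None = None
    fdr: float | None = None
    tpr: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    mae_total: float | None = None
    mae_group_a: float | None = None
    mae_group_b: float | None = None
    ari: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}


def correlation_matrix(X: np.ndarray, axis: str = "samples",
                       method: str = "pearson") -> np.ndarray:
    """Correlation matrix between rows (samples) or columns (genes).

    Zero-variance vectors get correlation 0 with every other vector (with
    a warning); the diagonal is always 1.
    """
    X = np.asarray(X, dtype=np.float64)
    if axis == "genes":
        X = X.T
    elif axis != "samples":
        raise ValueError("axis must be 'samples' or 'genes'")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 vectors")
    if method == "spearman":
        X = scipy.stats.rankdata(X, axis=1)
    elif method != "pearson":
        raise ValueError("method must be 'pearson' or 'spearman'")
    sd = X.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance vectors; their "
                      "correlations are set to 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X)
    R = np.where(np.isfinite(R), R, 0.0)
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)


def cmd(R1: np.ndarray, R2: np.ndarray) -> float:
    """Correlation matrix distance: 1 - tr(R1 R2) / (||R1||_F ||R2||_F).

    0 when the two correlation structures coincide (up to scale), 1 when
    they are maximally different.
    """
    R1 = np.asarray(R1, dtype=np.float64)
    R2 = np.asarray(R2, dtype=np.float64)
    if R1.shape != R2.shape or R1.ndim != 2 or R1.shape[0] != R1.shape[1]:
        raise ValueError("R1 and R2 must be square matrices of equal shape")
    n1 = np.linalg.norm(R1, "fro")
    n2 = np.linalg.norm(R2, "fro")
    if n1 == 0 or n2 == 0:
        raise ValueError("zero Frobenius norm")
    return float(1.0 - np.trace(R1 @ R2) / (n1 * n2))


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray) -> tuple[float, float]:
    """Exact two-sided permutation p-value for the Spearman correlation of
    two (mid)rank vectors; enumerates all n! orderings."""
    from itertools import permutations

    def _corr(a, b):
        a = a - a.mean()
        b = b - b.mean()
        denom = np.sqrt((a ** 2).sum() * (b ** 2).sum())
        return float((a * b).sum() / denom) if denom > 0 else 0.0

    obs = _corr(rx, ry)
    count = total = 0
    for perm in permutations(ry):
        total += 1
        if abs(_corr(rx, np.asarray(perm))) >= abs(obs) - 1e-12:
            count += 1
    return obs, count / total


def spearman_pvalues(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman rho and two-sided p-values for columns of X.

    Exact permutation p-values for n <= 8 cells, the t-approximation
    otherwise; ties handled by midranks.  Constant columns get rho = 0,
    p = 1.
    """
    X = np.asarray(X, dtype=np.float64)
    n, g = X.shape
    if n < 3:
        raise ValueError("need at least 3 observations")
    if n <= 8:
        ranks = scipy.stats.rankdata(X, axis=0)
        rho = np.ones((g, g))
        p = np.zeros((g, g))
        for i in range(g):
            for j in range(i + 1, g):
                if ranks[:, i].std() == 0 or ranks[:, j].std() == 0:
                    r, pv = 0.0, 1.0
                else:
                    r, pv = _exact_spearman_p(ranks[:, i], ranks[:, j])
                rho[i, j] = rho[j, i] = r
                p[i, j] = p[j, i] = pv
        return rho, p
    ranks = scipy.stats.rankdata(X, axis=0)
    sd = ranks.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant genes; reported as "
                      "not significant", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.where(np.isfinite(rho), rho, 0.0)
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(rho, -1.0, 1.0)
    r2 = np.clip(rho ** 2, 0.0, 1.0 - 1e-15)
    t = np.abs(rho) * np.sqrt((n - 2) / (1.0 - r2))
    p = 2.0 * scipy.stats.t.sf(t, df=n - 2)
    p[constant, :] = 1.0
    p[:, constant] = 1.0
    np.fill_diagonal(p, 0.0)
    return rho, np.clip(p, 0.0, 1.0)


def gene_gene_significance(X: np.ndarray, alpha_fw: float = 0.05) -> np.ndarray:
    """Bonferroni-corrected Spearman gene-gene correlation detection.

    A pair (i, j) is flagged iff its Spearman p-value is below
    ``alpha_fw / C(G, 2)``, controlling the family-wise error at alpha_fw.
    Returns a symmetric boolean G x G matrix with a False diagonal.
    """
    X = np.asarray(X, dtype=np.float64)
    g = X.shape[1]
    if g < 2:
        raise ValueError("need at least 2 genes")
    _, p = spearman_pvalues(X)
    n_tests = comb(g, 2)
    flagged = p < (alpha_fw / n_tests)
    np.fill_diagonal(flagged, False)
    return flagged


def fdr_tpr(detected: np.ndarray, truth_de: np.ndarray) -> tuple[float, float]:
    """FDR and TPR of pairwise detections against the DE-pair truth.

    A pair is truly correlated iff both genes are DE (they covary through
    the shared group structure); any other detected pair is a false
    positive.  FDR = FP / max(1, FP + TP); TPR = TP / #(DE, DE) pairs.
    """
    detected = np.asarray(detected, dtype=bool)
    truth_de = np.asarray(truth_de, dtype=bool)
    g = truth_de.size
    if detected.shape != (g, g):
        raise ValueError("detected must be G x G with G = len(truth_de)")
    iu = np.triu_indices(g, k=1)
    det = detected[iu]
    true_pair = truth_de[iu[0]] & truth_de[iu[1]]
    tp = int((det & true_pair).sum())
    fp = int((det & ~true_pair).sum())
    n_true = int(true_pair.sum())
    fdr = fp / max(1, fp + tp)
    tpr = tp / n_true if n_true else float("nan")
    return float(fdr), float(tpr)


def kw_de_eval(X: np.ndarray, groups, truth_de, fdr_level: float = 0.05) -> tuple[float, float]:
    """Kruskal-Wallis DE detection with BH correction; sensitivity/specificity.

    Per-gene KW p-values across the groups are BH-adjusted at
    ``fdr_level``.  Sensitivity = flagged DE genes / DE genes;
    specificity = unflagged non-DE genes / non-DE genes.
    """
    X = np.asarray(X, dtype=np.float64)
    groups = np.asarray(groups)
    truth_de = np.asarray(truth_de, dtype=bool)
    labels = np.unique(groups)
    if labels.size < 2:
        raise ValueError("need at least 2 groups")
    idx = [np.flatnonzero(groups == lab) for lab in labels]
    if any(len(i) < 2 for i in idx):
        raise ValueError("every group needs at least 2 cells")
    pvals = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        samples = [X[i, j] for i in idx]
        try:
            pvals[j] = scipy.stats.kruskal(*samples).pvalue
        except ValueError:  # all values identical
            pvals[j] = 1.0
    adj = scipy.stats.false_discovery_control(pvals, method="bh")
    flagged = adj <= fdr_level
    n_de = int(truth_de.sum())
    n_non = truth_de.size - n_de
    sensitivity = float((flagged & truth_de).sum() / n_de) if n_de else float("nan")
    specificity = float((~flagged & ~truth_de).sum() / n_non) if n_non else float("nan")
    return sensitivity, specificity


def group_mae(imputed: np.ndarray, truth: np.ndarray, columns, groups) -> tuple[float, float, float]:
    """Mean absolute error over spiked columns: total and per group.

    Groups are taken in sorted label order (a = first, b = second).  The
    total is the entry-count-weighted mean of the group MAEs.
    """
    imputed = np.asarray(imputed, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if imputed.shape != truth.shape:
        raise ValueError("shape mismatch")
    columns = np.asarray(columns)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError("exactly two groups are required")
    err = np.abs(imputed[:, columns] - truth[:, columns])
    maes = []
    for lab in labels:
        sel = groups == lab
        if not sel.any():
            raise ValueError(f"empty group {lab!r}")
        maes.append(float(err[sel].mean()))
    return float(err.mean()), maes[0], maes[1]


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index between two partitions of the same cells."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label vectors must have equal length")
    return float(adjusted_rand_score(labels_a, labels_b))


def pairwise_pearson_truth(imputed: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Per-sample Pearson correlation between imputed and true profiles."""
    imputed = np.asarray(imputed, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if imputed.shape != truth.shape:
        raise ValueError("shape mismatch")
    a = imputed - imputed.mean(axis=1, keepdims=True)
    b = truth - truth.mean(axis=1, keepdims=True)
    denom = np.sqrt((a ** 2).sum(axis=1) * (b ** 2).sum(axis=1))
    if np.any(denom == 0):
        raise ValueError("zero-variance sample vector")
    return (a * b).sum(axis=1) / denom


def top_variable_genes(X: np.ndarray, n: int) -> np.ndarray:
    """Indices of the n highest-variance columns (for correlation heatmaps)."""
    X = np.asarray(X, dtype=np.float64)
    order = np.argsort(X.var(axis=0))[::-1]
    return np.sort(order[:n])
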