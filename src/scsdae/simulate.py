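"""Synthetic evaluation designs with full ground truth.

Three generators cover the benchmark settings used throughout the package:

* :func:`make_bulklike_profiles` + :func:`logistic_downsample` — a smooth
  developmental time-course of bulk-like profiles, thinned entrywise by a
  logistic capture-probability model to a target zero rate.  Used to test
  recovery of values and of the banded sample-sample correlation matrix.
* :func:`simulate_nb_two_group` — negative-binomial counts for two cell
  types with a stated fraction of differentially expressed genes; the
  gene-gene correlations induced by the group structure are the "true"
  signals for false-positive analyses.
* :func:`spike_artificial_genes` — artificial marker genes appended to a
  normalized matrix, near-zero in one group and high in the other, with
  extra zeros injected on the spiked columns; zeros in the low group are
  true zeros, zeros in the high group are dropouts.

All generators are driven by a ``numpy.random.Generator`` (or an integer
seed) and are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.special import expit

from .preprocess import CountMatrix, NormalizedMatrix


@dataclass
class DropoutModel:
    """Logistic capture model: P(captured) = sigmoid(intercept + slope * log(value))."""

    intercept: float
    slope: float

    def capture_probability(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=np.float64)
        with np.errstate(divide="ignore"):
            logv = np.where(v > 0, np.log(np.maximum(v, 1e-300)), -np.inf)
        return np.where(v > 0, expit(self.intercept + self.slope * logv), 0.0)


@dataclass
class SimTruth:
    """Ground truth emitted by every simulator.

    ``observed`` equals ``truth`` wherever ``dropout_mask`` is False and is
    0 wherever it is True; dropout never targets an entry that is already 0.
    """

    truth: np.ndarray
    observed: np.ndarray
    dropout_mask: np.ndarray
    group_labels: np.ndarray | None = None
    de_flags: np.ndarray | None = None
    spiked_columns: np.ndarray | None = None
    params: dict = field(default_factory=dict)


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


class UnreachableSparsityError(ValueError):
    """Requested zero rate is below the matrix's pre-existing zero fraction."""


def logistic_downsample(bulk: CountMatrix | np.ndarray, target_zero_rate: float,
                        slope: float = 1.0, rng=None) -> SimTruth:
    """Thin a positive matrix to a target zero fraction via logistic capture.

    Each positive entry is retained independently with probability
    sigmoid(intercept + slope * log(value)), so small values drop out
    preferentially.  The intercept is solved by bisection so that the
    *expected* overall zero fraction (pre-existing zeros plus expected
    dropouts) matches ``target_zero_rate`` to 1e-4.
    """
    rng = _as_rng(rng)
    values = bulk.values if isinstance(bulk, CountMatrix) else np.asarray(bulk, dtype=np.float64)
    if not 0.0 < target_zero_rate < 1.0:
        raise ValueError("target_zero_rate must be in (0, 1)")
    if slope <= 0:
        raise ValueError("slope must be positive")
    total = values.size
    pos = values > 0
    pre_zero_frac = 1.0 - pos.sum() / total
    if target_zero_rate <= pre_zero_frac:
        raise UnreachableSparsityError(
            f"unreachable sparsity: target {target_zero_rate} <= pre-existing "
            f"zero fraction {pre_zero_frac:.4f}")
    logv = np.log(values[pos])

    def expected_zero_frac(intercept: float) -> float:
        p_cap = expit(intercept + slope * logv)
        return pre_zero_frac + (1.0 - p_cap).sum() / total

    lo, hi = -700.0, 700.0  # expected zero frac is decreasing in intercept
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expected_zero_frac(mid) > target_zero_rate:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-10:
            break
    intercept = 0.5 * (lo + hi)
    assert abs(expected_zero_frac(intercept) - target_zero_rate) < 1e-4
    model = DropoutModel(intercept=intercept, slope=slope)
    p_cap = model.capture_probability(values)
    captured = rng.random(values.shape) < p_cap
    dropout_mask = pos & ~captured
    observed = np.where(dropout_mask, 0.0, values)
    return SimTruth(truth=values.copy(), observed=observed, dropout_mask=dropout_mask,
                    params={"intercept": intercept, "slope": slope,
                            "target_zero_rate": target_zero_rate})


def make_bulklike_profiles(n_samples: int = 206, n_genes: int = 2000,
                           trajectory_smoothness: float = 0.15, rng=None) -> CountMatrix:
    """Bulk-like profiles ordered along a latent developmental time.

    Per-gene log-expression profiles are Gaussian-smoothed white noise over
    the sample order (kernel width = smoothness x n_samples), on top of a
    gene-specific baseline, so neighbouring samples correlate strongly and
    distant ones weakly — a banded sample-sample correlation matrix.
    ``trajectory_smoothness = inf`` degenerates to identical samples.
    """
    rng = _as_rng(rng)
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    base = rng.uniform(np.log(10.0), np.log(1e4), size=n_genes)
    amplitude = rng.uniform(0.5, 2.0, size=n_genes)
    noise = rng.standard_normal((n_genes, n_samples))
    if np.isinf(trajectory_smoothness):
        profiles = np.zeros_like(noise)
    else:
        sigma = max(trajectory_smoothness * n_samples, 1e-6)
        profiles = gaussian_filter1d(noise, sigma=sigma, axis=1, mode="nearest")
        sd = profiles.std(axis=1, keepdims=True)
        profiles = np.where(sd > 0, profiles / np.maximum(sd, 1e-12), 0.0)
    logx = base[:, None] + amplitude[:, None] * profiles
    values = np.exp(logx).T  # samples x genes
    return CountMatrix(values=values,
                       cell_ids=[f"sample{i}" for i in range(n_samples)],
                       gene_ids=[f"gene{j}" for j in range(n_genes)])


def simulate_nb_two_group(n_cells: int = 1000, n_genes: int = 500,
                          mean_low: float = 1e3, mean_high: float = 1e4,
                          de_fraction: float = 0.5, fold_change: float = 3.0,
                          dispersion: float = 0.5, rng=None) -> SimTruth:
    """Two-cell-type negative-binomial count matrix with known DE genes.

    Per-gene base means are log-uniform on [mean_low, mean_high].  The
    first ceil(de_fraction * n_genes) genes are differentially expressed:
    their group-2 mean is multiplied or divided by ``fold_change``
    (alternating direction to avoid a global library-size shift).  Counts
    are NB with size parameter ``dispersion`` (variance mu + mu^2/size).
    """
    rng = _as_rng(rng)
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must be in [0, 1]")
    if dispersion <= 0:
        raise ValueError("dispersion (NB size) must be positive")
    if mean_low <= 0 or mean_high < mean_low:
        raise ValueError("means must be positive with mean_high >= mean_low")
    base_mean = np.exp(rng.uniform(np.log(mean_low), np.log(mean_high), size=n_genes))
    n_de = int(np.ceil(de_fraction * n_genes))
    de_flags = np.zeros(n_genes, dtype=bool)
    de_flags[:n_de] = True
    mu = np.tile(base_mean, (2, 1))  # group x gene
    direction = np.where(np.arange(n_de) % 2 == 0, fold_change, 1.0 / fold_change)
    mu[1, :n_de] = base_mean[:n_de] * direction
    n_g1 = n_cells // 2
    group_labels = np.repeat([0, 1], [n_g1, n_cells - n_g1])
    cell_mu = mu[group_labels]  # cells x genes
    p = dispersion / (dispersion + cell_mu)
    counts = rng.negative_binomial(dispersion, p).astype(np.float64)
    return SimTruth(truth=counts.copy(), observed=counts,
                    dropout_mask=np.zeros_like(counts, dtype=bool),
                    group_labels=group_labels, de_flags=de_flags,
                    params={"fold_change": fold_change, "dispersion": dispersion,
                            "mean_low": mean_low, "mean_high": mean_high})


def spike_artificial_genes(X: NormalizedMatrix | np.ndarray, group_labels,
                           n_genes: int = 5, mean_a: float = 0.0, mean_b: float = 2.0,
                           sd: float = float(np.sqrt(0.1)), zero_rate: float = 0.5,
                           rng=None) -> SimTruth:
    """Append artificial marker genes and inject extra zeros on them.

    Group-A cells draw the spiked genes from Normal(mean_a, sd) and
    group-B cells from Normal(mean_b, sd); negative draws are clamped to 0,
    so the low group contains true zeros.  Each positive spiked value is
    then independently zeroed with the probability that brings the overall
    zero fraction of the spiked columns to ``zero_rate``.
    """
    rng = _as_rng(rng)
    Xv = X.values if isinstance(X, NormalizedMatrix) else np.asarray(X, dtype=np.float64)
    group_labels = np.asarray(group_labels)
    labels = np.unique(group_labels)
    if labels.size != 2:
        raise ValueError("exactly two groups are required")
    if not 0.0 <= zero_rate < 1.0:
        raise ValueError("zero_rate must be in [0, 1)")
    n_cells = Xv.shape[0]
    if group_labels.size != n_cells:
        raise ValueError("group_labels length must equal the cell count")
    means = np.where(group_labels == labels[0], mean_a, mean_b)
    spiked = rng.normal(means[:, None], sd, size=(n_cells, n_genes))
    spiked = np.maximum(spiked, 0.0)
    pos = spiked > 0
    pre_zero_frac = 1.0 - pos.mean()
    q = 0.0
    if zero_rate > pre_zero_frac:
        q = (zero_rate - pre_zero_frac) / (1.0 - pre_zero_frac)
    dropped = pos & (rng.random(spiked.shape) < q)
    spiked_obs = np.where(dropped, 0.0, spiked)
    truth = np.hstack([Xv, spiked])
    observed = np.hstack([Xv, spiked_obs])
    dmask = np.hstack([np.zeros_like(Xv, dtype=bool), dropped])
    cols = np.arange(Xv.shape[1], Xv.shape[1] + n_genes)
    return SimTruth(truth=truth, observed=observed, dropout_mask=dmask,
                    group_labels=group_labels, spiked_columns=cols,
                    params={"mean_a": mean_a, "mean_b": mean_b, "sd": sd,
                            "zero_rate": zero_rate, "dropout_prob": q})
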