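"""Paired statistical tests used throughout the analysis.

Every comparison in the pipeline is paired within subjects, so the
permutation scheme is the sign-flip of paired differences: under the null
of exchangeable condition labels, each subject's difference is equally
likely to carry either sign.  The test statistic is the paired t.

The permutation p-value is exact (full enumeration of the 2^n sign
patterns) whenever 2^n <= 2^14; otherwise ``n_perm`` Monte-Carlo flips are
drawn and the add-one estimator (b + 1) / (n_perm + 1) is used so p never
underflows to zero.  Multiple-testing correction is Benjamini–Hochberg
step-up (via statsmodels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

EXHAUSTIVE_LIMIT = 2 ** 14


class DegenerateInputError(ValueError):
    """Raised when a test statistic is undefined (e.g. zero variance)."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of one (possibly vectorized) paired test."""

    statistic: np.ndarray
    p_raw: np.ndarray
    n_units: int
    n_permutations: int | None = None  # None => analytic
    exhaustive: bool = False

    @property
    def analytic(self) -> bool:
        return self.n_permutations is None


def _paired_t_stat(d: np.ndarray) -> np.ndarray:
    """Paired t statistic along axis 0; zero-variance cells give t = 0."""
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    # zero-variance cells: t is +-inf for a nonzero mean, 0 for an all-zero one
    with np.errstate(invalid="ignore"):
        degen = np.where(mean == 0, 0.0, np.sign(mean) * np.inf)
    return np.where(sd == 0, degen, t)


def paired_permutation_t(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = 0,
) -> TestResult:
    """Two-sided sign-flip permutation t-test on paired samples.

    ``a`` and ``b`` are arrays of shape ``(n_units, ...)``; the test is run
    independently for every trailing cell, sharing one set of sign flips
    (valid because flips are exchangeable across cells under the null).

    Returns raw two-sided p-values; enumeration is exhaustive when
    ``2**n_units <= 2**14``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"paired samples differ in shape: {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 paired units")
    d = a - b
    flat = d.reshape(n, -1)
    t_obs = _paired_t_stat(flat)

    exhaustive = 2 ** n <= EXHAUSTIVE_LIMIT
    if exhaustive:
        # all 2^n sign patterns, rows of +-1
        signs = np.array(
            [[1 if (i >> k) & 1 == 0 else -1 for k in range(n)]
             for i in range(2 ** n)],
            dtype=float,
        )
        n_draws = signs.shape[0]
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        n_draws = n_perm

    # t for every sign pattern: mean and sd of s_i * d_i per cell
    sd2 = flat ** 2  # invariant under sign flips
    m = signs @ flat / n                               # (P, cells)
    ss = sd2.sum(axis=0)[None, :] - n * m ** 2         # sum of squares about mean
    ss = np.maximum(ss, 0.0)                           # guard float cancellation
    with np.errstate(divide="ignore", invalid="ignore"):
        sdp = np.sqrt(ss / (n - 1))
        t_perm = m / (sdp / np.sqrt(n))
        degen = np.where(m == 0, 0.0, np.sign(m) * np.inf)
    t_perm = np.where(sdp == 0, degen, t_perm)

    exceed = (np.abs(t_perm) >= np.abs(t_obs)[None, :] - 1e-12).sum(axis=0)
    if exhaustive:
        p = exceed / n_draws
    else:
        p = (exceed + 1) / (n_draws + 1)
    shape = d.shape[1:]
    return TestResult(
        statistic=t_obs.reshape(shape),
        p_raw=p.reshape(shape),
        n_units=n,
        n_permutations=n_draws,
        exhaustive=exhaustive,
    )


def paired_t(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Classical two-sided paired t-test (vectorized over trailing axes).

    Raises
    ------
    DegenerateInputError
        If the differences have zero variance in every cell.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"paired samples differ in shape: {a.shape} vs {b.shape}")
    if a.shape[0] < 2:
        raise ValueError("need at least 2 paired units")
    d = a - b
    if np.all(d.std(axis=0) == 0):
        raise DegenerateInputError("paired differences have zero variance")
    res = sps.ttest_rel(a, b, axis=0)
    return TestResult(
        statistic=np.asarray(res.statistic),
        p_raw=np.asarray(res.pvalue),
        n_units=a.shape[0],
        n_permutations=None,
    )


def fdr_bh(
    p_values: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up FDR correction.

    Returns ``(reject, p_adjusted)`` with the input shape preserved.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(p.shape, dtype=bool), p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p.ravel(), alpha=alpha, method="fdr_bh")
    return reject.reshape(p.shape), p_adj.reshape(p.shape)
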