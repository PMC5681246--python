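"""Hold-out evaluation: train/test split, test-set R^2, a permutation test of
the difference in out-of-sample prediction between two models, and decile
stratification with standardized effect sizes.

The permutation test targets H0: the multi-score and the best single-score
model are exchangeable as prediction rules.  Each permutation independently
swaps, per individual with probability 1/2, the pair of predictions, and the
difference in R^2 is recomputed; the empirical two-sided p-value is the
+1-corrected fraction of null |differences| at least as extreme as observed.

Decile stratification compares outcome means across quantile bins of the
predicted score; the top-vs-bottom contrast is summarized by Cohen's d, by
Cohen's U3 = Phi(d) (fraction of the top group above the bottom group's mean)
and by the common-language effect size CL = Phi(d / sqrt(2)) (probability a
random top-group member outscores a random bottom-group member).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SplitSpec",
    "PermutationResult",
    "DecileReport",
    "train_test_split",
    "r2_test",
    "permutation_model_comparison",
    "decile_stratify",
    "cohens_d",
    "u3",
    "common_language_effect",
]


@dataclass
class SplitSpec:
    """Disjoint, exhaustive train/test partition of individual indices."""

    train: np.ndarray
    test: np.ndarray
    fraction: float
    seed: int

    def __post_init__(self) -> None:
        assert np.intersect1d(self.train, self.test).size == 0
        assert len(self.train) + len(self.test) == len(np.union1d(self.train, self.test))


def train_test_split(ids, fraction: float = 0.6, seed: int = 0) -> SplitSpec:
    """Seeded random split; train size is round(n * fraction)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    ids = np.asarray(ids)
    n = len(ids)
    if n < 5:
        raise ValueError("need at least 5 individuals to split")
    n_train = int(np.rint(n * fraction))
    perm = np.random.default_rng(seed).permutation(n)
    return SplitSpec(train=np.sort(ids[perm[:n_train]]), test=np.sort(ids[perm[n_train:]]),
                     fraction=fraction, seed=seed)


def r2_test(y, yhat, convention: str = "corr") -> float:
    """Coefficient of determination of predictions on held-out data.

    Default is squared Pearson correlation (so a sign-reversed perfect
    predictor still scores 1 — a documented caveat); ``convention="ss"``
    gives 1 - SS_res/SS_tot, which can be negative.  Constant predictions
    have undefined correlation and return 0 with a warning.
    """
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    if len(y) < 3:
        raise ValueError("need at least 3 observations")
    if convention == "ss":
        sst = float(((y - y.mean()) ** 2).sum())
        if sst == 0:
            raise ValueError("constant outcome")
        return 1.0 - float(((y - yhat) ** 2).sum()) / sst
    if yhat.std() == 0 or y.std() == 0:
        warnings.warn("constant prediction or outcome; R^2 defined as 0")
        return 0.0
    r = float(np.corrcoef(y, yhat)[0, 1])
    return r * r


@dataclass
class PermutationResult:
    """Observed out-of-sample R^2 difference and its permutation null."""

    observed_diff: float
    r2_a: float
    r2_b: float
    n_perm: int
    p_value: float
    seed: int
    sided: str = "two"

    def __post_init__(self) -> None:
        assert 0.0 < self.p_value <= 1.0


def _r2_rows(y: np.ndarray, s_p: np.ndarray, s_py: np.ndarray, s_pp: np.ndarray) -> np.ndarray:
    """Squared correlation of y with each of B prediction rows, given the
    per-row sums sum(pred), sum(pred*y), sum(pred^2)."""
    n = len(y)
    sy = y.sum()
    syy = float(y @ y)
    cov = s_py - s_p * sy / n
    var_p = s_pp - s_p**2 / n
    var_y = syy - sy**2 / n
    denom = var_p * var_y
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(denom > 0, cov**2 / denom, 0.0)
    return r2


def permutation_model_comparison(
    y,
    pred_a,
    pred_b,
    n_perm: int = 100_000,
    seed: int = 0,
    sided: str = "two",
    chunk: int = 5_000,
) -> PermutationResult:
    """Permutation test of exchangeability of two prediction vectors.

    observed_diff = R^2(y, pred_a) - R^2(y, pred_b) (squared-correlation
    convention).  Each of ``n_perm`` permutations independently swaps the two
    predictions per individual with probability 1/2 and recomputes the
    difference; p = (r + 1) / (B + 1) with r the count of null differences at
    least as extreme as observed (|.| for the default two-sided test).
    """
    y = np.asarray(y, float)
    a = np.asarray(pred_a, float)
    b = np.asarray(pred_b, float)
    if not len(y) == len(a) == len(b):
        raise ValueError("y and both prediction vectors must have equal length")
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives unstable p-values; refuse")
    r2a = r2_test(y, a) if a.std() > 0 else 0.0
    r2b = r2_test(y, b) if b.std() > 0 else 0.0
    observed = r2a - r2b
    diff = a - b
    rng = np.random.default_rng(seed)
    n = len(y)
    count = 0
    for start in range(0, n_perm, chunk):
        bsz = min(chunk, n_perm - start)
        mask = rng.integers(0, 2, size=(bsz, n)).astype(float)
        # perm_a = b + mask*diff ; perm_b = a - mask*diff  (mask^2 == mask)
        m_d = mask @ diff
        m_dy = mask @ (diff * y)
        m_bd = mask @ (b * diff)
        m_ad = mask @ (a * diff)
        m_dd = mask @ (diff * diff)
        s_pa = b.sum() + m_d
        s_pay = float(b @ y) + m_dy
        s_paa = float(b @ b) + 2 * m_bd + m_dd
        s_pb = a.sum() - m_d
        s_pby = float(a @ y) - m_dy
        s_pbb = float(a @ a) - 2 * m_ad + m_dd
        null = _r2_rows(y, s_pa, s_pay, s_paa) - _r2_rows(y, s_pb, s_pby, s_pbb)
        if sided == "two":
            count += int((np.abs(null) >= abs(observed) - 1e-15).sum())
        else:
            count += int((null >= observed - 1e-15).sum())
    p = (count + 1) / (n_perm + 1)
    return PermutationResult(observed_diff=float(observed), r2_a=float(r2a), r2_b=float(r2b),
                             n_perm=n_perm, p_value=float(p), seed=seed, sided=sided)


@dataclass
class DecileReport:
    """Outcome means by quantile of the predicted score, with top-vs-bottom
    standardized effect sizes."""

    table: pd.DataFrame        # quantile, n, mean, ci_low, ci_high
    d: float
    d_ci: tuple[float, float]
    u3: float
    cl: float
    n_quantiles: int


def decile_stratify(y, yhat, n_quantiles: int = 10) -> DecileReport:
    """Bin individuals by quantile of the prediction and summarize outcomes.

    Ties in the prediction are broken by stable rank order, so bin sizes
    always differ by at most one.  Per bin: n, mean outcome and a normal 95%
    CI (mean +/- 1.96 SD/sqrt(n)).  The top-vs-bottom contrast is summarized
    by Cohen's d with CI, U3 and the common-language effect size.
    """
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    n = len(y)
    if n < 2 * n_quantiles:
        raise ValueError("too few individuals for the requested quantile count")
    order = np.argsort(yhat, kind="stable")
    bins = np.array_split(order, n_quantiles)
    rows = []
    for q, idx in enumerate(bins, start=1):
        vals = y[idx]
        mu = vals.mean()
        half = 1.96 * vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
        rows.append({"quantile": q, "n": len(vals), "mean": mu,
                     "ci_low": mu - half, "ci_high": mu + half})
    d, ci = cohens_d(y[bins[-1]], y[bins[0]])
    return DecileReport(table=pd.DataFrame(rows), d=d, d_ci=ci,
                        u3=u3(d), cl=common_language_effect(d), n_quantiles=n_quantiles)


def cohens_d(top_group, bottom_group) -> tuple[float, tuple[float, float]]:
    """Cohen's d = (mean_top - mean_bottom) / pooled SD, with its normal 95% CI
    (SE = sqrt((n1+n2)/(n1 n2) + d^2 / (2(n1+n2))))."""
    a = np.asarray(top_group, float)
    b = np.asarray(bottom_group, float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 members")
    pooled = np.sqrt(((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2))
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    d = float((a.mean() - b.mean()) / pooled)
    se = np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2)))
    return d, (float(d - 1.96 * se), float(d + 1.96 * se))


def u3(d: float) -> float:
    """Cohen's U3: fraction of the higher group above the lower group's mean,
    Phi(d) under normality with equal variances."""
    return float(stats.norm.cdf(d))


def common_language_effect(d: float) -> float:
    """Common-language effect size: probability a random member of the higher
    group outscores a random member of the lower group, Phi(d / sqrt(2))."""
    return float(stats.norm.cdf(d / np.sqrt(2.0)))
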