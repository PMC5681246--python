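"""Polygenic score construction: LD estimation, effect-size shrinkage,
weighted allele sums, and standardization with principal-component adjustment.

Marginal GWAS effect estimates are inflated at SNPs that tag causal variants
through linkage disequilibrium.  The shrinkage step replaces the marginal
estimates beta_hat with (approximate) posterior-mean joint effects under a
Gaussian prior, conditioning on a windowed LD matrix D estimated from the
target panel:

* infinitesimal prior (every SNP causal, effect variance h2/M):
  closed form  w = (D + M/(N h2) I)^{-1} beta_hat  per window;
* point-normal prior (each SNP causal with probability p, causal effect
  variance h2/(M p)): posterior mean via a per-SNP Gibbs sampler, the
  mixture-prior generalization of the closed form above.

Scores are the weighted sums of allele dosages, then standardized and
residualized on genotype principal components to remove population
stratification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .simulate import GenotypePanel

__all__ = [
    "LDMatrix",
    "ShrunkEffects",
    "PCBasis",
    "estimate_ld",
    "shrink_infinitesimal",
    "shrink_gibbs",
    "compute_scores",
    "compute_pcs",
    "adjust_scores",
]


@dataclass
class LDMatrix:
    """Windowed LD: per-window correlation matrices of standardized dosages.

    Cross-window LD is treated as zero.  Monomorphic SNPs get an identity row
    (no LD information); they are reported in ``excluded``.
    """

    window_slices: list[slice]
    window_corrs: list[np.ndarray]
    excluded: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_snps(self) -> int:
        return self.window_slices[-1].stop if self.window_slices else 0

    def dense(self) -> np.ndarray:
        d = np.zeros((self.n_snps, self.n_snps))
        for sl, c in zip(self.window_slices, self.window_corrs):
            d[sl, sl] = c
        return d


@dataclass
class ShrunkEffects:
    """Posterior-mean SNP weights on the standardized-genotype scale."""

    weights: np.ndarray
    fraction_p: float
    h2: float
    n_gwas: int
    m_total: int
    method: str               # "infinitesimal" | "gibbs"
    iters: int = 0
    burn_in: int = 0
    seed: int | None = None


@dataclass
class PCBasis:
    """Genotype principal components: individuals x k PC scores, ordered by
    decreasing explained variance, mutually orthogonal columns."""

    components: np.ndarray           # n x k
    explained_variance_ratio: np.ndarray

    @property
    def k(self) -> int:
        return self.components.shape[1]


def _psd_regularize(corr: np.ndarray, floor: float = -1e-8) -> np.ndarray:
    evals = np.linalg.eigvalsh(corr)
    if evals.min() < floor:
        corr = corr + (abs(evals.min()) + 1e-8) * np.eye(corr.shape[0])
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
    return corr


def estimate_ld(panel: GenotypePanel | np.ndarray, window_size: int) -> LDMatrix:
    """Pearson correlation of standardized dosages within non-overlapping
    windows of ``window_size`` SNPs; zero across windows.

    Monomorphic SNPs carry no LD information: their rows are identity and
    their indices are returned in ``excluded`` with a warning.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    x = panel.dosages.astype(float) if isinstance(panel, GenotypePanel) else np.asarray(panel, float)
    n, m = x.shape
    if n < 2:
        raise ValueError("need at least 2 individuals to estimate LD")
    sd = x.std(axis=0)
    mono = np.flatnonzero(sd == 0)
    if mono.size:
        warnings.warn(f"{mono.size} monomorphic SNPs excluded from LD estimation")
    xs = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    xs[:, mono] = 0.0
    slices, corrs = [], []
    for lo in range(0, m, window_size):
        hi = min(lo + window_size, m)
        block = xs[:, lo:hi]
        corr = block.T @ block / n
        local_mono = mono[(mono >= lo) & (mono < hi)] - lo
        corr[local_mono, :] = 0.0
        corr[:, local_mono] = 0.0
        corr[local_mono, local_mono] = 1.0
        np.fill_diagonal(corr, 1.0)
        slices.append(slice(lo, hi))
        corrs.append(_psd_regularize(corr))
    return LDMatrix(slices, corrs, excluded=mono)


def shrink_infinitesimal(
    beta_marg: np.ndarray,
    ld: LDMatrix,
    n_gwas: int,
    h2: float,
    m_total: int | None = None,
) -> ShrunkEffects:
    """Closed-form infinitesimal shrinkage, per window:
    ``w = (D + (M / (N h2)) I)^{-1} beta_hat``.

    With identity LD this reduces to multiplying every marginal estimate by
    the shrinkage factor N h2 / (N h2 + M).
    """
    if h2 <= 0:
        raise ValueError("h2 must be positive")
    if n_gwas <= 0:
        raise ValueError("n_gwas must be positive")
    beta_marg = np.asarray(beta_marg, dtype=float)
    if beta_marg.shape[0] != ld.n_snps:
        raise ValueError("beta_marg length must match LD SNP count")
    m = int(m_total) if m_total is not None else ld.n_snps
    ridge = m / (n_gwas * h2)
    w = np.empty_like(beta_marg)
    for sl, corr in zip(ld.window_slices, ld.window_corrs):
        a = corr + ridge * np.eye(corr.shape[0])
        w[sl] = np.linalg.solve(a, beta_marg[sl])
    return ShrunkEffects(w, fraction_p=1.0, h2=h2, n_gwas=n_gwas, m_total=m,
                         method="infinitesimal")


@njit(cache=True)
def _gibbs_window(d, beta_hat, inv_n, sigma2, p, iters, burn_in, unif, norm):  # pragma: no cover
    m = beta_hat.shape[0]
    w = np.zeros(m)
    dw = np.zeros(m)          # running D @ w
    avg = np.zeros(m)
    shrink = sigma2 / (sigma2 + inv_n)
    post_sd = np.sqrt(sigma2 * inv_n / (sigma2 + inv_n))
    # log ratio of null/causal density prefactors
    odds_pref = (1.0 - p) / p * np.sqrt((sigma2 + inv_n) / inv_n)
    prec_gap = 1.0 / inv_n - 1.0 / (sigma2 + inv_n)   # > 0
    n_avg = 0
    for it in range(iters):
        for j in range(m):
            bt = beta_hat[j] - (dw[j] - d[j, j] * w[j])
            if p >= 1.0:
                pj = 1.0
            else:
                pj = 1.0 / (1.0 + odds_pref * np.exp(-0.5 * bt * bt * prec_gap))
            mean = shrink * bt
            new_w = 0.0
            if unif[it, j] < pj:
                new_w = mean + post_sd * norm[it, j]
            delta = new_w - w[j]
            if delta != 0.0:
                for k in range(m):
                    dw[k] += d[k, j] * delta
                w[j] = new_w
            if it >= burn_in:
                avg[j] += pj * mean
        if it >= burn_in:
            n_avg += 1
    return avg / n_avg


def shrink_gibbs(
    beta_marg: np.ndarray,
    ld: LDMatrix,
    n_gwas: int,
    h2: float,
    m_total: int | None = None,
    fraction_p: float = 0.1,
    iters: int = 500,
    burn_in: int = 100,
    seed: int = 0,
) -> ShrunkEffects:
    """Posterior-mean weights under the point-normal prior via Gibbs sampling.

    Each SNP is causal with probability ``fraction_p``; causal effects have
    variance h2/(M p).  Per sweep and SNP the sampler conditions on the
    window's LD and the current state of the other SNPs, samples the
    causal indicator and effect, and accumulates the Rao-Blackwellized
    conditional posterior mean; the returned weight is the post-burn-in
    average.  All random draws are pre-generated from a seeded Generator, so
    a fixed seed reproduces the result exactly.
    """
    if not 0.0 < fraction_p <= 1.0:
        raise ValueError("fraction_p must be in (0, 1]")
    if iters <= burn_in:
        raise ValueError("iters must exceed burn_in")
    if h2 <= 0 or n_gwas <= 0:
        raise ValueError("h2 and n_gwas must be positive")
    beta_marg = np.asarray(beta_marg, dtype=float)
    m = int(m_total) if m_total is not None else ld.n_snps
    sigma2 = h2 / (m * fraction_p)
    inv_n = 1.0 / n_gwas
    rng = np.random.default_rng(seed)
    w = np.empty_like(beta_marg)
    for sl, corr in zip(ld.window_slices, ld.window_corrs):
        width = sl.stop - sl.start
        unif = rng.uniform(size=(iters, width))
        norm = rng.standard_normal(size=(iters, width))
        w[sl] = _gibbs_window(
            np.ascontiguousarray(corr), beta_marg[sl], inv_n, sigma2,
            float(fraction_p), iters, burn_in, unif, norm,
        )
    guard = 100.0 * (np.abs(beta_marg).max() + np.sqrt(sigma2))
    if not np.all(np.isfinite(w)) or np.abs(w).max() > guard:
        raise RuntimeError(
            f"Gibbs sampler diverged: max |weight| {np.abs(w).max():.3g} "
            f"(guard {guard:.3g}); check LD regularization and h2/N inputs"
        )
    return ShrunkEffects(w, fraction_p=fraction_p, h2=h2, n_gwas=n_gwas, m_total=m,
                         method="gibbs", iters=iters, burn_in=burn_in, seed=seed)


def compute_scores(panel: GenotypePanel | np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted allele sums: ``score_i = sum_j dosage_ij * w_j``.

    ``weights`` may be a vector or a (n_snps x n_sets) matrix; dosages must be
    counted on the harmonized effect allele.  Pass ``panel.standardized()``
    for scores on the standardized-genotype scale.
    """
    x = panel.dosages.astype(float) if isinstance(panel, GenotypePanel) else np.asarray(panel, float)
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != x.shape[1]:
        raise ValueError(f"weights ({w.shape[0]}) not aligned to panel SNPs ({x.shape[1]})")
    return x @ w


def compute_pcs(panel: GenotypePanel | np.ndarray, k: int) -> PCBasis:
    """Top-k principal components of the column-standardized dosage matrix.

    Components are left singular directions scaled by their singular values
    (PC scores), ordered by decreasing explained variance.  Sign convention:
    the largest-magnitude SNP loading of each component is positive.
    """
    x = panel.standardized() if isinstance(panel, GenotypePanel) else np.asarray(panel, float)
    n, m = x.shape
    if k == 0:
        return PCBasis(np.empty((n, 0)), np.empty(0))
    if not 0 < k < min(n, m):
        raise ValueError(f"k must be in (0, min(n, m)) = (0, {min(n, m)})")
    if min(n, m) <= 500 or k > min(n, m) // 4:
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        u, s, vt = u[:, :k], s[:k], vt[:k]
    else:
        from scipy.sparse.linalg import svds

        u, s, vt = svds(x, k=k, v0=np.full(min(n, m), 1.0 / np.sqrt(min(n, m))))
        order = np.argsort(s)[::-1]
        u, s, vt = u[:, order], s[order], vt[order]
    for i in range(k):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    total_var = float((x ** 2).sum())
    evr = s**2 / total_var if total_var > 0 else np.zeros(k)
    return PCBasis(components=u * s, explained_variance_ratio=evr)


def adjust_scores(scores: np.ndarray, pcs: PCBasis | np.ndarray | None) -> np.ndarray:
    """Residualize each score column on the PC basis, then standardize to
    mean 0, SD 1 (population SD).

    With an empty basis this is plain standardization.  Raises on a constant
    score column (nothing to standardize).
    """
    s = np.asarray(scores, dtype=float)
    squeeze = s.ndim == 1
    if squeeze:
        s = s[:, None]
    basis = pcs.components if isinstance(pcs, PCBasis) else (
        np.empty((s.shape[0], 0)) if pcs is None else np.asarray(pcs, float)
    )
    if basis.shape[0] != s.shape[0]:
        raise ValueError("scores and PCs must cover the same individuals")
    if np.any(s.std(axis=0) == 0):
        raise ValueError("constant score column cannot be standardized")
    design = np.column_stack([np.ones(s.shape[0]), basis])
    coef, *_ = np.linalg.lstsq(design, s, rcond=None)
    resid = s - design @ coef
    sd = resid.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("score column fully explained by PCs; residual is constant")
    out = resid / sd
    return out[:, 0] if squeeze else out
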