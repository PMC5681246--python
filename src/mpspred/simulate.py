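"""Synthetic genotypes, multi-trait GWAS summary statistics and target phenotypes.

The generator emulates the data a multi-polygenic-score analysis consumes:

* a target cohort of unrelated individuals genotyped at SNPs with
  block-structured linkage disequilibrium (LD),
* a set of discovery GWASs of heterogeneous sample size whose true per-SNP
  effects share a specified genetic-correlation matrix under a point-normal
  (spike-and-slab) architecture,
* a quantitative outcome built as a weighted combination of several traits'
  genetic values plus environmental noise, optionally confounded by
  population stratification.

True effects and true genetic values are always returned alongside the
observable data so downstream stages can be tested for parameter recovery.

Genotypes come from a Gaussian-copula threshold model: each of the two
haplotypes at a SNP is the indicator that a latent standard normal (correlated
within an LD block) falls below the minor-allele-frequency quantile.  This
gives exact control over both LD and MAF.  Summary statistics are drawn
directly from the sampling distribution of marginal GWAS estimates on the
standardized-genotype scale, beta_hat ~ N(D beta, D/N) per LD block, which is
statistically equivalent to running per-SNP regressions on a simulated
discovery cohort but orders of magnitude faster.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "SimulationConfig",
    "StratificationConfig",
    "LDStructure",
    "TrueEffects",
    "GenotypePanel",
    "simulate_ld_structure",
    "simulate_genotypes",
    "simulate_effect_sizes",
    "simulate_sumstats",
    "simulate_target_cohort",
    "simulate_all",
    "write_sumstats",
    "write_phenotypes",
    "write_vcf",
    "read_vcf",
    "write_manifest",
    "stage_seed",
]

# non-palindromic allele pairs only, so default strand-ambiguity QC never
# removes simulated signal
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]

_SUMSTATS_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P", "N", "FRQ", "INFO"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage RNG seed from a global seed and a stage name.

    Uses a CRC32 hash of the stage name so inserting or reordering stages does
    not silently shift the randomness of unrelated stages.  Result is < 2**31.
    """
    return (int(global_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class StratificationConfig:
    """Population-stratification confounding: subpopulations with divergent
    allele frequencies (Balding–Nichols model) and an outcome mean shift."""

    n_subpops: int = 2
    fst: float = 0.05          # allele-frequency divergence between subpops
    outcome_shift: float = 0.5  # added to the outcome per subpopulation index


@dataclass
class SimulationConfig:
    """Full specification of one synthetic study.

    Defaults describe the scaled-down reference scenario used throughout the
    package: 3000 SNPs in 60 LD blocks, 10 discovery GWASs with moderate
    genetic correlations generated by a single-factor model, and a target
    cohort of 2000 individuals whose outcome mixes the genetic values of the
    first three traits at a heritable share of one half.
    """

    n_snps: int = 3000
    n_blocks: int = 60
    block_rho: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_traits: int = 10
    genetic_corr: np.ndarray | None = None   # default: one-factor, see __post_init__
    h2: float | Sequence[float] = 0.5
    causal_fraction: float | Sequence[float] = 1.0
    gwas_n: int | Sequence[int] = 50_000
    target_n: int = 2000
    outcome_weights: np.ndarray | None = None  # default: [0.6, 0.5, 0.4, 0, ...]
    outcome_noise_var: float | None = None     # default: equals genetic variance (share 0.5)
    stratification: StratificationConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks <= 0 or self.n_snps <= 0 or self.n_blocks > self.n_snps:
            raise ValueError("need 0 < n_blocks <= n_snps")
        if not 0.0 <= self.block_rho < 1.0:
            raise ValueError("block_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.genetic_corr is None:
            self.genetic_corr = one_factor_corr(self.n_traits)
        self.genetic_corr = np.asarray(self.genetic_corr, dtype=float)
        _check_corr_matrix(self.genetic_corr, self.n_traits)
        self.h2 = _as_per_trait(self.h2, self.n_traits, "h2")
        if np.any(self.h2 < 0) or np.any(self.h2 > 1):
            raise ValueError("h2 entries must lie in [0, 1]")
        self.causal_fraction = _as_per_trait(self.causal_fraction, self.n_traits, "causal_fraction")
        if np.any(self.causal_fraction <= 0) or np.any(self.causal_fraction > 1):
            raise ValueError("causal_fraction entries must lie in (0, 1]")
        self.gwas_n = _as_per_trait(self.gwas_n, self.n_traits, "gwas_n").astype(int)
        if np.any(self.gwas_n <= 0):
            raise ValueError("gwas_n must be positive")
        if self.outcome_weights is None:
            w = np.zeros(self.n_traits)
            w[: min(3, self.n_traits)] = [0.6, 0.5, 0.4][: min(3, self.n_traits)]
            self.outcome_weights = w
        self.outcome_weights = np.asarray(self.outcome_weights, dtype=float)
        if self.outcome_weights.shape != (self.n_traits,):
            raise ValueError("outcome_weights must have one entry per trait")
        if self.outcome_noise_var is None:
            self.outcome_noise_var = float(self.genetic_outcome_variance())
        if self.outcome_noise_var < 0:
            raise ValueError("outcome_noise_var must be nonnegative")

    def genetic_outcome_variance(self) -> float:
        """Theoretical variance of the genetic part of the outcome, w' R w,
        with R the genetic-correlation matrix (genetic values standardized)."""
        w = self.outcome_weights
        return float(w @ self.genetic_corr @ w)

    def heritable_share(self) -> float:
        g = self.genetic_outcome_variance()
        tot = g + self.outcome_noise_var
        return g / tot if tot > 0 else 0.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["genetic_corr"] = np.asarray(d["genetic_corr"]).tolist()
        for k in ("h2", "causal_fraction", "gwas_n", "outcome_weights"):
            d[k] = np.asarray(d[k]).tolist()
        d["maf_range"] = list(d["maf_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if d.get("stratification") is not None and not isinstance(
            d["stratification"], StratificationConfig
        ):
            d["stratification"] = StratificationConfig(**d["stratification"])
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        if d.get("genetic_corr") is not None:
            d["genetic_corr"] = np.asarray(d["genetic_corr"], dtype=float)
        return cls(**d)


def one_factor_corr(n_traits: int, loadings: Sequence[float] | None = None) -> np.ndarray:
    """Positive-definite correlation matrix from a single-factor model.

    Off-diagonals are loading_i * loading_j; the default loadings are spread
    over [0.55, 0.85], giving pairwise genetic correlations of about 0.3-0.7,
    the moderate-correlation regime typical of related complex traits.
    """
    if loadings is None:
        loadings = np.linspace(0.85, 0.55, n_traits)
    lam = np.asarray(loadings, dtype=float)
    corr = np.outer(lam, lam)
    np.fill_diagonal(corr, 1.0)
    return corr


def _check_corr_matrix(r: np.ndarray, n: int) -> None:
    if r.shape != (n, n):
        raise ValueError(f"genetic_corr must be {n}x{n}")
    if not np.allclose(r, r.T, atol=1e-10):
        raise ValueError("genetic_corr must be symmetric")
    if not np.allclose(np.diag(r), 1.0, atol=1e-10):
        raise ValueError("genetic_corr must have unit diagonal")
    if np.linalg.eigvalsh(r).min() < -1e-8:
        raise ValueError("genetic_corr must be positive semi-definite")


def _as_per_trait(x, n: int, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n, float(arr))
    if arr.shape != (n,):
        raise ValueError(f"{name} must be scalar or length {n}")
    return arr


@dataclass
class LDStructure:
    """Block-diagonal LD: AR(1) correlation within blocks, zero across."""

    block_slices: list[slice]
    block_corrs: list[np.ndarray]

    @property
    def n_snps(self) -> int:
        return self.block_slices[-1].stop if self.block_slices else 0

    def dense(self) -> np.ndarray:
        d = np.zeros((self.n_snps, self.n_snps))
        for sl, c in zip(self.block_slices, self.block_corrs):
            d[sl, sl] = c
        return d

    def quadratic_form(self, beta: np.ndarray) -> float:
        """beta' D beta without materializing the dense matrix."""
        return float(sum(beta[sl] @ c @ beta[sl] for sl, c in zip(self.block_slices, self.block_corrs)))


@dataclass
class TrueEffects:
    """Per-trait true SNP effects on the standardized-genotype scale."""

    beta_true: np.ndarray   # n_traits x n_snps
    causal_mask: np.ndarray  # n_traits x n_snps bool

    @property
    def n_traits(self) -> int:
        return self.beta_true.shape[0]


@dataclass
class GenotypePanel:
    """Individuals x SNPs dosage matrix with variant metadata.

    ``variants`` has columns snp_id, chr, bp, a1, a2, maf — a1 is the counted
    (dosage) allele, maf the realized minor-allele frequency.
    """

    dosages: np.ndarray          # n_individuals x n_snps, values in {0,1,2}
    variants: pd.DataFrame
    sample_ids: list[str]
    subpop: np.ndarray | None = None

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def standardized(self) -> np.ndarray:
        """Column-standardized dosages (population SD); monomorphic columns
        are left at zero."""
        x = self.dosages.astype(float)
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        out = x - mu
        nz = sd > 0
        out[:, nz] /= sd[nz]
        out[:, ~nz] = 0.0
        return out


def simulate_ld_structure(n_snps: int, n_blocks: int, block_rho: float) -> LDStructure:
    """Block-diagonal AR(1) LD: within a block corr(i, j) = rho^|i-j|."""
    if n_snps <= 0 or n_blocks <= 0:
        raise ValueError("n_snps and n_blocks must be positive")
    if n_blocks > n_snps:
        raise ValueError("n_blocks cannot exceed n_snps")
    if not 0.0 <= block_rho < 1.0:
        raise ValueError("block_rho must be in [0, 1)")
    bounds = np.linspace(0, n_snps, n_blocks + 1).astype(int)
    slices, corrs = [], []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        m = hi - lo
        idx = np.arange(m)
        corr = block_rho ** np.abs(idx[:, None] - idx[None, :])
        slices.append(slice(int(lo), int(hi)))
        corrs.append(corr)
    return LDStructure(slices, corrs)


def simulate_genotypes(
    n_individuals: int,
    ld: LDStructure,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    stratification: StratificationConfig | None = None,
) -> GenotypePanel:
    """Draw dosages in {0,1,2} via the Gaussian-copula threshold model.

    Each haplotype's latent vector is multivariate normal with the block LD
    correlation; the allele indicator is latent < Phi^{-1}(MAF), so realized
    allele frequency matches the requested MAF and dosage correlation tracks
    the latent LD.  With stratification, per-subpopulation frequencies are
    drawn from a Balding–Nichols Beta around the ancestral MAF.
    """
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("degenerate maf_range (monomorphic markers requested)")
    rng = np.random.default_rng(seed)
    m = ld.n_snps
    maf = rng.uniform(lo, hi, size=m) if lo < hi else np.full(m, lo)

    if stratification is None:
        subpop = None
        snp_maf = np.broadcast_to(maf, (n_individuals, m))
    else:
        k, fst = stratification.n_subpops, stratification.fst
        subpop = rng.integers(0, k, size=n_individuals)
        a = maf * (1 - fst) / fst
        b = (1 - maf) * (1 - fst) / fst
        pop_maf = np.clip(rng.beta(a, b, size=(k, m)), 1e-4, 1 - 1e-4)
        snp_maf = pop_maf[subpop]

    thresh = stats.norm.ppf(snp_maf)
    dosages = np.zeros((n_individuals, m), dtype=np.int8)
    for sl, corr in zip(ld.block_slices, ld.block_corrs):
        chol = np.linalg.cholesky(corr)
        for _hap in range(2):
            z = rng.standard_normal((n_individuals, sl.stop - sl.start)) @ chol.T
            dosages[:, sl] += z < thresh[:, sl]

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    a1 = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    a2 = [_ALLELE_PAIRS[i][1] for i in pair_idx]
    freq = dosages.mean(axis=0) / 2.0
    variants = pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1}" for i in range(m)],
            "chr": 1,
            "bp": np.arange(1, m + 1) * 1000,
            "a1": a1,
            "a2": a2,
            "maf": np.minimum(freq, 1 - freq),
        }
    )
    sample_ids = [f"id{i + 1}" for i in range(n_individuals)]
    return GenotypePanel(dosages, variants, sample_ids, subpop=subpop)


def simulate_effect_sizes(config: SimulationConfig, ld: LDStructure | None = None) -> TrueEffects:
    """Point-normal multi-trait effects with the configured genetic correlation.

    A single uniform draw per SNP thresholded at each trait's causal fraction
    makes causal sets nested across traits, so traits with equal fractions are
    causal at exactly the same SNPs; at jointly causal SNPs the raw effects are
    multivariate normal with correlation ``genetic_corr``.  Each trait's
    nonzero effects are then rescaled so the genetic variance beta' D beta
    equals that trait's h2 (D = identity when no LD structure is given).
    """
    rng = np.random.default_rng(stage_seed(config.seed, "effects"))
    t, m = config.n_traits, config.n_snps
    u = rng.uniform(size=m)
    causal_mask = u[None, :] < np.asarray(config.causal_fraction)[:, None]
    chol = np.linalg.cholesky(config.genetic_corr + 1e-10 * np.eye(t))
    raw = chol @ rng.standard_normal((t, m))
    beta = np.where(causal_mask, raw, 0.0)
    for i in range(t):
        if config.h2[i] == 0 or not causal_mask[i].any():
            beta[i] = 0.0
            causal_mask[i] = causal_mask[i] & (config.h2[i] > 0)
            continue
        var_g = ld.quadratic_form(beta[i]) if ld is not None else float(beta[i] @ beta[i])
        beta[i] *= np.sqrt(config.h2[i] / var_g)
    return TrueEffects(beta_true=beta, causal_mask=causal_mask)


def simulate_sumstats(
    true_effects: TrueEffects,
    ld: LDStructure,
    gwas_n: int | Sequence[int],
    seed: int = 0,
    panel: GenotypePanel | None = None,
    info: float = 0.95,
) -> list[pd.DataFrame]:
    """Marginal GWAS summary statistics, one table per trait.

    Per LD block, beta_hat ~ Normal(D beta_true, D/N) on the standardized
    scale; SE = 1/sqrt(N); two-sided p from the Wald z.  Allele and frequency
    columns come from the panel when given, otherwise from placeholder
    metadata on the same variant grid.
    """
    t = true_effects.n_traits
    n_per = _as_per_trait(gwas_n, t, "gwas_n").astype(int)
    if np.any(n_per <= 0):
        raise ValueError("gwas_n must be positive")
    rng = np.random.default_rng(seed)
    m = true_effects.beta_true.shape[1]
    if ld.n_snps != m:
        raise ValueError("LD structure and effects disagree on SNP count")
    if panel is not None:
        var = panel.variants
        frq = panel.dosages.mean(axis=0) / 2.0
    else:
        var = pd.DataFrame(
            {
                "snp_id": [f"rs{i + 1}" for i in range(m)],
                "chr": 1,
                "bp": np.arange(1, m + 1) * 1000,
                "a1": "A",
                "a2": "G",
            }
        )
        frq = np.full(m, 0.3)
    frq = np.clip(frq, 1e-4, 1 - 1e-4)

    chols = [np.linalg.cholesky(c + 1e-10 * np.eye(c.shape[0])) for c in ld.block_corrs]
    tables = []
    for i in range(t):
        n = int(n_per[i])
        beta_hat = np.empty(m)
        for sl, corr, chol in zip(ld.block_slices, ld.block_corrs, chols):
            mean = corr @ true_effects.beta_true[i, sl]
            noise = chol @ rng.standard_normal(sl.stop - sl.start) / np.sqrt(n)
            beta_hat[sl] = mean + noise
        se = np.full(m, 1.0 / np.sqrt(n))
        z = beta_hat / se
        p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
        tables.append(
            pd.DataFrame(
                {
                    "SNP": var["snp_id"].to_numpy(),
                    "CHR": var["chr"].to_numpy(),
                    "BP": var["bp"].to_numpy(),
                    "A1": var["a1"].to_numpy(),
                    "A2": var["a2"].to_numpy(),
                    "BETA": beta_hat,
                    "SE": se,
                    "P": p,
                    "N": n,
                    "FRQ": frq,
                    "INFO": info,
                }
            )
        )
    return tables


def simulate_target_cohort(
    panel: GenotypePanel,
    true_effects: TrueEffects,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Outcome = sum_t w_t * g_t + noise, with g_t the standardized genetic value.

    Returns a phenotype table with one row per individual: ``iid``,
    ``outcome``, and the latent oracle columns ``g_trait{t}`` (standardized
    true genetic values) plus ``genetic_value`` (the weighted combination
    before noise) for parameter-recovery tests.
    """
    w = config.outcome_weights
    if len(w) != true_effects.n_traits:
        raise ValueError("outcome_weights length must equal number of traits")
    rng = np.random.default_rng(stage_seed(config.seed, "target"))
    x = panel.standardized()
    g = x @ true_effects.beta_true.T   # n x t, variance ~ h2 per trait
    gsd = g.std(axis=0)
    g_std = np.divide(g, gsd, out=np.zeros_like(g), where=gsd > 0)
    genetic = g_std @ w
    noise = rng.standard_normal(panel.n_individuals) * np.sqrt(config.outcome_noise_var)
    outcome = genetic + noise
    if config.stratification is not None and panel.subpop is not None:
        outcome = outcome + config.stratification.outcome_shift * panel.subpop
    tab = pd.DataFrame({"iid": panel.sample_ids, "outcome": outcome})
    for t in range(true_effects.n_traits):
        tab[f"g_trait{t}"] = g_std[:, t]
    tab["genetic_value"] = genetic
    return tab


def simulate_all(config: SimulationConfig):
    """Run the full generator: LD, genotypes, effects, summary stats, phenotypes.

    Every stage derives its own seed from ``config.seed`` via :func:`stage_seed`,
    so the whole bundle is reproducible byte-for-byte.
    """
    ld = simulate_ld_structure(config.n_snps, config.n_blocks, config.block_rho)
    panel = simulate_genotypes(
        config.target_n,
        ld,
        config.maf_range,
        seed=stage_seed(config.seed, "genotypes"),
        stratification=config.stratification,
    )
    effects = simulate_effect_sizes(config, ld=ld)
    sumstats = simulate_sumstats(
        effects, ld, config.gwas_n, seed=stage_seed(config.seed, "sumstats"), panel=panel
    )
    phenotypes = simulate_target_cohort(panel, effects, config)
    return ld, panel, effects, sumstats, phenotypes


# ---------------------------------------------------------------------------
# text-format writers (all artifacts are plain text)

def write_sumstats(table: pd.DataFrame, path: str | Path) -> None:
    """Tab-delimited summary statistics with the standard header."""
    table.to_csv(path, sep="\t", index=False, columns=_SUMSTATS_COLUMNS, float_format="%.10g")


def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path, include_oracle: bool = False) -> None:
    cols = list(phenotypes.columns) if include_oracle else ["iid", "outcome"]
    phenotypes.to_csv(path, sep="\t", index=False, columns=cols, float_format="%.10g")


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Minimal VCFv4.2 with hard-call GT genotypes; a1 is written as ALT so
    the ALT dosage equals the panel dosage."""
    gt_codes = np.array(["0/0", "0/1", "1/1"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.sample_ids) + "\n")
        var = panel.variants
        for j in range(panel.n_snps):
            row = var.iloc[j]
            calls = "\t".join(gt_codes[panel.dosages[:, j]])
            fh.write(f"{row['chr']}\t{row['bp']}\t{row['snp_id']}\t{row['a2']}\t{row['a1']}"
                     f"\t.\tPASS\t.\tGT\t{calls}\n")


def read_vcf(path: str | Path) -> GenotypePanel:
    """Read a VCF into a GenotypePanel (ALT-allele dosage), via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, dosage_cols = [], []
    for v in vcf:
        if "DS" in dict(v.FORMAT or {}):
            ds = np.asarray(v.format("DS")).ravel()
        else:
            gts = np.asarray(v.genotype.array())[:, :2]
            ds = np.clip(gts, 0, None).sum(axis=1).astype(float)
        dosage_cols.append(ds)
        rows.append((v.ID, v.CHROM, v.POS, v.ALT[0] if v.ALT else ".", v.REF))
    if not rows:
        raise ValueError(f"no variants found in {path}")
    dosages = np.column_stack(dosage_cols)
    freq = dosages.mean(axis=0) / 2.0
    variants = pd.DataFrame(rows, columns=["snp_id", "chr", "bp", "a1", "a2"])
    variants["maf"] = np.minimum(freq, 1 - freq)
    return GenotypePanel(dosages, variants, sample_ids)


def write_manifest(config: SimulationConfig, path: str | Path, extra: dict | None = None) -> None:
    doc = {"simulation": config.to_dict()}
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
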