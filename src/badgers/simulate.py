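"""Synthetic-data engine and individual-level oracles.

Real biobank-scale inputs (cohort genotypes, thousands of trait GWAS) are
access-controlled, so every statistical contract of the package is exercised
on generated data instead:

* a block-LD genotype generator (latent Gaussian with exchangeable
  within-block correlation, thresholded to {0,1,2} hard calls at each
  variant's minor-allele frequency);
* four phenotype-simulation settings — (1) pure noise, (2) a polygenic trait
  with fixed heritability, (3) a polygenic trait plus a single PRS effect of
  known standardized size rho, (4) trait pairs Y_i = gamma_i T_i + eps_i with
  gamma_i ~ N(0, gamma_sd^2) and eps_i matched to var(T_i), analysed across
  two half-cohorts;
* a vectorised per-SNP GWAS scanner producing summary statistics tables; and
* an exact individual-level OLS oracle against which the summary-statistics
  tests are validated.

Every operation is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genio import (GenotypePanel, SummaryStatsTable, WeightMatrix,
                    two_sided_p)
from .assoc import multivariate_test, panel_moments, univariate_test
from .prs import build_prs

#: base-pair spacing between simulated variants (single synthetic chromosome)
VARIANT_SPACING_BP = 5_000


@dataclass
class SimConfig:
    """Generator parameters.

    Defaults describe a desk-scale stand-in for a biobank cohort: 5,000
    individuals, 1,000 variants in 50 LD blocks of 20 with exchangeable
    latent correlation 0.4, MAFs uniform on (0.05, 0.5), trait heritability
    0.1, PRS effect 0.02 (the top of the standard effect grid), and
    gamma_sd^2 = 2 for the paired-trait setting.
    """

    n_individuals: int = 5_000
    n_variants: int = 1_000
    ld_block_size: int = 20
    within_block_corr: float = 0.4
    maf_range: tuple[float, float] = (0.05, 0.5)
    heritability: float = 0.1
    prs_effect: float = 0.02
    gamma_sd: float = float(np.sqrt(2.0))
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.within_block_corr < 1:
            raise ValueError("within_block_corr must be in [0, 1)")
        if not 0 <= self.heritability < 1:
            raise ValueError("heritability must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.gamma_sd <= 0:
            raise ValueError("gamma_sd must be positive")


@dataclass
class SimOutput:
    """One simulated cohort with phenotypes and generating parameters."""

    panel: GenotypePanel
    traits: np.ndarray                  # (n_individuals, n_traits)
    trait_ids: list[str]
    true_params: dict = field(default_factory=dict)
    sumstats: list[SummaryStatsTable] | None = None


@dataclass
class Setting4Output:
    """Paired traits over a split cohort: T GWAS on subset 1, Y GWAS on 2."""

    panel: GenotypePanel
    t_traits: np.ndarray
    y_traits: np.ndarray
    gamma: np.ndarray
    n_subset1: int


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed % (2**31), stream])


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    return (x - x.mean(axis=0)) / sd


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def sim_genotypes(cfg: SimConfig, n_individuals: int | None = None,
                  rng: np.random.Generator | None = None,
                  mafs: np.ndarray | None = None) -> GenotypePanel:
    """Generate hard-call dosages with block-exchangeable LD.

    Per block and haplotype, a latent Gaussian with common-factor correlation
    ``within_block_corr`` is thresholded at the normal quantile of each
    variant's MAF; the dosage is the sum of the two haplotypes. MAFs are
    drawn uniformly from ``maf_range`` unless supplied (pass the cohort's
    MAFs to draw an independent reference panel from the same population).
    """
    n = n_individuals or cfg.n_individuals
    m = cfg.n_variants
    rng = rng or _rng(cfg, 0)
    if mafs is None:
        mafs = rng.uniform(*cfg.maf_range, size=m)
    else:
        mafs = np.asarray(mafs, dtype=float)
        if mafs.shape != (m,):
            raise ValueError("mafs length must equal cfg.n_variants")
    thresh = stats.norm.ppf(mafs)
    c = cfg.within_block_corr
    dosages = np.empty((n, m), dtype=float)
    for start in range(0, m, cfg.ld_block_size):
        stop = min(start + cfg.ld_block_size, m)
        b = stop - start
        dose = np.zeros((n, b))
        for _hap in range(2):
            common = rng.standard_normal((n, 1))
            latent = np.sqrt(c) * common + np.sqrt(1 - c) * rng.standard_normal((n, b))
            dose += (latent < thresh[None, start:stop]).astype(float)
        dosages[:, start:stop] = dose
    variants = pd.DataFrame({
        "id": [f"snp{j:06d}" for j in range(m)],
        "chrom": "1",
        "pos": np.arange(1, m + 1, dtype=np.int64) * VARIANT_SPACING_BP,
        "a1": "A", "a2": "G",
        "maf": mafs,
    })
    return GenotypePanel(variants, dosages)


def random_weights(panel: GenotypePanel, n_traits: int, snps_per_trait: int,
                   rng: np.random.Generator) -> WeightMatrix:
    """Sparse synthetic PRS weight set: per trait, a random variant subset
    with standard-normal weights (a stand-in for a library of trait PRS)."""
    m = panel.n_variants
    W = np.zeros((m, n_traits))
    for k in range(n_traits):
        idx = rng.choice(m, size=min(snps_per_trait, m), replace=False)
        W[idx, k] = rng.standard_normal(len(idx))
    variants = panel.variants[["id", "chrom", "pos", "a1", "a2"]].copy()
    return WeightMatrix(variants, W, [f"prs{k:04d}" for k in range(n_traits)])


# ---------------------------------------------------------------------------
# Phenotype settings
# ---------------------------------------------------------------------------

def _polygenic_background(dosages: np.ndarray, h2: float,
                          rng: np.random.Generator, n_traits: int,
                          centered: bool = False) -> np.ndarray:
    """Additive random-effect traits: Y = sqrt(h2)*std(X beta) + sqrt(1-h2)*std(eps),
    so the realized genetic variance fraction equals h2 up to the (small)
    genetic-environmental sample covariance."""
    n, m = dosages.shape
    eps = _standardize(rng.standard_normal((n, n_traits)))
    if h2 == 0:
        return eps
    beta = rng.standard_normal((m, n_traits))
    Xc = dosages if centered else dosages - dosages.mean(axis=0)
    g = _standardize(Xc @ beta)
    return np.sqrt(h2) * g + np.sqrt(1 - h2) * eps


def _maybe_sumstats(panel, traits, ids, compute: bool):
    if not compute:
        return None
    return [gwas_scan(panel, traits[:, k], trait_id=ids[k])
            for k in range(traits.shape[1])]


def sim_setting1(cfg: SimConfig, n_traits: int = 100,
                 compute_sumstats: bool = False) -> SimOutput:
    """Null traits: i.i.d. standard normal, independent of the genotypes."""
    panel = sim_genotypes(cfg)
    rng = _rng(cfg, 1)
    traits = rng.standard_normal((panel.n_individuals, n_traits))
    ids = [f"null{k:04d}" for k in range(n_traits)]
    return SimOutput(panel, traits, ids, {"setting": 1},
                     _maybe_sumstats(panel, traits, ids, compute_sumstats))


def sim_setting2(cfg: SimConfig, n_traits: int = 100,
                 compute_sumstats: bool = False) -> SimOutput:
    """Heritable polygenic traits (h2 = cfg.heritability) with no direct PRS
    effect."""
    panel = sim_genotypes(cfg)
    rng = _rng(cfg, 2)
    traits = _polygenic_background(panel.dosages, cfg.heritability, rng, n_traits)
    ids = [f"herit{k:04d}" for k in range(n_traits)]
    return SimOutput(panel, traits, ids,
                     {"setting": 2, "h2": cfg.heritability},
                     _maybe_sumstats(panel, traits, ids, compute_sumstats))


def sim_setting3(cfg: SimConfig, prs_weights: WeightMatrix,
                 rho: float | None = None, compute_sumstats: bool = False,
                 rng: np.random.Generator | None = None) -> SimOutput:
    """PRS-driven traits: Y = rho * std(P) + std(X beta + eps), one trait per
    weight column, with the polygenic-plus-noise term and the PRS each
    normalised separately so rho is a standardized effect size."""
    panel = sim_genotypes(cfg)
    rho = cfg.prs_effect if rho is None else rho
    rng = rng or _rng(cfg, 3)
    P = _standardize(panel.dosages @ prs_weights.weights)
    B = _polygenic_background(panel.dosages, cfg.heritability, rng, P.shape[1])
    traits = rho * P + _standardize(B)
    ids = [f"y_{t}" for t in prs_weights.trait_ids]
    return SimOutput(panel, traits, ids,
                     {"setting": 3, "rho": rho, "h2": cfg.heritability},
                     _maybe_sumstats(panel, traits, ids, compute_sumstats))


def sim_setting4(cfg: SimConfig, n_pairs: int = 100) -> Setting4Output:
    """Paired traits over a split cohort.

    T_i are heritable traits (h2 = cfg.heritability) over the full cohort;
    Y_i = gamma_i T_i + eps_i with gamma_i ~ N(0, gamma_sd^2) and
    eps_i ~ N(0, var(T_i)). The cohort is split in half: T GWAS are meant to
    be run on subset 1, Y GWAS on subset 2.
    """
    panel = sim_genotypes(cfg)
    rng = _rng(cfg, 4)
    T = _polygenic_background(panel.dosages, cfg.heritability, rng, n_pairs)
    gamma = rng.normal(0.0, cfg.gamma_sd, size=n_pairs)
    var_t = T.var(axis=0, ddof=1)
    eps = rng.standard_normal(T.shape) * np.sqrt(var_t)[None, :]
    Y = gamma[None, :] * T + eps
    return Setting4Output(panel, T, Y, gamma, panel.n_individuals // 2)


# ---------------------------------------------------------------------------
# GWAS scanner and OLS oracle
# ---------------------------------------------------------------------------

def gwas_scan_arrays(dosages: np.ndarray, Y: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised per-SNP simple linear regression (with intercept) of each
    trait column of Y on each dosage column. Returns (beta, se, z) of shape
    (n_variants, n_traits). Zero-variance variants get beta 0, se inf, z 0.
    """
    n = dosages.shape[0]
    if n < 3:
        raise ValueError("need at least 3 individuals for a per-SNP regression")
    Y = Y[:, None] if Y.ndim == 1 else Y
    Xc = dosages - dosages.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sxx = np.einsum("ij,ij->j", Xc, Xc)
    syy = np.einsum("ij,ij->j", Yc, Yc)
    sxy = Xc.T @ Yc                                   # (M, T)
    ok = sxx > 0
    beta = np.zeros_like(sxy)
    beta[ok] = sxy[ok] / sxx[ok, None]
    rss = np.maximum(syy[None, :] - beta * sxy, 0.0)
    sigma2 = rss / (n - 2)
    se = np.full_like(beta, np.inf)
    se[ok] = np.sqrt(sigma2[ok] / sxx[ok, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se        # se=0 -> signed inf; se=inf -> 0
    z[np.isnan(z)] = 0.0
    z[~ok] = 0.0
    return beta, se, z


def gwas_scan(panel: GenotypePanel, y: np.ndarray,
              trait_id: str = "trait") -> SummaryStatsTable:
    """Per-SNP GWAS of one trait on the panel, as a summary statistics table."""
    if np.isnan(panel.dosages).any():
        raise ValueError("panel has missing dosages")
    beta, se, z = (a[:, 0] for a in gwas_scan_arrays(panel.dosages, np.asarray(y)))
    flagged = ~np.isfinite(se)
    df = panel.variants[["id", "chrom", "pos", "a1", "a2"]].copy()
    df["beta"] = beta
    df["se"] = se
    df["z"] = z
    df["p"] = np.where(flagged, 1.0, two_sided_p(z))
    df["n"] = panel.n_individuals
    return SummaryStatsTable(df, trait_id=trait_id)


def ols_oracle(scores: np.ndarray, y: np.ndarray, multivariate: bool = False,
               z_cap: float = 1e8) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact individual-level OLS of y on imputed-trait scores, with
    intercept and classical standard errors.

    multivariate=False fits each score marginally; True fits all jointly.
    A zero-residual fit yields z at ``z_cap`` (sign preserved) rather than
    infinity. Returns (gamma, se, z), each of length K.
    """
    scores = scores[:, None] if scores.ndim == 1 else scores
    y = np.asarray(y, dtype=float)
    n, K = scores.shape
    if n <= K + 1:
        raise ValueError("need n > K + 1 observations")
    if not multivariate:
        beta, se, z = gwas_scan_arrays(scores, y[:, None])
        gamma, se, z = beta[:, 0], se[:, 0], z[:, 0]
    else:
        X = np.column_stack([np.ones(n), scores])
        XtX = X.T @ X
        if np.linalg.matrix_rank(XtX) < K + 1:
            raise np.linalg.LinAlgError("rank-deficient design in OLS oracle")
        coef = np.linalg.solve(XtX, X.T @ y)
        resid = y - X @ coef
        sigma2 = float(resid @ resid) / (n - K - 1)
        cov = sigma2 * np.linalg.inv(XtX)
        gamma = coef[1:]
        se = np.sqrt(np.diag(cov)[1:])
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, gamma / se, np.sign(gamma) * np.inf)
    z = np.clip(z, -z_cap, z_cap)
    return gamma, se, z


# ---------------------------------------------------------------------------
# Validation pipelines (the contracts the package is tested against)
# ---------------------------------------------------------------------------

def subset_panel(panel: GenotypePanel, idx: np.ndarray) -> GenotypePanel:
    return GenotypePanel(panel.variants.iloc[idx].reset_index(drop=True),
                         panel.dosages[:, idx], panel.log)


def _badgers_z_matrix(W: np.ndarray, var_x: np.ndarray, var_t: np.ndarray,
                      z_snp: np.ndarray) -> np.ndarray:
    """Univariate z for every (PRS trait, outcome) pair from SNP z-scores.

    z_snp: (M, T); returns (K, T). Pure linear algebra shortcut used by the
    large calibration runs; single-trait paths go through univariate_test.
    """
    A = np.sqrt(var_x)[:, None] * W            # (M, K)
    return (A / np.sqrt(var_t)[None, :]).T @ z_snp


def oracle_equivalence_run(cfg: SimConfig, n_traits: int = 20,
                           snps_per_trait: int = 50,
                           external_panel_n: int | None = None) -> dict:
    """Head-to-head comparison of summary-statistics z-scores with
    individual-level OLS on one simulated cohort.

    A mixture of null and PRS-associated outcomes is simulated; the outcome
    GWAS is scanned; univariate and multivariate tests are run from the
    summary statistics alone (moments from the cohort itself, or from an
    independent panel of ``external_panel_n`` draws sharing the cohort's
    MAFs and LD process); OLS fits the same scores directly.
    """
    panel = sim_genotypes(cfg)
    rng = _rng(cfg, 10)
    W = random_weights(panel, n_traits, snps_per_trait, rng)
    # standard effect grid, alternating sign, on half the traits; rest null
    # (small effects by design: the tests assume the imputed traits jointly
    # explain little outcome variance)
    grid = np.array([0.005, 0.008, 0.01, 0.015, 0.02])
    rho = np.zeros(n_traits)
    for i in range(n_traits // 2):
        rho[2 * i] = grid[i % len(grid)] * (-1) ** i
    P = _standardize(panel.dosages @ W.weights)
    B = _standardize(_polygenic_background(panel.dosages, cfg.heritability, rng, 1))
    y = P @ rho + B[:, 0]

    ss_y = gwas_scan(panel, y, trait_id="outcome")
    if external_panel_n is None:
        ref = panel
    else:
        ref = sim_genotypes(cfg, n_individuals=external_panel_n,
                            rng=_rng(cfg, 11), mafs=panel.variants["maf"].to_numpy())
    moments = panel_moments(W, ref)
    z_uni = np.array([univariate_test(W, ss_y, moments, trait=k).z
                      for k in range(n_traits)])
    z_multi = np.array([r.z for r in multivariate_test(W, ss_y, moments)])
    scores = panel.dosages @ W.weights
    _, _, z_ols_uni = ols_oracle(scores, y, multivariate=False)
    _, _, z_ols_multi = ols_oracle(scores, y, multivariate=True)
    return {"z_uni": z_uni, "z_multi": z_multi,
            "z_ols_uni": z_ols_uni, "z_ols_multi": z_ols_multi,
            "rho": rho}


def type1_run(cfg: SimConfig, setting: int = 1, n_null_traits: int = 500,
              n_prs: int = 8, snps_per_trait: int = 50) -> dict:
    """Null calibration: z for every (null outcome, PRS) pair.

    PRS supports are disjoint random SNP subsets so the per-outcome tests are
    near-independent; outcomes are independent across traits by construction.
    """
    panel = sim_genotypes(cfg)
    rng = _rng(cfg, 20 + setting)
    m = panel.n_variants
    perm = rng.permutation(m)
    W = np.zeros((m, n_prs))
    for k in range(n_prs):
        idx = perm[k * snps_per_trait:(k + 1) * snps_per_trait]
        W[idx, k] = rng.standard_normal(len(idx))
    weights = WeightMatrix(panel.variants[["id", "chrom", "pos", "a1", "a2"]].copy(),
                           W, [f"prs{k}" for k in range(n_prs)])
    if setting == 1:
        Y = rng.standard_normal((panel.n_individuals, n_null_traits))
    elif setting == 2:
        Y = _polygenic_background(panel.dosages, cfg.heritability, rng, n_null_traits)
    else:
        raise ValueError("type1_run supports settings 1 and 2")
    moments = panel_moments(weights, panel)
    _, _, z_snp = gwas_scan_arrays(panel.dosages, Y)
    Z = _badgers_z_matrix(W, moments.var_x, moments.var_t, z_snp)   # (K, T)
    p = two_sided_p(Z)
    return {"z": Z, "p": p, "n_tests": Z.size}


def power_run(cfg: SimConfig, rho_grid=(0.005, 0.008, 0.01, 0.015, 0.02),
              n_reps: int = 400, n_prs: int = 20, snps_per_trait: int = 50,
              alpha: float = 0.05) -> dict:
    """Setting-3 power and standardized-effect recovery, summary-statistics
    test vs the individual-level oracle on the same replicates.

    Each replicate draws one polygenic-plus-noise background and one PRS
    trait and reuses them across the whole rho grid (common random numbers:
    the power curve in rho is compared within replicates, not across
    independent ones). Consecutive replicates form antithetic pairs (same
    PRS, negated background), cancelling the background's first-order
    contribution to the mean recovered effect. Power is the fraction of
    replicates with p < alpha; the recovered effect is the standardized
    gamma-hat = z / sqrt(n).
    """
    panel = sim_genotypes(cfg)
    rng = _rng(cfg, 30)
    W = random_weights(panel, n_prs, snps_per_trait, rng)
    scores = panel.dosages @ W.weights
    scores_std = _standardize(scores)
    var_x = panel.dosages.var(axis=0, ddof=1)
    var_t = scores.var(axis=0, ddof=1)
    n = panel.n_individuals
    Xc = panel.dosages - panel.dosages.mean(axis=0)
    zcrit = stats.norm.isf(alpha / 2)
    n_rho = len(rho_grid)
    z_b = np.empty((n_rho, n_reps))
    z_o = np.empty((n_rho, n_reps))
    supports = [np.nonzero(W.weights[:, k])[0] for k in range(n_prs)]
    B = np.empty(n)
    for r in range(n_reps):
        k = (r // 2) % n_prs
        if r % 2 == 0:
            B = _standardize(_polygenic_background(
                Xc, cfg.heritability, rng, 1, centered=True))[:, 0]
        else:
            B = -B
        sup = supports[k]
        for i, rho in enumerate(rho_grid):
            y = rho * scores_std[:, k] + B
            _, _, z_snp = gwas_scan_arrays(panel.dosages[:, sup], y[:, None])
            z_b[i, r] = float(W.weights[sup, k] @ (np.sqrt(var_x[sup]) * z_snp[:, 0])
                              / np.sqrt(var_t[k]))
            _, _, zo = ols_oracle(scores[:, k], y)
            z_o[i, r] = zo[0]
    gam = z_b / np.sqrt(n)     # standardized gamma-hat per replicate
    return {"rho": list(rho_grid),
            "power_badgers": [float(np.mean(np.abs(z) > zcrit)) for z in z_b],
            "power_ols": [float(np.mean(np.abs(z) > zcrit)) for z in z_o],
            "gamma_mean": [float(g.mean()) for g in gam],
            "gamma_mc_se": [float(g.std(ddof=1) / np.sqrt(n_reps)) for g in gam]}


def setting4_recovery_run(cfg: SimConfig, n_pairs: int = 100,
                          p_threshold: float = 0.01, r2_cutoff: float = 0.1,
                          radius_bp: int = 1_000_000) -> dict:
    """End-to-end effect recovery under the paired-trait setting.

    Per pair: GWAS of T_i on half-cohort 1, marginal PRS built from it
    (p-filter + LD clump against the full panel), GWAS of Y_i on half-cohort
    2 at the PRS support, then the summary-statistics univariate test. The
    estimated standardized gamma is compared against the generating gamma.
    """
    sim = sim_setting4(cfg, n_pairs=n_pairs)
    panel = sim.panel
    n1 = sim.n_subset1
    panel1 = GenotypePanel(panel.variants, panel.dosages[:n1])
    panel2 = GenotypePanel(panel.variants, panel.dosages[n1:])
    gamma_hat = np.full(n_pairs, np.nan)
    n_snps = np.zeros(n_pairs, dtype=int)
    for i in range(n_pairs):
        ss_t = gwas_scan(panel1, sim.t_traits[:n1, i], trait_id=f"t{i}")
        w = build_prs(ss_t, panel, p_threshold, r2_cutoff, radius_bp)
        if w.n_variants == 0:
            continue
        key = panel.variants["pos"]
        idx = key[key.isin(w.variants["pos"])].index.to_numpy()
        sub = subset_panel(panel, idx)
        ss_y = gwas_scan(GenotypePanel(sub.variants, sub.dosages[n1:]),
                         sim.y_traits[n1:, i], trait_id=f"y{i}")
        moments = panel_moments(w, sub)
        if moments.var_t[0] <= 0:
            continue
        res = univariate_test(w, ss_y, moments)
        gamma_hat[i] = res.gamma_hat
        n_snps[i] = res.n_snps
    ok = np.isfinite(gamma_hat)
    corr = float(np.corrcoef(gamma_hat[ok], sim.gamma[ok])[0, 1]) if ok.sum() > 2 else np.nan
    return {"gamma_hat": gamma_hat, "gamma_true": sim.gamma,
            "corr": corr, "n_snps": n_snps, "n_usable": int(ok.sum())}
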