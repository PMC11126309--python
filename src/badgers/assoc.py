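"""The summary-statistics association core.

Tests the association between an outcome trait Y (observed only through GWAS
summary statistics) and traits genetically imputed through linear weights
(PRS), using a reference genotype panel to estimate the second moments that
individual-level data would normally provide.

Univariate test
---------------
With imputed trait T-hat = X W and the regression Y = a + g*T-hat + e, the
z-score of the OLS estimate g-hat can be recovered from SNP-level GWAS
z-scores Z_j alone:

    Z = sum_j W_j * (sd(X_j) / sd(T~)) * Z_j

where sd(X_j) and sd(T~) (the imputed-trait standard deviation) come from
the reference panel. The standard-deviation (not variance) ratio follows
from substituting se(beta_j) ~ sqrt(var(Y) / (N var(X_j))) into
Z = g-hat/se(g-hat); the OLS-oracle equivalence tests pin this down
numerically. se(g-hat) = sqrt(var(Y) / (N var(T~))) with the standardized
outcome convention var(Y) = 1: z and p are unaffected by this convention
and g-hat is reported on the standardized scale.

Multivariate (conditional) test
-------------------------------
For K jointly modelled imputed traits with weights W* and panel imputed-trait
covariance C (U := C^-1):

    Z_k = (1 / sqrt(U_kk)) * [ U (W*)^T diag(sd(X_j)) Z~ ]_k

Both reduce to exact OLS quantities when the panel is the GWAS cohort itself,
up to the small-variance-explained approximation var(residual) ~ var(Y).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import (AssociationResult, GenotypePanel, SummaryStatsTable,
                    WeightMatrix, logger, two_sided_log10p, two_sided_p)
from .harmonize import fill_missing_dosages, harmonize
from .prs import score_panel

#: condition number above which a ridge is added to the trait covariance
COND_LIMIT = 1e10
#: ridge magnitude, as a fraction of the mean covariance diagonal
RIDGE_FRACTION = 1e-6


class UnusableTraitError(ValueError):
    pass


@dataclass
class PanelMoments:
    """Second moments of the reference panel needed by the tests: per-variant
    dosage variances (diagonal of Theta squared), imputed-trait variances,
    and the imputed-trait covariance (whose inverse is U). Sample
    (co)variances with denominator n-1 over centred columns."""

    var_x: np.ndarray       # (M,)
    var_t: np.ndarray       # (K,)
    cov_t: np.ndarray       # (K, K)
    n_panel: int
    trait_ids: list[str]
    n_snps: np.ndarray      # contributing variants per trait

    def usable(self) -> np.ndarray:
        return self.var_t > 0


def panel_moments(w: WeightMatrix, panel: GenotypePanel) -> PanelMoments:
    """Estimate panel moments for the given weights.

    Uses the score-space shortcut: rather than the M x M SNP covariance,
    impute the traits on the panel and take the K x K sample covariance of
    the scores, which is algebraically identical and O(n K^2).
    """
    if panel.n_individuals < 2:
        raise ValueError("panel must contain at least 2 individuals")
    scores, n_snps = score_panel(w, panel)
    var_x = panel.dosages.var(axis=0, ddof=1)
    cov_t = np.atleast_2d(np.cov(scores, rowvar=False, ddof=1))
    var_t = np.diag(cov_t).copy()
    for t, v in zip(w.trait_ids, var_t):
        if v <= 0:
            logger.warning("trait '%s' has zero imputed variance on the panel", t)
    return PanelMoments(var_x, var_t, cov_t, panel.n_individuals,
                        list(w.trait_ids), n_snps)


def _median_n(ss: SummaryStatsTable, n_override: int | None) -> int:
    if n_override is not None:
        return int(n_override)
    n = ss.df["n"].to_numpy(dtype=float)
    n = n[np.isfinite(n)]
    if n.size == 0:
        raise ValueError("summary statistics carry no sample size; pass n_override")
    return int(np.median(n))


def _result(trait_id, z, var_t_k, n_gwas, n_snps, analysis) -> AssociationResult:
    se = 1.0 / np.sqrt(n_gwas * var_t_k)
    gamma = z * se
    return AssociationResult(
        trait_id=trait_id, gamma_hat=float(gamma), se=float(se), z=float(z),
        p=float(two_sided_p(z)), log10_p=float(two_sided_log10p(z)),
        gamma_std=float(z / np.sqrt(n_gwas)),
        n_gwas=int(n_gwas), n_snps=int(n_snps), analysis=analysis)


def univariate_test(w: WeightMatrix, ss_y: SummaryStatsTable,
                    moments: PanelMoments, trait: int | str = 0,
                    n_override: int | None = None) -> AssociationResult:
    """Marginal association of one imputed trait with the outcome GWAS.

    Requires an aligned variant universe (weights rows == sumstats rows, same
    orientation); ``harmonize`` establishes this.
    """
    k = w.trait_ids.index(trait) if isinstance(trait, str) else trait
    if w.n_variants != ss_y.n_variants:
        raise ValueError("weights and summary statistics are not aligned")
    if w.n_variants == 0:
        raise UnusableTraitError(f"trait '{w.trait_ids[k]}' has an empty variant overlap")
    var_t = moments.var_t[k]
    if var_t <= 0:
        raise UnusableTraitError(
            f"trait '{w.trait_ids[k]}' has non-positive imputed variance")
    z_snp = ss_y.df["z"].to_numpy(dtype=float)
    z = float(w.weights[:, k] @ (np.sqrt(moments.var_x) * z_snp) / np.sqrt(var_t))
    n = _median_n(ss_y, n_override)
    return _result(w.trait_ids[k], z, var_t, n, moments.n_snps[k], "univariate")


def multivariate_test(w: WeightMatrix, ss_y: SummaryStatsTable,
                      moments: PanelMoments, ridge: float | str | None = "auto",
                      n_override: int | None = None) -> list[AssociationResult]:
    """Joint (conditional) association of K imputed traits with the outcome.

    The imputed-trait covariance is inverted to U; when its condition number
    exceeds COND_LIMIT a ridge of ``RIDGE_FRACTION * mean(diag)`` is added
    (ridge="auto"), a fixed ridge can be passed, or ridge=None raises on
    near-singularity naming the most collinear trait pair.
    """
    if w.n_variants != ss_y.n_variants:
        raise ValueError("weights and summary statistics are not aligned")
    C = moments.cov_t.copy()
    K = C.shape[0]
    cond = np.linalg.cond(C)
    if cond > COND_LIMIT:
        if ridge is None:
            corr = C / np.sqrt(np.outer(np.diag(C), np.diag(C)))
            off = np.abs(corr - np.eye(K))
            i, j = np.unravel_index(np.argmax(off), off.shape)
            raise np.linalg.LinAlgError(
                f"imputed-trait covariance is near-singular (cond={cond:.3g}); "
                f"most collinear pair: '{moments.trait_ids[i]}' / "
                f"'{moments.trait_ids[j]}' (|r|={corr[i, j]:.4f})")
        mag = RIDGE_FRACTION * float(np.mean(np.diag(C))) if ridge == "auto" else float(ridge)
        logger.warning("adding ridge %.3g to trait covariance (cond=%.3g)", mag, cond)
        C += mag * np.eye(K)
    U = np.linalg.inv(C)
    z_snp = ss_y.df["z"].to_numpy(dtype=float)
    v = w.weights.T @ (np.sqrt(moments.var_x) * z_snp)   # (K,)
    z_all = (U @ v) / np.sqrt(np.diag(U))
    n = _median_n(ss_y, n_override)
    return [_result(w.trait_ids[k], z_all[k], 1.0 / U[k, k], n,
                    moments.n_snps[k], "multivariate") for k in range(K)]


def scan(weights: WeightMatrix, ss_y: SummaryStatsTable, panel: GenotypePanel,
         strict_ambiguous: bool = True,
         n_override: int | None = None) -> list[AssociationResult]:
    """Trait-by-trait marginal scan: harmonize the three inputs, estimate
    panel moments, and run the univariate test per weight column. Unusable
    traits (no overlap or zero imputed variance) are recorded rather than
    raised."""
    panel = fill_missing_dosages(panel)
    hs = harmonize([weights, ss_y, panel], strict_ambiguous=strict_ambiguous)
    w_al, ss_al, panel_al = hs.aligned
    moments = panel_moments(w_al, panel_al)
    results: list[AssociationResult] = []
    for k, trait in enumerate(w_al.trait_ids):
        if moments.n_snps[k] == 0 or moments.var_t[k] <= 0:
            results.append(AssociationResult(
                trait_id=trait, gamma_hat=np.nan, se=np.nan, z=np.nan, p=np.nan,
                n_gwas=0, n_snps=int(moments.n_snps[k]), analysis="univariate",
                usable=False, note="no usable variants or zero imputed variance"))
            continue
        results.append(univariate_test(w_al, ss_al, moments, trait=k,
                                       n_override=n_override))
    return results


def conditional_scan(weights: WeightMatrix, ss_y: SummaryStatsTable,
                     panel: GenotypePanel, traits: list[str] | None = None,
                     ridge: float | str | None = "auto",
                     n_override: int | None = None) -> list[AssociationResult]:
    """Multivariate conditional analysis of a chosen trait subset."""
    if traits is not None:
        idx = [weights.trait_ids.index(t) for t in traits]
        weights = WeightMatrix(weights.variants, weights.weights[:, idx],
                               [weights.trait_ids[i] for i in idx],
                               weights.standardized)
    panel = fill_missing_dosages(panel)
    hs = harmonize([weights, ss_y, panel])
    w_al, ss_al, panel_al = hs.aligned
    moments = panel_moments(w_al, panel_al)
    return multivariate_test(w_al, ss_al, moments, ridge=ridge, n_override=n_override)
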