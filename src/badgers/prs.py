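"""PRS construction from GWAS summary statistics: p-value thresholding,
greedy LD clumping against a reference panel, region exclusion, and scoring.

The clumping algorithm mirrors PLINK's --clump: process variants in order of
ascending association p-value; each unprocessed variant becomes an index SNP
and absorbs every unprocessed variant on the same chromosome within the
radius whose squared dosage correlation with the index exceeds the cutoff.
Correlations are always against the index SNP, never transitive. Defaults
(p <= 0.01, r^2 0.1, radius 1 Mb) are the standard marginal-PRS recipe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import (GenotypePanel, RegionSet, SummaryStatsTable, WeightMatrix,
                    logger)

DEFAULT_P_THRESHOLD = 0.01
DEFAULT_R2_CUTOFF = 0.1
DEFAULT_RADIUS_BP = 1_000_000


@dataclass
class ClumpResult:
    """Outcome of greedy LD clumping."""

    index_variants: pd.DataFrame          # retained records in selection order
    removed: dict[str, str]               # removed key -> absorbing index key
    keep_mask: np.ndarray                 # over the input table's rows


def pvalue_filter(ss: SummaryStatsTable, threshold: float = DEFAULT_P_THRESHOLD
                  ) -> SummaryStatsTable:
    """Retain rows with p <= threshold (inclusive: only p strictly greater
    than the cutoff are removed)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    keep = ss.df["p"].to_numpy(dtype=float) <= threshold
    if not keep.any():
        logger.warning("p-value filter at %g removed every variant", threshold)
    out = ss.df[keep].reset_index(drop=True)
    return SummaryStatsTable(out, ss.log, ss.trait_id)


def _panel_index(panel: GenotypePanel) -> pd.Series:
    key = panel.variants["chrom"].astype(str) + ":" + panel.variants["pos"].astype(str)
    return pd.Series(np.arange(panel.n_variants), index=key.to_numpy())


def ld_clump(ss: SummaryStatsTable, panel: GenotypePanel,
             r2_cutoff: float = DEFAULT_R2_CUTOFF,
             radius_bp: int = DEFAULT_RADIUS_BP) -> ClumpResult:
    """Greedy LD clumping of ``ss`` using dosage correlations from ``panel``.

    Ties on p are broken by ascending (chrom, pos) for determinism.
    Zero-variance dosage columns contribute r^2 = 0 (never absorbed by LD).
    """
    if not 0 < r2_cutoff < 1:
        raise ValueError("r2_cutoff must be in (0, 1)")
    if radius_bp <= 0:
        raise ValueError("radius_bp must be positive")
    df = ss.df
    lookup = _panel_index(panel)
    keys = (df["chrom"].astype(str) + ":" + df["pos"].astype(str)).to_numpy()
    missing = [k for k in keys if k not in lookup.index]
    if missing:
        raise ValueError(f"{len(missing)} variants absent from panel "
                         f"(first offenders: {missing[:5]})")
    cols = lookup.loc[keys].to_numpy()

    # centred, unit-norm dosage columns; zero-variance columns stay zero
    X = panel.dosages[:, cols].astype(float)
    if np.isnan(X).any():
        obs = ~np.isnan(X)
        mean = np.nanmean(X, axis=0)
        X = np.where(obs, X, mean[None, :])
    X = X - X.mean(axis=0)
    norms = np.linalg.norm(X, axis=0)
    nz = norms > 0
    X[:, nz] /= norms[nz]

    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy(dtype=np.int64)
    p = df["p"].to_numpy(dtype=float)
    order = np.lexsort((pos, chrom, p))  # p, then chrom, then pos ascending

    unprocessed = np.ones(len(df), dtype=bool)
    keep = np.zeros(len(df), dtype=bool)
    removed: dict[str, str] = {}
    index_rows: list[int] = []
    for i in order:
        if not unprocessed[i]:
            continue
        unprocessed[i] = False
        keep[i] = True
        index_rows.append(i)
        window = unprocessed & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= radius_bp)
        if not window.any():
            continue
        r = X[:, window].T @ X[:, i]
        absorb = np.nonzero(window)[0][r * r > r2_cutoff]
        for j in absorb:
            unprocessed[j] = False
            removed[keys[j]] = keys[i]
    index_variants = df.iloc[index_rows][["id", "chrom", "pos", "a1", "a2"]].reset_index(drop=True)
    return ClumpResult(index_variants, removed, keep)


def build_prs(ss: SummaryStatsTable, panel: GenotypePanel,
              p_threshold: float = DEFAULT_P_THRESHOLD,
              r2_cutoff: float = DEFAULT_R2_CUTOFF,
              radius_bp: int = DEFAULT_RADIUS_BP,
              trait_id: str | None = None) -> WeightMatrix:
    """Marginal-effect PRS: p-value filter, LD clumping, weights = beta of the
    surviving variants (their GWAS z-scores when beta/se are absent, flagged
    as standardized weights)."""
    filtered = pvalue_filter(ss, p_threshold)
    trait = trait_id or ss.trait_id
    if filtered.n_variants == 0:
        return WeightMatrix(filtered.df[["id", "chrom", "pos", "a1", "a2"]].copy(),
                            np.zeros((0, 1)), [trait])
    clump = ld_clump(filtered, panel, r2_cutoff, radius_bp)
    kept = filtered.df[clump.keep_mask].sort_values(
        ["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    beta = kept["beta"].to_numpy(dtype=float)
    standardized = False
    if np.isnan(beta).all():
        beta = kept["z"].to_numpy(dtype=float)
        standardized = True
    return WeightMatrix(kept[["id", "chrom", "pos", "a1", "a2"]].copy(),
                        beta[:, None], [trait], standardized)


def exclude_region(w: WeightMatrix, regions: RegionSet) -> WeightMatrix:
    """Remove variants falling inside any interval (1-based, both ends
    inclusive) from every trait column."""
    if not regions.intervals:
        return w
    inside = regions.contains(w.variants["chrom"], w.variants["pos"])
    if inside.any():
        logger.info("region exclusion removed %d variants", int(inside.sum()))
    variants = w.variants[~inside].reset_index(drop=True)
    return WeightMatrix(variants, w.weights[~inside], list(w.trait_ids), w.standardized)


def score_panel(w: WeightMatrix, panel: GenotypePanel) -> tuple[np.ndarray, np.ndarray]:
    """Impute traits on the panel: scores = dosages @ weights.

    Requires a harmonized, missing-free panel whose variant order matches the
    weight rows. Returns (scores, n_contributing) where n_contributing counts
    nonzero weights per trait; all-zero traits are unusable for testing.
    """
    if w.n_variants != panel.n_variants:
        raise ValueError(f"weights ({w.n_variants}) and panel ({panel.n_variants}) "
                         "variant dimensions differ; harmonize first")
    if np.isnan(panel.dosages).any():
        raise ValueError("panel has missing dosages; run fill_missing_dosages first")
    scores = panel.dosages @ w.weights
    n_contributing = (w.weights != 0).sum(axis=0)
    for t, n in zip(w.trait_ids, n_contributing):
        if n == 0:
            logger.warning("trait '%s' has no contributing variants; flagged unusable", t)
    return scores, n_contributing
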