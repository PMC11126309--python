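"""Downstream processing of association scans: fixed-effects inverse-variance
meta-analysis across cohorts, Bonferroni and Benjamini-Hochberg multiple-
testing control, hierarchical-clustering-based selection of representative
traits for conditional analysis, and replication enrichment (hypergeometric).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .genio import AssociationResult, logger, two_sided_log10p, two_sided_p


@dataclass
class MetaResult:
    trait_id: str
    gamma_meta: float
    se_meta: float
    z_meta: float
    p_meta: float
    direction_consistent: bool
    k_studies: int
    log10_p: float = np.nan


@dataclass
class ClusterSelection:
    labels: dict[str, int]            # trait -> cluster id (1..k)
    representatives: dict[int, str]   # cluster id -> most significant trait
    linkage: str
    distance: str


@dataclass
class EnrichmentResult:
    universe: int
    replicated_in_universe: int
    discovery_hits: int
    overlap: int
    enrichment: float
    p: float


def meta_ivw(studies: list[list[AssociationResult]]) -> list[MetaResult]:
    """Fixed-effects inverse-variance-weighted combination per trait.

    gamma_meta = sum(g_i / se_i^2) / sum(1 / se_i^2);  se_meta = sqrt(1 / sum(1/se_i^2)).
    A trait absent (or unusable) in every study is omitted with a log entry.
    direction_consistent is true iff all contributing estimates share a sign.
    """
    per_trait: dict[str, list[AssociationResult]] = {}
    order: list[str] = []
    for study in studies:
        for r in study:
            if r.trait_id not in per_trait:
                per_trait[r.trait_id] = []
                order.append(r.trait_id)
            if r.usable and np.isfinite(r.se) and r.se > 0:
                per_trait[r.trait_id].append(r)
    out: list[MetaResult] = []
    for trait in order:
        rs = per_trait[trait]
        if not rs:
            logger.warning("trait '%s' has no usable study estimates; omitted", trait)
            continue
        w = np.array([1.0 / r.se**2 for r in rs])
        g = np.array([r.gamma_hat for r in rs])
        gamma = float(np.sum(w * g) / np.sum(w))
        se = float(1.0 / np.sqrt(np.sum(w)))
        z = gamma / se
        signs = np.sign(g[g != 0])
        consistent = bool(signs.size == 0 or np.all(signs == signs[0]))
        out.append(MetaResult(trait, gamma, se, z, float(two_sided_p(z)),
                              consistent, len(rs), float(two_sided_log10p(z))))
    return out


def bonferroni(p_values, alpha: float = 0.05, m: int | None = None) -> np.ndarray:
    """Family-wise flags: p < alpha / m (m defaults to the number of tests,
    but is explicit so a scan subset can be judged against the full family,
    e.g. 0.05/1738 for a biobank-wide scan)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p) if m is None else m
    if m < 1:
        raise ValueError("m must be >= 1")
    return p < alpha / m


def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up flags at FDR level q."""
    p = np.asarray(p_values, dtype=float)
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def cluster_select(corr: pd.DataFrame, p_meta: pd.Series, k: int,
                   linkage: str = "average",
                   distance: str = "abs_corr") -> ClusterSelection:
    """Cut an agglomerative tree over trait similarity into k clusters and
    pick the most significant (minimal-p) trait of each as its
    representative for conditional analysis.

    distance "abs_corr" uses d = 1 - |corr| (a trait and its mirror-image,
    e.g. a medication-use score anticorrelated with the diagnosis score,
    belong to the same family); "corr" uses d = 1 - corr.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    traits = list(corr.index)
    if k > len(traits):
        raise ValueError("k exceeds the number of traits")
    # deterministic trait order regardless of input order
    traits_sorted = sorted(traits)
    C = corr.loc[traits_sorted, traits_sorted].to_numpy(dtype=float)
    if distance == "abs_corr":
        D = 1.0 - np.abs(C)
    elif distance == "corr":
        D = 1.0 - C
    else:
        raise ValueError(f"unknown distance '{distance}'")
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    Z = scipy_linkage(squareform(D, checks=False), method=linkage)
    lab = fcluster(Z, t=k, criterion="maxclust")
    labels = {t: int(c) for t, c in zip(traits_sorted, lab)}
    representatives: dict[int, str] = {}
    for cid in sorted(set(lab)):
        members = [t for t in traits_sorted if labels[t] == cid]
        representatives[cid] = min(members, key=lambda t: (p_meta[t], t))
    return ClusterSelection(labels, representatives, linkage, distance)


def replication_enrichment(m: int, K: int, n: int, k: int) -> EnrichmentResult:
    """Hypergeometric replication enrichment.

    Of m traits scanned, K replicate in the full universe; n were declared
    discovery hits, k of which replicate. enrichment = (k/n) / (K/m), the
    observed-over-expected overlap; p = P(X >= k), X ~ Hypergeom(m, K, n).
    """
    if not (0 <= k <= min(n, K) and n <= m and K <= m):
        raise ValueError(f"inconsistent counts m={m}, K={K}, n={n}, k={k}")
    if K == 0:
        if k > 0:
            raise ValueError("k > 0 with K = 0 is impossible")
        return EnrichmentResult(m, K, n, k, 0.0, 1.0)
    enrichment = (k / n) / (K / m) if n > 0 else 0.0
    p = float(stats.hypergeom.sf(k - 1, m, K, n))
    return EnrichmentResult(m, K, n, k, float(enrichment), p)
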