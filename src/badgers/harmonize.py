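"""Variant and allele harmonization across summary statistics, weight tables,
and genotype panels.

All downstream algebra (PRS scoring, panel moments, z-score accumulation)
assumes one shared variant universe with one effect-allele orientation. This
module intersects sources on (chrom, pos), verifies allele pairs, flips signs
where a source reports the opposite allele, resolves strand (complementary
allele) differences, and drops strand-ambiguous (A/T, C/G) and duplicated
variants.

Matching is on genomic coordinates rather than rsID: variant IDs drift between
annotation builds, while (chrom, pos, allele pair) is stable within one
reference build. IDs are kept for reporting only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import (_COMPLEMENT, GenotypePanel, SummaryStatsTable, WeightMatrix,
                    logger)

Source = SummaryStatsTable | WeightMatrix | GenotypePanel


class HarmonizationError(ValueError):
    pass


def _complement(allele: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in allele)


def _is_ambiguous(a1: str, a2: str) -> bool:
    """Strand-ambiguous: the allele pair equals its own reverse complement."""
    return a2 == _complement(a1)


def match_alleles(a1: str, a2: str, ref_a1: str, ref_a2: str) -> int | None:
    """Orientation of (a1, a2) relative to (ref_a1, ref_a2).

    Returns +1 (same effect allele), -1 (alleles swapped: the source's effect
    is on the reference's other allele), trying direct then strand-complement
    matches; None if the pairs are irreconcilable.
    """
    if (a1, a2) == (ref_a1, ref_a2):
        return +1
    if (a2, a1) == (ref_a1, ref_a2):
        return -1
    ca1, ca2 = _complement(a1), _complement(a2)
    if (ca1, ca2) == (ref_a1, ref_a2):
        return +1
    if (ca2, ca1) == (ref_a1, ref_a2):
        return -1
    return None


def _variants_of(source: Source) -> pd.DataFrame:
    if isinstance(source, SummaryStatsTable):
        return source.df
    return source.variants


@dataclass
class HarmonizedSet:
    """Result of harmonization: the retained universe, per-source sign flips,
    aligned copies of every source, and a per-variant drop report."""

    variants: pd.DataFrame
    sign_flips: np.ndarray  # (n_sources, n_variants) in {+1, -1}
    aligned: list[Source]
    dropped: pd.DataFrame = field(default_factory=pd.DataFrame)  # key, reason

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def report(self) -> pd.DataFrame:
        kept = pd.DataFrame({
            "variant": self.variants["chrom"].astype(str) + ":" + self.variants["pos"].astype(str),
            "action": "retained", "reason": "",
        })
        return pd.concat([kept, self.dropped], ignore_index=True)


def _apply_flips(source: Source, order: np.ndarray, flips: np.ndarray,
                 universe: pd.DataFrame) -> Source:
    """Subset a source to the universe (row order given by ``order``) and
    reorient it: swapped alleles negate effects/weights and mirror dosages."""
    if isinstance(source, SummaryStatsTable):
        df = source.df.iloc[order].reset_index(drop=True).copy()
        for c in ("beta", "z"):
            df[c] = df[c].to_numpy(dtype=float) * flips
        df[["id", "chrom", "pos", "a1", "a2"]] = universe[
            ["id", "chrom", "pos", "a1", "a2"]].to_numpy()
        return SummaryStatsTable(df, source.log, source.trait_id)
    if isinstance(source, WeightMatrix):
        W = source.weights[order] * flips[:, None]
        return WeightMatrix(universe.reset_index(drop=True).copy(), W,
                            list(source.trait_ids), source.standardized)
    if isinstance(source, GenotypePanel):
        dos = source.dosages[:, order].copy()
        neg = flips < 0
        dos[:, neg] = 2.0 - dos[:, neg]  # NaN stays NaN
        return GenotypePanel(universe.reset_index(drop=True).copy(), dos, source.log)
    raise TypeError(type(source))


def harmonize(sources: list[Source], strict_ambiguous: bool = True) -> HarmonizedSet:
    """Intersect >=2 sources on (chrom, pos) and reconcile allele orientation.

    The first source defines the reference orientation. Per variant and
    source: identical allele pair -> keep; swapped pair -> sign flip -1;
    strand-complement pair -> complement then match; anything else ->
    dropped as mismatch. A/T and C/G variants are dropped when
    ``strict_ambiguous`` (their orientation cannot be established without
    allele frequencies). Coordinates duplicated within a source are dropped.
    """
    if len(sources) < 2:
        raise ValueError("harmonize requires at least two sources")
    frames = [_variants_of(s) for s in sources]
    keys = [f["chrom"].astype(str) + ":" + f["pos"].astype(str) for f in frames]

    dropped_rows: list[tuple[str, str, str]] = []
    dup_keys: set[str] = set()
    for k in keys:
        d = k[k.duplicated(keep=False)]
        for key in d.unique():
            dup_keys.add(key)
            dropped_rows.append((key, "dropped", "duplicate"))

    common = set(keys[0])
    for k in keys[1:]:
        common &= set(k)
    common -= dup_keys
    union = set().union(*[set(k) for k in keys])
    for key in sorted(union - common - dup_keys):
        dropped_rows.append((key, "dropped", "missing"))
    if not common:
        counts = ", ".join(f"source {i}: {len(k)} variants" for i, k in enumerate(keys))
        raise HarmonizationError(f"empty variant intersection across sources ({counts})")

    # reference orientation from source 0, in canonical (chrom, pos) order
    ref = frames[0].copy()
    ref["_key"] = keys[0]
    ref = ref[ref["_key"].isin(common)].sort_values(["chrom", "pos"], kind="mergesort")
    universe = ref[["id", "chrom", "pos", "a1", "a2"]].reset_index(drop=True)
    ordered_keys = ref["_key"].to_numpy()

    n_var = len(universe)
    flips = np.ones((len(sources), n_var), dtype=np.int8)
    orders = np.empty((len(sources), n_var), dtype=np.int64)
    keep = np.ones(n_var, dtype=bool)
    reasons = np.full(n_var, "", dtype=object)

    ref_a1 = universe["a1"].to_numpy()
    ref_a2 = universe["a2"].to_numpy()
    if strict_ambiguous:
        for i in range(n_var):
            if _is_ambiguous(ref_a1[i], ref_a2[i]):
                keep[i] = False
                reasons[i] = "ambiguous"

    for s, (frame, k) in enumerate(zip(frames, keys)):
        lookup = pd.Series(np.arange(len(frame)), index=k.to_numpy())
        idx = lookup.loc[ordered_keys].to_numpy()
        orders[s] = idx
        a1 = frame["a1"].to_numpy()[idx]
        a2 = frame["a2"].to_numpy()[idx]
        for i in np.nonzero(keep)[0]:
            m = match_alleles(a1[i], a2[i], ref_a1[i], ref_a2[i])
            if m is None:
                keep[i] = False
                reasons[i] = "mismatch"
            else:
                flips[s, i] = m

    for i in np.nonzero(~keep)[0]:
        dropped_rows.append((str(ordered_keys[i]), "dropped", reasons[i]))
    if not keep.any():
        raise HarmonizationError("no variants survive allele reconciliation")

    universe = universe[keep].reset_index(drop=True)
    flips = flips[:, keep]
    orders = orders[:, keep]
    aligned = [_apply_flips(s, orders[i], flips[i].astype(float), universe)
               for i, s in enumerate(sources)]
    dropped = pd.DataFrame(dropped_rows, columns=["variant", "action", "reason"])
    n_drop = len(dropped)
    if n_drop:
        logger.info("harmonize: retained %d variants, dropped %d", len(universe), n_drop)
    return HarmonizedSet(universe, flips, aligned, dropped)


def fill_missing_dosages(panel: GenotypePanel) -> GenotypePanel:
    """Replace missing dosages by the per-variant mean of observed dosages.

    Mean imputation preserves each variant's mean and keeps variance
    estimates well defined. Variants with no observed calls are removed.
    """
    dos = panel.dosages
    if not np.isnan(dos).any():
        return panel
    obs = ~np.isnan(dos)
    all_missing = ~obs.any(axis=0)
    if all_missing.any():
        logger.warning("dropping %d all-missing variants", int(all_missing.sum()))
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(np.where(all_missing[None, :], 0.0, dos), axis=0)
    filled = np.where(obs, dos, col_mean[None, :])[:, ~all_missing]
    variants = panel.variants[~all_missing].reset_index(drop=True)
    return GenotypePanel(variants, filled, panel.log)
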