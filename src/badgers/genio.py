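"""Readers and writers for the external file formats used in a summary-statistics
association scan: GWAS summary statistics tables, PRS weight tables, reference
genotype panels (PLINK bed/bim/fam, VCF, plain dosage matrices), genomic region
files, and result tables.

All tabular formats are plain text. Internally, coordinates are 1-based and
inclusive on both ends; BED input (0-based, half-open) is converted at the
boundary. Chromosome names are normalised by stripping a leading ``chr``.

The canonical in-memory containers are thin dataclasses around pandas
DataFrames (variant metadata) and numpy arrays (dosages, weights).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("badgers")

#: canonical variant identity columns; ``a1`` is the effect (counted) allele
VARIANT_COLUMNS = ["id", "chrom", "pos", "a1", "a2"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class EmptyInputError(ValueError):
    """Raised when a parsed file contains no usable rows."""


def _norm_chrom(c) -> str:
    s = str(c)
    return s[3:] if s.lower().startswith("chr") else s


def two_sided_p(z: np.ndarray) -> np.ndarray:
    """Two-sided normal p-value, computed in log space so |z| > 38 survives.

    Values that underflow double precision are clipped to the smallest
    positive float rather than reported as exact zeros.
    """
    z = np.asarray(z, dtype=float)
    logp = stats.norm.logsf(np.abs(z)) + np.log(2.0)
    p = np.exp(logp)
    return np.clip(p, np.nextafter(0.0, 1.0), 1.0)


def two_sided_log10p(z: np.ndarray) -> np.ndarray:
    """log10 of the two-sided normal p-value (no underflow)."""
    z = np.asarray(z, dtype=float)
    return (stats.norm.logsf(np.abs(z)) + np.log(2.0)) / np.log(10.0)


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass
class ParseLog:
    """Counts of rows dropped or repaired while reading a file."""

    n_input: int = 0
    n_kept: int = 0
    dropped_nonfinite: int = 0
    dropped_zero_se: int = 0
    skipped_multiallelic: int = 0
    na_weights_zeroed: int = 0
    zp_inconsistent: int = 0


@dataclass
class SummaryStatsTable:
    """Per-SNP GWAS association records for one trait.

    ``df`` columns: id, chrom, pos, a1 (effect allele), a2, beta, se, z, p, n.
    beta/se may be all-NaN (z-only mode); z and p are always populated.
    """

    df: pd.DataFrame
    log: ParseLog = field(default_factory=ParseLog)
    trait_id: str = "trait"

    @property
    def n_variants(self) -> int:
        return len(self.df)

    def sort_canonical(self) -> "SummaryStatsTable":
        df = self.df.sort_values(["chrom", "pos", "a1", "a2"], kind="mergesort")
        return SummaryStatsTable(df.reset_index(drop=True), self.log, self.trait_id)


@dataclass
class GenotypePanel:
    """Reference genotype dosages (individuals x variants), missing as NaN.

    Column order of ``dosages`` matches the row order of ``variants``; the
    dosage counts copies of each variant's ``a1`` allele.
    """

    variants: pd.DataFrame
    dosages: np.ndarray
    log: ParseLog = field(default_factory=ParseLog)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]


@dataclass
class WeightMatrix:
    """SNP-by-trait linear imputation weights (the PRS models).

    ``weights`` has one column per trait; absent variant-trait entries are
    exact zeros. ``standardized`` marks weights built from z-scores rather
    than effect sizes.
    """

    variants: pd.DataFrame
    weights: np.ndarray
    trait_ids: list[str]
    standardized: bool = False

    @property
    def n_variants(self) -> int:
        return self.weights.shape[0]

    @property
    def n_traits(self) -> int:
        return self.weights.shape[1]


@dataclass
class RegionSet:
    """A union of genomic intervals, 1-based inclusive on both ends."""

    intervals: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if end < start:
                raise FormatError(f"region {chrom}:{start}-{end} has end < start")

    def contains(self, chrom: Sequence[str], pos: Sequence[int]) -> np.ndarray:
        """Boolean mask of positions falling inside any interval."""
        chrom = np.asarray([_norm_chrom(c) for c in chrom])
        pos = np.asarray(pos, dtype=np.int64)
        mask = np.zeros(len(pos), dtype=bool)
        for c, s, e in self.intervals:
            mask |= (chrom == _norm_chrom(c)) & (pos >= s) & (pos <= e)
        return mask

    def union(self, other: "RegionSet") -> "RegionSet":
        return RegionSet(self.intervals + other.intervals)


@dataclass
class AssociationResult:
    """One trait's association test against the outcome GWAS."""

    trait_id: str
    gamma_hat: float
    se: float
    z: float
    p: float
    n_gwas: int
    n_snps: int
    analysis: str  # univariate | multivariate | meta
    log10_p: float = np.nan
    #: effect per standard deviation of the imputed trait (z / sqrt(N)); the
    #: scale on which simulated standardized effects are recovered
    gamma_std: float = np.nan
    usable: bool = True
    note: str = ""


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

#: default header synonyms, all compared lower-case
_DEFAULT_SYNONYMS = {
    "id": ["id", "snp", "rsid", "markername", "variant", "snpid"],
    "chrom": ["chrom", "chr", "chromosome"],
    "pos": ["pos", "bp", "position", "base_pair_location"],
    "a1": ["a1", "effect_allele", "alt", "allele1", "ea"],
    "a2": ["a2", "other_allele", "ref", "allele2", "oa", "nea"],
    "beta": ["beta", "effect", "b", "log_odds"],
    "se": ["se", "stderr", "standard_error"],
    "z": ["z", "zscore", "z_score", "tstat"],
    "p": ["p", "pval", "pvalue", "p_value"],
    "n": ["n", "nobs", "sample_size", "n_complete_samples"],
}


def _resolve_columns(header: Sequence[str], column_map: Mapping[str, str] | None):
    """Map canonical field names onto actual header names."""
    lower = {h.lower(): h for h in header}
    resolved: dict[str, str] = {}
    explicit = {k: v for k, v in (column_map or {}).items()}
    for canon, synonyms in _DEFAULT_SYNONYMS.items():
        if canon in explicit:
            if explicit[canon] not in header:
                raise FormatError(f"mapped column '{explicit[canon]}' for '{canon}' not in header")
            resolved[canon] = explicit[canon]
            continue
        for syn in synonyms:
            if syn in lower:
                resolved[canon] = lower[syn]
                break
    return resolved


def read_sumstats(path, column_map: Mapping[str, str] | None = None,
                  trait_id: str | None = None) -> SummaryStatsTable:
    """Read a whitespace/tab-delimited GWAS summary statistics table.

    Required: variant identity columns plus at least two of {beta, se, z, p}.
    Missing z is derived as beta/se; missing p from z (two-sided normal).
    z is authoritative when z and p disagree beyond 1e-4 relative tolerance
    (p is recomputed and the disagreement logged). Rows with non-finite
    required values, or se == 0, are dropped and counted.
    """
    raw = pd.read_csv(path, sep=r"\s+", dtype=str, comment="#")
    cols = _resolve_columns(list(raw.columns), column_map)
    for req in ("id", "chrom", "pos", "a1", "a2"):
        if req not in cols:
            raise FormatError(f"missing required column '{req}' in {path}")
    stat_cols = [c for c in ("beta", "se", "z", "p") if c in cols]
    if len(stat_cols) < 2:
        raise FormatError(f"need at least two of beta/se/z/p in {path}, found {stat_cols}")

    log = ParseLog(n_input=len(raw))
    df = pd.DataFrame({
        "id": raw[cols["id"]].astype(str),
        "chrom": raw[cols["chrom"]].map(_norm_chrom),
        "pos": pd.to_numeric(raw[cols["pos"]], errors="coerce"),
        "a1": raw[cols["a1"]].astype(str).str.upper(),
        "a2": raw[cols["a2"]].astype(str).str.upper(),
    })
    for c in ("beta", "se", "z", "p", "n"):
        df[c] = pd.to_numeric(raw[cols[c]], errors="coerce") if c in cols else np.nan

    keep = np.isfinite(df["pos"].to_numpy())
    have_beta_se = "beta" in cols and "se" in cols
    if have_beta_se:
        zero_se = np.isfinite(df["se"].to_numpy()) & (df["se"].to_numpy() == 0)
        log.dropped_zero_se = int(zero_se.sum())
        keep &= np.isfinite(df["beta"]) & np.isfinite(df["se"]) & ~zero_se
    if "z" in cols:
        keep &= np.isfinite(df["z"])
    elif not have_beta_se:
        keep &= np.isfinite(df["p"])
    log.dropped_nonfinite = int((~keep).sum()) - log.dropped_zero_se
    df = df[keep].reset_index(drop=True)
    if len(df) == 0:
        raise EmptyInputError(f"no usable rows parsed from {path}")
    df["pos"] = df["pos"].astype(np.int64)

    if df["z"].isna().all() and have_beta_se:
        df["z"] = df["beta"] / df["se"]
    z = df["z"].to_numpy(dtype=float)
    if np.isfinite(z).all():
        p_from_z = two_sided_p(z)
        p = df["p"].to_numpy(dtype=float)
        bad = ~np.isfinite(p)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.abs(p - p_from_z) / np.maximum(p_from_z, np.nextafter(0, 1))
        incons = np.isfinite(p) & (rel > 1e-4)
        if incons.any():
            log.zp_inconsistent = int(incons.sum())
            logger.warning("%d rows with p inconsistent with z; p recomputed from z",
                           log.zp_inconsistent)
        df.loc[bad | incons, "p"] = p_from_z[bad | incons]
    log.n_kept = len(df)
    return SummaryStatsTable(df, log, trait_id or Path(str(path)).stem)


def write_sumstats(ss: SummaryStatsTable, path) -> None:
    ss.df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


# ---------------------------------------------------------------------------
# Genotypes: PLINK bed/bim/fam, VCF, dosage matrix
# ---------------------------------------------------------------------------

# PLINK 1.9 binary: 3 magic bytes then SNP-major 2-bit codes per individual:
# 00 hom A1 (dosage 2 of A1), 10 het, 11 hom A2, 01 missing.
_BED_MAGIC = b"\x6c\x1b\x01"
_BED_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def _read_plink(prefix: str) -> GenotypePanel:
    prefix = str(prefix)
    if prefix.endswith(".bed"):
        prefix = prefix[:-4]
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"], dtype=str)
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None, dtype=str)
    n_ind, n_var = len(fam), len(bim)
    data = Path(prefix + ".bed").read_bytes()
    if data[:3] != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic bytes (not SNP-major PLINK bed)")
    bytes_per_snp = (n_ind + 3) // 4
    expected = 3 + bytes_per_snp * n_var
    if len(data) != expected:
        raise FormatError(
            f"{prefix}.bed: size {len(data)} != {expected} expected from "
            f"{n_ind} individuals x {n_var} variants")
    codes = np.frombuffer(data, dtype=np.uint8, offset=3).reshape(n_var, bytes_per_snp)
    # unpack 2-bit codes, little-endian within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    two_bit = (codes[:, :, None] >> shifts[None, None, :]) & 0b11
    dosages = _BED_CODE_TO_DOSAGE[two_bit.reshape(n_var, -1)[:, :n_ind]].T
    variants = pd.DataFrame({
        "id": bim["id"], "chrom": bim["chrom"].map(_norm_chrom),
        "pos": pd.to_numeric(bim["pos"]).astype(np.int64),
        "a1": bim["a1"].str.upper(), "a2": bim["a2"].str.upper(),
    })
    return GenotypePanel(variants, np.ascontiguousarray(dosages))


def write_plink(panel: GenotypePanel, prefix) -> None:
    """Write a panel as a PLINK bed/bim/fam triplet (hard calls; fractional
    dosages are rounded, NaN written as missing)."""
    prefix = str(prefix)
    v = panel.variants
    bim = pd.DataFrame({0: v["chrom"], 1: v["id"], 2: 0, 3: v["pos"],
                        4: v["a1"], 5: v["a2"]})
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    n = panel.n_individuals
    fam = pd.DataFrame({0: [f"F{i}" for i in range(n)], 1: [f"I{i}" for i in range(n)],
                        2: 0, 3: 0, 4: 0, 5: -9})
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)
    dos = panel.dosages
    code = np.full(dos.shape, 1, dtype=np.uint8)  # 01 = missing
    with np.errstate(invalid="ignore"):
        rounded = np.round(dos)
    code[rounded == 2] = 0
    code[rounded == 1] = 2
    code[rounded == 0] = 3
    pad = (-n) % 4
    if pad:
        code = np.vstack([code, np.full((pad, dos.shape[1]), 3, dtype=np.uint8)])
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    grouped = code.T.reshape(dos.shape[1], -1, 4)  # snp-major
    packed = (grouped << shifts[None, None, :]).sum(axis=2, dtype=np.uint8)
    Path(prefix + ".bed").write_bytes(_BED_MAGIC + packed.tobytes())


def _read_vcf(path: str) -> GenotypePanel:
    from cyvcf2 import VCF  # deferred: optional dependency

    log = ParseLog()
    ids, chroms, poss, a1s, a2s, cols = [], [], [], [], [], []
    vcf = VCF(str(path))
    for var in vcf:
        log.n_input += 1
        if len(var.ALT) != 1:
            log.skipped_multiallelic += 1
            logger.warning("skipping multi-allelic site %s:%d", var.CHROM, var.POS)
            continue
        if "DS" in var.FORMAT:
            d = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        else:
            gts = np.asarray([g[:2] for g in var.genotypes])
            d = np.where((gts < 0).any(axis=1), np.nan, (gts > 0).sum(axis=1)).astype(float)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}:{var.REF}:{var.ALT[0]}")
        chroms.append(_norm_chrom(var.CHROM))
        poss.append(var.POS)
        # effect allele = ALT (the counted allele in GT dosage)
        a1s.append(var.ALT[0].upper())
        a2s.append(var.REF.upper())
        cols.append(d)
        log.n_kept += 1
    if not cols:
        raise EmptyInputError(f"no biallelic variants parsed from {path}")
    variants = pd.DataFrame({"id": ids, "chrom": chroms,
                             "pos": np.asarray(poss, dtype=np.int64),
                             "a1": a1s, "a2": a2s})
    return GenotypePanel(variants, np.column_stack(cols), log)


def _read_matrix_tsv(path: str) -> GenotypePanel:
    """Plain dosage matrix: header row of variant ids formatted id:chrom:pos:a1:a2
    (or plain ids with a leading ``#variants`` metadata block), one row per
    individual."""
    df = pd.read_csv(path, sep="\t")
    ids, chroms, poss, a1s, a2s = [], [], [], [], []
    for col in df.columns:
        parts = str(col).split(":")
        if len(parts) == 5:
            ids.append(parts[0]); chroms.append(_norm_chrom(parts[1]))
            poss.append(int(parts[2])); a1s.append(parts[3].upper()); a2s.append(parts[4].upper())
        elif len(parts) == 4:
            ids.append(col); chroms.append(_norm_chrom(parts[0]))
            poss.append(int(parts[1])); a1s.append(parts[2].upper()); a2s.append(parts[3].upper())
        else:
            raise FormatError(f"matrix-tsv header '{col}' is not id:chrom:pos:a1:a2")
    for i, col in enumerate(df.columns):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna() \
            & ~df[col].astype(str).str.upper().isin(["NA", "NAN"])
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise FormatError(f"non-numeric dosage at row {row + 1}, column '{col}'")
    dos = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    variants = pd.DataFrame({"id": ids, "chrom": chroms,
                             "pos": np.asarray(poss, dtype=np.int64),
                             "a1": a1s, "a2": a2s})
    return GenotypePanel(variants, dos)


def read_genotypes(path, format: str = "plink-bed") -> GenotypePanel:
    """Read a reference genotype panel.

    format: ``plink-bed`` (bed/bim/fam prefix or .bed path), ``vcf``
    (uncompressed or bgzipped VCF with GT or DS), or ``matrix-tsv``.
    Dosages count copies of the effect allele of each variant record.
    """
    if format == "plink-bed":
        return _read_plink(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "matrix-tsv":
        return _read_matrix_tsv(path)
    raise ValueError(f"unknown genotype format '{format}'")


# ---------------------------------------------------------------------------
# Weights
# ---------------------------------------------------------------------------

def read_weights(path) -> WeightMatrix:
    """Read a weight table: variant identity columns plus >=1 weight columns.

    "NA" weight entries become zero with a logged warning; a variant id
    duplicated within the table is an error (ambiguous weight).
    """
    raw = pd.read_csv(path, sep=r"\s+", dtype=str)
    cols = _resolve_columns(list(raw.columns), None)
    for req in ("id", "chrom", "pos", "a1", "a2"):
        if req not in cols:
            raise FormatError(f"missing required column '{req}' in {path}")
    id_cols = {cols[c] for c in ("id", "chrom", "pos", "a1", "a2")}
    trait_cols = [c for c in raw.columns if c not in id_cols]
    if not trait_cols:
        raise FormatError(f"no weight columns found in {path}")
    key = raw[cols["chrom"]].astype(str) + ":" + raw[cols["pos"]].astype(str)
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0]
        raise FormatError(f"duplicated variant {dup} in weight table {path}")
    log = ParseLog(n_input=len(raw), n_kept=len(raw))
    W = np.zeros((len(raw), len(trait_cols)))
    for j, c in enumerate(trait_cols):
        col = pd.to_numeric(raw[c], errors="coerce")
        na = col.isna()
        if na.any():
            log.na_weights_zeroed += int(na.sum())
            logger.warning("%d NA weights in column '%s' treated as zero", na.sum(), c)
        W[:, j] = col.fillna(0.0).to_numpy()
    variants = pd.DataFrame({
        "id": raw[cols["id"]].astype(str),
        "chrom": raw[cols["chrom"]].map(_norm_chrom),
        "pos": pd.to_numeric(raw[cols["pos"]]).astype(np.int64),
        "a1": raw[cols["a1"]].str.upper(),
        "a2": raw[cols["a2"]].str.upper(),
    })
    return WeightMatrix(variants, W, list(trait_cols))


def write_weights(w: WeightMatrix, path) -> None:
    out = w.variants.copy()
    for j, t in enumerate(w.trait_ids):
        out[t] = w.weights[:, j]
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------

def read_regions(source) -> RegionSet:
    """Read regions from a BED file path or an inline "chr:start-end" string.

    BED rows (0-based half-open) become 1-based inclusive as start+1..end.
    Inline strings are already 1-based inclusive. Commas in coordinates are
    permitted.
    """
    text = str(source)
    if ":" in text and "-" in text.split(":")[-1] and not Path(text).exists():
        chrom, span = text.split(":", 1)
        lo, hi = span.replace(",", "").split("-")
        return RegionSet([(_norm_chrom(chrom), int(lo), int(hi))])
    intervals: list[tuple[str, int, int]] = []
    with open(text) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"BED row with <3 columns: '{line}'")
            intervals.append((_norm_chrom(parts[0]), int(parts[1]) + 1, int(parts[2])))
    return RegionSet(intervals)


def region_to_bed_row(chrom: str, start: int, end: int) -> str:
    """Internal 1-based inclusive interval -> BED row (exact inverse of parsing)."""
    return f"{chrom}\t{start - 1}\t{end}"


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

RESULT_COLUMNS = ["trait", "gamma_hat", "gamma_std", "se", "z", "p", "log10_p",
                  "n_gwas", "n_snps", "analysis", "usable", "note"]


def results_frame(results: Iterable[AssociationResult]) -> pd.DataFrame:
    rows = [(r.trait_id, r.gamma_hat, r.gamma_std, r.se, r.z, r.p, r.log10_p,
             r.n_gwas, r.n_snps, r.analysis, r.usable, r.note) for r in results]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(results: Iterable[AssociationResult], path) -> None:
    results_frame(results).to_csv(path, sep="\t", index=False, float_format="%.17g")
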