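"""Reading, validation, harmonization and masking of GWAS summary statistics.

Summary statistics are per-variant association records (effect size on the
log-odds scale, standard error, two-sided p-value, sample size).  Two GWAS are
joined on a shared variant panel with alleles of the second trait aligned to
the first: swapped alleles flip the sign of the effect, strand flips are
resolved through base complements, and strand-ambiguous palindromic variants
(A/T, C/G) are dropped because allele frequencies are not available to resolve
them.

The LD reference is block-diagonal: a list of blocks, each a set of variants on
one chromosome with a dense pairwise correlation matrix; correlations across
blocks are zero by convention.  Per-variant LD scores (sum of r^2 over the
block, including self) are recomputed from the stored correlations on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("pleioscan")

# Extended-LD regions excluded from empirical estimation (GRCh37, 1-based,
# closed intervals) and handled post hoc.
MHC_REGION = ("MHC", 6, 28_477_797, 33_448_354)
MAPT_REGION = ("MAPT", 17, 43_384_864, 44_913_631)

#: Default column names of a summary-statistics file.
DEFAULT_COLUMNS = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "a1": "A1",
    "a2": "A2",
    "beta": "BETA",
    "se": "SE",
    "pval": "P",
    "n": "N",
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset("ACGT")


@dataclass
class RegionMask:
    """A named closed genomic interval [start, end] on one chromosome."""

    name: str
    chrom: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"mask {self.name}: start > end")

    def contains(self, chrom: int, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def default_masks() -> list[RegionMask]:
    return [RegionMask(*MHC_REGION), RegionMask(*MAPT_REGION)]


def read_region_masks(path) -> list[RegionMask]:
    """Read masks from a BED-style file (0-based half-open; converted)."""
    masks = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, start, end, *rest = line.split("\t")
            name = rest[0] if rest else f"{chrom}:{start}-{end}"
            masks.append(
                RegionMask(name, int(chrom.removeprefix("chr")), int(start) + 1, int(end))
            )
    return masks


@dataclass
class SummaryStatTable:
    """One GWAS's validated per-variant records, sorted by (chrom, pos)."""

    trait_label: str
    table: pd.DataFrame
    drop_counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)


def read_sumstats(path, trait_label: str, column_map: dict[str, str] | None = None) -> SummaryStatTable:
    """Read and validate a tab-delimited summary-statistics file.

    Rows failing validation (bad alleles, non-positive se, p outside (0, 1],
    missing coordinates) are dropped and counted by reason.  If the p-value
    column is absent it is filled from the Wald statistic, 2*Phi(-|beta/se|).
    Duplicate variant ids keep the record with the smallest standard error.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype={cols["snp_id"]: str})
    if df.empty:
        raise ValueError(f"{path}: empty summary-statistics file")
    has_p = cols["pval"] in df.columns
    required = [k for k in ("snp_id", "chrom", "pos", "a1", "a2", "beta", "se", "n")]
    for key in required:
        if cols[key] not in df.columns:
            raise ValueError(f"{path}: missing required column '{cols[key]}'")
    rename = {cols[k]: k for k in (required + (["pval"] if has_p else []))}
    df = df.rename(columns=rename)[list(rename.values())].copy()

    drops: dict[str, int] = {}
    df["a1"] = df["a1"].astype(str).str.upper()
    df["a2"] = df["a2"].astype(str).str.upper()
    for col in ("chrom", "pos", "beta", "se", "n") + (("pval",) if has_p else ()):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    checks = [
        ("invalid_position", df["chrom"].isna() | df["pos"].isna() | (df["pos"] <= 0)
         | ~df["chrom"].between(1, 22)),
        ("invalid_alleles", ~df["a1"].isin(_VALID_ALLELES) | ~df["a2"].isin(_VALID_ALLELES)
         | (df["a1"] == df["a2"])),
        ("invalid_beta_se", df["beta"].isna() | df["se"].isna() | (df["se"] <= 0)),
        ("invalid_n", df["n"].isna() | (df["n"] <= 0)),
    ]
    if has_p:
        checks.append(("invalid_p", df["pval"].isna() | (df["pval"] <= 0) | (df["pval"] > 1)))
    seen = pd.Series(False, index=df.index)
    for reason, mask in checks:
        fresh = mask & ~seen
        if fresh.any():
            drops[reason] = int(fresh.sum())
        seen |= mask
    df = df.loc[~seen].copy()

    if not has_p:
        df["pval"] = 2.0 * stats.norm.sf(np.abs(df["beta"] / df["se"]))
        df["pval"] = df["pval"].clip(lower=np.nextafter(0.0, 1.0))

    if df.empty:
        raise ValueError(f"{path}: no valid rows after filtering")

    dup = df.duplicated(subset="snp_id", keep=False)
    if dup.any():
        n_dup = int(dup.sum()) - df.loc[dup, "snp_id"].nunique()
        logger.warning("%s: dropping %d duplicate snp_id records (keeping smallest se)",
                       trait_label, n_dup)
        drops["duplicate_snp_id"] = n_dup
        df = df.sort_values(["snp_id", "se"], kind="stable").drop_duplicates("snp_id")

    df = df.astype({"chrom": int, "pos": int})
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return SummaryStatTable(trait_label=trait_label, table=df, drop_counts=drops)


@dataclass
class HarmonizedPair:
    """Allele-aligned inner join of two GWAS on their shared variants.

    ``table`` carries, per variant: z-scores, betas, ses, p-values and sample
    sizes for both traits, a concordance flag (beta1*beta2 > 0) and the
    extended-LD region tag ('none', 'MHC' or 'MAPT').
    """

    pair_label: str
    table: pd.DataFrame
    provenance: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n1(self) -> float:
        return float(self.table["n1"].median())

    @property
    def n2(self) -> float:
        return float(self.table["n2"].median())


def _derive_z(beta: np.ndarray, se: np.ndarray, pval: np.ndarray) -> np.ndarray:
    """z-scores; the p-value is authoritative when it disagrees with beta/se.

    Summary files often store betas truncated to few digits, so when the Wald
    z from beta/se differs from the p-implied z by more than 10% relative, z is
    re-derived as sign(beta) * Phi^-1(1 - p/2).
    """
    z_wald = beta / se
    z_p = -stats.norm.ppf(np.minimum(pval / 2.0, 0.5))  # magnitude
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(np.abs(z_wald) - z_p) / np.where(z_p > 0, z_p, 1.0)
    use_p = (rel > 0.10) & np.isfinite(z_p)
    z = np.where(use_p, np.sign(beta) * z_p, z_wald)
    return z


def harmonize_pair(
    t1: SummaryStatTable,
    t2: SummaryStatTable,
    masks: list[RegionMask] | None = None,
) -> HarmonizedPair:
    """Join two GWAS on shared variants with trait 2 aligned to trait 1's alleles."""
    if masks is None:
        masks = default_masks()
    a = t1.table.rename(columns={c: c + "1" for c in ("beta", "se", "pval", "n")})
    b = t2.table.rename(columns={c: c + "2" for c in ("beta", "se", "pval", "n")})
    b = b.rename(columns={"a1": "b1", "a2": "b2"})
    merged = a.merge(
        b[["snp_id", "b1", "b2", "beta2", "se2", "pval2", "n2"]], on="snp_id", how="inner"
    )
    prov = {"only_in_one": len(t1) + len(t2) - 2 * len(merged)}
    if merged.empty:
        raise ValueError("harmonize_pair: no shared variants between the two tables")

    a1 = merged["a1"].to_numpy()
    a2 = merged["a2"].to_numpy()
    b1 = merged["b1"].to_numpy()
    b2 = merged["b2"].to_numpy()
    comp = np.vectorize(_COMPLEMENT.get)
    palindromic = (a2 == comp(a1))
    same = (b1 == a1) & (b2 == a2)
    swapped = (b1 == a2) & (b2 == a1)
    flip_same = (comp(b1) == a1) & (comp(b2) == a2)
    flip_swap = (comp(b1) == a2) & (comp(b2) == a1)

    keep_same = (same | flip_same) & ~palindromic
    keep_swap = (swapped | flip_swap) & ~palindromic
    mismatched = ~(same | swapped | flip_same | flip_swap)
    prov["palindromic"] = int((palindromic & ~mismatched).sum())
    prov["allele_mismatch"] = int(mismatched.sum())

    merged.loc[keep_swap, "beta2"] = -merged.loc[keep_swap, "beta2"]
    merged = merged.loc[keep_same | keep_swap].copy()
    if merged.empty:
        raise ValueError("harmonize_pair: no variants left after allele matching")

    merged["z1"] = _derive_z(
        merged["beta1"].to_numpy(), merged["se1"].to_numpy(), merged["pval1"].to_numpy()
    )
    merged["z2"] = _derive_z(
        merged["beta2"].to_numpy(), merged["se2"].to_numpy(), merged["pval2"].to_numpy()
    )
    merged["concordant"] = (merged["beta1"] * merged["beta2"]) > 0
    merged = merged.rename(columns={"pval1": "p1", "pval2": "p2"})
    cols = ["snp_id", "chrom", "pos", "a1", "a2",
            "beta1", "se1", "p1", "n1", "beta2", "se2", "p2", "n2",
            "z1", "z2", "concordant"]
    merged = merged[cols].sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    pair = HarmonizedPair(
        pair_label=f"{t1.trait_label}-{t2.trait_label}", table=merged, provenance=prov
    )
    return tag_masked_regions(pair, masks)


def tag_masked_regions(pair: HarmonizedPair, masks: list[RegionMask]) -> HarmonizedPair:
    """Assign each variant its containing mask region by closed-interval containment."""
    tab = pair.table
    region = np.full(len(tab), "none", dtype=object)
    chrom = tab["chrom"].to_numpy()
    pos = tab["pos"].to_numpy()
    for m in masks:
        inside = (chrom == m.chrom) & (pos >= m.start) & (pos <= m.end)
        region[inside] = m.name
    tab = tab.copy()
    tab["masked_region"] = region
    return HarmonizedPair(pair.pair_label, tab, dict(pair.provenance))


class LDReference:
    """Block-diagonal LD reference: per-block correlation matrices + LD scores.

    Cross-block correlation is implicitly zero.  ``r2(a, b)`` returns the
    squared correlation between two variants; ``ld_score`` maps each variant
    to its sum of r^2 over its block (>= 1, including self).
    """

    def __init__(self, blocks: list[tuple[int, list[str], np.ndarray]]):
        self.blocks: list[tuple[int, list[str], np.ndarray]] = []
        self._index: dict[str, tuple[int, int]] = {}
        self.ld_score: dict[str, float] = {}
        for bi, (chrom, snps, R) in enumerate(blocks):
            R = np.asarray(R, dtype=float)
            if R.shape != (len(snps), len(snps)):
                raise ValueError(f"block {bi}: correlation matrix shape mismatch")
            if np.any(np.abs(R) > 1 + 1e-12):
                raise ValueError(f"block {bi}: |r| > 1")
            if not np.allclose(np.diag(R), 1.0):
                raise ValueError(f"block {bi}: diagonal of a correlation matrix must be 1")
            for j, s in enumerate(snps):
                if s in self._index:
                    raise ValueError(f"snp '{s}' appears in more than one LD block")
                self._index[s] = (bi, j)
            scores = (R**2).sum(axis=0)
            for s, sc in zip(snps, scores):
                self.ld_score[s] = float(sc)
            self.blocks.append((int(chrom), list(snps), R))

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    @property
    def n_snps(self) -> int:
        return len(self._index)

    def block_of(self, snp_id: str) -> tuple[int, int]:
        return self._index[snp_id]

    def r2(self, a: str, b: str) -> float:
        ba, ia = self._index[a]
        bb, ib = self._index[b]
        if ba != bb:
            return 0.0
        return float(self.blocks[ba][2][ia, ib] ** 2)

    def submatrix(self, block_idx: int, keep: np.ndarray) -> np.ndarray:
        R = self.blocks[block_idx][2]
        return R[np.ix_(keep, keep)]


def load_ld_reference(path) -> LDReference:
    """Load the plain-text LD reference.

    Format: for each block, a header line ``#BLOCK <chrom> <snp1> <snp2> ...``
    followed by the lower triangle of the correlation matrix (including the
    unit diagonal), one row per line, whitespace-separated.
    """
    blocks = []
    with open(path) as fh:
        chrom = None
        snps: list[str] = []
        rows: list[list[float]] = []

        def _finish():
            if chrom is None:
                return
            k = len(snps)
            if len(rows) != k:
                raise ValueError(f"LD block on chrom {chrom}: expected {k} rows, got {len(rows)}")
            R = np.zeros((k, k))
            for i, row in enumerate(rows):
                if len(row) != i + 1:
                    raise ValueError(f"LD block row {i}: expected {i + 1} values")
                R[i, : i + 1] = row
                R[: i + 1, i] = row
            blocks.append((chrom, snps, R))

        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#BLOCK"):
                _finish()
                parts = line.split()
                chrom = int(parts[1])
                snps = parts[2:]
                rows = []
            else:
                rows.append([float(x) for x in line.split()])
        _finish()
    if not blocks:
        raise ValueError(f"{path}: no LD blocks found")
    return LDReference(blocks)


def write_ld_reference(ld: LDReference, path) -> None:
    with open(path, "w") as fh:
        for chrom, snps, R in ld.blocks:
            fh.write("#BLOCK " + str(chrom) + " " + " ".join(snps) + "\n")
            for i in range(len(snps)):
                fh.write(" ".join(f"{v:.6g}" for v in R[i, : i + 1]) + "\n")


def write_results_table(records: pd.DataFrame, path) -> None:
    """Write a tabular result as tab-delimited text with >= 6 significant digits."""
    if records is None or len(records) == 0:
        raise ValueError("write_results_table: empty record set")
    records.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
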