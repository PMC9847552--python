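"""Clumping pleiotropic variants into loci and classifying pleiotropy direction.

Locus definition follows the standard two-stage clumping used by functional
mapping pipelines: pleiotropic variants mutually below r^2 = 0.6 (greedy in
ascending conjFDR order) become independent significant variants; among those,
variants mutually below r^2 = 0.1 become lead variants; each lead's locus
spans every pleiotropic variant in LD (r^2 >= 0.6) with any of its independent
significant variants; intervals closer than 250 kb are merged.  All loci
overlapping the MHC interval are merged into a single locus named 'MHC'.

A variant is concordant when the product of its two effect sizes is positive.
A locus with >= 90% concordant members is classified concordant, <= 10%
antagonistic, and anything between ambiguous; the boundaries are evaluated in
exact integer arithmetic (10 * n_concordant vs n_total).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sumstats import HarmonizedPair, LDReference, RegionMask

__all__ = [
    "ClumpConfig",
    "Locus",
    "clump_loci",
    "merge_mhc_locus",
    "classify_direction",
    "overlap_between_pairs",
    "loci_frame",
]


@dataclass(frozen=True)
class ClumpConfig:
    """LD and distance thresholds of the locus definition."""

    r2_candidate: float = 0.6
    r2_lead: float = 0.1
    merge_kb: float = 250.0

    def __post_init__(self) -> None:
        if not (0 < self.r2_lead <= self.r2_candidate < 1):
            raise ValueError("need 0 < r2_lead <= r2_candidate < 1")
        if self.merge_kb < 0:
            raise ValueError("merge_kb must be >= 0")


def classify_direction(n_concordant: int, n_total: int) -> str:
    """Three-bin direction rule on the concordant-member ratio.

    >= 90% concordant -> 'concordant'; <= 10% -> 'antagonistic'; otherwise
    'ambiguous'.  Boundaries are inclusive on the outer bins and decided in
    integer arithmetic, so exactly 10% is antagonistic and exactly 90% is
    concordant.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not (0 <= n_concordant <= n_total):
        raise ValueError("need 0 <= n_concordant <= n_total")
    if 10 * n_concordant >= 9 * n_total:
        return "concordant"
    if 10 * n_concordant <= n_total:
        return "antagonistic"
    return "ambiguous"


@dataclass
class Locus:
    """A clumped genomic interval of pleiotropic variants (closed, bp)."""

    chrom: int
    start: int
    end: int
    lead_snp: str
    lead_conjfdr: float
    member_snps: list[str]
    n_concordant: int
    n_total: int
    is_mhc: bool = False

    @property
    def concordant_ratio(self) -> float:
        return self.n_concordant / self.n_total

    @property
    def direction(self) -> str:
        return classify_direction(self.n_concordant, self.n_total)


def _locus_from_members(members: pd.DataFrame, is_mhc: bool = False) -> Locus:
    lead = members.sort_values(
        ["conjfdr", "p1p2", "pos"], kind="stable"
    ).iloc[0]
    return Locus(
        chrom=int(members["chrom"].iloc[0]),
        start=int(members["pos"].min()),
        end=int(members["pos"].max()),
        lead_snp=str(lead["snp_id"]),
        lead_conjfdr=float(lead["conjfdr"]),
        member_snps=members["snp_id"].tolist(),
        n_concordant=int(members["concordant"].sum()),
        n_total=len(members),
        is_mhc=is_mhc,
    )


def clump_loci(
    pleio: pd.DataFrame,
    pair: HarmonizedPair,
    ld: LDReference,
    cfg: ClumpConfig | None = None,
) -> list[Locus]:
    """Partition pleiotropic variants into disjoint loci.

    ``pleio`` needs columns snp_id, chrom, pos, p1, p2, conjfdr, concordant.
    Output is deterministic and independent of input row order: the greedy
    passes are ordered by (conjfdr, p1*p2, position).
    """
    cfg = cfg or ClumpConfig()
    if len(pleio) == 0:
        return []
    df = pleio.copy()
    missing = [s for s in df["snp_id"] if s not in ld]
    if missing:
        raise ValueError(f"{len(missing)} pleiotropic variants missing from LD reference")
    df["p1p2"] = df["p1"] * df["p2"]
    df = df.sort_values(["conjfdr", "p1p2", "pos"], kind="stable").reset_index(drop=True)
    snps = df["snp_id"].tolist()

    # stage 1: independent significant variants (greedy, mutually r2 < r2_candidate)
    indep: list[int] = []
    assigned_to: dict[int, int] = {}  # pleio row -> indep row it clumps with
    for i in range(len(df)):
        r2s = [ld.r2(snps[i], snps[j]) for j in indep]
        hits = [j for j, r2 in zip(indep, r2s) if r2 >= cfg.r2_candidate]
        if hits:
            best = max(hits, key=lambda j: ld.r2(snps[i], snps[j]))
            assigned_to[i] = best
        else:
            indep.append(i)
            assigned_to[i] = i

    # stage 2: lead variants among independent significant (mutually r2 < r2_lead)
    leads: list[int] = []
    lead_of: dict[int, int] = {}
    for i in indep:
        hits = [j for j in leads if ld.r2(snps[i], snps[j]) >= cfg.r2_lead]
        if hits:
            best = max(hits, key=lambda j: ld.r2(snps[i], snps[j]))
            lead_of[i] = best
        else:
            leads.append(i)
            lead_of[i] = i

    df["locus_key"] = [lead_of[assigned_to[i]] for i in range(len(df))]

    # stage 3: intervals, then distance-based merging per chromosome
    loci = [
        _locus_from_members(g)
        for _, g in df.groupby("locus_key", sort=True)
    ]
    loci.sort(key=lambda L: (L.chrom, L.start, L.end))
    merged: list[Locus] = []
    gap = int(cfg.merge_kb * 1000)
    members_by_id = df.set_index("snp_id")
    for loc in loci:
        if merged and merged[-1].chrom == loc.chrom and loc.start - merged[-1].end <= gap:
            pooled = members_by_id.loc[merged[-1].member_snps + loc.member_snps].reset_index()
            merged[-1] = _locus_from_members(pooled)
        else:
            merged.append(loc)
    return merged


def merge_mhc_locus(loci: list[Locus], mask: RegionMask) -> list[Locus]:
    """Merge every locus overlapping the MHC interval into one 'MHC' locus."""
    is_in = [L.chrom == mask.chrom and L.start <= mask.end and L.end >= mask.start
             for L in loci]
    inside = [L for L, f in zip(loci, is_in) if f]
    if not inside:
        return list(loci)
    outside = [L for L, f in zip(loci, is_in) if not f]
    members = []
    for L in inside:
        members.extend(L.member_snps)
    lead = min(inside, key=lambda L: (L.lead_conjfdr, L.lead_snp))
    mhc = Locus(
        chrom=mask.chrom,
        start=min(L.start for L in inside),
        end=max(L.end for L in inside),
        lead_snp=lead.lead_snp,
        lead_conjfdr=lead.lead_conjfdr,
        member_snps=members,
        n_concordant=sum(L.n_concordant for L in inside),
        n_total=sum(L.n_total for L in inside),
        is_mhc=True,
    )
    out = outside + [mhc]
    out.sort(key=lambda L: (L.chrom, L.start, L.end))
    return out


def overlap_between_pairs(
    loci_a: list[Locus], loci_b: list[Locus]
) -> tuple[int, list[tuple[Locus, Locus]]]:
    """Count loci in A overlapping >= 1 locus in B (same chromosome, closed)."""
    pairs = []
    count = 0
    for A in loci_a:
        matched = [B for B in loci_b
                   if B.chrom == A.chrom and A.start <= B.end and A.end >= B.start]
        if matched:
            count += 1
            pairs.extend((A, B) for B in matched)
    return count, pairs


def loci_frame(loci: list[Locus]) -> pd.DataFrame:
    """Tabular view of a locus list (mirrors the reported locus-table layout)."""
    return pd.DataFrame(
        [{"CHR": L.chrom, "Start": L.start, "End": L.end,
          "LeadSNP": L.lead_snp, "conjFDR": L.lead_conjfdr,
          "Direction": L.direction,
          "Ratio": f"{L.n_concordant}/{L.n_total}",
          "isMHC": L.is_mhc}
         for L in loci]
    )
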