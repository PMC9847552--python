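"""Published per-locus tallies from the Parkinson's disease / IBD overlap study.

The cross-trait conjFDR analysis of Parkinson's disease against the two
inflammatory-bowel-disease subtypes reported, for every pleiotropic locus, the
number of concordant member SNPs (beta_PD * beta_IBD > 0) out of the total
pleiotropic SNPs in the locus, together with the locus's published direction
label.  Those tallies are bundled here as worked-example inputs for the
direction classifier; the underlying GWAS are access-restricted, so the
tallies are the only locus-level ground truth available at desk scale.

Each entry is (lead_snp, n_concordant, n_total, published_direction).
"""

from __future__ import annotations

__all__ = [
    "PD_CROHNS_LOCUS_TALLIES",
    "PD_UC_LOCUS_TALLIES",
    "PD_CROHNS_SNP_COUNTS",
    "PD_UC_SNP_COUNTS",
]

# Parkinson's disease - Crohn's disease: 27 loci (10 shared with the UC pair
# plus 17 pair-specific).
PD_CROHNS_LOCUS_TALLIES: list[tuple[str, int, int, str]] = [
    ("rs35902694", 4, 37, "ambiguous"),
    ("rs10800309", 0, 2, "antagonistic"),
    ("rs3738255", 7, 7, "concordant"),
    ("rs3218921", 0, 3, "antagonistic"),
    ("rs73082337", 5, 9, "ambiguous"),
    ("rs200966", 0, 1, "antagonistic"),
    ("rs1738434", 199, 208, "concordant"),      # MHC
    ("rs9708958", 0, 148, "antagonistic"),
    ("rs12936169", 67, 67, "concordant"),
    ("rs1736023", 52, 52, "concordant"),
    ("rs11576494", 0, 66, "antagonistic"),
    ("rs744877", 1, 1, "concordant"),
    ("rs34305899", 1, 1, "concordant"),
    ("rs10916037", 0, 14, "antagonistic"),
    ("rs13001158", 0, 25, "antagonistic"),
    ("rs13107325", 0, 14, "antagonistic"),
    ("rs62541503", 1, 1, "concordant"),
    ("rs28370649", 495, 495, "concordant"),
    ("rs59884956", 0, 1, "antagonistic"),
    ("rs55848327", 1, 1, "concordant"),
    ("rs72781032", 0, 5, "antagonistic"),
    ("rs35695082", 1, 1, "concordant"),
    ("rs3760013", 0, 3, "antagonistic"),
    ("rs2067085", 83, 83, "concordant"),
    ("rs7209801", 30, 30, "concordant"),
    ("rs62060837", 2, 2, "concordant"),
    ("rs9607805", 0, 2, "antagonistic"),
]

# Parkinson's disease - ulcerative colitis: 15 loci (10 shared + 5 specific).
PD_UC_LOCUS_TALLIES: list[tuple[str, int, int, str]] = [
    ("rs7535292", 0, 12, "antagonistic"),
    ("rs6658353", 0, 17, "antagonistic"),
    ("rs12045164", 20, 20, "concordant"),
    ("rs7567514", 9, 9, "concordant"),
    ("rs9848268", 27, 28, "concordant"),
    ("rs17767294", 1, 1, "concordant"),
    ("rs9268556", 891, 951, "concordant"),      # MHC
    ("rs62036658", 0, 81, "antagonistic"),
    ("rs9897702", 35, 35, "concordant"),
    ("rs1736023", 52, 52, "concordant"),
    ("rs708723", 6, 6, "concordant"),
    ("rs9309337", 1, 2, "ambiguous"),
    ("rs2271543", 0, 3, "antagonistic"),
    ("rs800907", 1, 1, "concordant"),
    ("rs1938598", 141, 141, "concordant"),
]

#: (n_concordant_snps, n_pleiotropic_snps) across the genome, per trait pair.
PD_CROHNS_SNP_COUNTS: tuple[int, int] = (949, 1290)
PD_UC_SNP_COUNTS: tuple[int, int] = (1184, 1359)
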