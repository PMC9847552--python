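"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pleioscan.cfdr import CfdrConfig, CfdrTable, random_prune
from pleioscan.sumstats import HarmonizedPair, LDReference


def make_pair(
    z1,
    z2,
    n1: float = 10_000,
    n2: float = 10_000,
    chrom=None,
    pos=None,
    masked=None,
    label: str = "test-pair",
) -> HarmonizedPair:
    """Build a HarmonizedPair directly from z-scores (snp ids rs1, rs2, ...)."""
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    m = len(z1)
    chrom = np.ones(m, dtype=int) if chrom is None else np.asarray(chrom, dtype=int)
    pos = (np.arange(m) + 1) * 10_000 if pos is None else np.asarray(pos, dtype=int)
    p1 = np.clip(2 * stats.norm.sf(np.abs(z1)), np.nextafter(0.0, 1.0), 1.0)
    p2 = np.clip(2 * stats.norm.sf(np.abs(z2)), np.nextafter(0.0, 1.0), 1.0)
    tab = pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1}" for i in range(m)],
            "chrom": chrom,
            "pos": pos,
            "a1": "A",
            "a2": "G",
            "beta1": z1 / np.sqrt(n1),
            "se1": 1 / np.sqrt(n1),
            "p1": p1,
            "n1": float(n1),
            "beta2": z2 / np.sqrt(n2),
            "se2": 1 / np.sqrt(n2),
            "p2": p2,
            "n2": float(n2),
            "z1": z1,
            "z2": z2,
            "concordant": z1 * z2 > 0,
            "masked_region": "none" if masked is None else masked,
        }
    )
    return HarmonizedPair(pair_label=label, table=tab)


def identity_ld(snp_ids, chrom: int = 1) -> LDReference:
    """One block per SNP: no LD at all."""
    return LDReference([(chrom, [s], np.eye(1)) for s in snp_ids])


def single_block_ld(snp_ids, R, chrom: int = 1) -> LDReference:
    return LDReference([(chrom, list(snp_ids), np.asarray(R, dtype=float))])


def write_sumstats_file(path, rows, header=None):
    """Write a tab-delimited summary-statistics file from row dicts."""
    cols = header or ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P", "N"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join(str(r[c]) for c in cols if c in r) + "\n")
    return path


def brute_force_cfdr(pair: HarmonizedPair, ld: LDReference, cfg: CfdrConfig) -> CfdrTable:
    """Independent O(n^2 K) double-loop cFDR oracle (for small universes)."""
    tab = pair.table
    snp_ids = tab["snp_id"].tolist()
    unmasked_ids = tab.loc[tab["masked_region"] == "none", "snp_id"].tolist()
    p1 = tab["p1"].to_numpy()
    p2 = tab["p2"].to_numpy()
    pos_of = {s: i for i, s in enumerate(snp_ids)}
    n = len(snp_ids)
    sumA2 = np.zeros(n, dtype=np.int64)
    sumA1 = np.zeros(n, dtype=np.int64)
    sumB = np.zeros(n, dtype=np.int64)
    for k in range(cfg.n_iterations):
        kept = random_prune(unmasked_ids, ld, cfg.seed + k, cfg.r2_prune)
        kept_idx = [pos_of[s] for s in kept]
        for j in range(n):
            for i in kept_idx:
                if p2[i] <= p2[j]:
                    sumA2[j] += 1
                if p1[i] <= p1[j]:
                    sumA1[j] += 1
                if p1[i] <= p1[j] and p2[i] <= p2[j]:
                    sumB[j] += 1
    c12 = np.ones(n)
    c21 = np.ones(n)
    for j in range(n):
        if sumB[j] > 0:
            c12[j] = min(1.0, p1[j] * (sumA2[j] / sumB[j]))
            c21[j] = min(1.0, p2[j] * (sumA1[j] / sumB[j]))
    conj = np.maximum(c12, c21)
    out = pd.DataFrame(
        {
            "snp_id": tab["snp_id"],
            "chrom": tab["chrom"],
            "pos": tab["pos"],
            "p1": p1,
            "p2": p2,
            "cfdr_1given2": c12,
            "cfdr_2given1": c21,
            "conjfdr": conj,
            "is_pleiotropic": conj < cfg.conj_threshold,
            "concordant": tab["concordant"],
            "masked_region": tab["masked_region"],
        }
    ).reset_index(drop=True)
    return CfdrTable(pair_label=pair.pair_label, table=out, config=cfg)


def random_universe(rng: np.random.Generator):
    """A random small (pair, ld) universe with block LD and occasional masking."""
    m = int(rng.integers(130, 500))
    sizes = []
    left = m
    while left > 0:
        bs = int(min(left, rng.integers(1, 12)))
        sizes.append(bs)
        left -= bs
    snp_ids = [f"rs{i + 1}" for i in range(m)]
    blocks = []
    start = 0
    for bs in sizes:
        bs = int(bs)
        rho = float(rng.uniform(0, 0.95))
        idx = np.arange(bs)
        R = rho ** np.abs(idx[:, None] - idx[None, :])
        blocks.append((1, snp_ids[start:start + bs], R))
        start += bs
    ld = LDReference(blocks)
    z1 = rng.standard_normal(m) * rng.uniform(0.8, 3.0)
    z2 = rng.standard_normal(m) * rng.uniform(0.8, 3.0)
    masked = np.where(rng.random(m) < 0.05, "MHC", "none")
    if (masked == "none").sum() < 100:
        masked = np.full(m, "none", dtype=object)
    pair = make_pair(z1, z2, masked=masked)
    return pair, ld


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_230_103)
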