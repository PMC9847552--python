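"""Summary tables, figures, and the end-to-end pipeline.

``run_pipeline`` orchestrates, for each configured trait pair:
harmonization -> genetic correlation -> conditional Q-Q curves (both
directions) -> conjFDR -> pleiotropic loci -> summary artifacts; when two
pairs share a primary trait, the cross-pair locus overlap is computed as well.
All stage seeds derive deterministically from the single run seed and the
stage name, and a machine-readable manifest records config, seeds and outputs.
"""

from __future__ import annotations

import json
import logging
import sys
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from . import __version__
from .cfdr import (CfdrConfig, CfdrTable, QQCurveSet, compute_cfdr_pair,
                   conditional_qq_curves, select_pleiotropic)
from .genetic_correlation import fit_genetic_correlation
from .loci import (ClumpConfig, Locus, clump_loci, loci_frame,
                   merge_mhc_locus, overlap_between_pairs)
from .sumstats import (HarmonizedPair, default_masks, harmonize_pair,
                       load_ld_reference, read_sumstats, write_results_table)

logger = logging.getLogger("pleioscan")

_DIRECTION_COLORS = {"concordant": "#1b7837", "antagonistic": "#b2182b",
                     "ambiguous": "#756bb1"}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed: crc32 of the stage name folded into seed."""
    return (int(seed) ^ zlib.crc32(stage.encode())) % 2**31


@dataclass
class PairSummary:
    """Genome-wide pleiotropy tallies for one trait pair."""

    pair_label: str
    n_pleiotropic_snps: int
    n_concordant_snps: int
    n_loci: int
    n_loci_by_direction: dict[str, int]

    @property
    def pct_concordant(self) -> str:
        return format_pct(self.n_concordant_snps, self.n_pleiotropic_snps)


def format_pct(count: int, total: int) -> str:
    """Percentage to one decimal, or an en dash when the total is zero."""
    if total == 0:
        return "–"
    return f"{100.0 * count / total:.1f}"


def summary_table(cfdr: CfdrTable, loci: list[Locus]) -> PairSummary:
    """Tally pleiotropic SNPs, concordance, and loci by direction."""
    sel = cfdr.table.loc[cfdr.table["is_pleiotropic"]]
    by_dir = {"concordant": 0, "antagonistic": 0, "ambiguous": 0}
    for L in loci:
        by_dir[L.direction] += 1
    return PairSummary(
        pair_label=cfdr.pair_label,
        n_pleiotropic_snps=len(sel),
        n_concordant_snps=int(sel["concordant"].sum()),
        n_loci=len(loci),
        n_loci_by_direction=by_dir,
    )


def summary_frame(summary: PairSummary) -> pd.DataFrame:
    """Summary as a two-column table; externally annotated rows are 'NA'."""
    total = summary.n_pleiotropic_snps
    rows = [
        ("Pleiotropic SNPs, total", f"{total} (100%)" if total else "0"),
        ("Concordant SNPs",
         f"{summary.n_concordant_snps} ({summary.pct_concordant}%)"),
        ("Exonic SNPs", "NA (out of scope)"),
        ("Deleterious SNPs", "NA (out of scope)"),
        ("Loci, total", str(summary.n_loci)),
        ("Loci, novel", "NA (out of scope)"),
    ]
    for d in ("concordant", "antagonistic", "ambiguous"):
        c = summary.n_loci_by_direction[d]
        rows.append((f"Loci, {d}", f"{c} ({format_pct(c, summary.n_loci)}%)"))
    return pd.DataFrame(rows, columns=["Quantity", summary.pair_label])


def _genome_x(chrom: pd.Series, pos: pd.Series) -> tuple[pd.Series, dict[int, float]]:
    offsets = {}
    offset = 0.0
    x = pos.astype(float).copy()
    for c in sorted(chrom.unique()):
        sel = chrom == c
        offsets[int(c)] = offset
        x.loc[sel] = pos.loc[sel] + offset
        offset += float(pos.loc[sel].max()) + 1e6
    return x, offsets


def manhattan_plot(cfdr: CfdrTable, loci: list[Locus], path) -> None:
    """Genome-wide -log10 conjFDR scatter, pleiotropic SNPs colored by locus direction."""
    import numpy as np

    tab = cfdr.table
    fig, ax = plt.subplots(figsize=(10, 4))
    x, _ = _genome_x(tab["chrom"], tab["pos"])
    y = -np.log10(tab["conjfdr"].clip(lower=1e-300))
    ax.scatter(x, y, s=4, c="#cccccc", linewidths=0, rasterized=False)
    direction_of = {}
    for L in loci:
        for s in L.member_snps:
            direction_of[s] = L.direction
    sel = tab["is_pleiotropic"]
    if sel.any():
        colors = [_DIRECTION_COLORS.get(direction_of.get(s, "ambiguous"))
                  for s in tab.loc[sel, "snp_id"]]
        ax.scatter(x[sel], y[sel], s=9, c=colors, linewidths=0)
    thr = -np.log10(cfdr.config.conj_threshold)
    ax.axhline(thr, color="black", linestyle="--", linewidth=0.8)
    for L in loci:
        lead = tab.loc[tab["snp_id"] == L.lead_snp]
        if len(lead):
            xi = float(x[lead.index[0]])
            yi = float(y[lead.index[0]])
            ax.annotate(L.lead_snp, (xi, yi), fontsize=6, rotation=45,
                        textcoords="offset points", xytext=(0, 4))
    ax.set_xlabel("genomic position")
    ax.set_ylabel(r"$-\log_{10}$ conjFDR")
    ax.set_title(cfdr.pair_label)
    fig.tight_layout()
    _save_figure(fig, path)
    plt.close(fig)


def qq_plot(curves: QQCurveSet, path, title: str = "") -> None:
    """Conditional Q-Q curves, one per conditioning threshold, plus identity."""
    fig, ax = plt.subplots(figsize=(5, 5))
    lim = 0.0
    absent = []
    for t in curves.thresholds:
        obs = curves.observed[t]
        if obs is None:
            absent.append(t)
            continue
        ax.plot(curves.expected, obs, label=f"p2 ≤ {t:g}", linewidth=1.2)
        lim = max(lim, float(obs.max()))
    lim = max(lim, float(curves.expected.max()))
    ax.plot([0, lim], [0, lim], color="grey", linestyle=":", linewidth=0.8,
            label="identity")
    if absent:
        ax.plot([], [], " ", label=f"absent: {', '.join(f'{t:g}' for t in absent)}")
    ax.set_xlabel(r"expected $-\log_{10} p$")
    ax.set_ylabel(r"observed $-\log_{10} p$")
    ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    _save_figure(fig, path)
    plt.close(fig)


def _save_figure(fig, path) -> None:
    """Save with scrubbed metadata so reruns are byte-identical."""
    path = Path(path)
    if path.suffix == ".svg":
        with plt.rc_context({"svg.hashsalt": "pleioscan"}):
            fig.savefig(path, metadata={"Date": None})
    else:
        fig.savefig(path, metadata={"Software": None})


@dataclass
class PairSpec:
    """Input paths and labels for one trait pair."""

    label: str
    sumstats1: str
    sumstats2: str
    trait1: str = "trait1"
    trait2: str = "trait2"


@dataclass
class RunConfig:
    """Full pipeline configuration (TOML-loadable)."""

    out_dir: str
    ld_reference: str
    pairs: list[PairSpec]
    seed: int = 0
    log_level: str = "INFO"
    cfdr: CfdrConfig = field(default_factory=CfdrConfig)
    clump: ClumpConfig = field(default_factory=ClumpConfig)

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        run = raw.get("run", {})
        pairs = [PairSpec(**p) for p in raw.get("pairs", [])]
        cfdr_cfg = CfdrConfig(**{k: (tuple(v) if k == "qq_thresholds" else v)
                                 for k, v in raw.get("cfdr", {}).items()})
        clump_cfg = ClumpConfig(**raw.get("clump", {}))
        return cls(
            out_dir=run.get("out_dir", "pleioscan_out"),
            ld_reference=run["ld_reference"],
            pairs=pairs,
            seed=int(run.get("seed", 0)),
            log_level=run.get("log_level", "INFO"),
            cfdr=cfdr_cfg,
            clump=clump_cfg,
        )


def _setup_logging(out_dir: Path, level: str) -> None:
    logger.setLevel(level.upper())
    logger.handlers.clear()
    stream = logging.StreamHandler(sys.stderr)
    stream.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(stream)
    fileh = logging.FileHandler(out_dir / "run.log", mode="w")
    fileh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s: %(message)s"))
    logger.addHandler(fileh)


def analyze_pair(
    pair: HarmonizedPair,
    ld,
    cfdr_cfg: CfdrConfig,
    clump_cfg: ClumpConfig,
):
    """Library-level single-pair analysis: rg, Q-Q curves, cFDR, loci, summary."""
    rg = fit_genetic_correlation(pair, ld)
    curves1 = conditional_qq_curves(pair, ld, cfdr_cfg, primary=1)
    curves2 = conditional_qq_curves(pair, ld, cfdr_cfg, primary=2)
    cfdr_tab = compute_cfdr_pair(pair, ld, cfdr_cfg)
    pleio = select_pleiotropic(cfdr_tab)
    loci = clump_loci(pleio, pair, ld, clump_cfg)
    mhc = next(m for m in default_masks() if m.name == "MHC")
    loci = merge_mhc_locus(loci, mhc)
    summary = summary_table(cfdr_tab, loci)
    return rg, (curves1, curves2), cfdr_tab, pleio, loci, summary


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis for every configured pair; returns the out dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out, config.log_level)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": {}, "pairs": {}}
    ld = load_ld_reference(config.ld_reference)
    loci_by_pair: dict[str, list[Locus]] = {}
    for spec in config.pairs:
        label = spec.label
        stage = f"cfdr:{label}"
        seed_k = stage_seed(config.seed, stage)
        manifest["stages"][stage] = seed_k
        cfdr_cfg = CfdrConfig(
            r2_prune=config.cfdr.r2_prune,
            n_iterations=config.cfdr.n_iterations,
            conj_threshold=config.cfdr.conj_threshold,
            qq_thresholds=config.cfdr.qq_thresholds,
            seed=seed_k,
        )
        try:
            t1 = read_sumstats(spec.sumstats1, spec.trait1)
            t2 = read_sumstats(spec.sumstats2, spec.trait2)
            pair = harmonize_pair(t1, t2)
            pair.pair_label = label
            rg, curves, cfdr_tab, pleio, loci, summary = analyze_pair(
                pair, ld, cfdr_cfg, config.clump
            )
        except Exception as exc:
            raise RuntimeError(f"pipeline stage failed for pair '{label}': {exc}") from exc
        loci_by_pair[label] = loci
        write_results_table(
            pd.DataFrame([{**rg.to_dict()}]), out / f"{label}_rg.tsv"
        )
        write_results_table(cfdr_tab.table, out / f"{label}_cfdr_table.tsv")
        if len(pleio):
            write_results_table(pleio, out / f"{label}_pleiotropic_snps.tsv")
        lf = loci_frame(loci)
        if len(lf):
            write_results_table(lf, out / f"{label}_loci.tsv")
        write_results_table(summary_frame(summary), out / f"{label}_summary.tsv")
        manhattan_plot(cfdr_tab, loci, out / f"{label}_manhattan.png")
        manhattan_plot(cfdr_tab, loci, out / f"{label}_manhattan.svg")
        for primary, cv in ((1, curves[0]), (2, curves[1])):
            qq_plot(cv, out / f"{label}_qq_primary{primary}.png",
                    title=f"{label}: trait {primary} | trait {3 - primary}")
            qq_plot(cv, out / f"{label}_qq_primary{primary}.svg",
                    title=f"{label}: trait {primary} | trait {3 - primary}")
        manifest["pairs"][label] = {
            "rg": rg.to_dict(),
            "n_pleiotropic_snps": summary.n_pleiotropic_snps,
            "n_loci": summary.n_loci,
            "loci_by_direction": summary.n_loci_by_direction,
            "provenance": pair.provenance,
        }
        logger.info("pair %s: rg=%.4f (se %.4f), %d pleiotropic SNPs, %d loci",
                    label, rg.rg, rg.se, summary.n_pleiotropic_snps, summary.n_loci)

    if len(config.pairs) == 2:
        a, b = (config.pairs[0].label, config.pairs[1].label)
        count, matched = overlap_between_pairs(loci_by_pair[a], loci_by_pair[b])
        rows = [{"pair_a": a, "lead_a": A.lead_snp, "chrom": A.chrom,
                 "start_a": A.start, "end_a": A.end,
                 "pair_b": b, "lead_b": B.lead_snp,
                 "start_b": B.start, "end_b": B.end}
                for A, B in matched]
        manifest["locus_overlap"] = {"count": count, "pairs": [a, b]}
        overlap_df = pd.DataFrame(rows) if rows else pd.DataFrame(
            [{"pair_a": a, "pair_b": b, "note": "no overlapping loci"}]
        )
        write_results_table(overlap_df, out / "locus_overlap.tsv")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
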