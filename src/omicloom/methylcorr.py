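"""CpG methylation classification and integration with expression.

Beta values (fraction methylated signal, in [0, 1]) are classified with
the strict thresholds hypo < 0.33 and hyper > 0.66; probes are assigned to
promoter ([TSS-1500, TSS), strand-adjusted), gene body, or 3'UTR; and
methylation is correlated with transcript (FPKM) and protein (iBAQ)
abundance by Spearman rank correlation.

The informer-set selection emulates the multi-sample panel strategy used
with large tumor compendia: across a panel of samples, retain probe-gene
pairs whose methylation is inversely correlated with the gene's expression
(rho at most ``rho_max``, Benjamini-Hochberg q at most ``fdr_q``); those
sites are enriched for genuinely regulatory CpGs and are then scored
against the naive/memory cell-state deltas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import Annotation

HYPO_MAX = 0.33
HYPER_MIN = 0.66
PROMOTER_BP = 1500


# ---------------------------------------------------------------------------
# Beta classification


def classify_beta(betas) -> tuple[np.ndarray, dict[str, float]]:
    """Classify each beta as hypo / intermediate / hyper (strict thresholds).

    Returns (labels, fraction per class). Values exactly at 0.33 or 0.66
    are intermediate.
    """
    b = np.asarray(betas, dtype=float)
    if b.size and (np.nanmin(b) < 0 or np.nanmax(b) > 1):
        raise ValueError("beta values must lie in [0, 1]")
    labels = np.where(b < HYPO_MAX, "hypo", np.where(b > HYPER_MIN, "hyper", "intermediate"))
    n = max(b.size, 1)
    fractions = {
        "hypo": float((labels == "hypo").sum() / n),
        "intermediate": float((labels == "intermediate").sum() / n),
        "hyper": float((labels == "hyper").sum() / n),
    }
    return labels, fractions


# ---------------------------------------------------------------------------
# Region assignment


def _promoter_window(tss: int, strand: str) -> tuple[int, int]:
    """[TSS-1500, TSS) on the transcribed strand, as forward coordinates."""
    if strand == "+":
        return max(0, tss - PROMOTER_BP), tss
    return tss + 1, tss + 1 + PROMOTER_BP


def assign_regions(
    probes: pd.DataFrame, annotation: Annotation, multi: bool = False
) -> pd.DataFrame:
    """Assign each probe to promoter / 3'UTR / gene_body / intergenic.

    With ``multi=True`` a probe inside several genes' windows yields one
    row per gene-probe pair; otherwise a single assignment is made with
    precedence promoter > 3'UTR > gene_body.
    """
    rank = {"promoter": 0, "3'UTR": 1, "gene_body": 2}
    trees: dict[str, IntervalTree] = {}
    for tx in annotation:
        tree = trees.setdefault(tx.chrom, IntervalTree())
        lo, hi = _promoter_window(tx.tss, tx.strand)
        if lo < hi:
            tree.addi(lo, hi, ("promoter", tx.gene_id))
        for iv in tx.utr3_intervals():
            tree.addi(iv.start, iv.end, ("3'UTR", tx.gene_id))
        tree.addi(tx.start, tx.end, ("gene_body", tx.gene_id))
    rows = []
    for r in probes.itertuples(index=False):
        hits = sorted(
            {h.data for h in trees.get(r.chrom, IntervalTree())[r.pos]},
            key=lambda d: (rank[d[0]], d[1]),
        )
        if not hits:
            rows.append((r.probe_id, "intergenic", ""))
        elif multi:
            rows.extend((r.probe_id, reg, g) for reg, g in hits)
        else:
            rows.append((r.probe_id, hits[0][0], hits[0][1]))
    out = pd.DataFrame(rows, columns=["probe_id", "region_assignment", "region_gene"])
    return probes.merge(out, on="probe_id", how="right")


# ---------------------------------------------------------------------------
# Correlation report


def spearman(x, y) -> tuple[float, float, int]:
    """Spearman rho with average-rank ties; returns (rho, p, n)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return float("nan"), float("nan"), int(ok.sum())
    rho, p = stats.spearmanr(x[ok], y[ok])
    return float(rho), float(p), int(ok.sum())


def correlate_methylation_expression(
    probes: pd.DataFrame,
    expression: pd.DataFrame,
    protein: pd.DataFrame,
    beta_column: str = "naive",
    min_pairs: int = 10,
) -> dict:
    """Spearman correlations across the joined omic layers.

    Reports promoter-beta vs log FPKM, promoter-beta vs log iBAQ, per-region
    beta vs each abundance, and FPKM vs iBAQ. Pairings with fewer than
    ``min_pairs`` joined genes report ``insufficient_data``.
    """
    fpkm_per_gene = expression.groupby("gene_id", as_index=True)["fpkm"].max()
    ibaq_per_gene = protein.set_index("gene_id")["ibaq"]

    def corr_block(df: pd.DataFrame) -> dict:
        gene_beta = df.groupby("region_gene")[beta_column].mean()
        joined_f = pd.concat([gene_beta, fpkm_per_gene], axis=1, join="inner")
        joined_i = pd.concat([gene_beta, ibaq_per_gene], axis=1, join="inner")
        out = {}
        for name, j, col in (
            ("beta_vs_log_fpkm", joined_f, "fpkm"),
            ("beta_vs_log_ibaq", joined_i, "ibaq"),
        ):
            if len(j) < min_pairs:
                out[name] = {"status": "insufficient_data", "n": len(j)}
            else:
                rho, p, n = spearman(j[beta_column], np.log10(j[col] + 1e-9))
                out[name] = {"rho": rho, "p": p, "n": n}
        return out

    report: dict = {"by_region": {}}
    for region, df in probes.groupby("region_assignment"):
        if region == "intergenic":
            continue
        report["by_region"][region] = corr_block(df)
    if "promoter" in report["by_region"]:
        report["promoter"] = report["by_region"]["promoter"]

    joined = pd.concat([fpkm_per_gene, ibaq_per_gene], axis=1, join="inner")
    if len(joined) < min_pairs:
        report["fpkm_vs_ibaq"] = {"status": "insufficient_data", "n": len(joined)}
    else:
        rho, p, n = spearman(joined["fpkm"], joined["ibaq"])
        report["fpkm_vs_ibaq"] = {"rho": rho, "p": p, "n": n}
    return report


# ---------------------------------------------------------------------------
# Naive/memory differential methylation


def differential_methylation(
    probes: pd.DataFrame,
    expression: pd.DataFrame,
    db_min: float = 0.2,
    de_min: float = 1.0,
    pseudocount: float = 0.1,
    expression_is_log2: bool = True,
) -> pd.DataFrame:
    """Per-probe naive-minus-memory deltas with a concordance class.

    ``inverse`` — methylation and expression move in opposite directions
    with both effect sizes above the floors (the classic regulatory
    pattern); ``concordant`` — same direction above the floors;
    ``unchanged`` otherwise. Probes missing either condition value are
    dropped (count reported in ``df.attrs``).
    """
    expr = expression.set_index("gene_id")
    rows = []
    n_skipped = 0
    for r in probes.itertuples(index=False):
        gid = getattr(r, "region_gene", None) or getattr(r, "gene_id", None)
        if gid not in expr.index or pd.isna(r.naive) or pd.isna(r.memory):
            n_skipped += 1
            continue
        delta_beta = float(r.naive - r.memory)
        e_n, e_m = float(expr.loc[gid, "naive"]), float(expr.loc[gid, "memory"])
        if expression_is_log2:
            delta_expr = e_n - e_m
        else:
            delta_expr = float(
                np.log2((e_n + pseudocount) / (e_m + pseudocount))
            )
        if (
            abs(delta_beta) >= db_min
            and abs(delta_expr) >= de_min
            and delta_beta * delta_expr < 0
        ):
            cls = "inverse"
        elif abs(delta_beta) >= db_min and abs(delta_expr) >= de_min:
            cls = "concordant"
        else:
            cls = "unchanged"
        rows.append(
            {
                "probe_id": r.probe_id,
                "gene_id": gid,
                "delta_beta": delta_beta,
                "delta_expr": delta_expr,
                "concordance": cls,
            }
        )
    out = pd.DataFrame(
        rows, columns=["probe_id", "gene_id", "delta_beta", "delta_expr", "concordance"]
    )
    out.attrs["n_skipped"] = n_skipped
    return out


# ---------------------------------------------------------------------------
# Informer-set selection


@dataclass
class InformerSite:
    probe_id: str
    gene_id: str
    panel_rho: float
    q_value: float
    delta_beta: float = float("nan")
    delta_expr: float = float("nan")


def select_informer_sites(
    panel_probes: pd.DataFrame,
    panel_expression: pd.DataFrame,
    sample_columns: list[str],
    rho_max: float = -0.3,
    fdr_q: float = 0.05,
) -> tuple[list[InformerSite], pd.DataFrame]:
    """Inverse methylation-expression CpGs across a multi-sample panel.

    For each probe-gene pair, the sample-wise Spearman correlation and its
    large-sample p-value are computed; pairs with rho <= ``rho_max`` and
    BH q <= ``fdr_q`` form the informer set. Constant-beta probes are
    skipped. Returns (informer sites, full per-pair table).
    """
    if len(sample_columns) < 30:
        raise ValueError(
            f"panel must have >= 30 samples, got {len(sample_columns)}"
        )
    expr = panel_expression.set_index("gene_id")[sample_columns]
    rows = []
    for r in panel_probes.itertuples(index=False):
        gid = getattr(r, "gene_id")
        if gid not in expr.index:
            continue
        betas = np.array([getattr(r, s) for s in sample_columns], dtype=float)
        if np.ptp(betas) == 0:
            continue
        rho, p, n = spearman(betas, expr.loc[gid].to_numpy())
        rows.append({"probe_id": r.probe_id, "gene_id": gid, "rho": rho, "p": p, "n": n})
    table = pd.DataFrame(rows)
    if table.empty:
        return [], table
    table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    keep = table[(table["rho"] <= rho_max) & (table["q"] <= fdr_q)]
    sites = [
        InformerSite(
            probe_id=r.probe_id, gene_id=r.gene_id, panel_rho=r.rho, q_value=r.q
        )
        for r in keep.itertuples(index=False)
    ]
    return sites, table


def score_informer_sites(
    sites: list[InformerSite], deltas: pd.DataFrame
) -> list[InformerSite]:
    """Attach naive/memory deltas (from differential_methylation) to the set."""
    idx = deltas.set_index("probe_id")
    for s in sites:
        if s.probe_id in idx.index:
            s.delta_beta = float(idx.loc[s.probe_id, "delta_beta"])
            s.delta_expr = float(idx.loc[s.probe_id, "delta_expr"])
    return sites


# ---------------------------------------------------------------------------
# miRNA target repression trend


def bin_mirna_target_trend(
    targets: pd.DataFrame,
    mirna: pd.DataFrame,
    fpkm: pd.DataFrame,
    ibaq: pd.DataFrame,
    n_bins: int = 5,
) -> pd.DataFrame:
    """Mean target abundance per bin of summed targeting-miRNA reads.

    ``targets`` maps gene_id to mirna_id (prediction is an input, not
    computed here). Genes are binned by the summed read counts of the
    miRNAs targeting them; mean log10 iBAQ and log10 FPKM per bin are
    reported with a Spearman trend statistic over the bin means in
    ``df.attrs['trend']``.
    """
    reads = mirna.set_index("mirna_id")["reads"]
    load = (
        targets.assign(reads=targets["mirna_id"].map(reads))
        .groupby("gene_id")["reads"]
        .sum()
        .rename("mirna_reads")
    )
    fpkm_g = fpkm.groupby("gene_id")["fpkm"].max()
    ibaq_g = ibaq.set_index("gene_id")["ibaq"]
    df = pd.concat([load, fpkm_g, ibaq_g], axis=1, join="inner").dropna()
    df["bin"] = pd.qcut(df["mirna_reads"].rank(method="first"), n_bins, labels=False)
    out = (
        df.assign(
            log_fpkm=np.log10(df["fpkm"] + 1e-9),
            log_ibaq=np.log10(df["ibaq"] + 1e-9),
        )
        .groupby("bin")
        .agg(
            mean_mirna_reads=("mirna_reads", "mean"),
            mean_log_fpkm=("log_fpkm", "mean"),
            mean_log_ibaq=("log_ibaq", "mean"),
            n=("fpkm", "size"),
        )
        .reset_index()
    )
    rho_i, _, _ = spearman(out["bin"], out["mean_log_ibaq"])
    rho_f, _, _ = spearman(out["bin"], out["mean_log_fpkm"])
    out.attrs["trend"] = {"ibaq_rho": rho_i, "fpkm_rho": rho_f}
    return out
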