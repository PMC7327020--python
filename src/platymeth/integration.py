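"""Methylation-expression integration and family-level reporting.

The inverse-correlation flag operationalises "CG methylation down while
expression up (or vice versa)" for a gene at one treatment time point: the
gene-level CG methylation change and the expression change must have
strictly opposite signs, the gene must carry at least one CG-DMC at that
time point, and the expression change must pass the treatment screen
(p < 0.01, \\|fold-change\\| >= 1.5).  The screen requirement keeps genes
whose expression merely wobbles out of the list; a Pearson r over the
4-sample time course is reported alongside for transparency but is not used
for flagging (four points make r unstable).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import TIMEPOINT_OF_SAMPLE
from .dmc import DMC_KEY, family_dmc_share, family_ratio_table, top_fraction_genes
from .formats import GeneModel

logger = logging.getLogger(__name__)

REGIONS = ("upstream", "coding")


def summarize_gene_methylation(
    calls_by_sample: Mapping[str, pd.DataFrame],
    genes: Sequence[GeneModel],
    flank: int = 2000,
    context: str = "CG",
) -> pd.DataFrame:
    """Mean methylation per gene x sample x region (upstream / coding).

    Means are unweighted over depth-passing sites of the requested context,
    in percent; regions without usable sites get NaN and n_sites = 0.
    """
    rows = []
    for sample, calls in calls_by_sample.items():
        usable = calls[calls["passes_depth"] & (calls["context"] == context)]
        by_chrom = {
            chrom: grp.sort_values("pos", kind="stable") for chrom, grp in usable.groupby("chrom", observed=True)
        }
        for gene in genes:
            grp = by_chrom.get(gene.chrom)
            for region, interval_region in (("upstream", "upstream"), ("coding", "body")):
                if grp is None:
                    mean, n = np.nan, 0
                else:
                    lo, hi = gene.region_interval(interval_region, flank)
                    pos0 = grp["pos"].to_numpy() - 1
                    a, b = np.searchsorted(pos0, [lo, hi])
                    n = b - a
                    mean = 100.0 * grp["level"].to_numpy()[a:b].mean() if n else np.nan
                rows.append(
                    {
                        "gene_id": gene.gene_id,
                        "family": gene.family,
                        "sample": sample,
                        "region": region,
                        "mean_level_pct": mean,
                        "n_sites": int(n),
                    }
                )
    return pd.DataFrame(rows)


def _gene_meth_deltas(summaries: pd.DataFrame, control: str) -> pd.DataFrame:
    """Per gene x treatment sample x region methylation change vs control (pp)."""
    pivot = summaries.pivot_table(
        index=["gene_id", "family", "region"], columns="sample", values="mean_level_pct"
    )
    frames = []
    for sample in pivot.columns:
        if sample == control:
            continue
        delta = (pivot[sample] - pivot[control]).rename("meth_delta_pp").reset_index()
        delta["sample"] = sample
        frames.append(delta)
    return pd.concat(frames, ignore_index=True)


def flag_inverse_genes(
    summaries: pd.DataFrame,
    mj_de_results: pd.DataFrame,
    dmc_annotations: pd.DataFrame,
    control: str = "CT_12h",
    context: str = "CG",
    require_significant: bool = True,
    fpkm: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Flag genes whose CG methylation and expression move in opposite directions.

    One row per gene x time point with the methylation change (mean over
    upstream+coding region means), the expression log2 fold change, CG-DMC
    support, the flag, and ``both_regions`` (sign opposition holds for the
    upstream and the coding region separately).  When ``fpkm`` is given a
    Pearson r between region-mean methylation and log2(FPKM + 1) across the
    control + treatment samples is reported per gene.
    """
    deltas = _gene_meth_deltas(summaries, control)
    families = summaries[["gene_id", "family"]].drop_duplicates().set_index("gene_id")["family"]

    cg_ann = dmc_annotations[dmc_annotations["context"] == context]
    dmc_counts = (
        cg_ann.drop_duplicates(subset=DMC_KEY + ["timepoint", "gene_id"])
        .groupby(["gene_id", "timepoint"], observed=True)
        .size()
    )

    de = mj_de_results.set_index(["gene", "timepoint"])
    rows = []
    for (gene, sample), grp in deltas.groupby(["gene_id", "sample"], observed=True):
        timepoint = TIMEPOINT_OF_SAMPLE.get(sample, sample)
        if (gene, timepoint) not in de.index:
            continue
        de_row = de.loc[(gene, timepoint)]
        expr_fc = float(de_row["log2_fold_change"])
        region_delta = grp.set_index("region")["meth_delta_pp"]
        meth_delta = float(region_delta.mean())
        n_dmc = int(dmc_counts.get((gene, timepoint), 0))
        opposite = bool(np.sign(meth_delta) * np.sign(expr_fc) == -1.0)
        flagged = opposite and n_dmc >= 1
        if require_significant:
            flagged = flagged and bool(de_row["significant"])
        both_regions = all(
            region in region_delta.index
            and np.isfinite(region_delta[region])
            and np.sign(region_delta[region]) * np.sign(expr_fc) == -1.0
            for region in REGIONS
        )
        rows.append(
            {
                "gene_id": gene,
                "family": families.get(gene, "other"),
                "timepoint": timepoint,
                "meth_delta_pp": meth_delta,
                "expr_log2fc": expr_fc,
                "n_cg_dmcs": n_dmc,
                "de_significant": bool(de_row["significant"]),
                "flagged": flagged,
                "both_regions": bool(both_regions and flagged),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "family",
            "timepoint",
            "meth_delta_pp",
            "expr_log2fc",
            "n_cg_dmcs",
            "de_significant",
            "flagged",
            "both_regions",
        ],
    )
    if fpkm is not None and not out.empty:
        out["pearson_r"] = _timecourse_correlation(summaries, fpkm, control, out["gene_id"])
    return out.sort_values(["family", "gene_id", "timepoint"], ignore_index=True)


def _timecourse_correlation(
    summaries: pd.DataFrame, fpkm: pd.DataFrame, control: str, gene_order: pd.Series
) -> np.ndarray:
    samples = [control] + [s for s in TIMEPOINT_OF_SAMPLE if s in fpkm.columns]
    meth = summaries.pivot_table(index="gene_id", columns="sample", values="mean_level_pct", aggfunc="mean")
    res = []
    for gene in gene_order:
        if gene not in meth.index or gene not in fpkm.index:
            res.append(np.nan)
            continue
        m = meth.loc[gene, samples].to_numpy(dtype=float)
        e = np.log2(fpkm.loc[gene, samples].to_numpy(dtype=float) + 1.0)
        if np.isnan(m).any() or np.std(m) == 0 or np.std(e) == 0:
            res.append(np.nan)
        else:
            res.append(float(np.corrcoef(m, e)[0, 1]))
    return np.array(res)


def build_family_report(
    annotations: pd.DataFrame,
    summaries: pd.DataFrame,
    mj_de_results: pd.DataFrame,
    inverse_calls: pd.DataFrame,
    universe: Sequence[str],
    params: Mapping | None = None,
    outdir: str | Path | None = None,
    top_fraction: float = 0.3,
    pseudocount: float = 0.5,
) -> dict[str, pd.DataFrame]:
    """Assemble the family-level report tables (and optionally write them).

    Tables: ``family_shares`` (DMC share per family over the gene universe),
    ``top_genes`` (top-fraction genes by CG-DMC count, with families),
    ``family_ratios`` (log2 hyper/hypo per family x timepoint x context and
    per region), ``inverse_genes``.  A JSON manifest records every
    parameter when ``outdir`` is given.
    """
    for name, df in (("annotations", annotations), ("summaries", summaries), ("de", mj_de_results)):
        if df is None:
            raise ValueError(f"missing stage output: {name}")

    cg = annotations[annotations["context"] == "CG"]
    counts = (
        cg.drop_duplicates(subset=DMC_KEY + ["timepoint", "gene_id"]).groupby("gene_id", observed=True).size()
    )
    gene_counts = {g: int(counts.get(g, 0)) for g in universe}
    top = top_fraction_genes(gene_counts, top_fraction)
    families = summaries[["gene_id", "family"]].drop_duplicates().set_index("gene_id")["family"]
    tables = {
        "family_shares": family_dmc_share(cg, universe) if len(cg) else pd.DataFrame(
            columns=["family", "n_annotations", "share_pct"]
        ),
        "top_genes": pd.DataFrame(
            {
                "gene_id": top,
                "family": [families.get(g, "other") for g in top],
                "n_cg_dmcs": [gene_counts[g] for g in top],
            }
        ),
        "family_ratios": family_ratio_table(annotations, pseudocount),
        "family_ratios_by_region": family_ratio_table(annotations, pseudocount, by_region=True),
        "inverse_genes": inverse_calls,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        manifest = {
            "tables": sorted(tables),
            "n_universe_genes": len(list(universe)),
            "top_fraction": top_fraction,
            "pseudocount": pseudocount,
            "params": dict(params or {}),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return tables
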