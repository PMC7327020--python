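"""Differentially methylated cytosines (DMCs) between control and treatment.

A cytosine covered by >= ``min_depth`` reads in BOTH samples is a DMC when
the absolute difference of its methylation levels (in percentage points)
meets ``min_delta`` (default 10).  Direction is hyper when the treatment
level is higher, hypo when lower.  This is a pure threshold rule: no further
statistical test is applied to the level difference.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import GeneModel

DMC_KEY = ["chrom", "pos0", "strand", "context"]


def call_dmcs(
    calls_control: pd.DataFrame,
    calls_treatment: pd.DataFrame,
    timepoint: str,
    min_delta: float = 10.0,
    min_depth: int = 5,
) -> pd.DataFrame:
    """Compare two calling tables site by site and return the DMC table.

    Columns: chrom, pos0, strand, context, level_control, level_treatment
    (percent), delta (treatment - control, percentage points), direction,
    timepoint.
    """
    if set(calls_control["chrom"].unique()) != set(calls_treatment["chrom"].unique()):
        raise ValueError("control and treatment were called against different genomes")
    cols = ["chrom", "pos", "strand", "context", "count_m", "count_u", "level"]
    merged = calls_control[cols].merge(
        calls_treatment[cols],
        on=["chrom", "pos", "strand", "context"],
        suffixes=("_c", "_t"),
    )
    depth_c = merged["count_m_c"] + merged["count_u_c"]
    depth_t = merged["count_m_t"] + merged["count_u_t"]
    merged = merged[(depth_c >= min_depth) & (depth_t >= min_depth)]
    delta = (merged["level_t"] - merged["level_c"]) * 100.0
    keep = delta.abs() >= min_delta
    out = pd.DataFrame(
        {
            "chrom": merged.loc[keep, "chrom"],
            "pos0": merged.loc[keep, "pos"] - 1,
            "strand": merged.loc[keep, "strand"],
            "context": merged.loc[keep, "context"],
            "level_control": merged.loc[keep, "level_c"] * 100.0,
            "level_treatment": merged.loc[keep, "level_t"] * 100.0,
            "delta": delta[keep],
            "direction": np.where(delta[keep] > 0, "hyper", "hypo"),
            "timepoint": timepoint,
        }
    ).reset_index(drop=True)
    return out


def dmc_overlap(
    dmcs_12h: pd.DataFrame, dmcs_24h: pd.DataFrame, dmcs_48h: pd.DataFrame
) -> dict:
    """Three-way overlap of DMC sets keyed by (chrom, pos0, strand, context).

    Returns the percentage of the union detected at all three time points
    plus the full 7-category membership breakdown.
    """
    sets = {
        "12h": set(map(tuple, dmcs_12h[DMC_KEY].itertuples(index=False))),
        "24h": set(map(tuple, dmcs_24h[DMC_KEY].itertuples(index=False))),
        "48h": set(map(tuple, dmcs_48h[DMC_KEY].itertuples(index=False))),
    }
    union = sets["12h"] | sets["24h"] | sets["48h"]
    inter = sets["12h"] & sets["24h"] & sets["48h"]
    breakdown = {}
    for key in union:
        members = tuple(tp for tp in ("12h", "24h", "48h") if key in sets[tp])
        label = "_".join(members)
        breakdown[label] = breakdown.get(label, 0) + 1
    return {
        "n_union": len(union),
        "n_all_three": len(inter),
        "pct_all_three": (100.0 * len(inter) / len(union)) if union else float("nan"),
        "breakdown": breakdown,
    }


def annotate_dmcs(
    dmcs: pd.DataFrame, genes: Sequence[GeneModel], flank: int = 2000
) -> pd.DataFrame:
    """Assign DMCs to gene regions (upstream / coding / downstream).

    A DMC hitting several genes yields one annotation row per gene; DMCs
    outside every gene span are absent from the output (they remain in the
    genome-wide DMC table).
    """
    columns = DMC_KEY + ["delta", "direction", "timepoint"]
    chunks = []
    for chrom, grp in dmcs.groupby("chrom", observed=True):
        grp = grp.sort_values("pos0", kind="stable")
        sorted_pos = grp["pos0"].to_numpy()
        for gene in genes:
            if gene.chrom != chrom:
                continue
            for region, interval_region in (
                ("upstream", "upstream"),
                ("coding", "body"),
                ("downstream", "downstream"),
            ):
                lo, hi = gene.region_interval(interval_region, flank)
                a, b = np.searchsorted(sorted_pos, [lo, hi])
                if a == b:
                    continue
                chunk = grp.iloc[a:b][columns].copy()
                chunk["gene_id"] = gene.gene_id
                chunk["region"] = region
                chunk["family"] = gene.family
                chunks.append(chunk)
    out_columns = columns + ["gene_id", "region", "family"]
    if not chunks:
        return pd.DataFrame(columns=out_columns)
    return pd.concat(chunks, ignore_index=True)[out_columns]


def family_dmc_share(
    annotations: pd.DataFrame, universe: Iterable[str]
) -> pd.DataFrame:
    """Percentage of DMC-gene annotations carried by each family.

    ``universe`` is the gene-id set over which shares are computed (default
    choice upstream: all family-labelled genes).  Annotation rows are
    deduplicated per (DMC site, gene) so a site annotated to both upstream
    and coding regions of the same gene counts once.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    ann = annotations[annotations["gene_id"].isin(universe)]
    dedup = ann.drop_duplicates(subset=DMC_KEY + ["timepoint", "gene_id"])
    total = len(dedup)
    rows = []
    for family, grp in dedup.groupby("family", observed=True):
        rows.append(
            {
                "family": family,
                "n_annotations": len(grp),
                "share_pct": (100.0 * len(grp) / total) if total else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["family", "n_annotations", "share_pct"]).sort_values(
        "share_pct", ascending=False, ignore_index=True
    )


def top_fraction_genes(gene_dmc_counts: Mapping[str, int], fraction: float = 0.3) -> list[str]:
    """Genes in the top ``fraction`` by DMC count.

    Ranked by count descending with lexicographic gene-id tie-break; the top
    ceil(fraction * N) genes are returned.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    ranked = sorted(gene_dmc_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    k = math.ceil(fraction * len(ranked))
    return [gene for gene, _ in ranked[:k]]


def hyper_hypo_log2_ratio(n_hyper: int, n_hypo: int, pseudocount: float = 0.5) -> float:
    """log2((n_hyper + c) / (n_hypo + c)); negative means relative hypomethylation."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if n_hyper < 0 or n_hypo < 0:
        raise ValueError("counts must be >= 0")
    num, den = n_hyper + pseudocount, n_hypo + pseudocount
    if num == 0 or den == 0:
        return float("inf") if den == 0 and num > 0 else float("-inf") if num == 0 and den > 0 else float("nan")
    return math.log2(num / den)


def family_ratio_table(
    annotations: pd.DataFrame,
    pseudocount: float = 0.5,
    by_region: bool = False,
) -> pd.DataFrame:
    """Hyper/hypo counts and log2 ratio per family x timepoint x context (x region).

    Annotation rows are deduplicated per (site, gene) within each group so
    the same cytosine does not count twice for one gene.
    """
    keys = ["family", "timepoint", "context"] + (["region"] if by_region else [])
    dedup_cols = DMC_KEY + ["timepoint", "gene_id"] + (["region"] if by_region else [])
    dedup = annotations.drop_duplicates(subset=dedup_cols)
    rows = []
    for key, grp in dedup.groupby(keys, observed=True):
        n_hyper = int((grp["direction"] == "hyper").sum())
        n_hypo = int((grp["direction"] == "hypo").sum())
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row.update(
            n_hyper=n_hyper,
            n_hypo=n_hypo,
            log2_ratio=hyper_hypo_log2_ratio(n_hyper, n_hypo, pseudocount),
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=keys + ["n_hyper", "n_hypo", "log2_ratio"])
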