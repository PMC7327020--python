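"""Expression quantification and screening.

FPKM = counts / ((gene_length / 1e3) * (library_total / 1e6)).  Tissue
specificity is a two-sided Fisher's exact test on a 2x2 fragment-count table
(gene vs all other genes, one tissue vs the rest).  The methyl-jasmonate
screen compares the control library with one treatment library per gene with
the same exact-test construction and applies the joint rule p < 0.01 and
\\|fold-change\\| >= 1.5 (fold change on pseudocounted FPKM).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .calling import bh_fdr

MJ_FC_THRESHOLD = 1.5
MJ_P_THRESHOLD = 0.01


def compute_fpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    sample_totals: pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments.

    ``sample_totals`` defaults to the per-column count sums; a zero total or
    a non-positive gene length is an error.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive length")
    if sample_totals is None:
        sample_totals = counts.sum(axis=0)
    else:
        sample_totals = sample_totals.reindex(counts.columns)
    if (sample_totals <= 0).any() or sample_totals.isna().any():
        raise ValueError("every sample needs a positive total fragment count")
    kb = lengths.to_numpy(dtype=float)[:, None] / 1e3
    millions = sample_totals.to_numpy(dtype=float)[None, :] / 1e6
    return pd.DataFrame(counts.to_numpy(dtype=float) / (kb * millions), index=counts.index, columns=counts.columns)


def _fisher_gene_vs_rest(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Odds ratio and two-sided exact p for the 2x2 table [[a, b], [c, d]]."""
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return odds, p


def tissue_specificity_test(
    counts: pd.DataFrame, gene: str, tissue: str, tissues: list[str] | None = None
) -> dict:
    """Fisher's exact test of one gene's enrichment in one tissue.

    Table: [gene counts in tissue, other-gene counts in tissue; gene counts
    in remaining tissues, other-gene counts in remaining tissues].  A result
    with odds_ratio > 1 indicates higher relative expression in the tissue.
    """
    if tissues is None:
        tissues = list(counts.columns)
    if gene not in counts.index:
        raise KeyError(f"gene {gene!r} absent from the count matrix")
    if tissue not in tissues or len(tissues) < 2:
        raise ValueError("need the target tissue plus at least one other tissue")
    others = [t for t in tissues if t != tissue]
    a = int(counts.at[gene, tissue])
    b = int(counts[tissue].sum()) - a
    c = int(counts.loc[gene, others].sum())
    d = int(counts[others].sum().sum()) - c
    odds, p = _fisher_gene_vs_rest(a, b, c, d)
    return {"gene": gene, "tissue": tissue, "odds_ratio": odds, "p_value": p}


def tissue_specificity_all(counts: pd.DataFrame, tissues: list[str] | None = None) -> pd.DataFrame:
    """Run the tissue test for every gene x tissue; BH q across all tests."""
    if tissues is None:
        tissues = list(counts.columns)
    rows = [
        tissue_specificity_test(counts, gene, tissue, tissues)
        for gene in counts.index
        for tissue in tissues
    ]
    out = pd.DataFrame(rows)
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    return out


def mj_differential_expression(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    control: str,
    treatment: str,
    timepoint: str,
    p_threshold: float = MJ_P_THRESHOLD,
    fc_threshold: float = MJ_FC_THRESHOLD,
) -> pd.DataFrame:
    """Screen genes responding to the MJ treatment at one time point.

    Per gene, a two-sided Fisher's exact test on (gene vs all other genes) x
    (control vs treatment) fragment counts substitutes for an
    isoform-resolved differential test; log2 fold change is computed from
    FPKM with a pseudocount of 1.  ``significant`` applies the joint rule
    p < ``p_threshold`` and \\|fold-change\\| >= ``fc_threshold``.
    """
    for sample in (control, treatment):
        if sample not in counts.columns:
            raise KeyError(f"sample {sample!r} absent from the count matrix")
    fpkm = compute_fpkm(counts[[control, treatment]], gene_lengths)
    log2fc = np.log2((fpkm[treatment] + 1.0) / (fpkm[control] + 1.0))
    total_c = int(counts[control].sum())
    total_t = int(counts[treatment].sum())
    log2_fc_gate = np.log2(fc_threshold)
    rows = []
    for gene in counts.index:
        a = int(counts.at[gene, control])
        b = int(counts.at[gene, treatment])
        _, p = _fisher_gene_vs_rest(a, total_c - a, b, total_t - b)
        fc = float(log2fc[gene])
        rows.append(
            {
                "gene": gene,
                "timepoint": timepoint,
                "log2_fold_change": fc,
                "p_value": p,
                "significant": bool(p < p_threshold and abs(fc) >= log2_fc_gate),
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    return out
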