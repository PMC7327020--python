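"""Metagene methylation profiles: 2-kb upstream, gene body, 2-kb downstream.

Regions are divided into 10 / 50 / 10 bins respectively, ordered 5'->3'
relative to the gene (70 bins total).  Bin means are unweighted averages of
per-site methylation levels over every (gene, site) assignment in the bin: a
site inside the flanks of two genes contributes to both profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import GeneModel


@dataclass(frozen=True)
class MetageneBins:
    """Bin layout; the default 10/50/10 over 2-kb flanks gives 70 bins."""

    upstream: int = 10
    body: int = 50
    downstream: int = 10
    flank_bp: int = 2000

    def __post_init__(self) -> None:
        if min(self.upstream, self.body, self.downstream, self.flank_bp) < 1:
            raise ValueError("bin counts and flank must be >= 1")

    @property
    def total(self) -> int:
        return self.upstream + self.body + self.downstream

    def region_of(self, bin_index: int) -> str:
        if bin_index < self.upstream:
            return "upstream"
        if bin_index < self.upstream + self.body:
            return "body"
        return "downstream"


def assign_bin(gene: GeneModel, pos0: int, bins: MetageneBins = MetageneBins()) -> int | None:
    """Global bin index (0..total-1) of a genomic position, or None outside.

    Offsets are measured 5'->3' along the gene's strand; the fractional
    offset within a region is floored into its bin count, clamping the last
    base of a region into its last bin.
    """
    fwd = gene.strand == "+"
    flank = bins.flank_bp

    def _bin(offset: int, span: int, n_bins: int) -> int:
        return min(int(offset * n_bins // span), n_bins - 1)

    if fwd:
        if gene.start - flank <= pos0 < gene.start:
            return _bin(pos0 - (gene.start - flank), flank, bins.upstream)
        if gene.start <= pos0 < gene.end:
            return bins.upstream + _bin(pos0 - gene.start, gene.length, bins.body)
        if gene.end <= pos0 < gene.end + flank:
            return bins.upstream + bins.body + _bin(pos0 - gene.end, flank, bins.downstream)
        return None
    # - strand: 5' flank is genomically right of the gene end
    if gene.end <= pos0 < gene.end + flank:
        return _bin(gene.end + flank - 1 - pos0, flank, bins.upstream)
    if gene.start <= pos0 < gene.end:
        return bins.upstream + _bin(gene.end - 1 - pos0, gene.length, bins.body)
    if gene.start - flank <= pos0 < gene.start:
        return bins.upstream + bins.body + _bin(gene.start - 1 - pos0, flank, bins.downstream)
    return None


def _assign_bins_vector(gene: GeneModel, pos0: np.ndarray, bins: MetageneBins) -> np.ndarray:
    """Vectorised assign_bin for positions already restricted to the gene span."""
    out = np.full(len(pos0), -1, dtype=np.int64)
    fwd = gene.strand == "+"
    flank = bins.flank_bp

    def _fill(sel: np.ndarray, offset: np.ndarray, span: int, n_bins: int, base: int) -> None:
        out[sel] = base + np.minimum(offset * n_bins // span, n_bins - 1)

    if fwd:
        up = (pos0 >= gene.start - flank) & (pos0 < gene.start)
        _fill(up, pos0[up] - (gene.start - flank), flank, bins.upstream, 0)
        body = (pos0 >= gene.start) & (pos0 < gene.end)
        _fill(body, pos0[body] - gene.start, gene.length, bins.body, bins.upstream)
        down = (pos0 >= gene.end) & (pos0 < gene.end + flank)
        _fill(down, pos0[down] - gene.end, flank, bins.downstream, bins.upstream + bins.body)
    else:
        up = (pos0 >= gene.end) & (pos0 < gene.end + flank)
        _fill(up, gene.end + flank - 1 - pos0[up], flank, bins.upstream, 0)
        body = (pos0 >= gene.start) & (pos0 < gene.end)
        _fill(body, gene.end - 1 - pos0[body], gene.length, bins.body, bins.upstream)
        down = (pos0 >= gene.start - flank) & (pos0 < gene.start)
        _fill(down, gene.start - 1 - pos0[down], flank, bins.downstream, bins.upstream + bins.body)
    return out


def compute_profile(
    calls: pd.DataFrame,
    genes: list[GeneModel],
    gene_set: list[GeneModel] | None = None,
    context: str = "CG",
    bins: MetageneBins = MetageneBins(),
    label: str = "all",
) -> pd.DataFrame:
    """Average methylation profile of a gene set in one context.

    ``calls`` is a per-sample calling table; only depth-passing sites in the
    requested context are used (the methylated/FDR flag is not required — it
    marks significance, not usability of the level estimate).

    Returns a DataFrame with bin_index, region, mean_level, n_sites and the
    gene-set ``label``.
    """
    subset = genes if gene_set is None else gene_set
    if not subset:
        raise ValueError("empty gene set")
    usable = calls[calls["passes_depth"] & (calls["context"] == context)]
    sums = np.zeros(bins.total)
    counts = np.zeros(bins.total, dtype=np.int64)
    for chrom, grp in usable.groupby("chrom", observed=True):
        pos0 = grp["pos"].to_numpy() - 1
        order = np.argsort(pos0, kind="stable")
        pos0 = pos0[order]
        levels = grp["level"].to_numpy()[order]
        for gene in subset:
            if gene.chrom != chrom:
                continue
            lo, hi = gene.start - bins.flank_bp, gene.end + bins.flank_bp
            a, b = np.searchsorted(pos0, [lo, hi])
            if a == b:
                continue
            assigned = _assign_bins_vector(gene, pos0[a:b], bins)
            valid = assigned >= 0
            np.add.at(sums, assigned[valid], levels[a:b][valid])
            np.add.at(counts, assigned[valid], 1)
    mean = np.divide(sums, counts, out=np.full(bins.total, np.nan), where=counts > 0)
    return pd.DataFrame(
        {
            "bin_index": np.arange(bins.total),
            "region": [bins.region_of(i) for i in range(bins.total)],
            "mean_level": mean,
            "n_sites": counts,
            "gene_set": label,
            "context": context,
        }
    )
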