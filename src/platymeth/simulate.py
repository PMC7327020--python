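"""Synthetic genome, methylome and transcriptome generator with known ground truth.

The generator emulates a single-accession WGBS + RNA-seq study design: one
control and three methyl-jasmonate (MJ) time points for the methylome, eight
tissues plus the treatment samples for expression.  Its noise model is

* per-site true methylation drawn from a beta distribution around the
  per-context mean (CG high, CHG mid, CHH low), concentration
  ``site_dispersion``; the per-site draw is shared across samples so that
  between-sample differences reflect only injected effects and read sampling;
* injected family x treatment effects shift the true proportion additively
  (percentage points / 100, clipped to [0, 1]) over upstream and/or body
  spans of every gene in the named family;
* read coverage per site per sample is negative-binomial
  (mean ``coverage_mean``, size ``coverage_dispersion``);
* methylated read counts are binomial with success probability
  ``p_apparent = p_true + (1 - p_true) * non_conversion_rate`` — bisulfite
  non-conversion appears as false methylation of unmethylated molecules;
  sequencing miscalls of methylated molecules are not modelled (error of the
  opposite sign is zero), matching the one-sided binomial null used in
  calling.

Expression is negative-binomial fragment counts around per-gene lognormal
baselines, with injected tissue/treatment log2 effects and an optional signed
``coupling`` that converts each injected methylation shift into an expression
shift of ``coupling * delta_pp / 10`` log2 units for the same genes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ConfigError, SimulationConfig
from .formats import (
    CX_COLUMNS,
    GeneModel,
    write_cx_report,
    write_family_map,
    write_fasta,
    write_gff3,
    write_matrix_tsv,
)

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = (ord(b) for b in "ACGT")
_COMPLEMENT = np.zeros(256, dtype=np.uint8)
for _x, _y in zip(b"ACGTN", b"TGCAN"):
    _COMPLEMENT[_x] = _y


class PlacementError(ValueError):
    """Raised when the genome is too small to place the requested genes."""


@dataclass
class GroundTruth:
    """True per-site methylation, per-gene expression means and injected effects."""

    sites: pd.DataFrame  # chrom, pos0, strand, context
    true_levels: dict[str, np.ndarray]  # sample -> true proportion per site
    effect_genes: pd.DataFrame  # gene_id, family, sample, delta_pp, region
    expression_means: pd.DataFrame | None = None  # gene x sample true means


def _seed_streams(config: SimulationConfig) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(config.seed).spawn(4)
    names = ("genome", "genes", "methylome", "expression")
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def generate_genome(config: SimulationConfig, rng: np.random.Generator | None = None) -> dict[str, str]:
    """Draw i.i.d. bases with P(C) = P(G) = gc_fraction / 2."""
    if rng is None:
        rng = _seed_streams(config)["genome"]
    gc = config.gc_fraction
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome: dict[str, str] = {}
    for i in range(config.n_chromosomes):
        arr = rng.choice(_BASES, size=config.chrom_length_bp, p=probs)
        genome[f"chr{i + 1}"] = arr.tobytes().decode("ascii")
    return genome


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


def generate_gene_models(
    genome: dict[str, str], config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[GeneModel]:
    """Place non-overlapping single-exon genes with >= 2 kb clearance to chromosome ends.

    Family labels follow ``family_spec``; remaining genes are labelled
    ``other``.  Genes are returned in genomic order (chrom, start).
    """
    if rng is None:
        rng = _seed_streams(config)["genes"]
    clearance = max(2000, config.flank_bp)
    chroms = list(genome)
    n_per = np.full(len(chroms), config.n_genes // len(chroms))
    n_per[: config.n_genes % len(chroms)] += 1
    lo, hi = config.gene_length_range

    genes: list[GeneModel] = []
    idx = 0
    for chrom, n in zip(chroms, n_per):
        if n == 0:
            continue
        chrom_len = len(genome[chrom])
        lengths = rng.integers(lo, hi + 1, size=n)
        gap = config.min_intergenic_gap_bp
        available = chrom_len - 2 * clearance
        needed = int(lengths.sum()) + (n - 1) * gap
        if available < needed:
            raise PlacementError(
                f"{chrom}: cannot place {n} genes totalling {lengths.sum()} bp in {available} bp"
            )
        extra = rng.multinomial(available - needed, np.full(n + 1, 1.0 / (n + 1)))
        pos = clearance + int(extra[0])
        for j in range(n):
            start = pos
            end = start + int(lengths[j])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"PGSYN{idx:05d}", chrom, start, end, strand))
            idx += 1
            pos = end + gap + int(extra[j + 1])

    # family labels: a random permutation of genes takes the family blocks
    order = rng.permutation(len(genes))
    labels = {}
    cursor = 0
    for family, count in config.family_spec.items():
        for k in order[cursor : cursor + count]:
            labels[int(k)] = family
        cursor += count
    return [
        GeneModel(g.gene_id, g.chrom, g.start, g.end, g.strand, labels.get(i, "other"))
        for i, g in enumerate(genes)
    ]


# ---------------------------------------------------------------------------
# cytosine enumeration
# ---------------------------------------------------------------------------


def enumerate_cytosines(genome: dict[str, str]) -> pd.DataFrame:
    """Enumerate every strand-specific cytosine with a defined CG/CHG/CHH context.

    Cytosines whose two 3' bases extend past the chromosome end have an
    undefined context and are skipped.  Output is sorted by (chrom, pos0)
    with the + strand record first at positions carrying both.
    """
    frames = []
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        n = len(arr)
        # + strand: C at p with downstream arr[p+1], arr[p+2]
        p_plus = np.nonzero(arr[: max(0, n - 2)] == _C)[0]
        n1, n2 = arr[p_plus + 1], arr[p_plus + 2]
        ctx_plus = np.where(n1 == _G, "CG", np.where(n2 == _G, "CHG", "CHH"))
        tri_plus = _trinucleotides(arr[p_plus], n1, n2)
        # - strand: C is a forward G at p with downstream comp(arr[p-1]), comp(arr[p-2])
        p_minus = np.nonzero(arr[2:] == _G)[0] + 2
        m1, m2 = arr[p_minus - 1], arr[p_minus - 2]
        ctx_minus = np.where(m1 == _C, "CG", np.where(m2 == _C, "CHG", "CHH"))
        tri_minus = _trinucleotides(_COMPLEMENT[arr[p_minus]], _COMPLEMENT[m1], _COMPLEMENT[m2])

        pos0 = np.concatenate([p_plus, p_minus])
        strand = np.concatenate([np.full(len(p_plus), "+"), np.full(len(p_minus), "-")])
        context = np.concatenate([ctx_plus, ctx_minus])
        tri = np.concatenate([tri_plus, tri_minus])
        order = np.argsort(pos0, kind="stable")
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos0": pos0[order].astype(np.int64),
                    "strand": strand[order],
                    "context": context[order],
                    "trinucleotide": tri[order],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos0", "strand", "context", "trinucleotide"])
    return pd.concat(frames, ignore_index=True)


def _trinucleotides(b0: np.ndarray, b1: np.ndarray, b2: np.ndarray) -> np.ndarray:
    stacked = np.stack([b0, b1, b2], axis=1).astype(np.uint8)
    return np.frombuffer(stacked.tobytes(), dtype="S3").astype("U3")


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------


def _region_mask(
    sites: pd.DataFrame, genes: list[GeneModel], family: str, region: str, flank: int
) -> np.ndarray:
    """Boolean mask of sites falling in the given region of any gene of ``family``."""
    mask = np.zeros(len(sites), dtype=bool)
    pos0 = sites["pos0"].to_numpy()
    chrom_arr = sites["chrom"].to_numpy()
    bounds: dict[str, tuple[int, int]] = {}
    start_idx = 0
    for chrom in pd.unique(chrom_arr):
        end_idx = start_idx + int((chrom_arr == chrom).sum())
        bounds[chrom] = (start_idx, end_idx)
        start_idx = end_idx
    regions = ("upstream", "body") if region == "both" else (region,)
    for g in genes:
        if g.family != family or g.chrom not in bounds:
            continue
        i0, i1 = bounds[g.chrom]
        chrom_pos = pos0[i0:i1]
        for r in regions:
            lo, hi = g.region_interval(r, flank)
            a, b = np.searchsorted(chrom_pos, [lo, hi])
            mask[i0 + a : i0 + b] = True
    return mask


def simulate_methylome(
    genome: dict[str, str],
    genes: list[GeneModel],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Simulate per-sample CX reports for every cytosine of the genome.

    Returns ``({sample: cx_dataframe}, GroundTruth)``.  Conservation holds by
    construction: ``count_m + count_u`` equals the drawn coverage at every
    site.
    """
    if rng is None:
        rng = _seed_streams(config)["methylome"]
    known = {g.family for g in genes}
    for eff in config.family_effects:
        if eff.family not in known:
            raise ConfigError(f"family effect names family {eff.family!r} absent from gene models")

    sites = enumerate_cytosines(genome)
    n = len(sites)
    mu = sites["context"].map(config.context_means).to_numpy(dtype=float)

    if np.isinf(config.site_dispersion):
        base = mu.copy()
    else:
        d = config.site_dispersion
        base = np.empty(n)
        interior = (mu > 0) & (mu < 1)
        base[~interior] = mu[~interior]  # degenerate means stay exact
        base[interior] = rng.beta(mu[interior] * d, (1 - mu[interior]) * d)

    deltas: dict[str, np.ndarray] = {s: np.zeros(n) for s in config.samples}
    effect_rows = []
    for eff in config.family_effects:
        mask = _region_mask(sites, genes, eff.family, eff.region, config.flank_bp)
        deltas[eff.sample][mask] += eff.delta_pp / 100.0
        for g in genes:
            if g.family == eff.family:
                effect_rows.append(
                    {
                        "gene_id": g.gene_id,
                        "family": g.family,
                        "sample": eff.sample,
                        "delta_pp": eff.delta_pp,
                        "region": eff.region,
                    }
                )

    eps = config.non_conversion_rate
    k = config.coverage_dispersion
    p_nb = k / (k + config.coverage_mean)
    cx_by_sample: dict[str, pd.DataFrame] = {}
    true_levels: dict[str, np.ndarray] = {}
    for sample in config.samples:
        true = np.clip(base + deltas[sample], 0.0, 1.0)
        true_levels[sample] = true
        coverage = rng.negative_binomial(k, p_nb, size=n)
        apparent = true + (1.0 - true) * eps
        count_m = rng.binomial(coverage, apparent)
        cx = pd.DataFrame(
            {
                "chrom": sites["chrom"],
                "pos": sites["pos0"] + 1,
                "strand": sites["strand"],
                "count_m": count_m,
                "count_u": coverage - count_m,
                "context": sites["context"],
                "trinucleotide": sites["trinucleotide"],
            }
        )
        cx_by_sample[sample] = cx
        logger.info("simulated %s: %d cytosines, mean coverage %.2f", sample, n, coverage.mean())

    truth = GroundTruth(
        sites=sites[["chrom", "pos0", "strand", "context"]].copy(),
        true_levels=true_levels,
        effect_genes=pd.DataFrame(
            effect_rows, columns=["gene_id", "family", "sample", "delta_pp", "region"]
        ),
    )
    return cx_by_sample, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(
    genes: list[GeneModel],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate fragment counts and FPKM for tissues + treatment samples.

    Returns ``(counts, fpkm, true_means)``, all gene x sample DataFrames.
    """
    from .expression import compute_fpkm

    if rng is None:
        rng = _seed_streams(config)["expression"]
    samples = list(config.tissues) + list(config.samples)
    gene_ids = [g.gene_id for g in genes]
    families = np.array([g.family for g in genes])
    n_genes = len(genes)

    if config.expression_baseline_median <= 0:
        baseline = np.zeros(n_genes)
    else:
        baseline = rng.lognormal(np.log(config.expression_baseline_median), config.expression_log_sd, n_genes)

    log2_shift = pd.DataFrame(0.0, index=gene_ids, columns=samples)
    for eff in config.expression_effects:
        if eff.sample not in samples:
            raise ConfigError(f"expression effect names unknown sample {eff.sample!r}")
        log2_shift.loc[families == eff.family, eff.sample] += eff.log2_effect
    if config.coupling != 0.0:
        for eff in config.family_effects:
            log2_shift.loc[families == eff.family, eff.sample] += config.coupling * (eff.delta_pp / 10.0)

    means = baseline[:, None] * np.power(2.0, log2_shift.to_numpy())
    k = config.expression_nb_size
    with np.errstate(divide="ignore"):
        p_nb = k / (k + means)
    counts = rng.negative_binomial(k, p_nb, size=means.shape)
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=samples)
    lengths = pd.Series([g.length for g in genes], index=gene_ids)
    totals = counts_df.sum(axis=0)
    if (totals > 0).all():
        fpkm_df = compute_fpkm(counts_df, lengths)
    else:
        fpkm_df = counts_df.astype(float) * 0.0
    true_means = pd.DataFrame(means, index=gene_ids, columns=samples)
    return counts_df, fpkm_df, true_means


# ---------------------------------------------------------------------------
# full simulation + disk output
# ---------------------------------------------------------------------------


def simulate_study(config: SimulationConfig):
    """Run the full generator: genome, genes, methylome, expression.

    Returns ``(genome, genes, cx_by_sample, truth)`` with
    ``truth.expression_means`` populated.
    """
    streams = _seed_streams(config)
    genome = generate_genome(config, streams["genome"])
    genes = generate_gene_models(genome, config, streams["genes"])
    cx_by_sample, truth = simulate_methylome(genome, genes, config, streams["methylome"])
    counts, fpkm, true_means = simulate_expression(genes, config, streams["expression"])
    truth.expression_means = true_means
    return genome, genes, cx_by_sample, truth, counts, fpkm


def write_simulation(outdir: str | Path, config: SimulationConfig) -> Path:
    """Simulate a study and write every artifact under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes, cx_by_sample, truth, counts, fpkm = simulate_study(config)

    write_fasta(genome, outdir / "genome.fa")
    write_gff3(genes, outdir / "genes.gff3")
    write_family_map(genes, outdir / "families.tsv")
    for sample, cx in cx_by_sample.items():
        write_cx_report(cx, outdir / f"cx_{sample}.txt.gz")
    write_matrix_tsv(counts, outdir / "counts.tsv")
    write_matrix_tsv(fpkm, outdir / "fpkm.tsv")

    levels = truth.sites.copy()
    for sample, arr in truth.true_levels.items():
        levels[sample] = arr
    levels.to_csv(outdir / "true_levels.tsv.gz", sep="\t", index=False)
    truth.expression_means.to_csv(outdir / "true_expression.tsv", sep="\t", index_label="gene_id")
    manifest = {
        "config": config.to_dict(),
        "effect_genes": truth.effect_genes.to_dict(orient="records"),
        "files": {
            "genome": "genome.fa",
            "genes": "genes.gff3",
            "families": "families.tsv",
            "cx_reports": {s: f"cx_{s}.txt.gz" for s in cx_by_sample},
            "counts": "counts.tsv",
            "fpkm": "fpkm.tsv",
            "true_levels": "true_levels.tsv.gz",
            "true_expression": "true_expression.tsv",
        },
    }
    (outdir / "ground_truth.json").write_text(json.dumps(manifest, indent=2))
    return outdir
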