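"""End-to-end orchestration: simulate -> call -> profile -> DMC -> express -> integrate."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import dmc as dmc_mod
from .calling import CallingParams, call_methylome, global_context_means
from .config import TIMEPOINT_OF_SAMPLE, SimulationConfig
from .expression import mj_differential_expression
from .formats import GeneModel
from .integration import build_family_report, flag_inverse_genes, summarize_gene_methylation
from .metagene import MetageneBins, compute_profile
from .simulate import GroundTruth, simulate_study

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything the pipeline computed, keyed the way the report tables need it."""

    config: SimulationConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    truth: GroundTruth
    calls: dict[str, pd.DataFrame]
    context_means: dict[str, pd.DataFrame]
    profiles: pd.DataFrame
    dmcs: dict[str, pd.DataFrame]  # timepoint -> genome-wide DMC table
    annotations: pd.DataFrame  # gene-annotated DMCs, all time points
    counts: pd.DataFrame
    fpkm: pd.DataFrame
    de_results: pd.DataFrame
    summaries: pd.DataFrame
    inverse_calls: pd.DataFrame
    report: dict[str, pd.DataFrame] = field(default_factory=dict)


def run_pipeline(
    config: SimulationConfig,
    calling_params: CallingParams = CallingParams(),
    min_delta: float = 10.0,
    bins: MetageneBins = MetageneBins(),
    control: str = "CT_12h",
    outdir: str | Path | None = None,
    profile_families: tuple[str, ...] | None = None,
) -> PipelineResult:
    """Run the full analysis on one simulated study.

    The gene universe for family shares and the top-fraction ranking is the
    set of family-labelled genes (family != 'other').
    """

    def _stage(name: str, t0: float) -> float:
        t1 = time.perf_counter()
        logger.info("stage %-12s %6.1f s", name, t1 - t0)
        return t1

    t = time.perf_counter()
    genome, genes, cx_by_sample, truth, counts, fpkm = simulate_study(config)
    t = _stage("simulate", t)

    calls = {s: call_methylome(cx, genome, calling_params) for s, cx in cx_by_sample.items()}
    context_means = {s: global_context_means(c) for s, c in calls.items()}
    t = _stage("call", t)

    family_genes = [g for g in genes if g.family != "other"]
    profile_sets: dict[str, list[GeneModel]] = {"all": list(genes)}
    for fam in profile_families or ():
        profile_sets[fam] = [g for g in genes if g.family == fam]
    profile_frames = []
    for sample, c in calls.items():
        for label, subset in profile_sets.items():
            for context in ("CG", "CHG", "CHH"):
                prof = compute_profile(c, genes, subset, context, bins, label)
                prof["sample"] = sample
                profile_frames.append(prof)
    profiles = pd.concat(profile_frames, ignore_index=True)
    t = _stage("profile", t)

    dmcs = {}
    ann_frames = []
    for sample, timepoint in TIMEPOINT_OF_SAMPLE.items():
        if sample not in calls:
            continue
        d = dmc_mod.call_dmcs(calls[control], calls[sample], timepoint, min_delta, calling_params.min_depth)
        dmcs[timepoint] = d
        ann_frames.append(dmc_mod.annotate_dmcs(d, genes, config.flank_bp))
        logger.info("DMCs at %s: %d (%d hypo)", timepoint, len(d), int((d["direction"] == "hypo").sum()))
    annotations = (
        pd.concat(ann_frames, ignore_index=True)
        if ann_frames
        else pd.DataFrame(columns=dmc_mod.DMC_KEY + ["delta", "direction", "timepoint", "gene_id", "region", "family"])
    )
    t = _stage("dmc", t)

    lengths = pd.Series({g.gene_id: g.length for g in genes})
    de_frames = [
        mj_differential_expression(counts, lengths, control, sample, timepoint)
        for sample, timepoint in TIMEPOINT_OF_SAMPLE.items()
        if sample in counts.columns
    ]
    de_results = pd.concat(de_frames, ignore_index=True)
    t = _stage("express", t)

    summaries = summarize_gene_methylation(calls, genes, config.flank_bp)
    inverse_calls = flag_inverse_genes(summaries, de_results, annotations, control, fpkm=fpkm)
    universe = [g.gene_id for g in family_genes]
    report = build_family_report(
        annotations,
        summaries,
        de_results,
        inverse_calls,
        universe,
        params={
            "seed": config.seed,
            "min_depth": calling_params.min_depth,
            "error_rate": calling_params.error_rate,
            "fdr_threshold": calling_params.fdr_threshold,
            "min_delta": min_delta,
        },
        outdir=outdir,
    )
    _stage("integrate", t)

    return PipelineResult(
        config=config,
        genome=genome,
        genes=genes,
        truth=truth,
        calls=calls,
        context_means=context_means,
        profiles=profiles,
        dmcs=dmcs,
        annotations=annotations,
        counts=counts,
        fpkm=fpkm,
        de_results=de_results,
        summaries=summaries,
        inverse_calls=inverse_calls,
        report=report,
    )
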