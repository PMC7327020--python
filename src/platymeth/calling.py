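"""Per-cytosine methylation calling.

The methylation level of a cytosine is ``mC / (mC + umC)``, the fraction of
reads reporting it methylated.  A site is called methylated when its
methylated read count is improbably high under a one-sided binomial null
whose success probability is the bisulfite non-conversion (error) rate;
p-values from all depth-passing cytosines of one sample (all contexts
pooled) are corrected by Benjamini-Hochberg, and sites with q below the FDR
threshold are flagged.  Sites below the read-depth cutoff never enter
testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_A, _C, _G, _T = (ord(b) for b in "ACGT")
_VALID = {_A, _C, _G, _T}


@dataclass(frozen=True)
class CallingParams:
    """Thresholds of the calling step.

    min_depth: minimum reads covering a site for it to be usable (default 5).
    error_rate: binomial null success probability — the apparent methylation
        expected from non-conversion alone (default 0.005).
    fdr_threshold: Benjamini-Hochberg q cutoff for the methylated flag
        (default 0.01).
    """

    min_depth: int = 5
    error_rate: float = 0.005
    fdr_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0.0 < self.error_rate < 1.0:
            raise ValueError("error_rate must be in (0, 1)")
        if not 0.0 < self.fdr_threshold <= 1.0:
            raise ValueError("fdr_threshold must be in (0, 1]")


def classify_context(seq: str, pos0: int, strand: str) -> str:
    """Sequence context (CG/CHG/CHH) of the cytosine at ``pos0`` on ``strand``.

    The context is read from the two bases 3' of the C on its own strand
    (H = A, C or T).  Returns ``"undefined"`` when fewer than two downstream
    bases exist or any involved base is not A/C/G/T.  Raises when the stated
    base is not a cytosine on that strand.
    """
    if not 0 <= pos0 < len(seq):
        raise IndexError(f"position {pos0} out of range for sequence of length {len(seq)}")
    base = seq[pos0].upper()
    if strand == "+":
        if base != "C":
            raise ValueError(f"base at {pos0} on + strand is {base!r}, not C")
        down = seq[pos0 + 1 : pos0 + 3].upper()
        if len(down) < 2 or any(b not in "ACGT" for b in down):
            return "undefined"
        if down[0] == "G":
            return "CG"
        return "CHG" if down[1] == "G" else "CHH"
    if strand == "-":
        if base != "G":
            raise ValueError(f"base at {pos0} on - strand is {base!r} forward, not G (no C on -)")
        if pos0 < 2:
            return "undefined"
        down = seq[pos0 - 2 : pos0].upper()  # forward order: positions pos0-2, pos0-1
        if any(b not in "ACGT" for b in down):
            return "undefined"
        # downstream on the - strand, 5'->3', is forward pos0-1 then pos0-2,
        # complemented; comp(X) == G iff X == C
        if down[1] == "C":
            return "CG"
        return "CHG" if down[0] == "C" else "CHH"
    raise ValueError(f"strand must be + or -, got {strand!r}")


def compute_level(count_m: int, count_u: int) -> float:
    """Methylation level mC / (mC + umC); errors on zero total coverage."""
    total = count_m + count_u
    if total <= 0:
        raise ValueError("methylation level undefined at zero coverage")
    return count_m / total


def binomial_methylation_test(count_m, total, error_rate: float):
    """One-sided upper-tail binomial p-value P(X >= count_m | Binomial(total, error_rate)).

    Exact (incomplete-beta) tail; accepts scalars or arrays.
    """
    if not 0.0 < error_rate < 1.0:
        raise ValueError("error_rate must be in (0, 1)")
    count_m = np.asarray(count_m)
    total = np.asarray(total)
    if np.any(count_m < 0) or np.any(count_m > total) or np.any(total < 1):
        raise ValueError("require 0 <= count_m <= total and total >= 1")
    p = stats.binom.sf(count_m - 1, total, error_rate)
    return float(p) if p.ndim == 0 else p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    return multipletests(p, method="fdr_bh")[1]


def _derive_contexts(genome: dict[str, str], chrom: np.ndarray, pos0: np.ndarray, strand: np.ndarray) -> np.ndarray:
    """Vectorised genome-derived context for arrays of site coordinates."""
    out = np.empty(len(pos0), dtype="U9")
    for name in pd.unique(chrom):
        seq = genome.get(name)
        if seq is None:
            raise KeyError(f"chromosome {name!r} absent from genome")
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        sel = chrom == name
        p = pos0[sel]
        if p.min(initial=0) < 0 or p.max(initial=-1) >= len(arr):
            raise IndexError(f"position out of range on {name}")
        sub = np.empty(int(sel.sum()), dtype="U9")
        plus = strand[sel] == "+"
        # + strand
        pp = p[plus]
        ok = pp <= len(arr) - 3
        ctx = np.full(len(pp), "undefined", dtype="U9")
        n1 = arr[np.minimum(pp + 1, len(arr) - 1)]
        n2 = arr[np.minimum(pp + 2, len(arr) - 1)]
        ctx[ok & (n1 == _G)] = "CG"
        ctx[ok & (n1 != _G) & (n2 == _G)] = "CHG"
        ctx[ok & (n1 != _G) & (n2 != _G)] = "CHH"
        if np.any(arr[pp] != _C):
            raise ValueError(f"{name}: a + strand record does not sit on a C")
        sub[plus] = ctx
        # - strand
        pm = p[~plus]
        ok = pm >= 2
        ctx = np.full(len(pm), "undefined", dtype="U9")
        m1 = arr[np.maximum(pm - 1, 0)]
        m2 = arr[np.maximum(pm - 2, 0)]
        ctx[ok & (m1 == _C)] = "CG"
        ctx[ok & (m1 != _C) & (m2 == _C)] = "CHG"
        ctx[ok & (m1 != _C) & (m2 != _C)] = "CHH"
        if np.any(arr[pm] != _G):
            raise ValueError(f"{name}: a - strand record does not sit on a C (forward G)")
        sub[~plus] = ctx
        out[sel] = sub
    return out


def call_methylome(
    records: pd.DataFrame,
    genome: dict[str, str] | None,
    params: CallingParams = CallingParams(),
) -> pd.DataFrame:
    """Turn one sample's CX records into methylation calls.

    Context is re-derived from the genome when one is supplied; records whose
    reported context disagrees keep the genome-derived context (a warning
    logs the count).  Sites with coverage below ``min_depth`` are flagged
    ``passes_depth = False`` and excluded from the BH pool; the pool spans
    all contexts jointly.

    Returns a DataFrame with columns chrom, pos, strand, context, count_m,
    count_u, level, p_value, q_value, passes_depth, passes_fdr (level is a
    proportion; NaN at zero coverage).
    """
    calls = records[["chrom", "pos", "strand", "count_m", "count_u", "context"]].copy()
    if genome is not None:
        derived = _derive_contexts(
            genome,
            calls["chrom"].to_numpy(),
            calls["pos"].to_numpy() - 1,
            calls["strand"].to_numpy(),
        )
        n_mismatch = int((derived != calls["context"].to_numpy()).sum())
        if n_mismatch:
            logger.warning("%d records had contexts disagreeing with the genome; genome wins", n_mismatch)
        calls["context"] = derived
        calls = calls[calls["context"] != "undefined"].reset_index(drop=True)

    coverage = calls["count_m"] + calls["count_u"]
    calls["level"] = np.where(coverage > 0, calls["count_m"] / coverage.replace(0, 1), np.nan)
    calls["passes_depth"] = coverage >= params.min_depth

    p = np.full(len(calls), np.nan)
    q = np.full(len(calls), np.nan)
    tested = calls["passes_depth"].to_numpy()
    if tested.any():
        p[tested] = binomial_methylation_test(
            calls.loc[tested, "count_m"].to_numpy(),
            coverage[tested].to_numpy(),
            params.error_rate,
        )
        q[tested] = bh_fdr(p[tested])
    calls["p_value"] = p
    calls["q_value"] = q
    calls["passes_fdr"] = calls["passes_depth"] & (calls["q_value"] < params.fdr_threshold)
    return calls


def global_context_means(calls: pd.DataFrame) -> pd.DataFrame:
    """Global mean methylation per context over depth-passing sites, in percent.

    ``weighted_pct`` is the coverage-weighted mean, sum(mC) / sum(mC + umC)
    — the headline value; ``unweighted_pct`` averages per-site levels with
    equal weight.  Contexts with no depth-passing sites are absent.
    """
    usable = calls[calls["passes_depth"]]
    rows = {}
    for ctx, grp in usable.groupby("context", observed=True):
        total = (grp["count_m"] + grp["count_u"]).sum()
        if len(grp) == 0 or total == 0:
            continue
        rows[ctx] = {
            "weighted_pct": 100.0 * grp["count_m"].sum() / total,
            "unweighted_pct": 100.0 * grp["level"].mean(),
            "n_sites": len(grp),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
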