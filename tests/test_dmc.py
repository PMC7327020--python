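import math

import numpy as np
import pandas as pd
import pytest

from platymeth import (
    GeneModel,
    SimulationConfig,
    annotate_dmcs,
    call_dmcs,
    dmc_overlap,
    family_dmc_share,
    generate_genome,
    hyper_hypo_log2_ratio,
    simulate_methylome,
    top_fraction_genes,
)
from platymeth.calling import CallingParams, call_methylome
from platymeth.dmc import DMC_KEY, family_ratio_table


def _calls(rows):
    """(pos, count_m, count_u) tuples -> minimal single-chromosome calling table."""
    df = pd.DataFrame(rows, columns=["pos", "count_m", "count_u"])
    df["chrom"] = "chr1"
    df["strand"] = "+"
    df["context"] = "CG"
    df["level"] = df["count_m"] / (df["count_m"] + df["count_u"]).replace(0, np.nan)
    return df


def brute_force_dmcs(calls_c, calls_t, min_delta=10.0, min_depth=5):
    """Independent site-by-site scan over dictionaries."""
    t = {
        (r.chrom, r.pos, r.strand, r.context): r
        for r in calls_t.itertuples()
    }
    out = set()
    for r in calls_c.itertuples():
        key = (r.chrom, r.pos, r.strand, r.context)
        if key not in t:
            continue
        s = t[key]
        if r.count_m + r.count_u < min_depth or s.count_m + s.count_u < min_depth:
            continue
        delta = (s.level - r.level) * 100.0
        if abs(delta) >= min_delta:
            out.add((key, "hyper" if delta > 0 else "hypo"))
    return out


class TestCallDmcs:
    @pytest.mark.parametrize(
        "ct,mj,expect",
        [
            ((8, 2), (13, 7), ("hypo", -15.0)),  # 80% -> 65%
            ((8, 2), (15, 5), (None, -5.0)),  # |delta| = 5: below threshold
            ((5, 5), (7, 3), ("hyper", 20.0)),  # 50% -> 70%
        ],
    )
    def test_threshold_rule(self, ct, mj, expect):
        dmcs = call_dmcs(_calls([(100, *ct)]), _calls([(100, *mj)]), "12h")
        direction, delta = expect
        if direction is None:
            assert dmcs.empty
        else:
            assert len(dmcs) == 1
            assert dmcs.at[0, "direction"] == direction
            assert dmcs.at[0, "delta"] == pytest.approx(delta)
            assert dmcs.at[0, "pos0"] == 99
            assert dmcs.at[0, "timepoint"] == "12h"

    def test_low_depth_in_either_sample_excludes_site(self):
        dmcs = call_dmcs(_calls([(100, 10, 0)]), _calls([(100, 0, 3)]), "12h")
        assert dmcs.empty

    def test_antisymmetry_swapping_samples_flips_directions(self, small_study):
        genome, _, cx, _ = small_study
        a = call_methylome(cx["CT_12h"], genome)
        b = call_methylome(cx["MJ_12h"], genome)
        fwd = call_dmcs(a, b, "12h")
        rev = call_dmcs(b, a, "12h")
        key_fwd = fwd.set_index(DMC_KEY)["direction"]
        key_rev = rev.set_index(DMC_KEY)["direction"]
        assert len(key_fwd) == len(key_rev)
        flipped = key_rev.map({"hyper": "hypo", "hypo": "hyper"})
        pd.testing.assert_series_equal(key_fwd.sort_index(), flipped.sort_index(), check_names=False)

    def test_matches_brute_force_scan(self):
        cfg = SimulationConfig(
            seed=17, chrom_length_bp=25_000, n_genes=0, family_spec={}, samples=("CT_12h", "MJ_12h")
        )
        genome = generate_genome(cfg)
        cx, _ = simulate_methylome(genome, [], cfg)
        a = call_methylome(cx["CT_12h"], genome)
        b = call_methylome(cx["MJ_12h"], genome)
        assert len(a) <= 10_000
        got = call_dmcs(a, b, "12h")
        got_set = {
            ((r.chrom, r.pos0 + 1, r.strand, r.context), r.direction) for r in got.itertuples()
        }
        assert got_set == brute_force_dmcs(a, b)


class TestOverlap:
    def _df(self, positions):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "pos0": list(positions),
                "strand": "+",
                "context": "CG",
            }
        )

    def test_set_arithmetic(self):
        stats = dmc_overlap(self._df([1, 2, 3]), self._df([2, 3]), self._df([2, 3, 4]))
        assert stats["pct_all_three"] == pytest.approx(50.0)
        assert stats["n_union"] == 4 and stats["n_all_three"] == 2

    def test_identical_sets_give_100(self):
        d = self._df([1, 2])
        assert dmc_overlap(d, d, d)["pct_all_three"] == pytest.approx(100.0)

    def test_disjoint_sets_give_0(self):
        stats = dmc_overlap(self._df([1]), self._df([2]), self._df([3]))
        assert stats["pct_all_three"] == 0.0
        assert stats["breakdown"] == {"12h": 1, "24h": 1, "48h": 1}


GENES = [
    GeneModel("gA", "chr1", 10_000, 12_000, "+", "CYP716"),
    GeneModel("gB", "chr1", 15_000, 16_000, "-", "bAS"),
]


def _dmcs(positions, direction="hypo", timepoint="12h"):
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "pos0": positions,
            "strand": "+",
            "context": "CG",
            "delta": -15.0 if direction == "hypo" else 15.0,
            "direction": direction,
            "timepoint": timepoint,
        }
    )


class TestAnnotate:
    def test_body_midpoint_is_coding(self):
        ann = annotate_dmcs(_dmcs([11_000]), GENES)
        assert ann[["gene_id", "region"]].values.tolist() == [["gA", "coding"]]

    def test_upstream_of_minus_gene_is_genomically_right(self):
        ann = annotate_dmcs(_dmcs([16_500]), GENES)  # 500 bp right of gB end
        assert ann[["gene_id", "region"]].values.tolist() == [["gB", "upstream"]]

    def test_shared_flank_yields_two_annotations(self):
        # 13 500 is in gA's downstream flank (12 000..14 000) and gB's
        # downstream flank for - strand (13 000..15 000)
        ann = annotate_dmcs(_dmcs([13_500]), GENES)
        assert sorted(ann["gene_id"]) == ["gA", "gB"]

    def test_intergenic_dmc_is_dropped_from_annotations(self):
        ann = annotate_dmcs(_dmcs([50_000]), GENES)
        assert ann.empty


class TestFamilyStats:
    def test_single_family_holds_100_percent(self):
        ann = annotate_dmcs(_dmcs([10_100, 11_000]), GENES)
        shares = family_dmc_share(ann, {"gA", "gB"})
        assert shares.set_index("family").at["CYP716", "share_pct"] == pytest.approx(100.0)

    def test_equal_counts_split_50_50(self):
        ann = annotate_dmcs(_dmcs([11_000, 15_500]), GENES)
        shares = family_dmc_share(ann, {"gA", "gB"}).set_index("family")
        assert shares.at["CYP716", "share_pct"] == pytest.approx(50.0)
        assert shares.at["bAS", "share_pct"] == pytest.approx(50.0)

    def test_empty_universe_is_an_error(self):
        with pytest.raises(ValueError):
            family_dmc_share(annotate_dmcs(_dmcs([11_000]), GENES), set())

    def test_ratio_table_counts_and_antisymmetry(self):
        ann = pd.concat(
            [
                annotate_dmcs(_dmcs([11_000, 11_100], "hypo"), GENES),
                annotate_dmcs(_dmcs([11_200], "hyper"), GENES),
            ],
            ignore_index=True,
        )
        table = family_ratio_table(ann, pseudocount=0.5).set_index("family")
        assert table.at["CYP716", "n_hyper"] == 1 and table.at["CYP716", "n_hypo"] == 2
        flipped = ann.copy()
        flipped["direction"] = flipped["direction"].map({"hyper": "hypo", "hypo": "hyper"})
        t2 = family_ratio_table(flipped, pseudocount=0.5).set_index("family")
        assert t2.at["CYP716", "log2_ratio"] == pytest.approx(-table.at["CYP716", "log2_ratio"])


class TestTopFractionAndRatio:
    def test_ceiling_rule(self):
        counts = {f"g{i}": i for i in range(10)}
        top = top_fraction_genes(counts, 0.3)
        assert top == ["g9", "g8", "g7"]

    def test_ties_break_lexicographically(self):
        counts = {"b": 1, "a": 1, "c": 1, "d": 1}
        assert top_fraction_genes(counts, 0.3) == ["a", "b"]

    def test_dominant_gene_always_included(self):
        counts = {"x": 100, **{f"g{i}": 1 for i in range(9)}}
        assert "x" in top_fraction_genes(counts, 0.1)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            top_fraction_genes({"a": 1}, 0.0)

    @pytest.mark.parametrize(
        "h,k,c,expected",
        [(4, 4, 0.5, 0.0), (2, 8, 0.0, -2.0), (0, 5, 0.5, math.log2(0.5 / 5.5))],
    )
    def test_log2_ratio_values(self, h, k, c, expected):
        assert hyper_hypo_log2_ratio(h, k, c) == pytest.approx(expected)

    def test_negative_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            hyper_hypo_log2_ratio(1, 1, -0.1)


class TestNullCalibration:
    def test_identical_truth_yields_symmetric_directions(self):
        # two samples simulated from the same truth: DMCs arise from read
        # sampling only, so hyper and hypo counts are exchangeable
        cfg = SimulationConfig(
            seed=23, chrom_length_bp=200_000, n_genes=0, family_spec={}, samples=("CT_12h", "MJ_12h")
        )
        genome = generate_genome(cfg)
        cx, _ = simulate_methylome(genome, [], cfg)
        a = call_methylome(cx["CT_12h"], genome)
        b = call_methylome(cx["MJ_12h"], genome)
        dmcs = call_dmcs(a, b, "12h")
        n_hyper = int((dmcs["direction"] == "hyper").sum())
        n = len(dmcs)
        assert n > 500  # threshold rule fires freely on sampling noise
        # binomial(n, 1/2) bound at 4 sigma
        assert abs(n_hyper - n / 2) < 4 * math.sqrt(n / 4)
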