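import numpy as np
import pandas as pd
import pytest

from cogsvd.cna_calling import (
    GAIN,
    LOSS,
    NONE,
    GenomicBaseline,
    call_chromosome_or_arm,
    call_probes,
    call_segment,
    compute_baseline,
    filter_segments,
    parse_region,
    probe_directions,
    segment_arraylet,
)

from conftest import make_probes


def alternating(n, a=0.1):
    """Deterministic bounded 'noise': +a, -a alternating (mean 0, std ~ a)."""
    return a * np.where(np.arange(n) % 2 == 0, 1.0, -1.0)


def planted_pattern(a=0.1, shift=3.5, arm_event=True):
    """Toy genome with chr1 gained, chr2p lost (optional), a 50-probe segment
    gained in chr3q; every shift is shift*a against alternating +/-a noise.

    The margins are deterministic, so region-level calls reproduce the
    planted truth exactly. Probe-level truth additionally requires
    ``arm_event=False``: an arm-only event shifts its chromosome's mean far
    enough that the chromosomal rule (correctly) fires on same-signed noise
    probes of the other arm.
    """
    genome = {"chr1": 200, "chr2": 200, "chr3": 500, "chrX": 100}
    probes = make_probes(genome)
    pattern = alternating(len(probes), a)
    chrom = probes["chromosome"].to_numpy()
    arm = probes["arm"].to_numpy()
    pattern[chrom == "chr1"] += shift * a
    if arm_event:
        pattern[(chrom == "chr2") & (arm == "p")] -= shift * a
    # 50-probe segment at the start of chr3q (chr3 probes 250..299)
    chr3_idx = np.flatnonzero(chrom == "chr3")
    seg_rows = chr3_idx[250:300]
    pattern[seg_rows] += shift * a
    seg_start = int(probes["start"].iloc[seg_rows[0]])
    seg_end = int(probes["end"].iloc[seg_rows[-1]]) + 1
    truth_probe = np.zeros(len(probes), dtype=int)
    truth_probe[chrom == "chr1"] = 1
    if arm_event:
        truth_probe[(chrom == "chr2") & (arm == "p")] = -1
    truth_probe[seg_rows] = 1
    return probes, pattern, (seg_start, seg_end), truth_probe


EXCLUDED = ("chr1", "chr2p", "chr3q")


class TestComputeBaseline:
    def test_exclusion_removes_signal(self):
        probes = make_probes({"chr7": 10, "chr1": 10})
        pattern = np.zeros(20)
        pattern[probes["chromosome"] == "chr7"] = 5.0
        pattern[-1] = 0.1  # avoid zero variance
        baseline = compute_baseline(pattern, probes, excluded=("chr7",))
        assert baseline.genomic_mean == pytest.approx(0.01)
        assert "chr7" not in baseline.excluded_regions or True

    def test_constant_pattern_degenerate(self):
        probes = make_probes({"chr1": 10})
        with pytest.raises(ValueError, match="deviation"):
            compute_baseline(np.full(10, 2.0), probes, excluded=())

    def test_hand_computed_two_chromosomes(self):
        probes = make_probes({"chr1": 2, "chr2": 2})
        pattern = np.array([1.0, 2.0, 3.0, 6.0])
        baseline = compute_baseline(pattern, probes, excluded=())
        assert baseline.genomic_mean == pytest.approx(3.0)
        assert baseline.genomic_std == pytest.approx(np.std(pattern, ddof=1))
        assert baseline.per_chromosome["chr1"][0] == pytest.approx(1.5)
        assert baseline.per_chromosome["chr2"][0] == pytest.approx(4.5)

    def test_chrx_excluded_from_genomic_stats(self):
        probes = make_probes({"chr1": 6, "chrX": 6})
        pattern = np.concatenate([alternating(6), np.full(6, 50.0)])
        baseline = compute_baseline(pattern, probes, excluded=())
        assert abs(baseline.genomic_mean) < 1e-12

    def test_unknown_exclusion_skipped_with_warning(self, caplog):
        probes = make_probes({"chr1": 6})
        with caplog.at_level("WARNING"):
            baseline = compute_baseline(alternating(6), probes, excluded=("chr7",))
        assert any("chr7" in r.message for r in caplog.records)
        assert baseline.excluded_regions == ()

    def test_strict_exclusion_raises(self):
        probes = make_probes({"chr1": 6})
        with pytest.raises(ValueError, match="chr7"):
            compute_baseline(
                alternating(6), probes, excluded=("chr7",), strict_excluded=True
            )


def test_parse_region_variants():
    chroms = {"chr1", "chr9"}
    assert parse_region("chr9", chroms) == ("chr9", None)
    assert parse_region("chr9p", chroms) == ("chr9", "p")
    assert parse_region("9q", chroms) == ("chr9", "q")
    with pytest.raises(ValueError):
        parse_region("chr99", chroms)


class TestRegionCalls:
    def make_baseline(self):
        return GenomicBaseline(
            genomic_mean=0.0,
            genomic_std=1.0,
            per_chromosome={"chr1": (0.0, 1.0)},
            excluded_regions=(),
        )

    def test_three_sigma_gain(self):
        probes = make_probes({"chr1": 4})
        call = call_chromosome_or_arm(
            np.full(4, 3.0), probes, self.make_baseline(), "chr1"
        )
        assert call.direction == GAIN and call.rule_fired == "genomic"

    def test_one_sigma_none(self):
        probes = make_probes({"chr1": 4})
        call = call_chromosome_or_arm(
            np.full(4, -1.0), probes, self.make_baseline(), "chr1"
        )
        assert call.direction == NONE

    def test_exact_boundary_is_none(self):
        probes = make_probes({"chr1": 4})
        call = call_chromosome_or_arm(
            np.full(4, -2.0), probes, self.make_baseline(), "chr1"
        )
        assert call.direction == NONE  # strict inequality

    def test_unknown_region_errors(self):
        probes = make_probes({"chr1": 4})
        with pytest.raises(ValueError, match="chr5"):
            call_chromosome_or_arm(
                np.zeros(4), probes, self.make_baseline(), "chr5"
            )


class TestSegmentRules:
    def baseline(self, chrom_mean=0.0, chrom_std=1.0):
        return GenomicBaseline(
            genomic_mean=0.0,
            genomic_std=1.0,
            per_chromosome={"chr1": (chrom_mean, chrom_std)},
            excluded_regions=(),
        )

    def test_genomic_rule(self):
        probes = make_probes({"chr1": 10})
        pattern = np.zeros(10)
        pattern[:4] = 2.5
        call = call_segment(pattern, probes, self.baseline(), "chr1", 0, 3500)
        assert call.direction == GAIN and call.rule_fired == "genomic"

    def test_chromosomal_rule_consistent(self):
        # segment at +0.5 genomic sigma, chromosome mean at -1 so the
        # chromosomal deviation (+1.5 sigma) is consistent with the genomic
        probes = make_probes({"chr1": 10})
        pattern = np.full(10, 0.5)
        call = call_segment(
            pattern, probes, self.baseline(chrom_mean=-1.0), "chr1", 0, 3500
        )
        assert call.direction == GAIN and call.rule_fired == "chromosomal"

    def test_chromosomal_rule_inconsistent_sign(self):
        # above the chromosome mean by 1.5 sigma but below the genomic mean
        probes = make_probes({"chr1": 10})
        pattern = np.full(10, -0.5)
        call = call_segment(
            pattern, probes, self.baseline(chrom_mean=-2.0), "chr1", 0, 3500
        )
        assert call.direction == NONE and call.rule_fired == "none"

    def test_zero_probe_segment_errors(self):
        probes = make_probes({"chr1": 4})
        with pytest.raises(ValueError, match="99000"):
            call_segment(np.zeros(4), probes, self.baseline(), "chr1", 99000, 99500)


def probe_call_oracle(pattern, probes, baseline):
    """Independent literal re-evaluation of the two probe rules."""
    out = []
    for i in range(len(probes)):
        x = float(pattern[i])
        chrom = probes["chromosome"].iloc[i]
        cmean, cstd = baseline.per_chromosome[chrom]
        dg = x - baseline.genomic_mean
        dc = x - cmean
        if abs(dg) > 2 * baseline.genomic_std:
            out.append(1 if dg > 0 else -1)
        elif abs(dc) > cstd and dg != 0 and np.sign(dc) == np.sign(dg):
            out.append(1 if dc > 0 else -1)
        else:
            out.append(0)
    return np.array(out)


class TestProbeCalls:
    def test_matches_independent_oracle(self, rng):
        probes = make_probes({"chr1": 40, "chr2": 40})
        pattern = rng.standard_normal(80)
        baseline = compute_baseline(pattern, probes, excluded=())
        calls = call_probes(pattern, probes, baseline)
        np.testing.assert_array_equal(
            probe_directions(calls), probe_call_oracle(pattern, probes, baseline)
        )

    def test_probe_at_genomic_mean_is_none(self):
        probes = make_probes({"chr1": 6})
        pattern = alternating(6)
        baseline = compute_baseline(pattern, probes, excluded=())
        calls = call_probes(pattern, probes, baseline)
        assert all(c.direction == NONE for c in calls)


class TestPlantedTruth:
    def test_all_resolutions_match_truth(self):
        probes, pattern, (seg_start, seg_end), truth_probe = planted_pattern()
        baseline = compute_baseline(pattern, probes, excluded=EXCLUDED)

        chrom_truth = {"chr1": GAIN, "chr2": NONE, "chr3": NONE, "chrX": NONE}
        for chrom, expected in chrom_truth.items():
            assert call_chromosome_or_arm(
                pattern, probes, baseline, chrom
            ).direction == expected, chrom

        arm_truth = {
            "chr1p": GAIN, "chr1q": GAIN, "chr2p": LOSS, "chr2q": NONE,
            "chr3p": NONE, "chr3q": NONE,
        }
        for arm, expected in arm_truth.items():
            assert call_chromosome_or_arm(
                pattern, probes, baseline, arm
            ).direction == expected, arm

        seg = call_segment(pattern, probes, baseline, "chr3", seg_start, seg_end)
        assert seg.direction == GAIN

    def test_probe_truth_exact_without_arm_event(self):
        probes, pattern, _, truth_probe = planted_pattern(arm_event=False)
        baseline = compute_baseline(pattern, probes, excluded=("chr1", "chr3q"))
        np.testing.assert_array_equal(
            probe_directions(call_probes(pattern, probes, baseline)), truth_probe
        )

    @pytest.mark.parametrize("offset,scale", [(2.7, 1.0), (0.0, 13.0), (-1.1, 0.4)])
    def test_offset_and_scale_invariance(self, offset, scale):
        probes, pattern, (seg_start, seg_end), _ = planted_pattern()
        transformed = scale * pattern + offset

        def all_calls(pat):
            baseline = compute_baseline(pat, probes, excluded=EXCLUDED)
            calls = [
                call_chromosome_or_arm(pat, probes, baseline, region)
                for region in ("chr1", "chr2", "chr3", "chr1p", "chr2p", "chr3q")
            ]
            calls.append(
                call_segment(pat, probes, baseline, "chr3", seg_start, seg_end)
            )
            calls += call_probes(pat, probes, baseline)
            return [c.direction for c in calls]

        assert all_calls(pattern) == all_calls(transformed)


class TestFilterSegments:
    def make_table(self, counts):
        return pd.DataFrame(
            {
                "chromosome": ["chr1"] * len(counts),
                "start": range(len(counts)),
                "end": [x + 10 for x in range(len(counts))],
                "probe_count": counts,
            }
        )

    def test_default_min_five(self):
        assert len(filter_segments(self.make_table([3, 5, 12]))) == 2

    def test_min_one_is_identity(self):
        table = self.make_table([3, 5, 12])
        assert len(filter_segments(table, min_probes=1)) == 3

    def test_empty_table(self):
        assert len(filter_segments(self.make_table([]))) == 0


class TestSegmentation:
    def test_constant_pattern_no_change_points(self):
        probes = make_probes({"chr1": 100})
        assert segment_arraylet(np.zeros(100), probes, n_permutations=100) == []

    def test_planted_step_found(self, rng):
        probes = make_probes({"chr1": 1000})
        pattern = np.concatenate([np.zeros(500), np.ones(500)])
        pattern += 0.1 * rng.standard_normal(1000)
        cps = segment_arraylet(pattern, probes, n_permutations=200, seed=0)
        assert any(abs(cp - 500) <= 2 for cp in cps)

    def test_no_boundary_crossing(self, rng):
        probes = make_probes({"chr1": 200, "chr2": 200})
        pattern = np.concatenate(
            [np.zeros(100), np.ones(100), np.full(100, 2.0), np.full(100, 3.0)]
        )
        pattern += 0.05 * rng.standard_normal(400)
        cps = segment_arraylet(pattern, probes, n_permutations=200, seed=0)
        in_chr1 = [cp for cp in cps if 0 < cp < 200]
        in_chr2 = [cp for cp in cps if 200 < cp < 400]
        assert in_chr1 and in_chr2
        assert 200 not in cps  # chromosome boundary is not a change point
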