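"""Segment filtering, HRD-LOH / LST scar scores and SCNA event extraction."""

import numpy as np
import pandas as pd
import pytest

from brcaness.genome import GenomeModel
from brcaness.scna import (HRDProfile, classify_brca_like, extract_events,
                           filter_segments, hrd_loh_score, hrd_profile,
                           lst_score, percent_genome_altered,
                           recurrent_focal_regions)
from brcaness.simulate import SimulationConfig, generate_segment_profile

from .conftest import random_profile
from .oracles import hrd_loh_oracle, lst_oracle

MB = 1_000_000


def seg(chrom, start, end, total, minor, sample="S1", probes=None):
    return dict(sample=sample, chrom=chrom, start=start, end=end,
                num_probes=probes if probes is not None
                else max(1, (end - start) // 1000),
                total_cn=total, minor_cn=minor)


def make_genome(**lengths):
    return GenomeModel(tuple(lengths), tuple(lengths.values()),
                       np.full(96, 1 / 96))


class TestFilterSegments:
    @pytest.mark.parametrize("length,probes,kept", [
        (40_000, 30, False),   # too short
        (60_000, 20, False),   # too few probes
        (60_000, 21, True),    # boundary: >50 kb with 21 probes passes
        (50_000, 30, False),   # exactly 50 kb is not "larger than 50 kb"
    ])
    def test_boundaries(self, length, probes, kept):
        df = pd.DataFrame([seg("chr1", 0, length, 1, 0, probes=probes)])
        assert (len(filter_segments(df)) == 1) is kept

    def test_diploid_background_always_retained(self):
        df = pd.DataFrame([seg("chr1", 0, 10_000, 2, 1, probes=1)])
        assert len(filter_segments(df)) == 1

    def test_invalid_segment_rejected(self):
        df = pd.DataFrame([seg("chr1", 100, 100, 2, 1)])
        with pytest.raises(ValueError, match="end must exceed"):
            filter_segments(df)


class TestHrdLoh:
    def test_diploid_heterozygous_genome_scores_zero(self, genome):
        df = pd.DataFrame([seg(c, 0, genome.length_of(c), 2, 1)
                           for c in genome.chrom_names])
        assert hrd_loh_score(df, genome) == 0

    def test_single_20mb_copy_neutral_loh_run(self):
        g = make_genome(chr1=100 * MB)
        df = pd.DataFrame([seg("chr1", 0, 40 * MB, 2, 1),
                           seg("chr1", 40 * MB, 60 * MB, 2, 0),
                           seg("chr1", 60 * MB, 100 * MB, 2, 1)])
        assert hrd_loh_score(df, g) == 1

    def test_whole_chromosome_loh_is_not_subchromosomal(self):
        g = make_genome(chr1=100 * MB)
        df = pd.DataFrame([seg("chr1", 0, 100 * MB, 2, 0)])
        assert hrd_loh_score(df, g) == 0

    def test_adjacent_loh_segments_merge_before_counting(self):
        g = make_genome(chr1=100 * MB)
        df = pd.DataFrame([seg("chr1", 0, 40 * MB, 2, 1),
                           seg("chr1", 40 * MB, 50 * MB, 2, 0),
                           seg("chr1", 50 * MB, 60 * MB, 1, 0),
                           seg("chr1", 60 * MB, 100 * MB, 2, 1)])
        assert hrd_loh_score(df, g) == 1  # one 20-Mb merged run, not two

    def test_homozygous_deletion_breaks_the_run(self):
        g = make_genome(chr1=100 * MB)
        df = pd.DataFrame([seg("chr1", 0, 10 * MB, 2, 0),
                           seg("chr1", 10 * MB, 12 * MB, 0, 0),
                           seg("chr1", 12 * MB, 22 * MB, 2, 0),
                           seg("chr1", 22 * MB, 100 * MB, 2, 1)])
        assert hrd_loh_score(df, g) == 0  # two 10-Mb runs, neither > 15 Mb

    def test_agrees_with_simulator_truth(self, genome):
        cfg = SimulationConfig(n_tumors=20, loh_segments=[i % 5 for i in
                                                          range(20)],
                               background_events=4, seed=31)
        sim = generate_segment_profile(cfg, genome)
        for rec in sim.truth.itertuples():
            grp = sim.segments[sim.segments["sample"] == rec.sample]
            assert hrd_loh_score(grp, genome) == rec.hrd_loh


class TestLst:
    def test_single_segment_chromosomes_score_zero(self, genome):
        df = pd.DataFrame([seg(c, 0, genome.length_of(c), 3, 1)
                           for c in genome.chrom_names])
        assert lst_score(df) == 0

    def test_one_qualifying_breakpoint(self):
        df = pd.DataFrame([seg("chr1", 0, 50 * MB, 2, 1),
                           seg("chr1", 50 * MB, 100 * MB, 3, 1)])
        assert lst_score(df) == 1

    def test_small_segment_smoothed_away(self):
        df = pd.DataFrame([seg("chr1", 0, 50 * MB, 2, 1),
                           seg("chr1", 50 * MB, 52 * MB, 5, 1),
                           seg("chr1", 52 * MB, 100 * MB, 2, 1)])
        assert lst_score(df) == 0  # 2-Mb insert vanishes, flanks merge

    def test_short_flank_does_not_qualify(self):
        df = pd.DataFrame([seg("chr1", 0, 8 * MB, 2, 1),
                           seg("chr1", 8 * MB, 100 * MB, 3, 1)])
        assert lst_score(df) == 0

    def test_agrees_with_simulator_truth(self, genome):
        cfg = SimulationConfig(n_tumors=12, lst_breakpoints=[i % 7 for i in
                                                             range(12)],
                               background_events=3, seed=32)
        sim = generate_segment_profile(cfg, genome)
        for rec in sim.truth.itertuples():
            grp = sim.segments[sim.segments["sample"] == rec.sample]
            assert lst_score(grp) == rec.lst


class TestOracleEquivalence:
    def test_scores_match_brute_force_on_random_profiles(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            segs, lengths = random_profile(rng)
            g = GenomeModel(tuple(lengths), tuple(lengths.values()),
                            np.full(96, 1 / 96))
            assert hrd_loh_score(segs, g) == hrd_loh_oracle(segs, lengths)
            assert lst_score(segs) == lst_oracle(segs)

    def test_scores_invariant_under_segment_splitting(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            segs, lengths = random_profile(rng)
            g = GenomeModel(tuple(lengths), tuple(lengths.values()),
                            np.full(96, 1 / 96))
            split_rows = []
            for r in segs.to_dict("records"):
                mid = (r["start"] + r["end"]) // 2
                if mid > r["start"] and rng.random() < 0.5:
                    split_rows.append(dict(r, end=mid))
                    split_rows.append(dict(r, start=mid))
                else:
                    split_rows.append(r)
            split = pd.DataFrame(split_rows)
            assert hrd_loh_score(split, g) == hrd_loh_score(segs, g)

    def test_hrd_monotone_in_planted_loh_runs(self, genome):
        cfg = dict(n_tumors=1, seed=3)
        scores = [
            generate_segment_profile(
                SimulationConfig(loh_segments=k, **cfg), genome).truth
            .loc[0, "hrd_loh"] for k in range(6)
        ]
        assert scores == sorted(scores) == list(range(6))


class TestClassification:
    def test_threshold_boundary_inclusive(self):
        p = classify_brca_like(HRDProfile("s", hrd_loh=15, lst=14,
                                          pct_altered=10.0))
        assert p.brca_like_hrd and not p.brca_like_lst

    def test_zero_scores_not_flagged(self):
        p = classify_brca_like(HRDProfile("s", 0, 0, 0.0))
        assert not p.brca_like_hrd and not p.brca_like_lst

    def test_simulated_high_scar_cohort_flag_fraction(self, genome):
        """80% of tumors planted above both thresholds -> flagged fraction
        within the binomial 95% CI of 0.8."""
        from scipy import stats
        rng = np.random.default_rng(12)
        n = 50
        high = rng.random(n) < 0.8
        loh = [16 if h else 2 for h in high]
        lst = [16 if h else 3 for h in high]
        cfg = SimulationConfig(n_tumors=n, loh_segments=loh,
                               lst_breakpoints=lst, seed=8)
        sim = generate_segment_profile(cfg, genome)
        flagged = 0
        for sample, grp in sim.segments.groupby("sample"):
            p = hrd_profile(grp, str(sample), genome)
            flagged += p.brca_like_hrd and p.brca_like_lst
        lo = stats.binom.ppf(0.025, n, 0.8)
        hi = stats.binom.ppf(0.975, n, 0.8)
        assert lo <= flagged <= hi


class TestPercentAltered:
    def test_diploid_genome_is_zero(self, genome):
        df = pd.DataFrame([seg(c, 0, genome.length_of(c), 2, 1)
                           for c in genome.chrom_names])
        assert percent_genome_altered(df, genome) == 0.0

    def test_one_tenth_altered(self):
        g = make_genome(chr1=500 * MB)
        df = pd.DataFrame([seg("chr1", 0, 50 * MB, 3, 1),
                           seg("chr1", 50 * MB, 500 * MB, 2, 1)])
        assert percent_genome_altered(df, g) == pytest.approx(10.0)

    def test_matches_simulator_truth(self, genome):
        cfg = SimulationConfig(n_tumors=5, loh_segments=2, lst_breakpoints=2,
                               background_events=5, seed=14)
        sim = generate_segment_profile(cfg, genome)
        for rec in sim.truth.itertuples():
            grp = sim.segments[sim.segments["sample"] == rec.sample]
            assert percent_genome_altered(grp, genome) \
                == pytest.approx(rec.pct_altered)


class TestEvents:
    def test_classes_and_focal_flag(self):
        df = pd.DataFrame([
            seg("chr1", 0, 2 * MB, 5, 1),          # amplification
            seg("chr1", 2 * MB, 2_800_000, 3, 1),  # gain, focal (<1 Mb)
            seg("chr1", 3 * MB, 5 * MB, 1, 0),     # deletion
            seg("chr1", 5 * MB, 9 * MB, 2, 1),     # diploid: no event
            seg("chr1", 9 * MB, 12 * MB, 2, 0),    # CN-neutral LOH: no event
        ])
        ev = extract_events(df)
        assert ev["event_class"].tolist() == ["amplification", "gain",
                                              "deletion"]
        assert ev["focal"].tolist() == [False, True, False]

    def test_single_sample_cannot_be_recurrent(self):
        ev = pd.DataFrame([dict(sample="S1", chrom="chr1", start=0,
                                end=500_000, event_class="deletion",
                                focal=True)])
        out = recurrent_focal_regions(ev, cohort_size=10)
        assert out.empty

    def test_threshold_one_requires_every_sample(self):
        ev = pd.DataFrame([
            dict(sample=f"S{i}", chrom="chr1", start=0, end=500_000,
                 event_class="deletion", focal=True) for i in range(3)
        ])
        assert len(recurrent_focal_regions(ev, 3, min_frequency=0.99)) == 1
        assert recurrent_focal_regions(ev, 4, min_frequency=1.0).empty

    def test_planted_recurrent_deletion_recovered(self, genome):
        from brcaness.simulate import RecurrentLocus
        locus = RecurrentLocus("chr2", 30 * MB, 30_500_000, "deletion", 0.4)
        cfg = SimulationConfig(n_tumors=50, recurrent_loci=(locus,), seed=6)
        sim = generate_segment_profile(cfg, genome)
        ev = extract_events(filter_segments(sim.segments))
        out = recurrent_focal_regions(ev, cohort_size=50)
        hit = out[(out["chrom"] == "chr2") & (out["side"] == "loss")]
        assert len(hit) == 1
        assert hit["start"].iloc[0] == 30 * MB
        assert hit["frequency"].iloc[0] > 0.15
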