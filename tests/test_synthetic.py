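import numpy as np
import pytest

from conftest import PLANT, make_planted
from mtcpg.errors import CoordinateError, ParameterError
from mtcpg.islands import find_islands
from mtcpg.seqio import Interval
from mtcpg.synthetic import (IslandSpec, SynthSpec, empirical_stats,
                             generate_background, generate_feature_layout,
                             generate_genome, plant_islands,
                             stationary_pi, transition_matrix)


class TestTransitionMatrix:
    @pytest.mark.parametrize("gc,oe", [(0.40, 0.25), (0.44, 1.0),
                                       (0.62, 1.4), (0.30, 0.0)])
    def test_rows_sum_to_one_and_pi_is_stationary(self, gc, oe):
        T = transition_matrix(gc, oe)
        pi = stationary_pi(gc)
        assert np.allclose(T.sum(axis=1), 1.0)
        assert np.allclose(pi @ T, pi)
        # C->G transition encodes the obs/exp target
        assert T[1, 2] == pytest.approx(oe * gc / 2)

    def test_infeasible_combination_rejected(self):
        with pytest.raises(ParameterError):
            transition_matrix(0.9, 2.5)


class TestGenerateBackground:
    def test_deterministic_under_seed(self):
        spec = SynthSpec(length=2000, seed=42)
        assert generate_background(spec).sequence == \
            generate_background(spec).sequence

    def test_different_seeds_differ(self):
        a = generate_background(SynthSpec(length=2000, seed=1))
        b = generate_background(SynthSpec(length=2000, seed=2))
        assert a.sequence != b.sequence

    def test_single_genome_hits_targets(self):
        g = generate_background(SynthSpec(length=16500, seed=1))
        gc, oe = empirical_stats(g)
        assert gc == pytest.approx(0.40, abs=0.02)
        assert oe == pytest.approx(0.25, abs=0.05)

    def test_zero_obs_exp_forces_no_cpg(self):
        g = generate_background(SynthSpec(
            length=5000, background_obs_exp=0.0, seed=5))
        assert "CG" not in g.sequence

    def test_statistical_fidelity_over_seeds(self):
        # mean over 50 seeds: GC within +-0.01, obs/exp within +-0.03
        stats = [empirical_stats(generate_background(
            SynthSpec(length=16500, seed=s))) for s in range(50)]
        gcs, oes = zip(*stats)
        assert np.mean(gcs) == pytest.approx(0.40, abs=0.01)
        assert np.mean(oes) == pytest.approx(0.25, abs=0.03)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ParameterError):
            SynthSpec(background_gc=0.0)
        with pytest.raises(ParameterError):
            SynthSpec(background_obs_exp=-1.0)


class TestPlantIslands:
    def test_overlapping_islands_rejected(self):
        with pytest.raises(CoordinateError):
            SynthSpec(length=5000, islands=(
                IslandSpec(position=100, length=300),
                IslandSpec(position=350, length=300)))

    def test_island_outside_genome_rejected(self):
        with pytest.raises(CoordinateError):
            SynthSpec(length=1000, islands=(
                IslandSpec(position=900, length=300),))

    def test_truth_matches_plant_and_background_untouched(self):
        spec = SynthSpec(length=4000, seed=9, islands=(
            IslandSpec(position=2001, length=400, gc=0.62, obs_exp=1.4),))
        bg = generate_background(spec)
        genome, truth = plant_islands(bg, spec)
        assert truth.islands == (Interval(2001, 2400),)
        assert truth.seed == 9
        assert genome.sequence[:2000] == bg.sequence[:2000]
        assert genome.sequence[2400:] == bg.sequence[2400:]
        sub = genome.sequence[2000:2400]
        assert (sub.count("C") + sub.count("G")) / 400 > 0.5

    def test_zero_islands_detector_finds_nothing(self):
        genome, truth = generate_genome(SynthSpec(length=8000, seed=13))
        assert truth.islands == ()
        assert find_islands(genome) == []

    def test_pipeline_recovery_recall_and_precision(self):
        # the end-to-end invariant: islands planted well inside the
        # detectable regime are all found and nothing else is
        n_truth = n_hit = n_called = n_matched = 0
        for seed in range(20):
            genome, truth = make_planted(seed)
            called = find_islands(genome)
            n_called += len(called)
            for t in truth.islands:
                n_truth += 1
                if any(c.interval.start <= t.end and c.interval.end >= t.start
                       for c in called):
                    n_hit += 1
            n_matched += sum(
                1 for c in called
                if any(c.interval.start <= t.end and c.interval.end >= t.start
                       for t in truth.islands))
        assert n_hit == n_truth  # recall 1.0
        assert n_matched / n_called >= 0.9  # precision


class TestFeatureLayout:
    def test_canonical_layout_nonoverlapping(self):
        spec = SynthSpec(length=16500, seed=0)
        ft = generate_feature_layout(spec)
        names = [f.name for f in ft]
        assert names[0] == "TRNF" and "D-LOOP" in names
        assert len([f for f in ft if f.kind == "tRNA"]) == 22
        assert len([f for f in ft if f.kind == "protein_gene"]) == 13
        assert len([f for f in ft if f.kind == "rRNA"]) == 2
        spans = sorted(s for f in ft for s in f.spans(spec.length))
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2  # non-overlapping

    def test_circular_layout_wraps_dloop(self):
        ft = generate_feature_layout(SynthSpec(length=16500, topology="circular"))
        dloop = [f for f in ft if f.name == "D-LOOP"][0]
        assert dloop.wraps_origin
        assert len(dloop.spans(16500)) == 2

    def test_too_short_genome_rejected(self):
        with pytest.raises(ParameterError):
            generate_feature_layout(SynthSpec(length=10000))

    def test_island_inside_nd5_classified_single_feature(self):
        spec = SynthSpec(length=16500, seed=2, islands=(
            IslandSpec(position=12000, length=600, **{
                k: v for k, v in PLANT.items() if k != "length"}),))
        genome, truth = generate_genome(spec)
        ft = generate_feature_layout(spec)
        nd5 = [f for f in ft if f.name == "ND5"][0]
        (t,) = truth.islands
        assert nd5.start <= t.start and t.end <= nd5.end
        from mtcpg.annotate import classify_regions
        from mtcpg.cpgseek import seek_regions, SeekParams
        regions = [r for r in seek_regions(genome, SeekParams(threshold=100))
                   if r.interval.start >= t.start - 50
                   and r.interval.end <= t.end + 50]
        assert regions, "planted island should contain a high-scoring region"
        anns = classify_regions(regions, ft)
        assert {a.classification for a in anns} == {"single_feature"}
        assert all(a.features == ("ND5",) for a in anns)
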