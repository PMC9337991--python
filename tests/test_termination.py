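"""Radiolabel correction factors and termination-fraction equations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riboquant import (
    LabelingScheme,
    NoiseModel,
    TerminationLane,
    correction_factor,
    percent_termination_single,
    quantify_lane,
    readthrough_series,
    relative_radioactivity,
    simulate_transcription,
    tandem_fractions,
)
from riboquant.constructs import TranscriptSpecies

SINGLE = LabelingScheme.preset("single-2022")
TANDEM = LabelingScheme.preset("tandem-2022")

positive = st.floats(0.01, 1e6, allow_nan=False)


class TestLabelingScheme:
    def test_presets_carry_the_published_fractions(self):
        assert (SINGLE.f_init, SINGLE.f_elong) == (0.07, 0.002)
        assert (TANDEM.f_init, TANDEM.f_elong) == (0.03, 0.004)

    def test_elongation_hotter_than_initiation_rejected(self):
        with pytest.raises(ValueError):
            LabelingScheme(0.002, 0.07)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="preset"):
            LabelingScheme.preset("nope")


class TestRelativeRadioactivity:
    def test_direct_arithmetic(self):
        sp = TranscriptSpecies("T", 50, u_init=5, u_elong=10)
        assert relative_radioactivity(sp, SINGLE) == pytest.approx(0.37)

    def test_no_elongation_u(self):
        sp = TranscriptSpecies("T", 50, u_init=5, u_elong=0)
        assert relative_radioactivity(sp, SINGLE) == pytest.approx(0.35)

    def test_unlabelable_species_is_zero(self):
        sp = TranscriptSpecies("T", 50, u_init=0, u_elong=0)
        assert relative_radioactivity(sp, SINGLE) == 0.0


class TestCorrectionFactor:
    def test_plug_in(self):
        assert correction_factor(0.37, 0.43) == pytest.approx(0.37 / 0.43)

    def test_identical_composition_gives_unity(self):
        assert correction_factor(0.4, 0.4) == 1.0

    def test_inverted_composition_exceeds_unity(self):
        assert correction_factor(0.5, 0.4) > 1.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            correction_factor(0.4, 0.0)


class TestPercentTerminationSingle:
    def test_equal_bands_no_correction(self):
        assert percent_termination_single(100, 100, 1.0) == pytest.approx(50.0)

    def test_plug_in(self):
        assert percent_termination_single(500, 500, 0.8605) == pytest.approx(
            100 * 500 / (500 + 500 * 0.8605)
        )
        assert percent_termination_single(500, 500, 0.8605) == pytest.approx(
            53.75, abs=0.005
        )

    def test_no_full_length_is_total_termination(self):
        assert percent_termination_single(42, 0, 0.9) == 100.0

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            percent_termination_single(0, 0, 1.0)


class TestTandemFractions:
    def test_equal_r_corrections_vanish(self):
        res = tandem_fractions(20, 76, 4, 1.0, 1.0, 1.0)
        assert res.fractions == pytest.approx(
            {"T1": 0.20, "T2": 0.76, "FL": 0.04}
        )

    def test_no_t1_band_full_readthrough(self):
        res = tandem_fractions(0, 50, 50, 0.3, 0.6, 0.9)
        assert res.readthrough["T1"] == 1.0

    def test_fractions_sum_exactly_to_one(self):
        res = tandem_fractions(13, 7, 29, 0.31, 0.55, 0.92)
        assert sum(res.fractions.values()) == 1.0

    @given(
        i=st.tuples(positive, positive, positive),
        r=st.tuples(positive, positive, positive),
    )
    @settings(max_examples=200, deadline=None)
    def test_sequential_equals_corrected_count_normalization(self, i, r):
        """The paper-style sequential formulas agree with normalizing the
        corrected counts I_s / R_s (algebraic identity, checked against an
        inline independent computation)."""
        res = tandem_fractions(*i, *r)
        corrected = np.array(i) / np.array(r)
        expected = corrected / corrected.sum()
        got = [res.fractions[k] for k in ("T1", "T2", "FL")]
        assert np.allclose(got, expected, rtol=1e-9)

    @given(
        i=st.tuples(positive, positive, positive),
        r=st.tuples(positive, positive, positive),
        c=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, i, r, c):
        a = tandem_fractions(*i, *r)
        b = tandem_fractions(*(c * x for x in i), *r)
        assert a.fractions == pytest.approx(b.fractions, rel=1e-9)

    def test_all_zero_bands_rejected(self):
        with pytest.raises(ValueError):
            tandem_fractions(0, 0, 0, 0.3, 0.6, 0.9)


class TestQuantifyLane:
    def test_single_construct_round_trip(self, single_construct):
        species = single_construct.species()
        lane, counts = simulate_transcription(
            species, (0.4,), 20_000, SINGLE, noise=NoiseModel(cv=0.0, seed=3)
        )
        res = quantify_lane(lane, species, SINGLE)
        assert res.fractions["T"] == pytest.approx(counts["T"] / 20_000)

    def test_tandem_noisy_round_trip_within_three_se(self, tandem_construct):
        """cv 0.10 band noise: recovered T1 fraction stays within 3 standard
        errors of the generating probability over 100 seeds."""
        species = tandem_construct.species()
        n, p1, p2 = 10_000, 0.8, 0.05
        recovered = []
        for seed in range(100):
            lane, _ = simulate_transcription(
                species, (p1, p2), n, TANDEM,
                noise=NoiseModel(cv=0.10, seed=seed),
            )
            recovered.append(quantify_lane(lane, species, TANDEM).fractions["T1"])
        se = np.std(recovered, ddof=1) / 10  # sqrt(100) replicates
        assert abs(np.mean(recovered) - (1 - p1)) < 3 * se + 1e-3

    def test_missing_species_band_named(self, tandem_construct):
        species = tandem_construct.species()
        lane = TerminationLane("x", {"T1": 10.0, "FL": 5.0})
        with pytest.raises(ValueError, match="T2"):
            quantify_lane(lane, species, TANDEM)


class TestReadthroughSeries:
    def test_replicates_and_condition_mean(self, single_construct):
        species = single_construct.species()
        lanes = []
        for rep in range(3):
            lane, _ = simulate_transcription(
                species, (0.6,), 5_000, SINGLE,
                noise=NoiseModel(cv=0.1, seed=rep), condition="20 mM Na+",
                lane_id=f"rep{rep}",
            )
            lanes.append(lane)
        per_lane, per_cond = readthrough_series(lanes, species, SINGLE)
        assert len(per_lane) == 3 and len(per_cond) == 1
        assert per_cond.loc[0, "fraction_FL"] == pytest.approx(
            per_lane["fraction_FL"].mean()
        )

    def test_single_lane_mean_equals_point(self, single_construct):
        species = single_construct.species()
        lane, _ = simulate_transcription(species, (0.6,), 5_000, SINGLE)
        per_lane, per_cond = readthrough_series([lane], species, SINGLE)
        assert per_cond.loc[0, "fraction_T"] == per_lane.loc[0, "fraction_T"]

    def test_mixed_constructs_rejected(self, single_construct):
        species = single_construct.species()
        lanes = [
            TerminationLane("a", {"T": 1.0, "FL": 1.0}, construct="c1"),
            TerminationLane("b", {"T": 1.0, "FL": 1.0}, construct="c2"),
        ]
        with pytest.raises(ValueError, match="mix"):
            readthrough_series(lanes, species, SINGLE)
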