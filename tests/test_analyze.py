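"""Per-fibre analysis: matching, calibration, gating, counting, distances."""

import numpy as np
import pytest

from rnu2comb.analyze import (
    analyze_fibre,
    calibrate_stretch,
    count_repeats,
    match_barcode,
    measure_distances,
)
from rnu2comb.errors import CalibrationError, GatingError
from rnu2comb.locus import build_haplotype
from rnu2comb.simulate import (
    CohortConfig,
    Fibre,
    Signal,
    reverse_fibre,
    simulate_cohort,
    simulate_fibre,
    zero_noise,
)
from tests.conftest import make_config


def _drop_element(fibre, element_id):
    sigs = [s for s in fibre.signals
            if not (s.truth_source or "").startswith(element_id)]
    return Fibre(fibre.fibre_id, fibre.individual_id, sigs, fibre.truth)


class TestMatchBarcode:
    def test_zero_noise_full_span_matches_everything(self, clean_fibre_factory, lmap):
        fibre, _ = clean_fibre_factory(n=19, region="full")
        call = match_barcode(fibre, lmap)
        assert call.orientation == "+"
        for eid in [f"GMC{k:02d}" for k in range(1, 18)] + ["FP1", "FP2",
                                                            "FP3", "FP4"]:
            assert eid in call.matched_elements
        assert call.integrity == "full"
        assert call.status == "countable"

    def test_reversed_fibre_same_matches_minus_orientation(
            self, clean_fibre_factory, lmap):
        fibre, _ = clean_fibre_factory(n=19, region="full")
        fwd = match_barcode(fibre, lmap)
        rev = match_barcode(reverse_fibre(fibre), lmap)
        assert rev.orientation == "-"
        assert set(rev.matched_elements) == set(fwd.matched_elements)

    def test_fp3_dropout_gives_centromeric_only(self, clean_fibre_factory, lmap):
        fibre, _ = clean_fibre_factory(n=19, region="full")
        call = match_barcode(_drop_element(fibre, "FP3"), lmap)
        assert "FP3" not in call.matched_elements
        assert call.integrity == "centromeric_only"
        assert call.status == "measurable_only"

    def test_empty_fibre_unusable(self, lmap):
        call = match_barcode(Fibre("f", "i", []), lmap)
        assert call.status == "unusable"
        assert call.orientation == "unknown"


class TestCalibration:
    def test_nominal_stretch_recovered_from_64_um(self, clean_fibre_factory, lmap):
        # 128-kb motif at 2 kb/µm spans exactly 64 µm
        fibre, _ = clean_fibre_factory(n=19, region="calibration", stretch=2.0)
        call = match_barcode(fibre, lmap)
        m0 = call.matched_bars[(lmap.motif_start_element, 0)][0]
        last = len(lmap.element(lmap.motif_end_element).bars) - 1
        m1 = call.matched_bars[(lmap.motif_end_element, last)][0]
        assert m1[1] - m0[0] == pytest.approx(64.0, abs=1e-9)
        assert calibrate_stretch(call, lmap) == pytest.approx(2.0, abs=1e-9)

    def test_4dp_arithmetic(self, clean_fibre_factory, lmap):
        # motif measured at 58.18 µm -> 128/58.18 = 2.2001 kb/µm (4 dp)
        fibre, _ = clean_fibre_factory(n=19, region="calibration",
                                       stretch=128.0 / 58.18)
        call = match_barcode(fibre, lmap)
        assert round(calibrate_stretch(call, lmap), 4) == 2.2001

    def test_true_stretch_recovered_exactly_without_jitter(
            self, clean_fibre_factory, lmap):
        fibre, _ = clean_fibre_factory(n=19, region="calibration", stretch=1.9)
        call = match_barcode(fibre, lmap)
        assert calibrate_stretch(call, lmap) == pytest.approx(1.9, rel=1e-9)

    def test_unavailable_without_motif(self, clean_fibre_factory, lmap):
        fibre, _ = clean_fibre_factory(n=19, region="flanks", length_kb=160)
        call = match_barcode(fibre, lmap)
        with pytest.raises(CalibrationError):
            calibrate_stretch(call, lmap)


class TestCountRepeats:
    def test_zero_noise_count(self, clean_fibre_factory, lmap):
        fibre, _ = clean_fibre_factory(n=19, region="flanks", length_kb=400)
        call = match_barcode(fibre, lmap)
        assert count_repeats(call, fibre, lmap) == 19

    def test_pseudogene_in_window_does_not_change_count(
            self, clean_fibre_factory, lmap):
        short, _ = clean_fibre_factory(n=8, region="flanks", length_kb=120)
        full, _ = clean_fibre_factory(n=8, region="full")
        c1 = count_repeats(match_barcode(short, lmap), short, lmap)
        c2 = count_repeats(match_barcode(full, lmap), full, lmap)
        assert c1 == c2 == 8

    def test_split_detection_merges(self, clean_fibre_factory, lmap):
        fibre, _ = clean_fibre_factory(n=10, region="flanks", length_kb=300)
        # split one array signal into two detections 0.5 kb (0.25 µm) apart
        sigs = list(fibre.signals)
        k = next(i for i, s in enumerate(sigs)
                 if (s.truth_source or "").startswith("unit[3]"))
        s = sigs[k]
        mid = (s.start_um + s.end_um) / 2
        sigs[k:k + 1] = [Signal(s.channel, s.start_um, mid - 0.125, s.truth_source),
                         Signal(s.channel, mid + 0.125, s.end_um, s.truth_source)]
        split = Fibre(fibre.fibre_id, fibre.individual_id, sigs, fibre.truth)
        assert count_repeats(match_barcode(split, lmap), split, lmap) == 10

    def test_dropped_unit_imputed_from_gap(self, clean_fibre_factory, lmap):
        fibre, _ = clean_fibre_factory(n=15, region="flanks", length_kb=300)
        dropped = _drop_element(fibre, "unit[7]")
        assert count_repeats(match_barcode(dropped, lmap), dropped, lmap) == 15

    def test_gating_error_without_full_integrity(self, clean_fibre_factory, lmap):
        fibre, _ = clean_fibre_factory(n=19, region="full")
        call = match_barcode(_drop_element(fibre, "FP1"), lmap)
        with pytest.raises(GatingError):
            count_repeats(call, fibre, lmap)

    def test_no_count_emitted_without_all_flanks(self, lmap):
        # gating soundness on noisy fibres: a repeat count implies that all
        # four flanking probes were matched
        cfg = CohortConfig(n_individuals=3, genotypes=[(6, 19), (14, 28), (9, 23)],
                           fibres_per_individual=15, seed=21)
        ds = simulate_cohort(cfg)
        seen = 0
        for f in ds.fibres:
            call = analyze_fibre(f, lmap)
            if call.repeat_count is not None:
                seen += 1
                assert call.integrity == "full"
                assert all(fp in call.matched_elements
                           for fp in ("FP1", "FP2", "FP3", "FP4"))
        assert seen > 0


class TestDistances:
    def test_zero_noise_brca1_distance_exact(self, clean_fibre_factory, lmap):
        fibre, _ = clean_fibre_factory(n=19, region="full")
        call = analyze_fibre(fibre, lmap)
        assert call.distances["brca1_to_array_kb"] == pytest.approx(123.7,
                                                                    abs=1e-6)

    def test_zero_noise_signal_and_gap_lengths(self, clean_fibre_factory, lmap):
        fibre, _ = clean_fibre_factory(n=19, region="full")
        call = analyze_fibre(fibre, lmap)
        assert call.distances["signal_lengths_kb"] == pytest.approx(
            [2.393] * 19, abs=1e-6)
        assert call.distances["gap_lengths_kb"] == pytest.approx(
            [3.739] * 18, abs=1e-6)

    @pytest.mark.parametrize("stretch", [1.85, 2.0, 2.15])
    def test_calibration_makes_distances_stretch_invariant(
            self, clean_fibre_factory, lmap, stretch):
        fibre, _ = clean_fibre_factory(n=19, region="full", stretch=stretch)
        call = analyze_fibre(fibre, lmap)
        assert call.stretch_estimate == pytest.approx(stretch, rel=1e-9)
        assert call.distances["brca1_to_array_kb"] == pytest.approx(123.7,
                                                                    abs=1e-6)

    def test_anchor_missing_distance_omitted(self, clean_fibre_factory, lmap):
        fibre, _ = clean_fibre_factory(n=19, region="flanks", length_kb=160)
        call = analyze_fibre(fibre, lmap)
        assert "brca1_to_array_kb" not in call.distances


class TestOrientationInvariance:
    def test_noisy_fibre_outputs_invariant_under_reversal(self, lmap):
        hap = build_haplotype(lmap, 22)
        cfg = CohortConfig(orientation_prob=0.0)
        for k in range(10):
            rng = np.random.default_rng([31, k])
            fibre = simulate_fibre(hap, cfg, rng, require_region="full")
            fwd = analyze_fibre(fibre, lmap)
            rev = analyze_fibre(reverse_fibre(fibre), lmap)
            assert set(rev.matched_elements) == set(fwd.matched_elements)
            assert rev.integrity == fwd.integrity
            assert rev.repeat_count == fwd.repeat_count
            if fwd.stretch_estimate:
                assert rev.stretch_estimate == pytest.approx(
                    fwd.stretch_estimate, rel=1e-6)
            for key in ("brca1_to_array_kb",):
                if key in fwd.distances:
                    assert rev.distances[key] == pytest.approx(
                        fwd.distances[key], abs=1e-6)
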