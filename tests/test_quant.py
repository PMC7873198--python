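"""Per-cell scoring rules: top-k statistic, autofluorescence exclusion,
ratio normalization, percentile summaries, positive-fraction calls."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tissuedyn import (
    NucleusMask,
    calibrate_cutoff,
    dapi_normalize,
    flag_autofluorescent,
    fraction_positive,
    fraction_positive_comparison,
    generate_tissue_image,
    match_labels,
    normalize_cells,
    quantify_cells,
    ratio_normalize,
    summarize_tissue,
    top_percentile_summary,
    topk_intensity,
)
from tissuedyn.quant import autofluor_threshold, percentile_sensitivity_sweep

finite_values = st.lists(
    st.floats(min_value=0.0, max_value=1e6, allow_nan=False), min_size=1, max_size=60
)


class TestTopK:
    def test_mean_of_ten_brightest(self):
        assert topk_intensity(np.arange(1, 21), k=10) == 15.5  # mean of 11..20

    def test_constant_for_any_k(self):
        for k in (1, 5, 100):
            assert topk_intensity(np.full(20, 3.25), k=k) == 3.25

    def test_small_nucleus_averages_all_pixels(self):
        # k stays 10; a 7-pixel nucleus averages its 7 pixels
        vals = np.array([1.0, 2, 3, 4, 5, 6, 7])
        assert topk_intensity(vals, k=10) == pytest.approx(4.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            topk_intensity(np.array([]))

    @settings(derandomize=True, max_examples=60)
    @given(values=finite_values, c=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_equivariant(self, values, c):
        v = np.asarray(values)
        assert topk_intensity(c * v) == pytest.approx(
            c * topk_intensity(v), rel=1e-9, abs=1e-12
        )

    @settings(derandomize=True, max_examples=60)
    @given(values=finite_values, idx=st.integers(0, 59), bump=st.floats(0, 1e3))
    def test_monotone_in_every_pixel(self, values, idx, bump):
        v = np.asarray(values)
        w = v.copy()
        w[idx % len(w)] += bump
        assert topk_intensity(w) >= topk_intensity(v) - 1e-12


class TestAutofluorescence:
    def test_degenerate_constant_control_flags_nothing(self):
        cells = pd.DataFrame({"label": [1, 2, 3], "topk_control": [5.0, 5.0, 5.0]})
        flagged = flag_autofluorescent(cells)
        assert not flagged["autofluor_flag"].any()

    def test_noisefree_flagging_exact(self, noisefree_image):
        channels, truth = noisefree_image
        mask = NucleusMask(truth.label_map, int(truth.label_map.max()))
        cells = flag_autofluorescent(quantify_cells(mask, channels))
        flagged = set(cells.loc[cells["autofluor_flag"], "label"])
        assert flagged == set(truth.autofluor_labels.tolist())

    def test_flag_conservation(self, small_image):
        channels, truth = small_image
        mask = NucleusMask(truth.label_map, int(truth.label_map.max()))
        cells = flag_autofluorescent(quantify_cells(mask, channels))
        n_used = int((~cells["autofluor_flag"]).sum())
        n_flagged = int(cells["autofluor_flag"].sum())
        assert n_used + n_flagged == mask.n_nuclei

    def test_threshold_is_median_plus_k_mad(self):
        values = np.array([1.0, 2, 3, 4, 100])
        med = 3.0
        mad = 1.0
        assert autofluor_threshold(values, k_mad=5) == pytest.approx(med + 5 * mad)

    def test_missing_control_raises(self):
        with pytest.raises(ValueError, match="control"):
            flag_autofluorescent(pd.DataFrame({"label": [1]}))


class TestNormalization:
    def test_ratio_basic(self):
        assert ratio_normalize(10.0, 2.0, floor=0.1) == 5.0

    def test_zero_control_hits_floor(self):
        assert ratio_normalize(10.0, 0.0, floor=2.0) == 5.0
        assert np.isfinite(ratio_normalize(10.0, 0.0, floor=1e-6))

    def test_dapi_mode(self):
        assert dapi_normalize(6.0, 3.0, floor=0.1) == 2.0
        assert dapi_normalize(0.0, 3.0, floor=0.1) == 0.0

    def test_negative_inputs_raise(self):
        with pytest.raises(ValueError):
            ratio_normalize(-1.0, 2.0, floor=0.1)

    def test_shared_field_cancels(self, rng):
        # multiplying BOTH channels by any positive per-cell factor leaves
        # the ratio unchanged (the stated purpose of the normalization)
        signal = rng.random(200) * 100
        control = rng.random(200) * 50 + 10
        field = 1.0 + rng.random(200)
        base = ratio_normalize(signal, control)
        scaled = ratio_normalize(signal * field, control * field)
        np.testing.assert_allclose(scaled, base, rtol=1e-9)


class TestPercentileSummary:
    def test_top_two_percent_of_hundred(self):
        assert top_percentile_summary(np.arange(1, 101), 0.02) == 99.5

    def test_top_ten_percent_of_hundred(self):
        assert top_percentile_summary(np.arange(1, 101), 0.10) == 95.5

    def test_p_one_is_plain_mean(self, rng):
        values = rng.random(57)
        assert top_percentile_summary(values, 1.0) == pytest.approx(values.mean())

    def test_errors(self):
        with pytest.raises(ValueError):
            top_percentile_summary(np.array([]), 0.02)
        with pytest.raises(ValueError):
            top_percentile_summary(np.arange(5), 0.0)

    def test_summary_tracks_positive_class_mean(self):
        # uniform induction (no crypt gradient), 2000 cells, 2% positive:
        # the top-2% summary estimates the positive-class mean signal
        from tissuedyn import SyntheticImageParams

        p = SyntheticImageParams(
            image_height=1000,
            image_width=1000,
            n_crypts=45,
            cells_per_crypt=45,
            positive_fraction=0.02,
            autofluor_fraction=0.0,
            gradient_decay=1.0,
            seed=5,
        )
        channels, truth = generate_tissue_image(p)
        mask = NucleusMask(truth.label_map, int(truth.label_map.max()))
        cells = normalize_cells(quantify_cells(mask, channels))
        summary = top_percentile_summary(cells["normalized_signal"].to_numpy(), 0.02)
        positives = cells[cells["label"].isin(truth.positive_labels)]
        true_mean = positives["normalized_signal"].mean()
        assert abs(summary - true_mean) / true_mean < 0.10

    def test_sensitivity_sweep_reports_all_percentiles(self, rng):
        sweep = percentile_sensitivity_sweep(rng.random(500), [0.02, 0.05, 0.10])
        assert list(sweep["percentile"]) == [0.02, 0.05, 0.10]
        assert sweep["summary"].is_monotonic_decreasing


class TestFractionPositive:
    def test_examples(self):
        assert fraction_positive(np.array([1.0, 2, 3, 4]), 2.5) == 0.5
        assert fraction_positive(np.array([1.0, 2]), 10.0) == 0.0
        assert fraction_positive(np.array([1.0, 2]), 1.0) == 1.0

    @settings(derandomize=True, max_examples=40)
    @given(values=finite_values, c1=st.floats(-10, 1e6), c2=st.floats(-10, 1e6))
    def test_non_increasing_in_cutoff(self, values, c1, c2):
        v = np.asarray(values)
        lo, hi = sorted((c1, c2))
        assert fraction_positive(v, lo) >= fraction_positive(v, hi)

    def test_comparison_api_requires_single_scalar_cutoff(self, rng):
        samples = {"a": rng.random(10), "b": rng.random(10)}
        out = fraction_positive_comparison(samples, 0.5)
        assert set(out) == {"a", "b"}
        with pytest.raises(ValueError):
            fraction_positive_comparison(samples, np.array([0.5, 0.6]))

    def test_calibrated_cutoff_is_high_percentile(self, rng):
        negative = rng.normal(1.0, 0.1, size=5000)
        cutoff = calibrate_cutoff(negative)
        assert cutoff == pytest.approx(np.percentile(negative, 99.0))


class TestSummarizeTissue:
    def test_single_sample_constant(self):
        ts = summarize_tissue({"s0": np.full(50, 4.0)}, "spleen", 2.0, "IR", p=0.1)
        assert ts.summary_value == 4.0
        assert ts.sem == 0.0
        assert ts.n_cells == 50

    def test_sem_across_three_replicates(self, rng):
        samples = {f"s{i}": rng.random(100) for i in range(3)}
        ts = summarize_tissue(samples, "gut", p=0.02)
        per_sample = [top_percentile_summary(v, 0.02) for v in samples.values()]
        assert ts.summary_value == pytest.approx(np.mean(per_sample))
        assert ts.sem == pytest.approx(np.std(per_sample, ddof=1) / math.sqrt(3))

    def test_empty_sample_error_names_it(self):
        with pytest.raises(ValueError, match="bad_sample"):
            summarize_tissue({"bad_sample": np.array([])}, "gut")
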