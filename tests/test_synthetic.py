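"""Generator contracts: determinism, class counts, geometry, noise-free
intensity model, tiling, qPCR tables, and induction schedules."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from tissuedyn import (
    SyntheticImageParams,
    generate_qpcr_table,
    generate_tiles,
    generate_tissue_image,
)
from tissuedyn.qpcr import fold_changes
from tissuedyn.synthetic import (
    simulate_timecourse_summaries,
    sustained_schedule,
    transient_schedule,
)


class TestTissueImage:
    def test_same_seed_bit_identical(self, small_params):
        ch1, t1 = generate_tissue_image(small_params)
        ch2, t2 = generate_tissue_image(small_params)
        for role in ch1:
            np.testing.assert_array_equal(ch1[role].pixels, ch2[role].pixels)
        np.testing.assert_array_equal(t1.label_map, t2.label_map)
        np.testing.assert_array_equal(t1.positive_labels, t2.positive_labels)
        assert t1.crypt_assignments == t2.crypt_assignments

    def test_different_seed_differs(self, small_params):
        other = dataclasses.replace(small_params, seed=small_params.seed + 1)
        _, t1 = generate_tissue_image(small_params)
        _, t2 = generate_tissue_image(other)
        assert not np.array_equal(t1.nucleus_centers, t2.nucleus_centers)

    def test_class_counts_round_fraction(self):
        # 500 cells at fraction 0.2 -> exactly 100 positives
        p = SyntheticImageParams(
            image_height=900,
            image_width=1100,
            n_crypts=25,
            cells_per_crypt=20,
            positive_fraction=0.2,
            autofluor_fraction=0.06,
            noise_model="none",
        )
        _, truth = generate_tissue_image(p)
        assert len(truth.positive_labels) == 100
        assert len(truth.autofluor_labels) == 30
        assert not set(truth.positive_labels) & set(truth.autofluor_labels)

    def test_labels_in_classes_exist_in_label_map(self, small_image):
        _, truth = small_image
        present = set(np.unique(truth.label_map)) - {0}
        assert set(truth.positive_labels.tolist()) <= present
        assert set(truth.autofluor_labels.tolist()) <= present

    def test_nuclei_non_overlapping(self, small_image):
        _, truth = small_image
        dist = squareform(pdist(truth.nucleus_centers))
        np.fill_diagonal(dist, np.inf)
        radius_sum = truth.radii[:, None] + truth.radii[None, :]
        assert (dist > radius_sum).all()

    def test_position_index_contiguous_from_base(self, small_image):
        _, truth = small_image
        for crypt, labels in truth.crypt_ordered_labels().items():
            positions = [truth.crypt_assignments[lab][1] for lab in labels]
            assert positions == list(range(len(labels)))
            # base cell (position 0) sits lowest in the frame (largest row)
            rows = [truth.nucleus_centers[lab - 1][0] for lab in labels]
            assert rows[0] == max(rows)

    def test_noisefree_intensity_model(self):
        # no positives, no autofluorescence, flat illumination, no noise:
        # signal inside a nucleus is exactly background + base * decay^pos
        p = SyntheticImageParams(
            image_height=300,
            image_width=420,
            n_crypts=6,
            cells_per_crypt=12,
            positive_fraction=0.0,
            autofluor_fraction=0.0,
            illumination_amplitude=1.0,
            noise_model="none",
        )
        channels, truth = generate_tissue_image(p)
        sig = channels["signal"].pixels
        for lab, (_, pos) in truth.crypt_assignments.items():
            expected = p.background_level + p.signal_level * p.gradient_decay**pos
            got = sig[truth.label_map == lab]
            np.testing.assert_allclose(got, expected, rtol=1e-12)
        # background region is exactly background_level
        assert np.all(sig[truth.label_map == 0] == p.background_level)

    def test_autofluor_bright_in_all_nondapi_channels(self, noisefree_image):
        channels, truth = noisefree_image
        p = truth.params
        lab = int(truth.autofluor_labels[0])
        where = truth.label_map == lab
        for role in ("signal", "costain", "control"):
            normal = channels[role].pixels[truth.label_map == _normal_label(truth)]
            assert channels[role].pixels[where].min() > normal.max()
        # DAPI is class-independent: same base level under the field
        dapi_base = (channels["dapi"].pixels[where] - p.background_level) / (
            truth.illumination_field[where]
        )
        np.testing.assert_allclose(dapi_base, p.dapi_level, rtol=1e-12)

    @pytest.mark.parametrize(
        "bad",
        [
            {"positive_fraction": 1.2},
            {"positive_fraction": 0.7, "autofluor_fraction": 0.5},
            {"gradient_decay": 0.0},
            {"illumination_amplitude": 0.5},
            {"noise_model": "salt"},
            {"image_height": 40, "image_width": 40},
            {"background_level": -1.0},
        ],
    )
    def test_invalid_params_raise(self, bad):
        with pytest.raises(ValueError):
            generate_tissue_image(SyntheticImageParams(**bad))


def _normal_label(truth):
    """A label that is neither positive nor autofluorescent."""
    flagged = set(truth.positive_labels) | set(truth.autofluor_labels)
    for lab in truth.crypt_assignments:
        if lab not in flagged:
            return lab
    raise AssertionError("no unflagged cell in truth")


class TestTiles:
    def test_single_tile_is_identity(self, rng):
        img = rng.random((40, 60))
        tiles = generate_tiles(img, 1, 1, overlap_px=0)
        assert len(tiles) == 1
        np.testing.assert_array_equal(tiles[0].pixels, img)

    def test_two_by_one_grid_shapes(self, rng):
        img = rng.random((100, 100))
        tiles = generate_tiles(img, 2, 1, overlap_px=0)
        assert [t.shape for t in tiles] == [(50, 100), (50, 100)]

    def test_neighbor_overlap_strips_identical(self, rng):
        img = rng.random((100, 120))
        tiles = generate_tiles(img, 2, 2, overlap_px=10)
        by_pos = {(t.row_index, t.col_index): t for t in tiles}
        top, bottom = by_pos[(0, 0)], by_pos[(1, 0)]
        np.testing.assert_array_equal(top.pixels[-10:, :], bottom.pixels[:10, :])
        left, right = by_pos[(0, 0)], by_pos[(0, 1)]
        np.testing.assert_array_equal(left.pixels[:, -10:], right.pixels[:, :10])

    def test_overlap_exceeding_tile_raises(self, rng):
        with pytest.raises(ValueError):
            generate_tiles(rng.random((100, 100)), 2, 2, overlap_px=60)


class TestQpcrTable:
    GENES = ["ACTB", "TARGET"]
    FC = {"TARGET": {"treated": 4.0}}

    def _table(self, fc=None, noise_sd=0.0, seed=0, replicates=2):
        return generate_qpcr_table(
            genes=self.GENES,
            conditions=["control", "treated"],
            true_fold_changes=fc or self.FC,
            control_condition="control",
            noise_sd=noise_sd,
            replicates=replicates,
            seed=seed,
        )

    def test_null_fold_change_gives_equal_ct(self):
        table = self._table(fc={"TARGET": {"treated": 1.0}})
        ct = table.groupby(["condition", "gene"])["ct"].mean()
        assert ct[("treated", "TARGET")] == ct[("control", "TARGET")]

    def test_fc4_lowers_target_ct_by_two_cycles(self):
        table = self._table()
        ct = table.groupby(["condition", "gene"])["ct"].mean()
        assert ct[("control", "TARGET")] - ct[("treated", "TARGET")] == pytest.approx(2.0)
        # reference gene untouched
        assert ct[("control", "ACTB")] == ct[("treated", "ACTB")]

    def test_monte_carlo_mean_recovery_within_5pct(self):
        # 200 noisy tables at true FC = 2: generator + ddCt round trip
        fcs = []
        for seed in range(200):
            table = self._table(
                fc={"TARGET": {"treated": 2.0}}, noise_sd=0.1, seed=seed
            )
            fc = fold_changes(table, control_condition="control")
            fcs.append(fc.set_index(["gene", "condition"]).loc[("TARGET", "treated"), "fc"])
        assert abs(np.mean(fcs) - 2.0) / 2.0 < 0.05

    def test_nonpositive_fold_change_raises(self):
        with pytest.raises(ValueError):
            self._table(fc={"TARGET": {"treated": 0.0}})
        with pytest.raises(ValueError):
            generate_qpcr_table(
                self.GENES, ["control"], {}, "control", replicates=0
            )


class TestSchedules:
    def test_transient_peaks_at_2h_and_decays_by_5h(self):
        peak = transient_schedule(2.0)
        assert peak > transient_schedule(0.0)
        assert abs(transient_schedule(5.0) - 1.0) < 0.2 * (peak - 1.0)

    def test_sustained_stays_elevated(self):
        assert sustained_schedule(5.0) > 0.8 * sustained_schedule(2.0)
        assert sustained_schedule(7.0) > 0.9 * (sustained_schedule(2.0))

    def test_summary_simulation_deterministic(self):
        a = simulate_timecourse_summaries("transient", [0, 2, 5], "gut", seed=3)
        b = simulate_timecourse_summaries("transient", [0, 2, 5], "gut", seed=3)
        pd.testing.assert_frame_equal(a, b)
        assert set(a.columns) >= {"tissue", "time_h", "sample", "summary"}
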