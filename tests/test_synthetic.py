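"""Generators: planted ground truth, seeding, and closed-form checks."""

import numpy as np
import pandas as pd
import pytest

import pbmquant as pq
from pbmquant.errors import ParameterError
from pbmquant.synthetic import child_rng


class TestSimulateTracks:
    def test_stationary_zero_displacement(self):
        t = pq.simulate_tracks(
            pq.MotilityModelParams(model="stationary", n_steps=10, n_tracks=3, seed=0)
        )
        assert (t.df[["x", "y"]].to_numpy() == 0).all()

    def test_ballistic_constant_step_length(self):
        t = pq.simulate_tracks(
            pq.MotilityModelParams(model="ballistic", speed=2.0, delta_t=10.0,
                                   n_steps=8, n_tracks=4, seed=1)
        )
        for _, g in t.iter_tracks():
            steps = np.diff(g[["x", "y"]].to_numpy(), axis=0)
            np.testing.assert_allclose(np.hypot(*steps.T), 20.0, atol=1e-9)

    def test_brownian_ensemble_msd_closed_form(self):
        """E‖Δr‖² at lag i is 2iσ² for 2-D i.i.d. Gaussian steps."""
        t = pq.simulate_tracks(
            pq.MotilityModelParams(model="brownian", step_sigma=1.0, delta_t=1.0,
                                   n_steps=72, n_tracks=500, seed=42)
        )
        curves = [pq.lag_statistics(g, tid) for tid, g in t.iter_tracks()]
        for i in (1, 5, 10):
            ens = np.mean([c.msd[i - 1] for c in curves])
            assert ens == pytest.approx(2.0 * i, rel=0.05)

    def test_track_shape_and_origin(self):
        t = pq.simulate_tracks(
            pq.MotilityModelParams(model="prw", n_steps=12, n_tracks=2, seed=5)
        )
        for _, g in t.iter_tracks():
            assert len(g) == 13
            assert g.loc[0, "x"] == 0 and g.loc[0, "y"] == 0

    def test_seed_determinism(self):
        p = pq.MotilityModelParams(model="prw", n_tracks=3, seed=9)
        pd.testing.assert_frame_equal(
            pq.simulate_tracks(p).df, pq.simulate_tracks(p).df
        )

    def test_invalid_model_rejected(self):
        with pytest.raises(ParameterError):
            pq.MotilityModelParams(model="levy")


class TestScratchFrames:
    def test_planted_area_exact_to_one_pixel(self):
        _, masks = pq.render_scratch_frames(
            pq.ScratchSceneParams(height=512, width=512,
                                  wound_fraction_per_frame=(0.30,), seed=0)
        )
        assert abs(int(masks[0].sum()) - round(0.30 * 512 * 512)) <= 1

    def test_zero_fraction_empty_mask(self):
        _, masks = pq.render_scratch_frames(
            pq.ScratchSceneParams(wound_fraction_per_frame=(0.0,), seed=0)
        )
        assert masks.sum() == 0

    def test_healing_series_strictly_decreasing_areas(self):
        stack, masks = pq.render_scratch_frames(
            pq.ScratchSceneParams(wound_fraction_per_frame=(0.3, 0.2, 0.1), seed=1)
        )
        areas = masks.sum(axis=(1, 2))
        assert stack.n_frames == 3
        assert (np.diff(areas) < 0).all()

    def test_increasing_fractions_rejected_by_default(self):
        with pytest.raises(ParameterError):
            pq.ScratchSceneParams(wound_fraction_per_frame=(0.2, 0.3))
        # explicit override allows wound enlargement scenarios
        pq.ScratchSceneParams(wound_fraction_per_frame=(0.2, 0.3),
                              allow_nonmonotone=True)

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ParameterError):
            pq.ScratchSceneParams(wound_fraction_per_frame=(1.2,))

    def test_horizontal_orientation_transposes_band(self):
        _, mv = pq.render_scratch_frames(
            pq.ScratchSceneParams(height=64, width=128,
                                  wound_fraction_per_frame=(0.25,),
                                  gap_orientation="vertical", seed=2)
        )
        _, mh = pq.render_scratch_frames(
            pq.ScratchSceneParams(height=64, width=128,
                                  wound_fraction_per_frame=(0.25,),
                                  gap_orientation="horizontal", seed=2)
        )
        assert mv[0].sum() == mh[0].sum()
        # vertical band spans all rows; horizontal spans all columns
        assert mv[0].any(axis=1).all() and mh[0].any(axis=0).all()


class TestFluorescenceField:
    def test_planted_counts(self):
        stack, truth = pq.render_fluorescence_field(
            pq.FluorescenceSceneParams(height=512, width=512, n_nuclei=100,
                                       positive_fraction=0.4, n_puncta=25, seed=3)
        )
        nuclei = truth[truth["object"] == "nucleus"]
        assert len(nuclei) == 100
        assert int(nuclei["positive"].sum()) == 40
        assert len(truth[truth["object"] == "punctum"]) == 25
        assert stack.n_channels == 3

    def test_zero_noise_background_exactly_zero(self):
        stack, truth = pq.render_fluorescence_field(
            pq.FluorescenceSceneParams(n_nuclei=5, n_puncta=0, background=0.0,
                                       noise_sigma=0.0, seed=4)
        )
        nuc = stack.frame(0, 0)
        assert nuc.max() > 0
        assert (nuc[nuc != 0] == 200.0).all()  # off-object pixels exactly 0

    def test_overdense_scene_raises(self):
        with pytest.raises(pq.errors.GenerationError):
            pq.render_fluorescence_field(
                pq.FluorescenceSceneParams(height=64, width=64, n_nuclei=500,
                                           seed=0)
            )

    def test_positive_fraction_bounds(self):
        with pytest.raises(ParameterError):
            pq.FluorescenceSceneParams(positive_fraction=1.5)


class TestCtSimulation:
    def test_zero_noise_exact_fold_recovery(self):
        table, truth = pq.simulate_ct_table(
            pq.CtSceneParams(genes=("Gapdh", "TgfB1"), true_log2_fold=(0.0, 1.0),
                             ct_noise_sd=0.0, seed=0)
        )
        res = pq.fold_changes(table, "Gapdh", "control")
        assert res.fold("TgfB1", "treated") == pytest.approx(2.0, abs=1e-12)

    def test_all_zero_folds_give_unity(self):
        table, _ = pq.simulate_ct_table(
            pq.CtSceneParams(genes=("Gapdh", "a", "b"),
                             true_log2_fold=(0.0, 0.0, 0.0),
                             ct_noise_sd=0.0, seed=1)
        )
        res = pq.fold_changes(table, "Gapdh", "control")
        np.testing.assert_allclose(res.by_condition["fold_mean"], 1.0, atol=1e-12)

    def test_noisy_fold_recovery_envelope(self):
        """fold=4 planted, Ct noise 0.1, 3 replicates: estimates stay in a
        Monte-Carlo envelope around 4 (computed over many seeds)."""
        for seed in range(10):
            table, _ = pq.simulate_ct_table(
                pq.CtSceneParams(genes=("Gapdh", "g"), true_log2_fold=(0.0, 2.0),
                                 ct_noise_sd=0.1, n_replicates=3, seed=seed)
            )
            res = pq.fold_changes(table, "Gapdh", "control")
            assert 3.5 <= res.fold("g", "treated") <= 4.6

    def test_reference_missing_from_genes_rejected(self):
        with pytest.raises(ParameterError, match="missing from gene list"):
            pq.CtSceneParams(genes=("a", "b"), true_log2_fold=(0.0, 1.0),
                             reference_gene="Gapdh")

    def test_reference_fold_must_be_zero(self):
        with pytest.raises(ParameterError):
            pq.CtSceneParams(genes=("Gapdh", "a"), true_log2_fold=(0.5, 1.0))


def test_child_rng_streams_are_independent():
    """Adding a generator must not perturb another's stream."""
    a1 = child_rng(7, "tracks").normal(size=4)
    _ = child_rng(7, "scratch").normal(size=100)
    a2 = child_rng(7, "tracks").normal(size=4)
    np.testing.assert_array_equal(a1, a2)
    assert not np.allclose(a1, child_rng(8, "tracks").normal(size=4))
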