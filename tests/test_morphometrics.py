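"""Nucleus counting, adhesion features, and cohort aggregation."""

import math

import numpy as np
import pytest

import pbmquant as pq
from pbmquant.errors import ValidationError


def _field(**kw):
    defaults = dict(height=512, width=512, n_nuclei=100, positive_fraction=0.4,
                    n_puncta=25, puncta_axis_ratio=3.0, noise_sigma=0.0, seed=0)
    defaults.update(kw)
    return pq.render_fluorescence_field(pq.FluorescenceSceneParams(**defaults))


class TestCountPositiveNuclei:
    def test_planted_recovery_zero_noise(self):
        stack, _ = _field()
        q = pq.count_positive_nuclei(stack.frame(0, 0), stack.frame(0, 1))
        assert (q.n_total, q.n_positive) == (100, 40)
        assert q.positive_pct == pytest.approx(40.0, abs=1e-12)
        assert not q.flagged

    def test_recovery_within_5pct_at_moderate_noise(self):
        hits_total, hits_pos = [], []
        for seed in range(10):
            stack, _ = _field(noise_sigma=10.0, seed=seed)
            q = pq.count_positive_nuclei(stack.frame(0, 0), stack.frame(0, 1))
            hits_total.append(q.n_total)
            hits_pos.append(q.n_positive)
        assert max(abs(t - 100) for t in hits_total) <= 5
        assert max(abs(p - 40) for p in hits_pos) <= 2

    def test_blank_marker_channel_zero_positive(self):
        stack, _ = _field(positive_fraction=0.0)
        q = pq.count_positive_nuclei(stack.frame(0, 0), stack.frame(0, 1))
        assert q.n_total == 100 and q.n_positive == 0

    def test_blank_nuclei_channel_flagged(self):
        q = pq.count_positive_nuclei(np.zeros((64, 64)), np.zeros((64, 64)))
        assert q == pq.NucleiQuant(0, 0, 0.0, flagged=True)

    def test_rotation_invariance_counts_exact(self):
        stack, _ = _field(seed=5)
        nuc, mrk = stack.frame(0, 0), stack.frame(0, 1)
        q0 = pq.count_positive_nuclei(nuc, mrk)
        q90 = pq.count_positive_nuclei(np.rot90(nuc), np.rot90(mrk))
        assert (q0.n_total, q0.n_positive) == (q90.n_total, q90.n_positive)


class TestAdhesionMetrics:
    def test_planted_puncta_count_and_elongation(self):
        stack, _ = _field()
        m = pq.adhesion_metrics(
            np.ones((512, 512), dtype=bool), {"pfak": stack.frame(0, 2)}
        )
        assert m.adhesion_count == 25
        assert m.mean_adhesion_elongation == pytest.approx(3.0, rel=0.10)

    def test_uniform_channel_no_puncta(self):
        m = pq.adhesion_metrics(
            np.ones((64, 64), dtype=bool), {"pfak": np.full((64, 64), 7.0)}
        )
        assert m.adhesion_count == 0
        assert math.isnan(m.mean_adhesion_area)

    def test_intensity_doubling_linearity(self):
        stack, _ = _field(n_nuclei=0, n_puncta=10, seed=2)
        ch = stack.frame(0, 2)
        mask = np.ones(ch.shape, dtype=bool)
        m1 = pq.adhesion_metrics(mask, {"pfak": ch})
        m2 = pq.adhesion_metrics(mask, {"pfak": 2 * ch})
        assert m2.intensity_total["pfak"] == pytest.approx(
            2 * m1.intensity_total["pfak"], rel=1e-12
        )
        # threshold is data-relative, so counts and shapes are unchanged
        assert m2.adhesion_count == m1.adhesion_count
        assert m2.mean_adhesion_elongation == pytest.approx(
            m1.mean_adhesion_elongation, rel=1e-9
        )

    def test_intensity_additive_over_mask_partition(self):
        stack, _ = _field(n_nuclei=0, n_puncta=8, seed=3)
        ch = stack.frame(0, 2)
        full = np.ones(ch.shape, dtype=bool)
        left, right = full.copy(), full.copy()
        left[:, 256:] = False
        right[:, :256] = False
        tot = pq.adhesion_metrics(full, {"c": ch}).intensity_total["c"]
        parts = (pq.adhesion_metrics(left, {"c": ch}).intensity_total["c"]
                 + pq.adhesion_metrics(right, {"c": ch}).intensity_total["c"])
        assert parts == pytest.approx(tot, abs=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            pq.adhesion_metrics(np.zeros((32, 32), dtype=bool), {})

    def test_cell_shape_features(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[20:44, 10:58] = True  # 24 x 48 rectangle
        m = pq.adhesion_metrics(mask, {})
        assert m.cell_area == 24 * 48
        assert m.aspect_ratio == pytest.approx(2.0, rel=0.02)


class TestCohortMorphometrics:
    def _cells(self, intensity, seed, n=4):
        out = []
        for i in range(n):
            stack, _ = _field(n_nuclei=0, n_puncta=10,
                              puncta_intensity=intensity, seed=seed + i,
                              height=256, width=256)
            out.append((np.ones((256, 256), dtype=bool),
                        {"pfak": stack.frame(0, 2)}))
        return out

    def test_planted_intensity_ratio_recovered(self):
        fields = {"control": self._cells(100.0, seed=10),
                  "treated": self._cells(200.0, seed=20)}
        _, by_cond = pq.cohort_morphometrics(fields)
        g = by_cond.set_index("condition")
        ratio = (g.loc["treated", "pfak_total_mean"]
                 / g.loc["control", "pfak_total_mean"])
        assert ratio == pytest.approx(2.0, rel=0.10)

    def test_identical_seeds_identical_summaries(self):
        fields = {"a": self._cells(100.0, seed=1), "b": self._cells(100.0, seed=1)}
        _, by_cond = pq.cohort_morphometrics(fields)
        a = by_cond[by_cond["condition"] == "a"].drop(columns="condition")
        b = by_cond[by_cond["condition"] == "b"].drop(columns="condition")
        np.testing.assert_allclose(a.to_numpy(dtype=float),
                                   b.to_numpy(dtype=float), atol=0, rtol=0)

    def test_single_cell_condition_sem_nan(self):
        fields = {"solo": self._cells(100.0, seed=5, n=1)}
        _, by_cond = pq.cohort_morphometrics(fields)
        assert math.isnan(by_cond["pfak_total_sem"].iloc[0])

    def test_unmeasurable_condition_excluded_not_fatal(self):
        fields = {
            "ok": self._cells(100.0, seed=7, n=2),
            "broken": [(np.zeros((32, 32), dtype=bool), {})],
        }
        per_cell, by_cond = pq.cohort_morphometrics(fields)
        assert set(by_cond["condition"]) == {"ok"}
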