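"""Descriptive sensory summaries on the 150-mm line scale."""

import numpy as np
import pandas as pd
import pytest

import ricotype as rt
from ricotype.synth import STUDY_SENSORY_MOMENTS


def _scores(values, attr="hardness", sample="s1"):
    return pd.DataFrame({
        "sample_id": [sample] * len(values),
        "panelist_id": [f"p{i}" for i in range(len(values))],
        "session": 1,
        "attribute": attr,
        "intensity_mm": values,
    })


class TestSummaries:
    def test_constant_scores(self):
        scores = _scores([70.0] * 6)
        summary = rt.summarize_sensory(scores, pd.Series({"s1": 1}))
        assert summary.loc["hardness", (1, "mean")] == 70.0
        # single sample in the cluster: sample-level SD is undefined
        assert np.isnan(summary.loc["hardness", (1, "sd")])

    def test_five_sample_hand_arithmetic(self):
        frames = [_scores([v], sample=f"s{i}") for i, v in
                  enumerate([60.0, 62.0, 64.0, 66.0, 68.0])]
        scores = pd.concat(frames, ignore_index=True)
        cmap = pd.Series({f"s{i}": 1 for i in range(5)})
        summary = rt.summarize_sensory(scores, cmap)
        assert summary.loc["hardness", (1, "mean")] == pytest.approx(64.0)
        assert summary.loc["hardness", (1, "sd")] == pytest.approx(3.16, abs=0.005)
        assert summary.loc["hardness", (1, "n")] == 5

    def test_panelists_averaged_per_sample_first(self):
        """Cluster SD is over sample means, not raw panelist scores."""
        a = _scores([50.0, 70.0], sample="s1")   # sample mean 60
        b = _scores([58.0, 66.0], sample="s2")   # sample mean 62
        scores = pd.concat([a, b], ignore_index=True)
        summary = rt.summarize_sensory(scores, pd.Series({"s1": 1, "s2": 1}))
        assert summary.loc["hardness", (1, "mean")] == pytest.approx(61.0)
        assert summary.loc["hardness", (1, "sd")] == pytest.approx(np.sqrt(2.0))

    def test_row_order_invariance(self):
        scores, cmap = rt.gen_sensory_scores(seed=0)
        a = rt.summarize_sensory(scores, cmap)
        b = rt.summarize_sensory(scores.sample(frac=1, random_state=1), cmap)
        pd.testing.assert_frame_equal(a, b)

    def test_reference_sample_excluded(self):
        scores = pd.concat([_scores([70.0], sample="s1"),
                            _scores([10.0], sample="STD")], ignore_index=True)
        cmap = pd.Series({"s1": 1, "STD": 1})
        summary = rt.summarize_sensory(scores, cmap, reference_sample="STD")
        assert summary.loc["hardness", (1, "mean")] == 70.0


class TestValidation:
    def test_out_of_scale_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            rt.summarize_sensory(_scores([151.0]), pd.Series({"s1": 1}))

    def test_unknown_attribute_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            rt.summarize_sensory(_scores([70.0], attr="umami"), pd.Series({"s1": 1}))

    def test_unassigned_sample_rejected(self):
        with pytest.raises(ValueError, match="without a cluster"):
            rt.summarize_sensory(_scores([70.0]), pd.Series({"other": 1}))


class TestCompare:
    def test_ordering_matches_study_uniformity_of_bite(self):
        """With the study's summary moments, uniformity of bite orders the
        clusters 1 (93.3) > 3 (91.6) > 2 (65.9)."""
        scores, cmap = rt.gen_sensory_scores(
            n_samples=40, n_panelists=4, seed=5)
        summary = rt.summarize_sensory(scores, cmap)
        comp = rt.compare_clusters(summary, "uniformity of bite")
        assert list(comp["cluster"]) == [1, 3, 2]

    def test_equal_means_zero_differences(self):
        frames = []
        for k in (1, 2):
            frames.append(_scores([50.0], sample=f"s{k}"))
        scores = pd.concat(frames, ignore_index=True)
        cmap = pd.Series({"s1": 1, "s2": 2})
        comp = rt.compare_clusters(rt.summarize_sensory(scores, cmap), "hardness")
        assert comp["gap_to_next_mm"].to_numpy() == pytest.approx([0.0, 0.0])

    def test_missing_attribute_rejected(self):
        scores = _scores([50.0])
        summary = rt.summarize_sensory(scores, pd.Series({"s1": 1}))
        with pytest.raises(ValueError):
            rt.compare_clusters(summary, "toothpack")


class TestGenerator:
    def test_zero_sd_returns_spec_means_exactly(self):
        moments = {"hardness": ((60.0, 0.0), (50.0, 0.0), (40.0, 0.0))}
        scores, cmap = rt.gen_sensory_scores(moments, n_samples=3,
                                             n_panelists=2, panelist_sd=0.0, seed=0)
        summary = rt.summarize_sensory(scores, cmap)
        for k, mu in zip((1, 2, 3), (60.0, 50.0, 40.0)):
            assert summary.loc["hardness", (k, "mean")] == pytest.approx(mu)
            assert summary.loc["hardness", (k, "sd")] == pytest.approx(0.0)

    def test_determinism(self):
        a, _ = rt.gen_sensory_scores(seed=9)
        b, _ = rt.gen_sensory_scores(seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_large_n_mean_recovery(self):
        """Cluster-attribute means are recovered within 3 SD/sqrt(n)."""
        scores, cmap = rt.gen_sensory_scores(n_samples=200, n_panelists=2, seed=3)
        summary = rt.summarize_sensory(scores, cmap)
        for attr, per_cluster in STUDY_SENSORY_MOMENTS.items():
            for k, (mu, sd) in enumerate(per_cluster, start=1):
                # panelist noise adds variance on top of the cluster SD
                tol = 3 * np.sqrt(sd**2 + 6.0**2 / 2) / np.sqrt(200)
                assert abs(summary.loc[attr, (k, "mean")] - mu) <= tol + 0.5, attr

    def test_scores_within_scale(self):
        scores, _ = rt.gen_sensory_scores(seed=1)
        assert scores["intensity_mm"].between(0, 150).all()
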