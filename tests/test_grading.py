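"""Reference fitting, normalized distances, Q score and grade assignment."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fruitgrade.color import FeatureVector
from fruitgrade.grading import (
    EPS_SCALE,
    assign_grade,
    feature_distances,
    fit_grade_reference,
    fit_q_ranges,
    fit_references,
    load_references,
    quality_score,
    save_references,
)


def make_fv(R=100.0, G=100.0, B=100.0, size=500, weight=100.0):
    return FeatureVector(
        R_mean=R, G_mean=G, B_mean=B,
        r=0.0, g=0.0, b=0.0, H=0.0, S=0.0, I=(R + G + B) / 3,
        size_px=size, weight_g=weight,
    )


def population(rng, center, sds, n):
    """Draw n feature vectors around (R,G,B,size,weight) = center."""
    R, G, B, size, weight = center
    return [
        make_fv(
            R=rng.normal(R, sds[0]), G=rng.normal(G, sds[1]), B=rng.normal(B, sds[2]),
            size=int(rng.normal(size, sds[3])), weight=rng.normal(weight, sds[4]),
        )
        for _ in range(n)
    ]


class TestFitReference:
    def test_hand_arithmetic_population_variance(self):
        samples = [make_fv(size=s) for s in (2, 4, 6)]
        ref = fit_grade_reference(samples, 1)
        assert ref.means["size"] == 4.0
        assert ref.variances["size"] == pytest.approx(8 / 3, abs=1e-12)
        assert ref.range_min["size"] == pytest.approx(4 - 8 / 3, abs=1e-12)
        assert ref.range_max["size"] == pytest.approx(4 + 8 / 3, abs=1e-12)
        assert ref.scales["size"] == pytest.approx(math.sqrt(8 / 3), abs=1e-12)

    def test_identical_samples_floor_scale(self):
        ref = fit_grade_reference([make_fv()] * 5, 2)
        for k in ref.scales:
            assert ref.scales[k] == EPS_SCALE
            assert ref.range_min[k] == ref.range_max[k] == ref.means[k]

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(7)
        samples = population(rng, (120, 80, 60, 900, 140), (5, 5, 5, 30, 8), 25)
        ref = fit_grade_reference(samples, 3)
        weights = [fv.weight_g for fv in samples]
        mu = sum(weights) / len(weights)
        var = sum((w - mu) ** 2 for w in weights) / len(weights)
        assert ref.means["weight"] == pytest.approx(mu, abs=1e-9)
        assert ref.variances["weight"] == pytest.approx(var, abs=1e-9)

    def test_variance_scale_mode(self):
        samples = [make_fv(size=s) for s in (2, 4, 6)]
        ref = fit_grade_reference(samples, 1, scale_mode="variance")
        assert ref.scales["size"] == pytest.approx(8 / 3, abs=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_grade_reference([make_fv()], 1)


class TestDistances:
    def ref(self):
        rng = np.random.default_rng(0)
        return fit_grade_reference(population(rng, (150, 90, 60, 800, 120), (4, 4, 4, 25, 5), 30), 1)

    def test_zero_at_reference_means(self):
        ref = self.ref()
        fv = make_fv(
            R=ref.means["R"], G=ref.means["G"], B=ref.means["B"],
            size=ref.means["size"], weight=ref.means["weight"],
        )
        dR, dS, dW = feature_distances(fv, ref)
        assert dR == pytest.approx(0.0, abs=1e-9)
        assert dS == pytest.approx(0.0, abs=1e-9)
        assert dW == pytest.approx(0.0, abs=1e-9)

    def test_unit_z_score(self):
        ref = self.ref()
        fv = make_fv(
            R=ref.means["R"] + ref.scales["R"], G=ref.means["G"], B=ref.means["B"],
            size=ref.means["size"], weight=ref.means["weight"],
        )
        dR, _, _ = feature_distances(fv, ref)
        assert dR == pytest.approx(1.0, abs=1e-9)

    def test_pythagorean_combination(self):
        ref = self.ref()
        fv = make_fv(
            R=ref.means["R"] + 3 * ref.scales["R"],
            G=ref.means["G"],
            B=ref.means["B"] + 4 * ref.scales["B"],
            size=ref.means["size"], weight=ref.means["weight"],
        )
        dR, _, _ = feature_distances(fv, ref)
        assert dR == pytest.approx(5.0, abs=1e-9)

    def test_scale_invariance_of_z_distances(self):
        # rescaling a feature and its reference together leaves d unchanged
        rng = np.random.default_rng(1)
        samples = population(rng, (150, 90, 60, 800, 120), (4, 4, 4, 25, 5), 20)
        ref = fit_grade_reference(samples, 1)
        scaled = [
            FeatureVector(
                R_mean=fv.R_mean, G_mean=fv.G_mean, B_mean=fv.B_mean,
                r=fv.r, g=fv.g, b=fv.b, H=fv.H, S=fv.S, I=fv.I,
                size_px=fv.size_px, weight_g=fv.weight_g * 10.0,
            )
            for fv in samples
        ]
        ref_scaled = fit_grade_reference(scaled, 1)
        probe = samples[0]
        probe_scaled = scaled[0]
        d = feature_distances(probe, ref)
        d_scaled = feature_distances(probe_scaled, ref_scaled)
        assert d[2] == pytest.approx(d_scaled[2], rel=1e-9)


class TestQualityScore:
    def test_closed_forms(self):
        assert quality_score(0, 0, 0) == 1.0
        assert quality_score(1, 1, 1) == pytest.approx(math.exp(-1), abs=1e-12)
        assert quality_score(500.0, 0, 0) == pytest.approx(2 / 3, abs=1e-12)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            quality_score(-0.1, 0, 0)

    @given(
        st.floats(min_value=0, max_value=20),
        st.floats(min_value=0, max_value=20),
        st.floats(min_value=0, max_value=20),
        st.floats(min_value=1e-6, max_value=5),
    )
    def test_strictly_decreasing_in_each_distance(self, dR, dS, dW, delta):
        q = quality_score(dR, dS, dW)
        assert 0.0 < q <= 1.0
        assert quality_score(dR + delta, dS, dW) < q
        assert quality_score(dR, dS + delta, dW) < q
        assert quality_score(dR, dS, dW + delta) < q


class TestQRangesAndAssignment:
    CENTERS = {
        1: (220, 120, 90, 2900, 180),
        2: (200, 130, 95, 2400, 150),
        3: (180, 140, 100, 1900, 120),
        4: (160, 150, 105, 1450, 90),
    }
    SDS = (4, 4, 4, 60, 5)

    def fitted_refs(self, seed=0, n=20):
        rng = np.random.default_rng(seed)
        training = []
        for g, center in self.CENTERS.items():
            training += [(fv, g) for fv in population(rng, center, self.SDS, n)]
        return fit_references(training, n_reference=10), training

    def test_training_at_means_gives_unit_q_band(self):
        refs = {}
        training = []
        for g, center in self.CENTERS.items():
            fvs = [make_fv(R=center[0], G=center[1], B=center[2], size=center[3], weight=center[4])] * 3
            refs[g] = fit_grade_reference(fvs, g)
            training += [(fv, g) for fv in fvs]
        refs = fit_q_ranges(refs, training)
        for g in refs:
            assert refs[g].q_min == refs[g].q_max == 1.0

    def test_q_band_contains_training_scores_and_positive(self):
        refs, training = self.fitted_refs()
        for fv, g in training:
            q = quality_score(*feature_distances(fv, refs[g]))
            assert refs[g].q_min - 1e-12 <= q <= refs[g].q_max + 1e-12
        assert all(refs[g].q_min > 0 for g in refs)

    def test_missing_grade_training_rejected(self):
        refs, training = self.fitted_refs()
        only_g1 = [(fv, g) for fv, g in training if g == 1]
        with pytest.raises(ValueError):
            fit_q_ranges(refs, only_g1)

    def test_own_mean_vector_assigned_to_own_grade(self):
        refs, _ = self.fitted_refs()
        for g in (1, 2, 3, 4):
            fv = make_fv(
                R=refs[g].means["R"], G=refs[g].means["G"], B=refs[g].means["B"],
                size=refs[g].means["size"], weight=refs[g].means["weight"],
            )
            res = assign_grade(fv, refs)
            assert res.assigned_grade == g
            assert res.q[g] == max(res.q.values())

    def test_tie_breaks_to_lowest_grade(self):
        refs = {}
        for g in (1, 2, 3, 4):
            # grades 1 and 2 share a reference; a probe at their common mean ties
            center = self.CENTERS[1] if g in (1, 2) else self.CENTERS[g]
            fvs = [
                make_fv(R=center[0] + d, G=center[1], B=center[2], size=center[3], weight=center[4])
                for d in (-1, 0, 1)
            ]
            refs[g] = fit_grade_reference(fvs, g)
        probe = make_fv(
            R=self.CENTERS[1][0], G=self.CENTERS[1][1], B=self.CENTERS[1][2],
            size=self.CENTERS[1][3], weight=self.CENTERS[1][4],
        )
        res = assign_grade(probe, refs)
        assert res.q[1] == res.q[2]
        assert res.assigned_grade == 1

    def test_well_separated_population_recovery(self):
        # 4 x 50 fresh samples against references fitted at seed 0
        refs, _ = self.fitted_refs(seed=0)
        rng = np.random.default_rng(1)
        correct = total = 0
        for g, center in self.CENTERS.items():
            for fv in population(rng, center, self.SDS, 50):
                total += 1
                correct += assign_grade(fv, refs).assigned_grade == g
        assert correct / total >= 0.95

    def test_accuracy_monotone_in_separation(self):
        accs = []
        for sep in (1.0, 2.0, 3.0):
            rng = np.random.default_rng(2)
            centers = {
                g: (
                    220 - (g - 1) * sep * 4, 120, 90,
                    2900 - (g - 1) * sep * 60, 180 - (g - 1) * sep * 5,
                )
                for g in (1, 2, 3, 4)
            }
            training = []
            for g, c in centers.items():
                training += [(fv, g) for fv in population(rng, c, self.SDS, 20)]
            refs = fit_references(training, n_reference=10)
            correct = total = 0
            for g, c in centers.items():
                for fv in population(rng, c, self.SDS, 50):
                    total += 1
                    correct += assign_grade(fv, refs).assigned_grade == g
            accs.append(correct / total)
        assert accs[0] <= accs[1] <= accs[2]

    def test_incomplete_references_rejected(self):
        refs, _ = self.fitted_refs()
        del refs[3]
        with pytest.raises(ValueError):
            assign_grade(make_fv(), refs)

    def test_reference_json_round_trip(self, tmp_path):
        refs, _ = self.fitted_refs()
        save_references(refs, tmp_path / "refs.json")
        loaded = load_references(tmp_path / "refs.json")
        assert loaded.keys() == refs.keys()
        for g in refs:
            assert loaded[g].means == refs[g].means
            assert loaded[g].q_min == refs[g].q_min
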