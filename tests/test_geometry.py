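"""Admixture circle, outgroup-F3 projection, F4 angles and F4-ratio."""

import numpy as np
import pytest

from fstatpca import (
    AlleleFreqMatrix,
    DegeneracyError,
    GraphSpec,
    SimConfig,
    ValidationError,
    admixture_circle,
    classify_f3,
    f2,
    f3,
    f4,
    f4_angle,
    f4_ratio,
    orthogonality_test,
    outgroup_f3_rank,
    pca_from_data,
    residual_rotation,
    simulate,
)
from .conftest import make_freqs


class TestAdmixtureCircle:
    def test_center_and_radius_in_subspace(self, rng):
        fr = make_freqs(rng, n=5, s=40)
        d = pca_from_data(fr)
        c = admixture_circle(d, "P0", "P1", (1, 2))
        pa, pb = d.coords_of("P0")[:2], d.coords_of("P1")[:2]
        assert np.allclose(c.center, 0.5 * (pa + pb))
        assert c.radius == pytest.approx(0.5 * np.linalg.norm(pa - pb))

    def test_same_source_zero_radius(self, rng):
        d = pca_from_data(make_freqs(rng, n=4, s=20))
        c = admixture_circle(d, "P0", "P0", (1, 2))
        assert c.radius == 0.0

    def test_projected_circle_never_exceeds_full_ball(self, rng):
        d = pca_from_data(make_freqs(rng, n=7, s=50))
        for sub in [(1,), (1, 2), (2, 3), (1, 2, 3)]:
            c = admixture_circle(d, "P2", "P5", sub)
            assert c.radius**2 <= c.full_diameter_f2 / 4 + 1e-12

    def test_empty_subspace_rejected(self, rng):
        d = pca_from_data(make_freqs(rng, n=4, s=20))
        with pytest.raises(ValidationError):
            admixture_circle(d, "P0", "P1", ())


class TestClassifyF3:
    def test_midpoint_mixture_inside_ball(self, rng):
        fr = make_freqs(rng, n=4, s=30)
        mid = 0.5 * (fr.row("P0") + fr.row("P1"))
        fr2 = AlleleFreqMatrix(
            np.vstack([fr.values, mid]), fr.pop_labels + ("MIX",)
        )
        d = pca_from_data(fr2)
        r = classify_f3(fr2, d, "MIX", "P0", "P1")
        assert r.position == "inside_ball"
        assert r.f3_value == pytest.approx(-f2(fr2, "P0", "P1") / 4, abs=1e-12)
        assert not r.outside_projected_circle

    def test_right_angle_target_on_sphere(self):
        fr = AlleleFreqMatrix(
            np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]), ("t", "a", "b")
        )
        d = pca_from_data(fr)
        r = classify_f3(fr, d, "t", "a", "b", subspace=(1, 2))
        assert r.position == "on_sphere"

    def test_outside_projected_circle_implies_positive_f3(self, rng):
        """Positivity guarantee over randomized higher-PC completions."""
        violations = 0
        tested = 0
        for trial in range(20):
            fr = make_freqs(
                np.random.default_rng(1000 + trial), n=8, s=40, lo=0.35, hi=0.65
            )
            base = pca_from_data(fr)
            mu, load = base.snp_means, base.loadings
            k = base.k_max
            r2 = np.random.default_rng(2000 + trial)
            for _ in range(10):
                c = r2.normal(scale=0.02, size=k)
                x = mu + np.sqrt(fr.n_snps) * (c @ load)
                if x.min() < 0 or x.max() > 1:
                    continue
                fr2 = AlleleFreqMatrix(
                    np.vstack([fr.values, x]), fr.pop_labels + ("T",)
                )
                d2 = pca_from_data(fr2)
                res = classify_f3(fr2, d2, "T", "P0", "P1", (1, 2))
                tested += 1
                if res.outside_projected_circle and res.f3_value <= 0:
                    violations += 1
        assert tested > 100
        assert violations == 0


class TestOutgroupF3:
    def test_unknown_itself_tops_ranking(self, rng):
        fr = make_freqs(rng, n=6, s=50)
        ranking = outgroup_f3_rank(fr, "P0", "P1", ["P1", "P2", "P3"])
        assert ranking[0].label == "P1"
        assert ranking[0].f3 == pytest.approx(f2(fr, "P0", "P1"), abs=1e-12)

    def test_outgroup_in_panel_gets_zero(self, rng):
        fr = make_freqs(rng, n=5, s=50)
        ranking = outgroup_f3_rank(fr, "P0", "P1", ["P0", "P2"])
        entry = next(e for e in ranking if e.label == "P0")
        assert entry.f3 == 0.0
        assert entry.projected_length == 0.0

    def test_ranking_matches_brute_force_sort(self, rng):
        fr = make_freqs(rng, n=8, s=60)
        panel = [f"P{i}" for i in range(2, 8)]
        ranking = outgroup_f3_rank(fr, "P0", "P1", panel)
        brute = sorted(
            panel, key=lambda x: f3(fr, "P0", "P1", x), reverse=True
        )
        assert [e.label for e in ranking] == brute
        # projected lengths share the ordering (same positive scale factor)
        lens = [e.projected_length for e in ranking]
        assert lens == sorted(lens, reverse=True)

    def test_zero_axis_rejected(self, rng):
        fr = make_freqs(rng, n=3, s=20)
        with pytest.raises(DegeneracyError):
            outgroup_f3_rank(fr, "P0", "P0", ["P1"])


class TestF4Angle:
    def test_parallel_vectors_give_cos_one(self):
        fr = AlleleFreqMatrix(
            np.array(
                [[0.8, 0.2], [0.2, 0.2], [0.7, 0.5], [0.4, 0.5]]
            ),
            ("a", "b", "c", "d"),
        )
        r = f4_angle(fr, "a", "b", "c", "d")
        assert r.cos_phi == pytest.approx(1.0, abs=1e-12)
        assert r.phi_degrees == pytest.approx(0.0, abs=1e-5)

    def test_orthogonal_vectors_give_ninety_degrees(self):
        fr = AlleleFreqMatrix(
            np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 1.0]]), ("a", "b", "c")
        )
        r = f4_angle(fr, "a", "b", "c", "b")
        assert r.cos_phi == pytest.approx(0.0, abs=1e-12)
        assert r.phi_degrees == pytest.approx(90.0, abs=1e-9)

    def test_matches_vector_oracle(self, rng):
        fr = make_freqs(rng, n=4, s=30)
        u = fr.row("P0") - fr.row("P1")
        v = fr.row("P2") - fr.row("P3")
        oracle = (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
        r = f4_angle(fr, "P0", "P1", "P2", "P3")
        assert r.cos_phi == pytest.approx(oracle, abs=1e-12)
        assert -1.0 <= r.cos_phi <= 1.0
        assert r.f4_value == pytest.approx(
            f4(fr, "P0", "P1", "P2", "P3"), abs=1e-15
        )

    def test_truncated_full_k_equals_frequency_space(self, rng):
        fr = make_freqs(rng, n=6, s=50)
        d = pca_from_data(fr)
        full = f4_angle(fr, "P0", "P1", "P2", "P3")
        onpcs = f4_angle(d, "P0", "P1", "P2", "P3", K=d.k_max)
        assert onpcs.cos_phi == pytest.approx(full.cos_phi, abs=1e-10)
        assert onpcs.f4_value == pytest.approx(full.f4_value, abs=1e-10)

    def test_zero_difference_rejected(self, rng):
        fr = make_freqs(rng, n=4, s=20)
        with pytest.raises(DegeneracyError):
            f4_angle(fr, "P0", "P0", "P1", "P2")


class TestF4Ratio:
    def _with_mixture(self, rng, w, s=100):
        fr = make_freqs(rng, n=4, s=s, labels=("R1", "R2", "X1", "X2"))
        mix = (1 - w) * fr.row("X1") + w * fr.row("X2")
        return AlleleFreqMatrix(
            np.vstack([fr.values, mix]), fr.pop_labels + ("XX",)
        )

    def test_target_at_endpoints(self, rng):
        fr = self._with_mixture(rng, 0.0)
        assert f4_ratio(fr, "R1", "R2", "XX", "X1", "X2").alpha == (
            pytest.approx(0.0, abs=1e-12)
        )
        fr = self._with_mixture(rng, 1.0)
        assert f4_ratio(fr, "R1", "R2", "XX", "X1", "X2").alpha == (
            pytest.approx(1.0, abs=1e-12)
        )

    def test_drift_free_mixture_recovers_weight(self, rng):
        fr = self._with_mixture(rng, 0.3)
        r = f4_ratio(fr, "R1", "R2", "XX", "X1", "X2")
        assert r.alpha == pytest.approx(0.3, abs=1e-10)

    def test_perturbation_orthogonal_to_reference_axis_is_ignored(self, rng):
        fr = self._with_mixture(rng, 0.3)
        axis = fr.row("R1") - fr.row("R2")
        pert = rng.normal(scale=0.01, size=fr.n_snps)
        pert -= (pert @ axis) / (axis @ axis) * axis
        vals = fr.values.copy()
        vals[fr.index("XX")] = np.clip(vals[fr.index("XX")] + pert, 0, 1)
        # verify clipping stayed inactive so orthogonality is exact
        assert np.all(vals[fr.index("XX")] == fr.row("XX") + pert)
        fr2 = AlleleFreqMatrix(vals, fr.pop_labels)
        r = f4_ratio(fr2, "R1", "R2", "XX", "X1", "X2")
        assert r.alpha == pytest.approx(0.3, abs=1e-10)

    def test_degenerate_references_rejected(self, rng):
        fr = make_freqs(rng, n=3, s=30, labels=("R1", "X1", "X2"))
        vals = np.vstack([fr.values, fr.row("R1"), fr.row("X1")])
        fr2 = AlleleFreqMatrix(vals, ("R1", "X1", "X2", "R2", "XX"))
        # R1 == R2 makes the reference axis, hence the denominator, zero
        with pytest.raises(DegeneracyError):
            f4_ratio(fr2, "R1", "R2", "XX", "X1", "X2")


class TestResidualRotation:
    def test_axis_separation_is_sqrt_f2(self, rng):
        fr = make_freqs(rng, n=6, s=50)
        d = pca_from_data(fr)
        rot = residual_rotation(d, "P0", "P1")
        i, j = d.index("P0"), d.index("P1")
        sep = abs(rot.axis_positions[j] - rot.axis_positions[i])
        assert sep == pytest.approx(np.sqrt(f2(fr, "P0", "P1")), abs=1e-10)

    def test_references_have_equal_residuals(self, rng):
        d = pca_from_data(make_freqs(rng, n=6, s=50))
        rot = residual_rotation(d, "P0", "P1")
        i, j = d.index("P0"), d.index("P1")
        assert np.abs(
            rot.residual_coords[i] - rot.residual_coords[j]
        ).max() < 1e-10

    def test_axis_distance_ratio_equals_f4_ratio(self, rng):
        fr = make_freqs(rng, n=4, s=80, labels=("R1", "R2", "X1", "X2"))
        mix = 0.7 * fr.row("X1") + 0.3 * fr.row("X2")
        fr2 = AlleleFreqMatrix(
            np.vstack([fr.values, mix]), fr.pop_labels + ("XX",)
        )
        d = pca_from_data(fr2)
        rot = residual_rotation(d, "R1", "R2")
        t = dict(zip(rot.pop_labels, rot.axis_positions))
        ratio = (t["XX"] - t["X1"]) / (t["X2"] - t["X1"])
        alpha = f4_ratio(fr2, "R1", "R2", "XX", "X1", "X2").alpha
        assert ratio == pytest.approx(alpha, abs=1e-10)

    def test_drift_free_mixture_interpolates(self, rng):
        fr = make_freqs(rng, n=5, s=60)
        mix = 0.4 * fr.row("P2") + 0.6 * fr.row("P3")
        fr2 = AlleleFreqMatrix(
            np.vstack([fr.values, mix]), fr.pop_labels + ("MIX",)
        )
        d = pca_from_data(fr2)
        rot = residual_rotation(d, "P0", "P1")
        idx = {p: i for i, p in enumerate(rot.pop_labels)}
        expect = (
            0.4 * rot.residual_coords[idx["P2"]]
            + 0.6 * rot.residual_coords[idx["P3"]]
        )
        assert np.abs(rot.residual_coords[idx["MIX"]] - expect).max() < 1e-9

    def test_identical_references_rejected(self, rng):
        fr = make_freqs(rng, n=3, s=20)
        vals = np.vstack([fr.values, fr.row("P0")])
        fr2 = AlleleFreqMatrix(vals, fr.pop_labels + ("COPY",))
        d = pca_from_data(fr2)
        with pytest.raises(DegeneracyError):
            residual_rotation(d, "P0", "COPY")


class TestOrthogonalityTest:
    def test_identical_labels_trivially_orthogonal(self, rng):
        fr = make_freqs(rng, n=4, s=30)
        r = orthogonality_test(fr, "P0", "P0", "P1", "P2")
        assert r.f4_value == 0.0
        assert r.orthogonal

    def test_shared_drift_construction_fails_flag(self, rng):
        fr = make_freqs(rng, n=2, s=50, lo=0.2, hi=0.8, labels=("a", "b"))
        shift = rng.normal(scale=0.05, size=50)
        a2 = np.clip(fr.row("a") + shift, 0, 1)
        b2 = np.clip(fr.row("b") + shift, 0, 1)
        assert np.all(a2 == fr.row("a") + shift)  # no clipping
        assert np.all(b2 == fr.row("b") + shift)
        fr2 = AlleleFreqMatrix(
            np.vstack([fr.values, a2, b2]), ("a", "b", "a2", "b2")
        )
        r = orthogonality_test(fr2, "a", "a2", "b", "b2")
        assert r.cos_phi == pytest.approx(1.0, abs=1e-10)
        assert not r.orthogonal

    def test_independent_drift_branches_pass(self):
        graph = GraphSpec(
            nodes=("root", "a", "a2", "b", "b2"),
            edges=(
                ("root", "a", 0.02),
                ("a", "a2", 0.02),
                ("root", "b", 0.02),
                ("b", "b2", 0.02),
            ),
            leaves=("a", "a2", "b", "b2"),
        )
        cfg = SimConfig(n_snps=100000, seed=7)
        freqs, _ = simulate(graph, cfg)
        r = orthogonality_test(freqs, "a", "a2", "b", "b2", tol=0.1)
        assert abs(r.cos_phi) < 0.1
        assert r.orthogonal
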