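"""Elementary optics and the non-sequential trace: Snell, Fresnel, diffuse
sampling, energy bookkeeping, path tagging and symmetry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import iolglare as ig
from iolglare.engine import (
    TAG_EDGE_R,
    TAG_EDGE_T,
    fresnel_unpolarized,
    refract,
    reflect,
    scatter_hemisphere,
    trace,
)
from iolglare.retina import bin_hits
from iolglare.sources import SourceSpec, make_bundle


class TestRefract:
    def test_normal_incidence_unchanged(self):
        d = np.array([0.0, 0.0, 1.0])
        n = np.array([0.0, 0.0, -1.0])
        t, tir = refract(d, n, 1.0, 1.7)
        assert not tir
        assert np.allclose(t, d, atol=1e-15)

    def test_30_degrees_air_to_glass(self):
        # scalar Snell: theta2 = arcsin(sin 30 / 1.5) = 19.47122063 deg
        th1 = np.radians(30.0)
        d = np.array([np.sin(th1), 0.0, np.cos(th1)])
        n = np.array([0.0, 0.0, -1.0])
        t, tir = refract(d, n, 1.0, 1.5)
        assert not tir
        th2 = np.degrees(np.arctan2(t[0], t[2]))
        assert th2 == pytest.approx(19.47122063, abs=1e-8)

    def test_total_internal_reflection_beyond_critical(self):
        crit = np.arcsin(1.336 / 1.458)
        th1 = crit + 0.01
        d = np.array([np.sin(th1), 0.0, np.cos(th1)])
        n = np.array([0.0, 0.0, -1.0])
        t, tir = refract(d, n, 1.458, 1.336)
        assert tir

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(th=st.floats(0.0, 1.5), n1=st.floats(1.0, 1.8), n2=st.floats(1.0, 1.8))
    def test_snell_invariant(self, th, n1, n2):
        """n1 sin(theta1) = n2 sin(theta2) to 1e-12 whenever refraction occurs."""
        d = np.array([np.sin(th), 0.0, np.cos(th)])
        n = np.array([0.0, 0.0, -1.0])
        t, tir = refract(d, n, n1, n2)
        if not tir:
            assert np.linalg.norm(t) == pytest.approx(1.0, abs=1e-12)
            assert n1 * np.sin(th) == pytest.approx(n2 * abs(t[0]), abs=1e-12)


class TestFresnel:
    def test_normal_incidence_four_percent(self):
        assert fresnel_unpolarized(0.0, 1.0, 1.5) == pytest.approx(
            ((1.5 - 1.0) / 2.5) ** 2, abs=1e-15)

    def test_brewster_angle_p_vanishes(self):
        n1, n2 = 1.0, 1.5
        thb = np.arctan(n2 / n1)
        cost = np.sqrt(1 - (n1 / n2) ** 2 * np.sin(thb) ** 2)
        rs = ((n1 * np.cos(thb) - n2 * cost) / (n1 * np.cos(thb) + n2 * cost)) ** 2
        assert fresnel_unpolarized(thb, n1, n2) == pytest.approx(rs / 2, abs=1e-12)

    def test_matched_media_zero(self):
        assert fresnel_unpolarized(0.7, 1.4, 1.4) == 0.0

    def test_tir_gives_unity(self):
        assert fresnel_unpolarized(np.radians(80), 1.458, 1.336) == 1.0

    def test_grazing_limit(self):
        assert fresnel_unpolarized(np.radians(89.999), 1.0, 1.5) == pytest.approx(1.0, abs=1e-3)


class TestScatter:
    def test_all_samples_in_hemisphere(self):
        rng = np.random.default_rng(7)
        n = np.array([[0.3, -0.5, 0.81240384]])
        d = scatter_hemisphere(np.repeat(n, 5000, axis=0), rng)
        assert (d @ n[0] > 0).all()
        assert np.allclose(np.linalg.norm(d, axis=1), 1.0, atol=1e-12)

    def test_fixed_seed_reproducible(self):
        a = scatter_hemisphere(np.array([[0, 0, 1.0]]), np.random.default_rng(3), n=100)
        b = scatter_hemisphere(np.array([[0, 0, 1.0]]), np.random.default_rng(3), n=100)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("model,transform", [
        # Lambertian: cos^2(theta) is uniform on (0, 1)
        ("lambertian", lambda c: c**2),
        # isotropic: cos(theta) itself is uniform on (0, 1)
        ("isotropic", lambda c: c),
    ])
    def test_distribution_goodness_of_fit(self, model, transform):
        rng = np.random.default_rng(42)
        nrm = np.array([[0.0, 0.0, 1.0]])
        d = scatter_hemisphere(np.repeat(nrm, 100_000, axis=0), rng, model=model)
        u = transform(d[:, 2])
        p = stats.kstest(u, "uniform").pvalue
        assert p > 0.01


class TestTrace:
    def test_single_axial_ray(self, model6):
        pos = np.array([[0.0, 0.0, -10.0]])
        dirn = np.array([[0.0, 0.0, 1.0]])
        hits, ledger = trace(model6, pos, dirn, np.array([1.0]))
        # primary hit lands on the retinal apex
        i = np.argmax(hits.energy)
        assert np.allclose(hits.points[i], [0, 0, 23.95], atol=1e-9)
        assert ledger.balance < 1e-9
        # most energy arrives (4 interfaces of ~1-3% loss each)
        assert 0.9 < ledger.retina_total <= 1.0

    @pytest.mark.parametrize("angle", [0.0, 55.0, 77.5])
    def test_energy_ledger_closes(self, model6, angle):
        pos, dirn, energy = make_bundle(SourceSpec(angle, ray_count=4000))
        hits, ledger = trace(model6, pos, dirn, energy)
        assert ledger.balance < 1e-9
        assert ledger.emitted == pytest.approx(1.0, abs=1e-12)

    def test_frosted_ledger_closes_with_scatter(self):
        m = ig.build_model(6, "frosted")
        pos, dirn, energy = make_bundle(SourceSpec(77.5, ray_count=4000))
        hits, ledger = trace(m, pos, dirn, energy)
        assert ledger.balance < 1e-9

    def test_mirror_symmetry_of_retinal_map(self, model6):
        """Reflecting the source about the x-z plane reflects the map
        (v -> -v) bin-exactly for a deterministic source."""
        pos, dirn, energy = make_bundle(SourceSpec(65.0, ray_count=3000))
        hits_a, _ = trace(model6, pos, dirn, energy)
        pos_m = pos * np.array([1.0, -1.0, 1.0])
        hits_b, _ = trace(model6, pos_m, dirn, energy)
        map_a = bin_hits(hits_a, 0.2)
        map_b = bin_hits(hits_b, 0.2)
        assert np.array_equal(map_a.layers, map_b.layers[:, :, ::-1])

    def test_absorbing_edge_has_no_edge_tagged_energy(self):
        m = ig.build_model(6, "absorbing")
        pos, dirn, energy = make_bundle(SourceSpec(77.5, ray_count=4000))
        hits, ledger = trace(m, pos, dirn, energy)
        assert ledger.retina.get("edge_transmitted", 0.0) == 0.0
        assert ledger.retina.get("edge_reflected", 0.0) == 0.0

    def test_thin_edge_rays_never_carry_edge_tags(self, model6_thin):
        pos, dirn, energy = make_bundle(SourceSpec(77.5, ray_count=4000))
        hits, _ = trace(model6_thin, pos, dirn, energy)
        assert not ((hits.flags & (TAG_EDGE_T | TAG_EDGE_R)) > 0).any()

    def test_reflecting_edge_never_transmits(self):
        m = ig.build_model(6, "reflecting")
        pos, dirn, energy = make_bundle(SourceSpec(77.5, ray_count=4000))
        _, ledger = trace(m, pos, dirn, energy)
        assert ledger.retina.get("edge_transmitted", 0.0) == 0.0

    def test_anti_reflecting_edge_never_reflects(self):
        m = ig.build_model(6, "anti_reflecting")
        pos, dirn, energy = make_bundle(SourceSpec(77.5, ray_count=4000))
        _, ledger = trace(m, pos, dirn, energy)
        assert ledger.retina.get("edge_reflected", 0.0) == 0.0

    def test_energy_never_increases_along_lineages(self, model6):
        pos, dirn, energy = make_bundle(SourceSpec(60.0, ray_count=2000))
        hits, _ = trace(model6, pos, dirn, energy)
        assert (hits.energy <= energy.max() + 1e-15).all()

    def test_trace_is_deterministic(self, model6):
        pos, dirn, energy = make_bundle(SourceSpec(70.0, ray_count=2000))
        a, la = trace(model6, pos, dirn, energy)
        b, lb = trace(model6, pos, dirn, energy)
        assert np.array_equal(a.points, b.points)
        assert np.array_equal(a.energy, b.energy)
        assert la.retina == lb.retina
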