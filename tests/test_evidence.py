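"""Exact marginal likelihood and the four-term FIA expansion."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import expit

from occam.evidence import (
    EvidenceBreakdown,
    exact_log_marginal,
    fia_breakdown,
    log_likelihood,
    posterior_choice_prob,
    profile_exact,
    profile_fia,
)
from occam.manifolds import ArcManifold, NoiseModel, PointManifold, SegmentManifold

TOY_M1 = PointManifold((0.0, 0.0))
TOY_M2 = SegmentManifold((-0.5, 1.0), (0.5, 1.0))
TOY_NOISE = NoiseModel(sigma=1.0, n_obs=1)
TOY_X = np.array([[0.0, 0.5]])


def toy_posterior_oracle():
    """Independent quadrature of the toy marginal (direct scipy.integrate path)."""

    def lik_m2(t):
        return np.exp(-((0.0 - t) ** 2 + (0.5 - 1.0) ** 2) / 2) / (2 * np.pi)

    z2, err = quad(lik_m2, -0.5, 0.5, epsabs=1e-12)
    z1 = np.exp(-(0.0**2 + 0.5**2) / 2) / (2 * np.pi)
    return z1 / (z1 + z2), err


class TestLogLikelihood:
    def test_mode_density(self):
        assert np.isclose(
            log_likelihood(TOY_M1, 0.0, np.array([[0.0, 0.0]]), TOY_NOISE),
            -np.log(2 * np.pi),
        )

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 2))
        noise = NoiseModel(0.7, 6)
        m = SegmentManifold((-1, 0), (1, 0))
        shift = np.array([1.3, -0.4])
        m2 = SegmentManifold(tuple(np.array(m.a) + shift), tuple(np.array(m.b) + shift))
        assert np.isclose(
            log_likelihood(m, 0.8, X, noise), log_likelihood(m2, 0.8, X + shift, noise)
        )

    def test_against_per_point_summation(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            X = rng.normal(size=(8, 2))
            noise = NoiseModel(rng.uniform(0.3, 2.0), 8)
            m = SegmentManifold((-1, -1), (2, 0.5))
            s = rng.uniform(0, m.length)
            mu = m.embed(s)
            direct = sum(
                -np.log(2 * np.pi * noise.sigma**2)
                - np.sum((x - mu) ** 2) / (2 * noise.sigma**2)
                for x in X
            )
            assert abs(log_likelihood(m, s, X, noise) - direct) < 1e-12 * abs(direct)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood(TOY_M1, 0.0, np.empty((0, 2)), TOY_NOISE)


class TestExactMarginal:
    def test_point_model_equals_loglik(self):
        X = np.array([[0.3, -0.2], [0.1, 0.4]])
        noise = NoiseModel(1.0, 2)
        assert np.isclose(
            exact_log_marginal(TOY_M1, X, noise),
            log_likelihood(TOY_M1, 0.0, X, noise),
        )

    def test_toy_posterior_value(self):
        oracle, err = toy_posterior_oracle()
        p1 = posterior_choice_prob((TOY_M2, TOY_M1), TOY_X, TOY_NOISE, "exact")
        assert err < 1e-10
        assert abs(p1 - oracle) < 1e-6
        assert abs(p1 - 0.510) < 1e-3  # the simpler model is preferred

    def test_quadrature_self_convergence(self):
        rng = np.random.default_rng(2)
        arc = ArcManifold(center=(0, 0), radius=1.0, angle0=0.0, span=3.0)
        noise = NoiseModel(0.6, 10)
        for _ in range(20):
            X = rng.normal(0, 1.5, size=(10, 2))
            a = exact_log_marginal(arc, X, noise, method="quadrature", tol=1e-8)
            b = exact_log_marginal(arc, X, noise, method="quadrature", tol=1e-10)
            assert abs(a - b) < 1e-8

    def test_segment_closed_form_matches_quadrature(self):
        rng = np.random.default_rng(3)
        m = SegmentManifold((-1.2, 0.4), (0.8, 1.1))
        noise = NoiseModel(0.9, 7)
        for _ in range(20):
            X = rng.normal(0, 2, size=(7, 2))
            assert np.isclose(
                exact_log_marginal(m, X, noise, method="auto"),
                exact_log_marginal(m, X, noise, method="quadrature"),
                atol=1e-7,
            )


class TestFIABreakdown:
    def test_point_all_terms_zero(self):
        X = np.array([[1.0, 2.0], [0.0, -1.0]])
        b = fia_breakdown(TOY_M1, X, NoiseModel(1.0, 2), with_exact=True)
        assert b.term_dimensionality == b.term_boundary == 0.0
        assert b.term_volume == b.term_robustness == 0.0
        assert b.fia_log_evidence == b.log_max_likelihood == b.exact_log_evidence

    def test_additivity(self):
        rng = np.random.default_rng(4)
        noise = NoiseModel(0.8, 10)
        arc = ArcManifold(center=(0, -2), radius=1.5, angle0=1.0, span=2.0)
        for m in (TOY_M2, arc):
            for _ in range(50):
                X = rng.normal(0, 2, size=(10, 2))
                b = fia_breakdown(m, X, noise)
                if b.degenerate:
                    continue
                total = (
                    b.log_max_likelihood
                    + b.term_dimensionality
                    + b.term_boundary
                    + b.term_volume
                    + b.term_robustness
                )
                assert abs(total - b.fia_log_evidence) < 1e-12 * max(1, abs(total))

    def test_straight_interior_projection(self):
        X = np.tile([[0.05, 1.1]], (10, 1))
        b = fia_breakdown(TOY_M2, X, NoiseModel(0.5, 10))
        assert b.term_robustness == 0.0  # h = g exactly on a straight segment
        assert not b.on_boundary
        # only exponentially small truncation mass remains away from the ends
        assert abs(b.term_boundary) < 5e-3

    def test_interior_boundary_term_negligible_at_large_n(self):
        X = np.tile(np.array([[0.0, 1.1]]), (50, 1))
        b = fia_breakdown(TOY_M2, X, NoiseModel(0.3, 50))
        assert abs(b.term_boundary) < 1e-8

    def test_fia_equals_exact_for_segments(self):
        # the likelihood is exactly Gaussian in arc length on a straight
        # segment, so the expansion is exact there (boundary factor included)
        rng = np.random.default_rng(5)
        noise = NoiseModel(1.1, 10)
        for _ in range(50):
            X = rng.normal(0, 2.5, size=(10, 2))
            b = fia_breakdown(TOY_M2, X, noise, with_exact=True)
            assert abs(b.fia_log_evidence - b.exact_log_evidence) < 1e-7

    def test_fia_exact_gap_shrinks_with_n_on_arcs(self):
        arc = ArcManifold(center=(0, 0), radius=1.0, angle0=0.0, span=2.5)
        rng = np.random.default_rng(6)
        gaps = []
        for n in (10, 100, 1000):
            noise = NoiseModel(0.8, n)
            g = []
            for _ in range(30):
                mu = arc.embed(rng.uniform(0.3, 0.7) * arc.length)
                X = mu + noise.sigma * rng.standard_normal((n, 2))
                b = fia_breakdown(arc, X, noise, with_exact=True)
                if not b.degenerate and not b.on_boundary:
                    g.append(abs(b.fia_log_evidence - b.exact_log_evidence))
            gaps.append(np.median(g))
        assert gaps[2] < gaps[1] < gaps[0]

    def test_volume_penalty_monotone_in_length(self):
        noise = NoiseModel(1.0, 10)
        X = np.zeros((10, 2))
        penalties = []
        for lam in (0.5, 1.0, 2.0, 4.0):
            m = SegmentManifold((-lam / 2, 1.0), (lam / 2, 1.0))
            penalties.append(fia_breakdown(m, X, noise).term_volume)
        assert all(a > b for a, b in zip(penalties, penalties[1:]))

    def test_degenerate_flagged(self):
        arc = ArcManifold(center=(0.0, 0.0), radius=1.0, angle0=0.0, span=3.0)
        X = np.zeros((4, 2))  # centroid exactly at the center of curvature
        b = fia_breakdown(arc, X, NoiseModel(1.0, 4))
        assert b.degenerate
        assert not np.isfinite(b.term_robustness)

    def test_boundary_term_continuous_at_crossing(self):
        # slide the centroid so its projection moves from interior past the
        # endpoint: the (uniform) boundary term must change continuously,
        # passing through about -log 2 at the crossing
        noise = NoiseModel(0.25, 10)
        xs = np.linspace(0.0, 0.9, 901)  # step 1e-3; includes the crossing x=0.5
        vals = []
        for x in xs:
            X = np.tile([[x, 1.2]], (10, 1))
            vals.append(fia_breakdown(TOY_M2, X, noise).term_boundary)
        vals = np.asarray(vals)
        assert np.all(np.isfinite(vals))
        assert np.max(np.abs(np.diff(vals))) < 0.02  # no jump
        at_cross = vals[np.argmin(np.abs(xs - 0.5))]
        assert abs(at_cross - (-np.log(2.0))) < 1e-6
        assert abs(vals[0]) < 1e-8  # deep interior
        assert vals[-1] < -np.log(2.0)  # clamped: stronger penalty


class TestChoiceProb:
    def test_symmetric_pair_gives_half(self):
        m_up = SegmentManifold((-1, 1.0), (1, 1.0))
        m_dn = SegmentManifold((-1, -1.0), (1, -1.0))
        X = np.array([[0.3, 0.0]])  # centroid on the symmetry axis
        for method in ("exact", "fia", "ml_only"):
            p = posterior_choice_prob((m_dn, m_up), X, NoiseModel(1.0, 1), method)
            assert abs(p - 0.5) < 1e-10

    def test_toy_complement(self):
        p2 = posterior_choice_prob((TOY_M1, TOY_M2), TOY_X, TOY_NOISE, "exact")
        assert abs(p2 - 0.490) < 1e-3

    def test_ml_only_prefers_nearer_model(self):
        X = np.array([[0.0, 0.8]])  # strictly nearer the segment at y=1
        p2 = posterior_choice_prob((TOY_M1, TOY_M2), X, TOY_NOISE, "ml_only")
        assert p2 > 0.5

    def test_batch_profiles_match_scalar_api(self):
        rng = np.random.default_rng(8)
        noise = NoiseModel(0.9, 10)
        cents = rng.normal(0, 1.5, size=(40, 2))
        prof = profile_fia(TOY_M2, cents, noise)
        ex = profile_exact(TOY_M2, cents, noise)
        for i in rng.choice(40, 5, replace=False):
            X = np.tile(cents[i], (10, 1))
            b = fia_breakdown(TOY_M2, X, noise, with_exact=True)
            const = b.log_max_likelihood - prof["loglik_profile"][i]
            assert np.isclose(b.fia_log_evidence, prof["fia_profile"][i] + const)
            assert np.isclose(b.exact_log_evidence, ex[i] + const)
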