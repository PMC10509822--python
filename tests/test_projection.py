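"""Projector algebra, SSS separation and attenuation against a regression oracle."""

import numpy as np
import pytest

from opmarray import geometry, projection
from opmarray.exceptions import InvalidParameterError
from opmarray.harmonics import build_basis, evaluate_basis_at, n_terms


@pytest.fixture(scope="module")
def triaxial_180():
    """60-sensor triaxial array on the default scalp (180 channels)."""
    scalp = geometry.make_scalp_surface()
    return geometry.build_array(scalp, 3, n_sensors=60, seed=2)


@pytest.fixture(scope="module")
def small_instance():
    """10-channel random instance for brute-force regression oracles."""
    rng = np.random.default_rng(9)
    pos = rng.normal(size=(10, 3))
    pos = 0.1 * pos / np.linalg.norm(pos, axis=1, keepdims=True)
    ori = rng.normal(size=(10, 3))
    ori /= np.linalg.norm(ori, axis=1, keepdims=True)
    B = evaluate_basis_at(pos, ori, 1, "external", np.zeros(3))
    L = rng.normal(size=(10, 25))
    return B, L


class TestExternalProjector:
    def test_idempotent_annihilating_trace(self, triaxial_180):
        B = build_basis(triaxial_180, 3, "external")
        M = projection.external_projector(B)
        m = M.matrix
        assert np.linalg.norm(m @ m - m) < 1e-9 * np.linalg.norm(m)
        assert np.linalg.norm(m @ B.matrix) < 1e-9 * np.linalg.norm(B.matrix)
        # 180 channels, 15 full-rank columns -> trace 165
        assert np.trace(m) == pytest.approx(165, abs=1e-6)
        assert M.rank_removed == 15

    def test_kills_pure_external_field(self, triaxial_180):
        B = build_basis(triaxial_180, 2, "external")
        rng = np.random.default_rng(1)
        y = B.matrix @ rng.normal(size=(B.matrix.shape[1], 5))
        out = projection.external_projector(B).matrix @ y
        assert np.linalg.norm(out) < 1e-9 * np.linalg.norm(y)

    def test_white_noise_variance_ratio(self, triaxial_180):
        """Projected white-noise variance concentrates on (Nc - rank)/Nc."""
        B = build_basis(triaxial_180, 3, "external")
        M = projection.external_projector(B).matrix
        rng = np.random.default_rng(0)
        noise = rng.standard_normal((180, 10_000))
        ratio = np.var(M @ noise) / np.var(noise)
        assert ratio == pytest.approx(165 / 180, rel=0.02)

    def test_rank_deficient_warns(self):
        with pytest.warns(RuntimeWarning):
            projection.external_projector(np.ones((4, 6)))


class TestSSSSeparation:
    def test_exact_recovery_of_internal_coefficients(self, triaxial_180):
        A = build_basis(triaxial_180, 3, "internal")
        B = build_basis(triaxial_180, 3, "external")
        rng = np.random.default_rng(3)
        # scale coefficients to the column norms so the signal is balanced
        x = rng.normal(size=15) / np.linalg.norm(A.matrix, axis=0)
        y = A.matrix @ x
        coeffs, y_int = projection.sss_separate(A, B, y)
        np.testing.assert_allclose(coeffs.c_internal, x, atol=1e-8 * np.abs(x).max())
        assert np.linalg.norm(coeffs.c_external * np.linalg.norm(B.matrix, axis=0)) \
            < 1e-6 * np.linalg.norm(y)
        np.testing.assert_allclose(y_int, y, atol=1e-8 * np.linalg.norm(y))

    def test_pure_external_gives_zero_internal(self, triaxial_180):
        A = build_basis(triaxial_180, 2, "internal")
        B = build_basis(triaxial_180, 2, "external")
        rng = np.random.default_rng(4)
        y = B.matrix @ (rng.normal(size=8) / np.linalg.norm(B.matrix, axis=0))
        _, y_int = projection.sss_separate(A, B, y)
        assert np.linalg.norm(y_int) < 1e-6 * np.linalg.norm(y)

    def test_noisy_reconstruction_bounded(self, triaxial_180):
        A = build_basis(triaxial_180, 2, "internal")
        B = build_basis(triaxial_180, 2, "external")
        rng = np.random.default_rng(5)
        x = rng.normal(size=8) / np.linalg.norm(A.matrix, axis=0)
        clean = A.matrix @ x
        noise = 1e-4 * np.linalg.norm(clean) / np.sqrt(180) * rng.standard_normal(180)
        coeffs, y_int = projection.sss_separate(A, B, clean + noise)
        rel_err = np.linalg.norm(y_int - clean) / np.linalg.norm(clean)
        assert rel_err < 1e-4 * coeffs.condition_number


class TestAttenuation:
    def test_identity_projector_gives_zero_db(self, small_instance):
        _, L = small_instance
        res = projection.leadfield_attenuation(np.eye(10), L)
        np.testing.assert_allclose(res.per_source_db, 0.0, atol=1e-10)

    def test_source_inside_interference_span_flagged(self, small_instance):
        B, L = small_instance
        L = L.copy()
        L[:, 0] = B @ np.array([0.3, -1.0, 2.0])
        M = projection.external_projector(B)
        res = projection.leadfield_attenuation(M, L)
        assert np.isneginf(res.per_source_db[0])

    def test_constant_column_flagged_undefined(self, small_instance):
        B, L = small_instance
        L = L.copy()
        L[:, 1] = 3.14  # zero across-channel variance
        res = projection.leadfield_attenuation(projection.external_projector(B), L)
        assert res.undefined[1]
        assert np.isnan(res.per_source_db[1])

    def test_matches_regression_oracle(self, small_instance):
        """attenuation == 10 log10 of the residual-variance ratio from an
        explicit least-squares fit of the external basis to each column."""
        B, L = small_instance
        res = projection.leadfield_attenuation(projection.external_projector(B), L)
        for i in range(L.shape[1]):
            coef, *_ = np.linalg.lstsq(B, L[:, i], rcond=None)
            resid = L[:, i] - B @ coef
            expect = 10 * np.log10(np.var(resid, ddof=1) / np.var(L[:, i], ddof=1))
            assert res.per_source_db[i] == pytest.approx(expect, abs=1e-9)

    def test_projection_is_contraction(self, small_instance):
        B, L = small_instance
        M = projection.external_projector(B).matrix
        assert np.all(np.linalg.norm(M @ L, axis=0)
                      <= np.linalg.norm(L, axis=0) + 1e-12)

    def test_loss_monotone_in_order_and_statistical_blowup(self, triaxial_180):
        """Nested bases lose monotonically more signal; losses blow up as the
        regressor count approaches the channel count."""
        rng = np.random.default_rng(8)
        L = rng.normal(size=(180, 40))
        basis = build_basis(triaxial_180, 12, "external")
        losses = {}
        for order in (3, 7, 12):
            with np.errstate(invalid="ignore"):
                M = projection.external_projector(basis.truncated(order))
            att = projection.leadfield_attenuation(M, L).per_source_db
            losses[order] = att
        assert np.all(losses[7] <= losses[3] + 1e-9)
        assert np.all(losses[12] <= losses[7] + 1e-9)
        # n_terms(12)=168 ~ 0.93*Nc vs n_terms(7)=63 ~ 0.35*Nc
        assert -np.median(losses[12]) > -np.median(losses[7])

    def test_channel_mismatch_rejected(self, small_instance):
        B, L = small_instance
        with pytest.raises(InvalidParameterError):
            projection.leadfield_attenuation(np.eye(7), L)


class TestAttenuationSweep:
    def test_schema_and_axis_ordering(self, default_head):
        scalp, cortex, origin = default_head
        df = projection.attenuation_sweep(scalp, cortex, n_sensors_list=(40,),
                                          n_axes_list=(1, 2, 3), orders=(1, 3),
                                          seed=0, origin=origin)
        assert set(df.columns) >= {"spacing", "n_axes", "sensors", "channels",
                                   "order", "median_db", "q2p5_db"}
        assert len(df) == 6
        # worst-case quantile is at least the median loss
        assert (df.q2p5_db >= df.median_db - 1e-12).all()
        # triaxial < dual < single attenuation at matched sensor count
        at3 = df[df.order == 3].set_index("n_axes")
        assert at3.loc[3, "median_db"] < at3.loc[2, "median_db"] \
            < at3.loc[1, "median_db"]
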