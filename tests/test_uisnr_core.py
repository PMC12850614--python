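"""uiSNR quadratic form, convergence curves, masking, normalization."""

import numpy as np
import pytest
import scipy.linalg

from uisnr.basis_noise import FieldBasis, NoiseCovariance
from uisnr.phantom import FieldSpec
from uisnr.uisnr_core import (UiSNRConstants, UiSNRMap, convergence_curve,
                              convergence_mask, normalize_map,
                              quadratic_form_map, uisnr_map)


def synthetic_basis(n, shape, seed=0):
    """Random well-conditioned basis + PSD covariance on a tiny grid."""
    rng = np.random.default_rng(seed)
    b1 = rng.standard_normal((n,) + shape) \
        + 1j * rng.standard_normal((n,) + shape)
    basis = FieldBasis(e_fields=np.zeros((n,) + shape + (3,),
                                         dtype=complex),
                       b1minus=b1,
                       excitations=np.zeros((n, 1), dtype=complex),
                       frequency=128e6, seed=seed)
    a = rng.standard_normal((n, 2 * n)) + 1j * rng.standard_normal((n, 2 * n))
    psi = NoiseCovariance(psi=a @ a.conj().T)
    return basis, psi


class TestQuadraticForm:
    def test_single_element_closed_form(self):
        basis, psi = synthetic_basis(1, (3, 3, 3))
        spec = FieldSpec(B0=3.0)
        m = uisnr_map(basis, psi, spec, n_use=1, reduced=True)
        expect = spec.B0 ** 2 * np.abs(basis.b1minus[0]) \
            / np.sqrt(psi.psi[0, 0].real)
        np.testing.assert_allclose(m.values, expect, rtol=1e-12)

    def test_identity_psi_sums_magnitudes(self):
        basis, _ = synthetic_basis(5, (2, 2, 2))
        psi = NoiseCovariance(psi=np.eye(5, dtype=complex))
        q = quadratic_form_map(basis, psi)
        expect = np.sum(np.abs(basis.b1minus) ** 2, axis=0)
        np.testing.assert_allclose(q, expect, rtol=1e-12)

    def test_generalized_rayleigh_oracle(self):
        """q equals the largest generalized eigenvalue of (b b^H, Psi)."""
        basis, psi = synthetic_basis(6, (4, 4, 4), seed=3)
        q = quadratic_form_map(basis, psi)
        rng = np.random.default_rng(1)
        for vox in [(0, 0, 0), (1, 2, 3), (3, 3, 3)]:
            b = basis.b1minus[(slice(None),) + vox]
            eig = scipy.linalg.eigh(np.outer(b, b.conj()), psi.psi,
                                    eigvals_only=True)[-1]
            assert q[vox] == pytest.approx(eig, rel=1e-8)
            # random-search lower bound approaches the optimum
            w = rng.standard_normal((20000, 6)) \
                + 1j * rng.standard_normal((20000, 6))
            num = np.abs(w.conj() @ b) ** 2
            den = np.einsum("ij,jk,ik->i", w.conj(), psi.psi, w).real
            best = (num / den).max()
            assert best <= q[vox] * (1 + 1e-9)
            assert best >= 0.2 * q[vox]

    def test_basis_mixing_invariance(self):
        basis, psi = synthetic_basis(6, (3, 3, 3), seed=5)
        q = quadratic_form_map(basis, psi)
        rng = np.random.default_rng(8)
        m = rng.standard_normal((6, 6)) + 1j * rng.standard_normal((6, 6))
        m += 3 * np.eye(6)  # keep it well conditioned
        mixed = FieldBasis(
            e_fields=basis.e_fields,
            b1minus=np.einsum("ij,j...->i...", m, basis.b1minus),
            excitations=basis.excitations,
            frequency=basis.frequency, seed=basis.seed)
        psi_mixed = NoiseCovariance(psi=m @ psi.psi @ m.conj().T)
        q_mixed = quadratic_form_map(mixed, psi_mixed)
        assert np.max(np.abs(q_mixed - q) / q) <= 1e-8

    def test_field_scaling_b0_squared(self):
        basis, psi = synthetic_basis(4, (2, 2, 2))
        m1 = uisnr_map(basis, psi, FieldSpec(B0=1.0), reduced=True)
        m7 = uisnr_map(basis, psi, FieldSpec(B0=7.0), reduced=True)
        np.testing.assert_allclose(m7.values, 49.0 * m1.values, rtol=1e-12)

    def test_absolute_map_prefactor(self):
        basis, psi = synthetic_basis(3, (2, 2, 2))
        spec = FieldSpec(B0=3.0)
        const = UiSNRConstants()
        red = uisnr_map(basis, psi, spec, const, reduced=True)
        absolute = uisnr_map(basis, psi, spec, const, reduced=False,
                             voxel_volume=1e-6)
        gamma = 2 * np.pi * spec.gamma_over_2pi
        m0 = const.rho * gamma ** 2 * const.hbar ** 2 * spec.B0 \
            / (4 * const.k_b * const.T)
        pref = spec.omega * m0 * 1e-6 / np.sqrt(
            4 * const.k_b * const.T * const.delta_f)
        np.testing.assert_allclose(absolute.values,
                                   pref * red.values / spec.B0 ** 2,
                                   rtol=1e-12)

    def test_air_masked_to_nan(self):
        basis, psi = synthetic_basis(3, (3, 3, 3))
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        m = uisnr_map(basis, psi, FieldSpec(B0=3.0), body_mask=mask)
        assert np.isfinite(m.values[1, 1, 1])
        assert np.isnan(m.values[0, 0, 0])


class TestConvergenceCurve:
    def test_monotone_along_prefixes(self):
        basis, psi = synthetic_basis(8, (2, 2, 2), seed=7)
        curve = convergence_curve(basis, psi, (1, 1, 1),
                                  FieldSpec(B0=3.0),
                                  subset_sizes=(1, 2, 4, 6, 8))
        diffs = np.diff(curve)
        assert np.all(diffs >= -1e-9 * curve[:-1])

    def test_duplicate_element_changes_nothing(self):
        basis, psi = synthetic_basis(4, (2, 2, 2), seed=9)
        dup_b1 = np.concatenate([basis.b1minus, basis.b1minus[-1:]])
        dup = FieldBasis(e_fields=np.zeros((5, 2, 2, 2, 3),
                                           dtype=complex),
                         b1minus=dup_b1,
                         excitations=np.zeros((5, 1), dtype=complex),
                         frequency=basis.frequency, seed=basis.seed)
        psi5 = np.zeros((5, 5), dtype=complex)
        psi5[:4, :4] = psi.psi
        psi5[4, :4] = psi.psi[3]
        psi5[:4, 4] = psi.psi[:, 3]
        psi5[4, 4] = psi.psi[3, 3]
        psi_dup = NoiseCovariance(psi=psi5)
        q4 = quadratic_form_map(basis, psi, 4)
        q5 = quadratic_form_map(dup, psi_dup, 5)
        np.testing.assert_allclose(q5, q4, rtol=1e-8)

    def test_matches_per_size_maps(self):
        basis, psi = synthetic_basis(6, (3, 3, 3), seed=11)
        spec = FieldSpec(B0=7.0)
        sizes = (1, 3, 6)
        curve = convergence_curve(basis, psi, (2, 1, 0), spec, sizes)
        for s, v in zip(sizes, curve):
            m = uisnr_map(basis, psi, spec, n_use=s)
            assert v == pytest.approx(m.values[2, 1, 0], rel=1e-12)


class TestConvergenceMask:
    def _map(self, values, b0, n):
        return UiSNRMap(values=np.asarray(values, dtype=float), B0=b0,
                        n_basis_used=n, reduced=True)

    def test_identical_maps_all_converged(self):
        v = np.abs(np.random.default_rng(0).standard_normal((3, 3, 3)))
        pairs = {1.5: (self._map(v, 1.5, 48), self._map(v, 1.5, 46))}
        out = convergence_mask(pairs, threshold=1.0)
        assert np.all(out.mask)
        np.testing.assert_allclose(out.percent_change, 0.0)

    def test_two_percent_change_excluded_at_one_percent(self):
        base = np.ones((2, 2, 2))
        full = base.copy()
        full[0, 0, 0] = 1.02  # ~1.96% change relative to S_N
        pairs = {3.0: (self._map(full, 3.0, 48), self._map(base, 3.0, 46))}
        out = convergence_mask(pairs, threshold=1.0)
        assert not out.mask[0, 0, 0]
        assert out.mask[1, 1, 1]
        assert out.percent_change[0, 0, 0] == pytest.approx(
            100 * 0.02 / 1.02, rel=1e-9)

    def test_joint_over_all_field_strengths(self):
        base = np.ones((2, 2, 2))
        bad_at_7t = base.copy()
        bad_at_7t[1, 0, 1] = 1.05
        pairs = {
            1.5: (self._map(base, 1.5, 48), self._map(base, 1.5, 46)),
            7.0: (self._map(bad_at_7t, 7.0, 48),
                  self._map(base, 7.0, 46)),
        }
        out = convergence_mask(pairs, threshold=1.0)
        assert not out.mask[1, 0, 1]
        assert out.mask.sum() == 7

    def test_zero_snr_voxel_excluded(self):
        full = np.ones((2, 2, 2))
        full[0, 1, 0] = 0.0
        pairs = {3.0: (self._map(full, 3.0, 48),
                       self._map(full, 3.0, 46))}
        out = convergence_mask(pairs)
        assert not out.mask[0, 1, 0]


class TestNormalizeMap:
    def _map(self, values, b0=0.55):
        return UiSNRMap(values=np.asarray(values, dtype=float), B0=b0,
                        n_basis_used=48, reduced=True)

    def test_self_normalization_min_one(self):
        v = np.array([[[2.0, 5.0], [3.0, 9.0]],
                      [[4.0, 7.0], [6.0, 8.0]]])
        m = self._map(v)
        out = normalize_map(m, m, np.ones(v.shape, dtype=bool))
        assert out.values.min() == pytest.approx(1.0)

    def test_linear_in_input(self):
        v = np.array([[[2.0, 5.0]]])
        ref = self._map(v)
        out1 = normalize_map(self._map(v), ref, np.ones_like(v, bool))
        out10 = normalize_map(self._map(10 * v), ref,
                              np.ones_like(v, bool))
        np.testing.assert_allclose(out10.values, 10 * out1.values)

    def test_two_level_dynamic_range(self):
        v = np.array([[[3.0, 12.0]]])
        out = normalize_map(self._map(v), self._map(v),
                            np.ones_like(v, bool))
        assert out.values.max() == pytest.approx(4.0)

    def test_empty_mask_raises(self):
        v = np.ones((1, 1, 2))
        with pytest.raises(ValueError):
            normalize_map(self._map(v), self._map(v),
                          np.zeros_like(v, bool))
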