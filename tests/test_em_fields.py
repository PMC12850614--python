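"""Incident dipole fields, VIE solves and receive-field extraction."""

import numpy as np
import pytest

from uisnr.dipole_cloud import DipoleCloud
from uisnr.em_fields import (FieldVolume, SolverSettings, VIEProblem,
                             compute_b1minus, incident_fields, scattered_b,
                             vie_solve)
from uisnr.greens import self_term, wavenumber
from uisnr.phantom import EPS0, MU0, DielectricVolumes, VoxelModel

from conftest import tiny_dielectrics

RNG = np.random.default_rng(42)


def _single_dipole_cloud(model, voxel_idx, kind, axis):
    """Cloud with one dipole (plus its 5 zero-weighted partners)."""
    idx = np.array([voxel_idx])
    from uisnr.dipole_cloud import _dipoles_for_voxels
    positions, kinds, axes = _dipoles_for_voxels(model, idx)
    return DipoleCloud(positions=positions, kinds=kinds, axes=axes,
                       shell_voxel_indices=idx, d_min=0.01, d_max=0.02)


def _textbook_dipole_e(rvec, frequency, axis_vec):
    """Independent oracle: Hertzian dipole E in spherical components.

    E_r = eta Il cos(t)/(2 pi r^2) (1 + 1/(jkr)) e^{-jkr}
    E_t = j eta k Il sin(t)/(4 pi r) (1 + 1/(jkr) - 1/(kr)^2) e^{-jkr}
    """
    k = wavenumber(frequency)
    eta = np.sqrt(MU0 / EPS0)
    r = np.linalg.norm(rvec)
    rhat = rvec / r
    cos_t = rhat @ axis_vec
    theta_hat = cos_t * rhat - axis_vec
    norm = np.linalg.norm(theta_hat)
    phase = np.exp(-1j * k * r)
    e_r = eta * cos_t / (2 * np.pi * r ** 2) * (1 + 1 / (1j * k * r)) \
        * phase
    e_t = 1j * eta * k * np.sqrt(max(1 - cos_t ** 2, 0.0)) \
        / (4 * np.pi * r) * (1 + 1 / (1j * k * r) - 1 / (k * r) ** 2) \
        * phase
    field = e_r * rhat
    if norm > 0:
        field = field + e_t * theta_hat / norm
    return field


class TestIncidentFields:
    @pytest.fixture()
    def air_model(self, saline):
        labels = np.zeros((9, 9, 9), dtype=np.int32)
        labels[4, 4, 4] = saline.tissue_id  # token body far from dipole
        return VoxelModel(labels=labels, voxel_size=0.01,
                          tissue_table={saline.tissue_id: saline})

    def test_zero_weights_zero_fields(self, air_model):
        cloud = _single_dipole_cloud(air_model, (0, 0, 0), 0, 0)
        out = incident_fields(cloud, np.zeros(6, dtype=complex),
                              air_model, 128e6)
        assert np.all(out.E == 0) and np.all(out.B == 0)

    @pytest.mark.parametrize("axis", [0, 1, 2])
    def test_single_electric_dipole_matches_textbook(self, air_model,
                                                     axis):
        cloud = _single_dipole_cloud(air_model, (1, 1, 1), 0, axis)
        w = np.zeros(6, dtype=complex)
        w[axis] = 1.0  # unit electric dipole along `axis`
        out = incident_fields(cloud, w, air_model, 128e6)
        src = air_model.voxel_centers(np.array([[1, 1, 1]]))[0]
        axis_vec = np.eye(3)[axis]
        # one axial and one oblique far-ish point
        for obs_idx in ((1, 1, 7), (7, 6, 2)):
            obs = air_model.voxel_centers(np.array([obs_idx]))[0]
            expect = _textbook_dipole_e(obs - src, 128e6, axis_vec)
            got = out.E[obs_idx]
            np.testing.assert_allclose(got, expect, rtol=1e-10,
                                       atol=1e-12 * np.abs(expect).max())

    def test_linearity_in_weights(self, air_model):
        cloud = _single_dipole_cloud(air_model, (1, 2, 3), 0, 0)
        w = RNG.standard_normal(6) + 1j * RNG.standard_normal(6)
        a = incident_fields(cloud, w, air_model, 128e6)
        b = incident_fields(cloud, 2.0 * w, air_model, 128e6)
        np.testing.assert_allclose(b.E, 2.0 * a.E, rtol=1e-12)
        np.testing.assert_allclose(b.B, 2.0 * a.B, rtol=1e-12)


class TestVIESolve:
    def test_zero_contrast_identity(self):
        shape = (5, 5, 5)
        diel = DielectricVolumes(eps_r=np.ones(shape),
                                 sigma=np.zeros(shape),
                                 frequency=128e6, voxel_size=0.005)
        e = RNG.standard_normal(shape + (3,)) \
            + 1j * RNG.standard_normal(shape + (3,))
        inc = FieldVolume(E=e, B=None, frequency=128e6)
        for backend in ("dense", "fft_iterative"):
            out = vie_solve(diel, inc, SolverSettings(backend=backend))
            assert np.abs(out.E - e).max() <= 1e-12 * np.abs(e).max()

    def test_single_voxel_scatterer_closed_form(self):
        shape = (5, 5, 5)
        diel = tiny_dielectrics(shape, 60.0, 0.7,
                                body=(slice(2, 3),) * 3)
        chi = diel.contrast()[2, 2, 2]
        g_self = self_term(wavenumber(diel.frequency),
                           diel.voxel_size ** 3)
        e = RNG.standard_normal(shape + (3,)) \
            + 1j * RNG.standard_normal(shape + (3,))
        inc = FieldVolume(E=e, B=None, frequency=diel.frequency)
        for backend in ("dense", "fft_iterative"):
            out = vie_solve(diel, inc,
                            SolverSettings(backend=backend,
                                           rel_tolerance=1e-12))
            expect = e[2, 2, 2] / (1.0 - g_self * chi)
            np.testing.assert_allclose(out.E[2, 2, 2], expect, rtol=1e-9)

    def test_dense_vs_fft_on_heterogeneous_body(self):
        shape = (7, 7, 7)
        rng = np.random.default_rng(3)
        eps = np.ones(shape)
        sig = np.zeros(shape)
        eps[1:6, 1:6, 1:6] = rng.uniform(2, 70, (5, 5, 5))
        sig[1:6, 1:6, 1:6] = rng.uniform(0.1, 1.0, (5, 5, 5))
        diel = DielectricVolumes(eps_r=eps, sigma=sig, frequency=298e6,
                                 voxel_size=0.01)
        e = rng.standard_normal(shape + (3,)) \
            + 1j * rng.standard_normal(shape + (3,))
        inc = FieldVolume(E=e, B=None, frequency=298e6)
        rtol = 1e-10
        dense = vie_solve(diel, inc, SolverSettings(backend="dense"))
        fft = vie_solve(diel, inc,
                        SolverSettings(backend="fft_iterative",
                                       rel_tolerance=rtol,
                                       max_iterations=5000))
        err = np.abs(dense.E - fft.E).max() / np.abs(dense.E).max()
        assert err <= 10 * rtol

    def test_operator_equivalence_dense_vs_fft_apply(self):
        """Dense matrix rows and FFT operator agree to 1e-10."""
        shape = (6, 6, 6)
        rng = np.random.default_rng(4)
        eps = np.ones(shape)
        sig = np.zeros(shape)
        eps[1:5, 1:5, 1:5] = rng.uniform(2, 60, (4, 4, 4))
        sig[1:5, 1:5, 1:5] = rng.uniform(0.0, 1.0, (4, 4, 4))
        diel = DielectricVolumes(eps_r=eps, sigma=sig, frequency=447e6,
                                 voxel_size=0.008)
        x = rng.standard_normal(shape + (3,)) \
            + 1j * rng.standard_normal(shape + (3,))
        # FFT application of I - G chi restricted to body
        prob_fft = VIEProblem(diel,
                              SolverSettings(backend="fft_iterative"))
        sl, box_shape, op, apply = prob_fft._fft_operator()
        y_fft = apply(x[sl].reshape(-1)).reshape(box_shape + (3,))
        # dense application via explicit matrix rebuilt independently
        prob2 = VIEProblem(diel, SolverSettings(backend="dense"))
        y_dense = _dense_apply(prob2, x)
        err = np.abs(y_fft[prob_fft.body[sl]]
                     - y_dense[prob2.body]).max()
        scale = np.abs(y_dense[prob2.body]).max()
        assert err <= 1e-10 * scale

    def test_solve_linearity(self):
        shape = (6, 6, 6)
        diel = tiny_dielectrics(shape, 40.0, 0.5)
        e = RNG.standard_normal(shape + (3,)) \
            + 1j * RNG.standard_normal(shape + (3,))
        inc = FieldVolume(E=e, B=None, frequency=diel.frequency)
        inc2 = FieldVolume(E=(0.3 - 2j) * e, B=None,
                           frequency=diel.frequency)
        s = SolverSettings(backend="dense")
        a = vie_solve(diel, inc, s)
        b = vie_solve(diel, inc2, s)
        np.testing.assert_allclose(b.E, (0.3 - 2j) * a.E, rtol=1e-9)

    def test_dissipated_power_nonnegative(self):
        shape = (6, 6, 6)
        diel = tiny_dielectrics(shape, 50.0, 0.8)
        e = RNG.standard_normal(shape + (3,)) \
            + 1j * RNG.standard_normal(shape + (3,))
        inc = FieldVolume(E=e, B=None, frequency=diel.frequency)
        out = vie_solve(diel, inc, SolverSettings(backend="dense"))
        power = np.sum(diel.sigma[..., None] * np.abs(out.E) ** 2) \
            * diel.voxel_size ** 3
        assert power >= 0.0


def _dense_apply(prob, x):
    """Apply I - K chi via an independently assembled coupling sum."""
    from uisnr.greens import dyadic_green

    body_idx = np.argwhere(prob.body)
    pos = body_idx.astype(float) * prob.diel.voxel_size
    chi_b = prob.chi[prob.body]
    xb = x[prob.body]
    out = np.empty_like(xb)
    scale = prob.k ** 2 * prob.dv
    for m in range(len(pos)):
        rvec = pos[m] - pos
        r = np.linalg.norm(rvec, axis=1)
        sel = r > 0
        g = dyadic_green(rvec[sel], prob.k)
        coup = scale * np.einsum("nij,nj->i", g, chi_b[sel, None] * xb[sel])
        coup = coup + prob.g_self * chi_b[m] * xb[m]
        out[m] = xb[m] - coup
    full = np.zeros_like(x)
    full[prob.body] = out
    return full


class TestScatteredB:
    def test_zero_contrast_zero_bsc(self):
        shape = (5, 5, 5)
        diel = DielectricVolumes(eps_r=np.ones(shape),
                                 sigma=np.zeros(shape),
                                 frequency=128e6, voxel_size=0.005)
        e = RNG.standard_normal(shape + (3,)) \
            + 1j * RNG.standard_normal(shape + (3,))
        out = scattered_b(diel, FieldVolume(E=e, B=None, frequency=128e6))
        assert np.all(out.B == 0)

    def test_single_current_voxel_matches_point_element(self):
        shape = (7, 7, 7)
        diel = tiny_dielectrics(shape, 55.0, 0.6,
                                body=(slice(3, 4),) * 3)
        e = np.zeros(shape + (3,), dtype=complex)
        e[3, 3, 3] = [1.0 + 0.5j, -0.2j, 0.7]
        out = scattered_b(diel, FieldVolume(E=e, B=None,
                                            frequency=diel.frequency))
        # oracle: B of a point current element Il = J_eq dV
        omega = diel.omega
        chi = diel.contrast()[3, 3, 3]
        j_eq = 1j * omega * EPS0 * chi * e[3, 3, 3] * diel.voxel_size ** 3
        k = wavenumber(diel.frequency)
        rvec = (np.array([6, 5, 1]) - 3) * diel.voxel_size
        r = np.linalg.norm(rvec)
        g = np.exp(-1j * k * r) / (4 * np.pi * r)
        expect = -MU0 * (1 + 1j * k * r) * g / r \
            * np.cross(rvec / r, j_eq)
        np.testing.assert_allclose(out.B[6, 5, 1], expect, rtol=1e-10)

    def test_linearity_in_e(self):
        shape = (6, 6, 6)
        diel = tiny_dielectrics(shape, 30.0, 0.4)
        e = RNG.standard_normal(shape + (3,)) \
            + 1j * RNG.standard_normal(shape + (3,))
        a = scattered_b(diel, FieldVolume(E=e, B=None,
                                          frequency=diel.frequency))
        b = scattered_b(diel, FieldVolume(E=(2 - 1j) * e, B=None,
                                          frequency=diel.frequency))
        np.testing.assert_allclose(b.B, (2 - 1j) * a.B, rtol=1e-12)


class TestB1Minus:
    @pytest.mark.parametrize("b_vec,expect", [
        ([1.0, 0.0, 0.0], 0.5),
        ([0.0, 1j, 0.0], 0.5),
        ([0.0, 0.0, 3.7], 0.0),
    ])
    def test_closed_forms(self, b_vec, expect):
        b = np.broadcast_to(np.array(b_vec, dtype=complex),
                            (4, 4, 4, 3))
        out = compute_b1minus(b)
        np.testing.assert_allclose(out, expect)
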