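"""Free-space dyadic Green's function kernels and grid convolutions.

Everything here uses the exp(+j omega t) time convention, so the outgoing
scalar Green's function is ``g(r) = exp(-j k r) / (4 pi r)``.

Two translation-invariant kernels cover all field evaluations on a
regular voxel grid:

* the **dyadic** kernel ``G(R) = (I + grad grad / k^2) g(R)``, which maps
  electric dipole moments to E fields (up to ``-j omega mu0``) and
  magnetic dipole moments to B fields (up to ``mu0 k^2``);
* the **cross** kernel ``X(R) v = F(R) (R_hat x v)`` with
  ``F(R) = (1 + j k r) g(r) / r``, which maps electric dipole moments /
  volume currents to B fields (up to ``-mu0``) and magnetic moments to E
  fields (up to ``+j omega mu0``).

Because both kernels depend only on the voxel-offset vector, applying
them over a regular grid is a block-Toeplitz matrix-vector product,
evaluated exactly by zero-padded FFT circular convolution
(:class:`GridKernels`). The zero-offset dyadic entry is excluded from the
convolution and added separately: for incident-field evaluation it is
irrelevant (sources are disjoint from observation voxels), while for the
volume integral equation it is the analytic equal-volume-sphere self term
:func:`self_term`.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as spfft

from .phantom import EPS0, MU0


def wavenumber(frequency: float) -> float:
    """Free-space wavenumber k0 = omega * sqrt(mu0 eps0), rad/m."""
    return 2.0 * np.pi * frequency * np.sqrt(MU0 * EPS0)


def scalar_green(r: np.ndarray, k: float) -> np.ndarray:
    """g(r) = exp(-j k r) / (4 pi r)."""
    return np.exp(-1j * k * r) / (4.0 * np.pi * r)


def dyadic_green(rvec: np.ndarray, k: float) -> np.ndarray:
    """Dyadic Green's function G(R) as (..., 3, 3) for offsets (..., 3).

    G = g(r) [ C1 I + C2 r_hat r_hat ] with
    C1 = 1 - j/(kr) - 1/(kr)^2 and C2 = -1 + 3j/(kr) + 3/(kr)^2.
    Singular at R = 0 (caller must exclude zero offsets).
    """
    rvec = np.asarray(rvec, dtype=float)
    r = np.linalg.norm(rvec, axis=-1)
    if np.any(r == 0):
        raise ValueError("dyadic_green is singular at zero offset")
    g = scalar_green(r, k)
    ikr = 1.0 / (k * r)
    c1 = 1.0 - 1j * ikr - ikr ** 2
    c2 = -1.0 + 3j * ikr + 3.0 * ikr ** 2
    rhat = rvec / r[..., None]
    eye = np.eye(3)
    return (g * c1)[..., None, None] * eye \
        + (g * c2)[..., None, None] * (rhat[..., :, None]
                                       * rhat[..., None, :])


def curl_factor(r: np.ndarray, k: float) -> np.ndarray:
    """F(r) = (1 + j k r) g(r) / r, the scalar of the cross kernel."""
    return (1.0 + 1j * k * r) * scalar_green(r, k) / r


def self_term(k: float, voxel_volume: float) -> complex:
    """Analytic dyadic self-coupling of a voxel (equal-volume sphere).

    For a uniformly polarized sphere of equal volume, the scattered field
    at its center is ``g_self * chi * E`` with

        g_self = (2/3) (1 + j k a) exp(-j k a) - 1,
        a = (3 dV / 4 pi)^(1/3).

    The static limit is -1/3, the depolarization factor of a sphere, so a
    single-voxel scatterer solves to E_tot = E_inc / (1 - g_self chi).
    """
    a = (3.0 * voxel_volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    ka = k * a
    return (2.0 / 3.0) * (1.0 + 1j * ka) * np.exp(-1j * ka) - 1.0


# ---------------------------------------------------------------------------
# point-dipole closed forms (unit moment), used to seed the kernels and as
# the reference implementation for dense assembly
# ---------------------------------------------------------------------------

def electric_dipole_e(rvec: np.ndarray, k: float, frequency: float,
                      axis_vec: np.ndarray) -> np.ndarray:
    """E field (V/m) of a unit electric dipole (Il = 1 A m) along axis_vec."""
    omega = 2.0 * np.pi * frequency
    return -1j * omega * MU0 * np.einsum(
        "...ij,j->...i", dyadic_green(rvec, k), axis_vec)


def electric_dipole_b(rvec: np.ndarray, k: float,
                      axis_vec: np.ndarray) -> np.ndarray:
    """B field (T) of a unit electric dipole (Il = 1 A m) along axis_vec."""
    r = np.linalg.norm(rvec, axis=-1)
    rhat = rvec / r[..., None]
    return -MU0 * curl_factor(r, k)[..., None] * np.cross(rhat, axis_vec)


def magnetic_dipole_b(rvec: np.ndarray, k: float,
                      axis_vec: np.ndarray) -> np.ndarray:
    """B field (T) of a unit magnetic dipole (m = 1 A m^2) along axis_vec."""
    return MU0 * k ** 2 * np.einsum(
        "...ij,j->...i", dyadic_green(rvec, k), axis_vec)


def magnetic_dipole_e(rvec: np.ndarray, k: float, frequency: float,
                      axis_vec: np.ndarray) -> np.ndarray:
    """E field (V/m) of a unit magnetic dipole (m = 1 A m^2) along axis_vec."""
    omega = 2.0 * np.pi * frequency
    r = np.linalg.norm(rvec, axis=-1)
    rhat = rvec / r[..., None]
    return 1j * omega * MU0 * curl_factor(r, k)[..., None] \
        * np.cross(rhat, axis_vec)


# ---------------------------------------------------------------------------
# FFT block-Toeplitz application
# ---------------------------------------------------------------------------

class GridKernels:
    """Precomputed FFTs of the dyadic and cross kernels on a voxel grid.

    Supports exact block-Toeplitz products: ``conv_dyadic(S)[m] =
    sum_{n != m} G(R_mn) . S[n]`` and likewise ``conv_cross`` for the
    cross kernel, for any 3-component source grid ``S`` of the given
    shape. Zero-offset contributions are excluded; callers add self terms
    explicitly where the physics requires them.
    """

    def __init__(self, shape: tuple[int, int, int], voxel_size: float,
                 k: float):
        self.shape = tuple(shape)
        self.voxel_size = float(voxel_size)
        self.k = float(k)
        self._pad = tuple(spfft.next_fast_len(2 * n - 1) for n in self.shape)

        offs = []
        for n, p in zip(self.shape, self._pad):
            ax = np.arange(p)
            ax = np.where(ax < n, ax, ax - p)  # wrap to signed offsets
            # offsets beyond +-(n-1) are never touched by valid index
            # differences; their kernel values are zeroed below
            offs.append(ax.astype(float) * voxel_size)
        ox, oy, oz = np.meshgrid(*offs, indexing="ij")
        r = np.sqrt(ox ** 2 + oy ** 2 + oz ** 2)
        valid = np.ones(self._pad, dtype=bool)
        for dim, (n, p) in enumerate(zip(self.shape, self._pad)):
            ax = np.arange(p)
            off_idx = np.where(ax < n, ax, ax - p)
            bad = np.abs(off_idx) > n - 1
            sl = [None] * 3
            sl[dim] = slice(None)
            valid &= ~bad[tuple(sl)]
        origin = r == 0.0
        r_safe = np.where(origin, 1.0, r)

        g = scalar_green(r_safe, k)
        ikr = 1.0 / (k * r_safe)
        c1 = g * (1.0 - 1j * ikr - ikr ** 2)
        c2 = g * (-1.0 + 3j * ikr + 3.0 * ikr ** 2)
        f = curl_factor(r_safe, k)
        mask = valid & ~origin
        rh = [np.where(origin, 0.0, o / r_safe) for o in (ox, oy, oz)]

        def _fft(arr):
            arr = np.where(mask, arr, 0.0)
            return spfft.fftn(arr)

        # six unique dyadic components (G is symmetric)
        self._ghat = {}
        for (i, j) in ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)):
            comp = c2 * rh[i] * rh[j]
            if i == j:
                comp = comp + c1
            self._ghat[(i, j)] = _fft(comp)
        # three cross-kernel components F * R_hat
        self._xhat = [_fft(f * rh[i]) for i in range(3)]

    def _fft_source(self, source: np.ndarray) -> list[np.ndarray]:
        nx, ny, nz = self.shape
        out = []
        for c in range(3):
            buf = np.zeros(self._pad, dtype=complex)
            buf[:nx, :ny, :nz] = source[..., c]
            out.append(spfft.fftn(buf))
        return out

    def _crop(self, spec: np.ndarray) -> np.ndarray:
        nx, ny, nz = self.shape
        return spfft.ifftn(spec)[:nx, :ny, :nz]

    def conv_dyadic(self, source: np.ndarray) -> np.ndarray:
        """sum_n G(R_mn) . S[n] over the grid (zero offset excluded)."""
        shat = self._fft_source(source)
        out = np.empty(self.shape + (3,), dtype=complex)
        for i in range(3):
            acc = 0.0
            for j in range(3):
                key = (i, j) if i <= j else (j, i)
                acc = acc + self._ghat[key] * shat[j]
            out[..., i] = self._crop(acc)
        return out

    def conv_cross(self, source: np.ndarray) -> np.ndarray:
        """sum_n F(R_mn) (R_hat_mn x S[n]) over the grid."""
        shat = self._fft_source(source)
        ax, ay, az = self._xhat
        out = np.empty(self.shape + (3,), dtype=complex)
        out[..., 0] = self._crop(ay * shat[2] - az * shat[1])
        out[..., 1] = self._crop(az * shat[0] - ax * shat[2])
        out[..., 2] = self._crop(ax * shat[1] - ay * shat[0])
        return out
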