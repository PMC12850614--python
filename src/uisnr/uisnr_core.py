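"""Per-voxel ultimate intrinsic SNR, convergence curves and masking.

With ``b(r)`` the vector of basis receive sensitivities B1-_i(r) and
``Psi`` the noise covariance, the optimal-combination quadratic form

    q(r) = b(r)^H Psi^{-1} b(r)

is the largest generalized Rayleigh quotient |w^H b|^2 / (w^H Psi w)
over all coil weightings w: the best signal-to-noise power any receive
array built from the basis span can reach at r. The uiSNR itself is

    uiSNR(r) = omega M0 dV sqrt(q(r)) / sqrt(4 k_B T df),
    M0 = rho gamma^2 hbar^2 B0 / (4 k_B T)   (spin-1/2),

with proton density rho held constant (spatial variations of rho are
deliberately not modeled). Both omega and M0 are proportional to B0, so
the B0-dependent part of the uiSNR reduces to ``B0^2 sqrt(q(r))`` — the
"reduced" map used throughout the scaling analysis.

Psi is inverted by Hermitian eigendecomposition with a relative
eigenvalue floor (random bases become numerically rank-deficient before
N reaches the subspace dimension); the floor makes q monotone in the
basis size up to regularization tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .basis_noise import FieldBasis, NoiseCovariance
from .phantom import FieldSpec

K_BOLTZMANN = 1.380649e-23   # J/K
HBAR = 1.054571817e-34       # J s


@dataclass(frozen=True)
class UiSNRConstants:
    """Physical constants of the absolute uiSNR prefactor.

    None of these affect the B0 scaling exponents (they cancel in
    ratios); defaults are body temperature, unit bandwidth and unit
    proton density.
    """

    k_b: float = K_BOLTZMANN
    T: float = 310.0
    delta_f: float = 1.0
    hbar: float = HBAR
    rho: float = 1.0

    def __post_init__(self):
        if self.T <= 0 or self.delta_f <= 0:
            raise ValueError("T and delta_f must be positive")


@dataclass
class UiSNRMap:
    """Per-voxel uiSNR values at one field strength.

    ``reduced=True`` means the B0^2 sqrt(q) form (arbitrary units but
    consistent across field strengths); air voxels are NaN.
    """

    values: np.ndarray
    B0: float
    n_basis_used: int
    reduced: bool

    def __post_init__(self):
        finite = np.isfinite(self.values)
        if np.any(self.values[finite] < 0):
            raise ValueError("uiSNR values must be nonnegative")


@dataclass
class ConvergenceMask:
    """Voxels where growing the basis no longer moves the SNR estimate."""

    mask: np.ndarray
    percent_change: np.ndarray
    threshold: float
    delta_n: int


def _psi_pinv_factor(psi: NoiseCovariance, n_use: int) -> np.ndarray:
    """Factor W with Psi_n^+ = W W^H, via eigendecomposition + floor."""
    block = psi.psi[:n_use, :n_use]
    evals, evecs = np.linalg.eigh(block)
    if evals.size == 0 or evals.max() <= 0:
        raise np.linalg.LinAlgError(
            f"noise covariance block of size {n_use} has no positive "
            "eigenvalue (all-zero conductivity?)")
    floor = psi.regularization_floor * evals.max()
    keep = evals > floor
    if not keep.any():
        raise np.linalg.LinAlgError(
            f"noise covariance block of size {n_use} is singular beyond "
            "the regularization floor")
    return evecs[:, keep] / np.sqrt(evals[keep])


def quadratic_form_map(basis: FieldBasis, psi: NoiseCovariance,
                       n_use: int | None = None) -> np.ndarray:
    """q(r) = b^H Psi^+ b over the grid for the leading ``n_use`` block."""
    n = basis.n_elements if n_use is None else int(n_use)
    if not (1 <= n <= basis.n_elements):
        raise ValueError("n_use must lie in [1, N]")
    if psi.n < n:
        raise ValueError("psi smaller than requested block")
    w = _psi_pinv_factor(psi, n)            # (n, r)
    b = basis.b1minus[:n].reshape(n, -1)    # (n, nvox)
    proj = w.conj().T @ b                   # (r, nvox)
    q = np.einsum("ij,ij->j", proj, proj.conj()).real
    return np.maximum(q, 0.0).reshape(basis.grid_shape)


def uisnr_map(basis: FieldBasis, psi: NoiseCovariance, spec: FieldSpec,
              constants: UiSNRConstants | None = None,
              n_use: int | None = None, reduced: bool = True,
              body_mask: np.ndarray | None = None,
              voxel_volume: float = 1.0) -> UiSNRMap:
    """uiSNR map from the basis and its noise covariance.

    ``reduced=True`` returns ``B0^2 sqrt(q(r))``, the B0-dependent part
    used for scaling analysis; otherwise the absolute form
    ``omega M0 dV sqrt(q) / sqrt(4 k_B T df)`` with ``dV =
    voxel_volume``. Air voxels (where ``body_mask`` is False) are NaN.
    """
    constants = constants or UiSNRConstants()
    n = basis.n_elements if n_use is None else int(n_use)
    q = quadratic_form_map(basis, psi, n)
    root = np.sqrt(q)
    if reduced:
        values = spec.B0 ** 2 * root
    else:
        gamma = 2.0 * np.pi * abs(spec.gamma_over_2pi)
        m0 = constants.rho * gamma ** 2 * constants.hbar ** 2 * spec.B0 \
            / (4.0 * constants.k_b * constants.T)
        prefac = spec.omega * m0 * voxel_volume / np.sqrt(
            4.0 * constants.k_b * constants.T * constants.delta_f)
        values = prefac * root
    if body_mask is not None:
        values = np.where(body_mask, values, np.nan)
    return UiSNRMap(values=values, B0=spec.B0, n_basis_used=n,
                    reduced=reduced)


def convergence_curve(basis: FieldBasis, psi: NoiseCovariance,
                      voxel: tuple[int, int, int], spec: FieldSpec,
                      subset_sizes: Sequence[int],
                      constants: UiSNRConstants | None = None,
                      reduced: bool = True) -> np.ndarray:
    """SNR at one voxel versus nested-prefix basis subset size.

    Subsets are leading prefixes in generation order, so the optimized
    subspaces are nested and the curve is non-decreasing up to
    regularization tolerance.
    """
    sizes = list(subset_sizes)
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("subset sizes must be strictly increasing")
    if sizes[-1] > basis.n_elements:
        raise ValueError("subset size exceeds basis size")
    out = np.empty(len(sizes))
    for i, n in enumerate(sizes):
        m = uisnr_map(basis, psi, spec, constants, n_use=n, reduced=reduced)
        out[i] = m.values[voxel]
    return out


def convergence_mask(
        maps_by_frequency: Mapping[float, tuple[UiSNRMap, UiSNRMap]],
        threshold: float = 1.0,
        body_mask: np.ndarray | None = None) -> ConvergenceMask:
    """Mask of voxels converged at every simulated field strength.

    ``maps_by_frequency`` pairs, per B0, the map at the full basis size N
    with the map at N - delta_N. The per-voxel percent change
    ``100 |S_N - S_{N-dN}| / S_N`` is maximized over field strengths and
    compared against ``threshold`` (percent). Voxels with S_N = 0 are
    excluded from the mask.
    """
    if not maps_by_frequency:
        raise ValueError("no map pairs supplied")
    pct = None
    delta_n = None
    zero_flag = None
    for b0, (m_full, m_prev) in maps_by_frequency.items():
        if m_full.values.shape != m_prev.values.shape:
            raise ValueError(f"map grids differ at B0={b0}")
        dn = m_full.n_basis_used - m_prev.n_basis_used
        if dn <= 0:
            raise ValueError("full map must use more basis elements")
        delta_n = dn if delta_n is None else delta_n
        with np.errstate(divide="ignore", invalid="ignore"):
            change = 100.0 * np.abs(m_full.values - m_prev.values) \
                / m_full.values
        zero = np.isfinite(m_full.values) & (m_full.values == 0.0)
        change = np.where(zero, np.inf, change)
        pct = change if pct is None else np.fmax(pct, change)
        zero_flag = zero if zero_flag is None else (zero_flag | zero)
    mask = np.isfinite(pct) & (pct <= threshold)
    if body_mask is not None:
        mask &= body_mask
    return ConvergenceMask(mask=mask, percent_change=pct,
                           threshold=float(threshold), delta_n=delta_n)


def normalize_map(m: UiSNRMap, reference: UiSNRMap,
                  mask: np.ndarray) -> UiSNRMap:
    """Normalize by the minimum of ``reference`` within ``mask``.

    With ``reference`` the lowest-field map, the voxel with the smallest
    reference uiSNR maps to exactly 1 and all values become
    dimensionless multiples of that minimum.
    """
    if not np.any(mask):
        raise ValueError("mask is empty")
    ref_vals = reference.values[mask]
    ref_min = np.nanmin(ref_vals)
    if not np.isfinite(ref_min) or ref_min <= 0:
        raise ValueError("reference minimum within mask is zero or "
                         "undefined")
    return UiSNRMap(values=m.values / ref_min, B0=m.B0,
                    n_basis_used=m.n_basis_used, reduced=m.reduced)
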