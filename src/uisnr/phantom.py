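"""Voxelized body phantoms with frequency-dependent dielectric properties.

This module is the synthetic-data stage of the pipeline: it generates
labeled 3-D voxel grids standing in for anatomical body models at desk
scale, and assigns each tissue its relative permittivity ``eps_r`` and
conductivity ``sigma`` (S/m) at the Larmor frequency of a given static
field strength B0.

Conventions used throughout the package:

* voxels are cell-centered; the physical position of voxel ``(i, j, k)``
  is ``origin + index * voxel_size`` (0-based indices, SI meters);
* label 0 is air (``eps_r = 1``, ``sigma = 0``); every phantom keeps at
  least a one-voxel air frame on all faces so that a dipole shell can be
  constructed around the body;
* z (axis 2) is the B0 axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (DegenerateGeometryError, DielectricLookupError,
                     GeometryError, PlacementError)
from .tissues import GAMMA_OVER_2PI_1H

EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m
MU0 = 1.25663706212e-6   # vacuum permeability, H/m

_FREQ_RTOL = 1e-6  # relative tolerance for "exact" frequency lookup


@dataclass(frozen=True)
class TissueDielectric:
    """Dielectric properties of one tissue class.

    ``frequencies`` may be ``None``, in which case ``eps_r`` and ``sigma``
    are scalars valid at every frequency (convenient for idealized
    phantoms such as saline with nominally flat dispersion).
    """

    tissue_id: int
    name: str
    eps_r: np.ndarray | float
    sigma: np.ndarray | float
    frequencies: np.ndarray | None = None

    def __post_init__(self):
        if self.frequencies is not None:
            f = np.asarray(self.frequencies, dtype=float)
            e = np.asarray(self.eps_r, dtype=float)
            s = np.asarray(self.sigma, dtype=float)
            if not (f.shape == e.shape == s.shape) or f.ndim != 1:
                raise ValueError("frequencies, eps_r, sigma must be "
                                 "1-D arrays of equal length")
            if np.any(np.diff(f) <= 0):
                raise ValueError("frequencies must be strictly increasing")
            object.__setattr__(self, "frequencies", f)
            object.__setattr__(self, "eps_r", e)
            object.__setattr__(self, "sigma", s)
            e_all, s_all = e, s
        else:
            e_all = np.atleast_1d(float(self.eps_r))
            s_all = np.atleast_1d(float(self.sigma))
        if np.any(e_all < 1.0):
            raise ValueError("eps_r must be >= 1 at all frequencies")
        if np.any(s_all < 0.0):
            raise ValueError("sigma must be >= 0 at all frequencies")
        if self.tissue_id == 0 and (np.any(e_all != 1.0)
                                    or np.any(s_all != 0.0)):
            raise ValueError("label 0 is reserved for air "
                             "(eps_r = 1, sigma = 0)")

    @classmethod
    def air(cls) -> "TissueDielectric":
        return cls(tissue_id=0, name="air", eps_r=1.0, sigma=0.0)

    @classmethod
    def constant(cls, tissue_id: int, name: str, eps_r: float,
                 sigma: float) -> "TissueDielectric":
        """Frequency-independent tissue (valid at every frequency)."""
        return cls(tissue_id=tissue_id, name=name, eps_r=eps_r, sigma=sigma)

    def _lookup(self, values: np.ndarray, frequency: float,
                interpolate: bool) -> float:
        if self.frequencies is None:
            return float(values)
        f = self.frequencies
        close = np.isclose(f, frequency, rtol=_FREQ_RTOL, atol=0.0)
        if close.any():
            return float(np.asarray(values)[close][0])
        if not interpolate:
            raise DielectricLookupError(
                f"tissue {self.name!r} has no entry at {frequency:.6g} Hz "
                "and interpolation is disabled")
        if frequency < f[0] or frequency > f[-1]:
            raise DielectricLookupError(
                f"frequency {frequency:.6g} Hz outside tabulated range "
                f"[{f[0]:.6g}, {f[-1]:.6g}] for tissue {self.name!r}")
        i = int(np.searchsorted(f, frequency)) - 1
        f0, f1 = f[i], f[i + 1]
        v0, v1 = np.asarray(values)[i], np.asarray(values)[i + 1]
        if v0 > 0 and v1 > 0:
            # log-log linear interpolation (smooth dispersion)
            t = np.log(frequency / f0) / np.log(f1 / f0)
            return float(np.exp(np.log(v0) + t * (np.log(v1) - np.log(v0))))
        t = (frequency - f0) / (f1 - f0)
        return float(v0 + t * (v1 - v0))

    def eps_at(self, frequency: float, interpolate: bool = False) -> float:
        """Relative permittivity at ``frequency`` (Hz)."""
        return self._lookup(self.eps_r, frequency, interpolate)

    def sigma_at(self, frequency: float, interpolate: bool = False) -> float:
        """Conductivity (S/m) at ``frequency`` (Hz)."""
        return self._lookup(self.sigma, frequency, interpolate)


@dataclass(frozen=True)
class FieldSpec:
    """Static field strength and the corresponding Larmor frequency."""

    B0: float
    gamma_over_2pi: float = GAMMA_OVER_2PI_1H

    def __post_init__(self):
        if self.B0 <= 0:
            raise ValueError("B0 must be positive")

    @property
    def frequency(self) -> float:
        """Larmor frequency gamma/2pi * B0, Hz."""
        return abs(self.gamma_over_2pi) * self.B0

    @property
    def omega(self) -> float:
        """Angular Larmor frequency, rad/s."""
        return 2.0 * np.pi * self.frequency


@dataclass
class VoxelModel:
    """Labeled 3-D voxel grid with tissue dielectric table.

    ``truncation_axis`` marks models that are axial cut-outs of a longer
    body (e.g. a torso section); it enables the circumferential dipole
    shell that stays clear of the truncation faces.
    """

    labels: np.ndarray
    voxel_size: float
    tissue_table: Mapping[int, TissueDielectric]
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    truncation_axis: int | None = None

    def __post_init__(self):
        self.labels = np.ascontiguousarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.tissue_table = dict(self.tissue_table)
        self.tissue_table.setdefault(0, TissueDielectric.air())
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.tissue_table)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from "
                             "tissue_table")
        if not self._has_air_frame():
            raise GeometryError("model must keep a one-voxel air frame "
                                "on every face")

    def _has_air_frame(self) -> bool:
        lab = self.labels
        return not (lab[0].any() or lab[-1].any() or lab[:, 0].any()
                    or lab[:, -1].any() or lab[:, :, 0].any()
                    or lab[:, :, -1].any())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume(self) -> float:
        """Voxel volume dV = voxel_size**3, m^3."""
        return self.voxel_size ** 3

    @property
    def body_mask(self) -> np.ndarray:
        return self.labels != 0

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        """Physical positions (m) of voxels given (n, 3) integer indices."""
        return self.origin + np.asarray(indices, dtype=float) * self.voxel_size


@dataclass(frozen=True)
class DielectricVolumes:
    """Per-voxel dielectric maps at one frequency.

    ``eps_r`` and ``sigma`` share the label-grid shape; air voxels carry
    (1, 0). The complex permittivity follows the exp(+j omega t) time
    convention: ``eps_c = eps0*eps_r - j*sigma/omega``.
    """

    eps_r: np.ndarray
    sigma: np.ndarray
    frequency: float
    voxel_size: float

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.frequency

    def contrast(self) -> np.ndarray:
        """Dielectric contrast chi = eps_c/eps0 - 1 (complex volume)."""
        return (self.eps_r - 1.0) - 1j * self.sigma / (self.omega * EPS0)


def larmor_frequency(B0: float, gamma_over_2pi: float = GAMMA_OVER_2PI_1H
                     ) -> float:
    """Larmor frequency ``gamma/2pi * B0`` in Hz.

    ``gamma_over_2pi`` may be negative (some nuclei precess the other
    way); the precession frequency magnitude is returned.
    """
    if B0 < 0:
        raise ValueError("B0 must be nonnegative")
    return abs(gamma_over_2pi) * B0


def make_sphere_phantom(radius: float, voxel_size: float,
                        tissue: TissueDielectric, *,
                        margin: float | None = None,
                        min_radius_voxels: float = 3.0) -> VoxelModel:
    """Homogeneous sphere phantom centered on a voxel center.

    Parameters
    ----------
    radius, voxel_size:
        Sphere radius and isotropic voxel edge, meters.
    margin:
        Air margin beyond the sphere surface on every face, meters.
        Defaults to 4 voxels; size it to at least the planned dipole-shell
        outer distance plus one voxel.
    min_radius_voxels:
        Guard against spheres too small for the grid; set to 0 to allow
        degenerate single-voxel phantoms.
    """
    if radius < min_radius_voxels * voxel_size:
        raise DegenerateGeometryError(
            f"radius {radius} m below {min_radius_voxels} voxels at "
            f"voxel_size {voxel_size} m")
    if margin is None:
        margin = 4.0 * voxel_size
    if margin < voxel_size:
        raise GeometryError("margin must be at least one voxel")
    half = int(np.ceil((radius + margin) / voxel_size))
    n = 2 * half + 1
    coords = (np.arange(n) - half) * voxel_size
    x, y, z = np.meshgrid(coords, coords, coords, indexing="ij")
    inside = x * x + y * y + z * z <= radius * radius
    labels = np.where(inside, tissue.tissue_id, 0).astype(np.int32)
    origin = np.array([-half * voxel_size] * 3)
    return VoxelModel(labels=labels, voxel_size=voxel_size,
                      tissue_table={tissue.tissue_id: tissue},
                      origin=origin)


@dataclass(frozen=True)
class OrganSpec:
    """Ellipsoidal organ placed inside a torso phantom.

    ``center`` is relative to the torso center (m); ``semiaxes`` are the
    ellipsoid half-axes (m).
    """

    tissue: TissueDielectric
    center: tuple[float, float, float]
    semiaxes: tuple[float, float, float]


def make_torso_phantom(rx: float, ry: float, length: float,
                       voxel_size: float, *,
                       body_tissue: TissueDielectric,
                       fat_tissue: TissueDielectric | None = None,
                       fat_thickness: float = 0.0,
                       organs: Sequence[OrganSpec] = (),
                       margin: float | None = None) -> VoxelModel:
    """Heterogeneous torso stand-in: elliptic cylinder + fat shell + organs.

    The outer body is an elliptic cylinder with semi-axes ``rx``, ``ry``
    in the transverse plane and extent ``length`` along z (the B0 axis).
    A lateral fat shell of ``fat_thickness`` lines the outer ellipse (the
    flat end faces are truncation cuts and carry no fat cap). Organs are
    ellipsoids labeled in listing order; later organs overwrite earlier
    ones where they overlap. The model is flagged as truncated along z.
    """
    if min(rx, ry) < 3 * voxel_size or length < 3 * voxel_size:
        raise DegenerateGeometryError("torso dimensions below 3 voxels")
    if fat_thickness > 0 and fat_tissue is None:
        raise ValueError("fat_tissue required when fat_thickness > 0")
    if fat_thickness >= min(rx, ry):
        raise GeometryError("fat shell consumes the whole cross-section")
    if margin is None:
        margin = 4.0 * voxel_size

    half_xy = np.ceil((np.array([rx, ry]) + margin) / voxel_size).astype(int)
    half_z = int(np.ceil((length / 2 + margin) / voxel_size))
    nx, ny = 2 * half_xy + 1
    nz = 2 * half_z + 1
    cx = (np.arange(nx) - half_xy[0]) * voxel_size
    cy = (np.arange(ny) - half_xy[1]) * voxel_size
    cz = (np.arange(nz) - half_z) * voxel_size
    x, y, z = np.meshgrid(cx, cy, cz, indexing="ij")

    in_z = np.abs(z) <= length / 2
    outer = ((x / rx) ** 2 + (y / ry) ** 2 <= 1.0) & in_z
    labels = np.zeros((nx, ny, nz), dtype=np.int32)
    if fat_thickness > 0:
        inner = (((x / (rx - fat_thickness)) ** 2
                  + (y / (ry - fat_thickness)) ** 2) <= 1.0) & in_z
        labels[outer] = fat_tissue.tissue_id
        labels[inner] = body_tissue.tissue_id
    else:
        labels[outer] = body_tissue.tissue_id

    table = {body_tissue.tissue_id: body_tissue}
    if fat_thickness > 0:
        table[fat_tissue.tissue_id] = fat_tissue
    body_any = outer
    for organ in organs:
        ox, oy, oz = organ.center
        ax, ay, az = organ.semiaxes
        inside = (((x - ox) / ax) ** 2 + ((y - oy) / ay) ** 2
                  + ((z - oz) / az) ** 2) <= 1.0
        if not inside.any():
            raise PlacementError(
                f"organ {organ.tissue.name!r} covers no voxel")
        if np.any(inside & ~body_any):
            raise PlacementError(
                f"organ {organ.tissue.name!r} extends outside the body")
        labels[inside] = organ.tissue.tissue_id
        table[organ.tissue.tissue_id] = organ.tissue

    origin = np.array([-half_xy[0], -half_xy[1], -half_z]) * voxel_size
    return VoxelModel(labels=labels, voxel_size=voxel_size,
                      tissue_table=table, origin=origin,
                      truncation_axis=2)


def assign_dielectrics(model: VoxelModel, spec: FieldSpec, *,
                       interpolate: bool = False) -> DielectricVolumes:
    """Per-voxel ``eps_r`` and ``sigma`` volumes at the Larmor frequency.

    Air voxels map to (1, 0). Raises :class:`DielectricLookupError` when a
    tissue has no entry at the requested frequency and ``interpolate`` is
    off; with ``interpolate=True``, values between tabulated frequencies
    are filled by log-log linear interpolation.
    """
    f = spec.frequency
    eps = np.ones(model.shape, dtype=float)
    sig = np.zeros(model.shape, dtype=float)
    for label in np.unique(model.labels):
        if label == 0:
            continue
        tissue = model.tissue_table[int(label)]
        sel = model.labels == label
        eps[sel] = tissue.eps_at(f, interpolate=interpolate)
        sig[sel] = tissue.sigma_at(f, interpolate=interpolate)
    return DielectricVolumes(eps_r=eps, sigma=sig, frequency=f,
                             voxel_size=model.voxel_size)


# ---------------------------------------------------------------------------
# import/export: NIfTI-1 label grid + CSV tissue table
# ---------------------------------------------------------------------------

_TISSUE_COLUMNS = ["tissue_id", "name", "frequency_Hz", "eps_r",
                   "sigma_S_per_m"]


def save_tissue_table(table: Mapping[int, TissueDielectric],
                      path: str | Path) -> None:
    """Write a tissue table as CSV with one row per (tissue, frequency).

    Frequency-independent tissues are written with an empty frequency
    field.
    """
    rows = []
    for tid in sorted(table):
        t = table[tid]
        if t.frequencies is None:
            rows.append((t.tissue_id, t.name, np.nan, float(t.eps_r),
                         float(t.sigma)))
        else:
            for f, e, s in zip(t.frequencies, t.eps_r, t.sigma):
                rows.append((t.tissue_id, t.name, f, e, s))
    pd.DataFrame(rows, columns=_TISSUE_COLUMNS).to_csv(path, index=False)


def load_tissue_table(path: str | Path) -> dict[int, TissueDielectric]:
    """Read a tissue table CSV written by :func:`save_tissue_table`."""
    df = pd.read_csv(path)
    missing = set(_TISSUE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"tissue table missing columns {sorted(missing)}")
    table: dict[int, TissueDielectric] = {}
    for tid, group in df.groupby("tissue_id"):
        tid = int(tid)
        name = str(group["name"].iloc[0])
        if group["frequency_Hz"].isna().all():
            table[tid] = TissueDielectric(
                tissue_id=tid, name=name,
                eps_r=float(group["eps_r"].iloc[0]),
                sigma=float(group["sigma_S_per_m"].iloc[0]))
        else:
            g = group.sort_values("frequency_Hz")
            table[tid] = TissueDielectric(
                tissue_id=tid, name=name,
                frequencies=g["frequency_Hz"].to_numpy(float),
                eps_r=g["eps_r"].to_numpy(float),
                sigma=g["sigma_S_per_m"].to_numpy(float))
    return table


def save_model(model: VoxelModel, labels_path: str | Path,
               tissues_path: str | Path | None = None) -> None:
    """Write the label grid as NIfTI-1 (mm affine) plus a tissue CSV."""
    import nibabel as nib

    affine = np.eye(4)
    affine[:3, :3] *= model.voxel_size * 1e3  # NIfTI convention: mm
    affine[:3, 3] = model.origin * 1e3
    img = nib.Nifti1Image(model.labels.astype(np.int16), affine)
    img.header.set_xyzt_units("mm")
    if model.truncation_axis is not None:
        img.header["descrip"] = f"truncated_axis={model.truncation_axis}".encode()
    nib.save(img, str(labels_path))
    if tissues_path is not None:
        save_tissue_table(model.tissue_table, tissues_path)


def load_model(labels_path: str | Path,
               tissues_path: str | Path) -> VoxelModel:
    """Read a voxel model from NIfTI-1 labels + CSV tissue table."""
    import nibabel as nib

    img = nib.load(str(labels_path))
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0], rtol=1e-6):
        raise ValueError("only isotropic voxel grids are supported")
    labels = np.asarray(img.dataobj).astype(np.int32)
    origin = np.asarray(img.affine[:3, 3], dtype=float) * 1e-3
    descrip = bytes(img.header["descrip"]).rstrip(b"\x00").decode(
        "ascii", "ignore")
    trunc = None
    if descrip.startswith("truncated_axis="):
        trunc = int(descrip.split("=", 1)[1])
    return VoxelModel(labels=labels, voxel_size=float(zooms[0]) * 1e-3,
                      tissue_table=load_tissue_table(tissues_path),
                      origin=origin, truncation_axis=trunc)


def with_truncation(model: VoxelModel, axis: int) -> VoxelModel:
    """Copy of ``model`` flagged as truncated along ``axis``."""
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    return replace(model, truncation_axis=axis)
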