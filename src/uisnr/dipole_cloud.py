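"""Shell-shaped dipole clouds conformal to the body surface.

The dipole cloud is the basis support for all external RF sources: a thin
shell of air voxels at a prescribed distance band from the body surface,
each carrying three electric and three magnetic elementary point dipoles
oriented along the Cartesian axes. Random excitations of this cloud
generate the electromagnetic basis whose span approaches, with growing
size, the set of all fields producible by sources outside the body.

Distance convention: the discrete body surface is approximated by
(distance to the nearest non-air voxel center) minus half a voxel,
floored at zero. The shell band ``[d_min, d_max]`` is closed on voxel
centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import EmptyBodyError, EmptyShellError, GeometryError
from .phantom import VoxelModel

#: Dipole kind codes in a cloud's ``kinds`` array.
ELECTRIC, MAGNETIC = 0, 1

#: Paper-scale shell distances for body-model-scale runs, meters.
PAPER_D_MIN = 0.030
PAPER_D_MAX = 0.035
PAPER_END_MARGIN = 0.040


@dataclass(frozen=True)
class DipoleCloud:
    """Elementary dipoles populating a shell of air voxels.

    Exactly six dipoles sit at the center of every shell voxel, ordered
    (electric x, y, z, magnetic x, y, z) per voxel, voxels in C scan
    order of the grid. ``positions`` are physical (m); ``voxel_indices``
    stores the grid index of the shell voxel each dipole belongs to.
    """

    positions: np.ndarray          # (n_dipoles, 3) m
    kinds: np.ndarray              # (n_dipoles,) ELECTRIC | MAGNETIC
    axes: np.ndarray               # (n_dipoles,) 0 | 1 | 2
    shell_voxel_indices: np.ndarray  # (n_shell, 3) int
    d_min: float
    d_max: float

    @property
    def n_dipoles(self) -> int:
        return len(self.kinds)

    @property
    def n_shell_voxels(self) -> int:
        return len(self.shell_voxel_indices)


def surface_distance_map(model: VoxelModel) -> np.ndarray:
    """Distance (m) from every voxel center to the body surface.

    Zero on non-air voxels; elsewhere the exact Euclidean distance to the
    nearest non-air voxel center minus ``voxel_size/2`` (half-voxel
    surface offset), floored at zero.
    """
    body = model.body_mask
    if not body.any():
        raise EmptyBodyError("model contains no non-air voxel")
    # EDT of the air mask: distance from each air voxel to nearest body voxel
    dist = ndimage.distance_transform_edt(~body,
                                          sampling=model.voxel_size)
    dist = np.maximum(dist - model.voxel_size / 2.0, 0.0)
    dist[body] = 0.0
    return dist


def _dipoles_for_voxels(model: VoxelModel,
                        shell_idx: np.ndarray) -> tuple[np.ndarray, ...]:
    n = len(shell_idx)
    centers = model.voxel_centers(shell_idx)
    positions = np.repeat(centers, 6, axis=0)
    kinds = np.tile(np.array([ELECTRIC] * 3 + [MAGNETIC] * 3), n)
    axes = np.tile(np.array([0, 1, 2, 0, 1, 2]), n)
    return positions, kinds, axes


def build_shell(model: VoxelModel, d_min: float, d_max: float
                ) -> DipoleCloud:
    """Dipole cloud on air voxels with surface distance in [d_min, d_max].

    Raises :class:`GeometryError` if the band touches the grid boundary
    (the grid must be enlarged) and :class:`EmptyShellError` if no air
    voxel falls inside the band.
    """
    if not (0.0 < d_min < d_max):
        raise ValueError("require 0 < d_min < d_max")
    dist = surface_distance_map(model)
    in_band = (~model.body_mask) & (dist >= d_min) & (dist <= d_max)

    boundary = np.zeros(model.shape, dtype=bool)
    boundary[0] = boundary[-1] = True
    boundary[:, 0] = boundary[:, -1] = True
    boundary[:, :, 0] = boundary[:, :, -1] = True
    # if any boundary voxel is at distance <= d_max the band continues
    # past the grid edge and the shell would be clipped
    if (dist[boundary] <= d_max).any():
        raise GeometryError("shell clipped by the grid boundary; "
                            "enlarge the air margin")
    if not in_band.any():
        raise EmptyShellError(f"no air voxel at distance in "
                              f"[{d_min}, {d_max}] m")
    shell_idx = np.argwhere(in_band)
    positions, kinds, axes = _dipoles_for_voxels(model, shell_idx)
    return DipoleCloud(positions=positions, kinds=kinds, axes=axes,
                       shell_voxel_indices=shell_idx,
                       d_min=d_min, d_max=d_max)


def build_circumferential_shell(model: VoxelModel, d_min: float,
                                d_max: float, end_margin: float
                                ) -> DipoleCloud:
    """Shell for truncated models, kept clear of the truncation faces.

    As :func:`build_shell`, but shell voxels whose center lies within
    ``end_margin`` of either axial end of the body (along the model's
    truncation axis) are excluded, so the cloud wraps only around the
    lateral surface. The resulting optimal SNR approximates the
    ultimate limit away from the cut planes.
    """
    if model.truncation_axis is None:
        raise GeometryError("model is not flagged as truncated; "
                            "use build_shell or with_truncation()")
    if end_margin < 0:
        raise ValueError("end_margin must be nonnegative")
    axis = model.truncation_axis
    body_idx = np.argwhere(model.body_mask)
    lo = model.origin[axis] + body_idx[:, axis].min() * model.voxel_size
    hi = model.origin[axis] + body_idx[:, axis].max() * model.voxel_size
    if end_margin >= (hi - lo) / 2:
        raise GeometryError("end_margin consumes the whole body extent")

    full = build_shell(model, d_min, d_max)
    coord = full.shell_voxel_indices[:, axis] * model.voxel_size \
        + model.origin[axis]
    keep = (coord >= lo + end_margin) & (coord <= hi - end_margin)
    if not keep.any():
        raise EmptyShellError("axial margin removed every shell voxel")
    shell_idx = full.shell_voxel_indices[keep]
    positions, kinds, axes = _dipoles_for_voxels(model, shell_idx)
    return DipoleCloud(positions=positions, kinds=kinds, axes=axes,
                       shell_voxel_indices=shell_idx,
                       d_min=d_min, d_max=d_max)
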