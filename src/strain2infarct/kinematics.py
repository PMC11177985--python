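"""Green-Lagrange CRL strains from per-frame displacement fields.

Displacements between consecutive frames (as produced by image
registration, which is outside this package) are turned into per-pixel
incremental deformation gradients F_i = I + du/dX, composed into a total
deformation gradient F = F_n ... F_1, and converted into the Green-Lagrange
strain E = (F^T F - I)/2.  A per-pixel orthonormal frame (circumferential,
radial, longitudinal) built from the LV centroid and the slice normal
rotates E into the CRL components E_CC, E_RR, E_LL via E_CRL = Q E Q^T.

Grid convention: component arrays are indexed [i, j(, k)] with axis 0 the
X direction, axis 1 the Y direction and (for volumetric grids) axis 2 the Z
direction; ``spacing`` gives the physical step per axis.  Spatial derivatives
use central differences in the interior and first-order one-sided stencils at
the borders, which makes the pipeline exact for affine displacement fields at
interior pixels.  2-D slices are treated as 3-D fields with zero
through-plane displacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

_I3 = np.eye(3)


@dataclass
class DisplacementIncrement:
    """Displacement components between two consecutive frames."""

    u_x: np.ndarray
    u_y: np.ndarray
    u_z: np.ndarray | None = None
    spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.u_x = np.asarray(self.u_x, dtype=float)
        self.u_y = np.asarray(self.u_y, dtype=float)
        if self.u_z is not None:
            self.u_z = np.asarray(self.u_z, dtype=float)
        shapes = {self.u_x.shape, self.u_y.shape}
        if self.u_z is not None:
            shapes.add(self.u_z.shape)
        if len(shapes) != 1:
            raise ValueError("displacement component grids must share one shape")
        if self.u_x.ndim not in (2, 3):
            raise ValueError("grids must be 2-D or 3-D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def shape(self):
        return self.u_x.shape


def incremental_gradient(inc: DisplacementIncrement) -> np.ndarray:
    """Per-pixel incremental deformation gradient F_i = I + du/dX.

    Returns an array of shape grid + (3, 3) with F[..., a, b] = d u_a / d X_b
    + delta_ab.  Through-plane derivatives of a 2-D slice are zero.
    """
    grid = inc.shape
    if any(s < 3 for s in grid):
        raise ValueError("grid must be at least 3 samples per axis")
    ndim = len(grid)
    comps = [inc.u_x, inc.u_y,
             inc.u_z if inc.u_z is not None else np.zeros(grid)]
    F = np.zeros(grid + (3, 3))
    F[..., :, :] = _I3
    for a, u in enumerate(comps):
        for b in range(3):
            if b < ndim:
                F[..., a, b] += np.gradient(u, inc.spacing[b], axis=b)
            # derivatives along the missing through-plane axis are zero
    return F


def accumulate_deformation(incs) -> np.ndarray:
    """Compose incremental gradients, later increments left-multiplied."""
    incs = list(incs)
    if not incs:
        raise ValueError("need at least one increment")
    shapes = {i.shape for i in incs}
    if len(shapes) != 1:
        raise ValueError("increments have inconsistent grid shapes")
    F = incremental_gradient(incs[0])
    for inc in incs[1:]:
        F = np.einsum("...ij,...jk->...ik", incremental_gradient(inc), F)
    return F


def green_lagrange(F: np.ndarray) -> np.ndarray:
    """E = (F^T F - I)/2 per pixel; symmetric by construction."""
    C = np.einsum("...ji,...jk->...ik", F, F)
    return 0.5 * (C - _I3)


@dataclass
class CRLFrameField:
    """Per-pixel orthonormal (circumferential, radial, longitudinal) triad."""

    circ: np.ndarray
    rad: np.ndarray
    long: np.ndarray

    def __post_init__(self):
        for v in (self.circ, self.rad, self.long):
            if v.shape[-1] != 3:
                raise ValueError("frame vectors must have 3 components")

    @property
    def Q(self) -> np.ndarray:
        """Rotation with rows (circ, rad, long): E_CRL = Q E Q^T."""
        return np.stack([self.circ, self.rad, self.long], axis=-2)

    def check_orthonormal(self, atol: float = 1e-10):
        Q = self.Q
        QQt = np.einsum("...ij,...kj->...ik", Q, Q)
        if not np.allclose(QQt, _I3, atol=atol):
            raise ValueError("CRL frame is not orthonormal")


def crl_frame_from_centroid(grid_shape, centroid, spacing=(1.0, 1.0)) -> CRLFrameField:
    """Short-axis CRL frame: radial points away from the LV centroid,
    circumferential is 90 degrees counterclockwise in-plane, longitudinal is
    the slice normal +z.  At the centroid itself radial defaults to +x."""
    nx, ny = grid_shape[:2]
    X = (np.arange(nx)[:, None] * spacing[0]) - centroid[0]
    Y = (np.arange(ny)[None, :] * spacing[1]) - centroid[1]
    r = np.sqrt(X ** 2 + Y ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        rx = np.where(r > 0, X / r, 1.0)
        ry = np.where(r > 0, Y / r, 0.0)
    rad = np.stack([rx, ry, np.zeros_like(rx)], axis=-1)
    circ = np.stack([-ry, rx, np.zeros_like(rx)], axis=-1)
    lng = np.broadcast_to(np.array([0.0, 0.0, 1.0]), rad.shape).copy()
    return CRLFrameField(circ=circ, rad=rad, long=lng)


def to_crl(E: np.ndarray, frame: CRLFrameField) -> np.ndarray:
    """Rotate per-pixel strain tensors into the CRL frame: Q E Q^T.

    The returned tensor field has E_CC = [..., 0, 0], E_RR = [..., 1, 1]
    and E_LL = [..., 2, 2].
    """
    frame.check_orthonormal()
    Q = frame.Q
    return np.einsum("...ab,...bc,...dc->...ad", Q, E, Q)


# -- HDF5 interchange ----------------------------------------------------------

def save_increments(path, incs) -> None:
    with h5py.File(path, "w") as f:
        for k, inc in enumerate(incs):
            g = f.create_group(f"increment_{k:04d}")
            g.create_dataset("u_x", data=inc.u_x)
            g.create_dataset("u_y", data=inc.u_y)
            if inc.u_z is not None:
                g.create_dataset("u_z", data=inc.u_z)
            g.attrs["spacing"] = inc.spacing


def load_increments(path) -> list[DisplacementIncrement]:
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f):
            g = f[name]
            out.append(DisplacementIncrement(
                u_x=g["u_x"][()], u_y=g["u_y"][()],
                u_z=g["u_z"][()] if "u_z" in g else None,
                spacing=tuple(g.attrs["spacing"]),
            ))
    return out


def save_strain_field(path, E_crl: np.ndarray) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("E_crl", data=E_crl)
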