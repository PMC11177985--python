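"""Transversely isotropic hyperelastic model of passive + active myocardium.

The total Cauchy stress at a material point decomposes additively into a
passive part derived from a Fung-type strain energy and an active fiber
stress generated by myocyte contraction:

    T = (1/J) * Fbar * (dW_dev/dEbar) * Fbar^T + (dW_vol/dJ) * I
        + (1/J) * F * S_act * F^T

with deformation gradient F, J = det F, isochoric part Fbar = J^(-1/3) F and
Ebar = (Fbar^T Fbar - I)/2.  The deviatoric energy is W_dev = c (exp(Q) - 1)
with the anisotropic quadratic

    Q = B1*E11^2 + B2*(E22^2 + E33^2 + E23^2) + B3*(E12^2 + E13^2)

expressed in an orthonormal fiber frame (e1 = fiber direction), and the
volumetric energy is W_vol = (K/2) * ((J^2 - 1)/2 - ln J), which is
non-negative with a unique minimum at J = 1.  The active second
Piola-Kirchhoff stress is rank-one along the fiber:

    S_act = Ta(Ef) / (2 Ef + 1) * N (x) N,   Ef = N . E N,
    Ta(Ef) = T_Ca * (1 + beta * (sqrt(2 Ef + 1) - 1)),

an affine function of the fiber stretch sqrt(2 Ef + 1); infarcted tissue has
no contractile behaviour (T_Ca = 0).  Units are kPa for all stress-like
quantities.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

_I3 = np.eye(3)


class InvalidDeformationError(ValueError):
    """Raised when det(F) <= 0."""


class FiberCompressionError(ValueError):
    """Raised when 2*Ef + 1 <= 0 (unphysical fiber compression)."""


@dataclass(frozen=True)
class MaterialParameters:
    """Passive (c, B1, B2, B3, K) and active (T_Ca, beta) constants in kPa."""

    c: float
    B1: float
    B2: float
    B3: float
    K: float
    T_Ca: float = 0.0
    beta: float = 0.0

    def __post_init__(self):
        for name in ("c", "B1", "B2", "B3", "K"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.T_Ca < 0 or self.beta < 0:
            raise ValueError("T_Ca and beta must be non-negative")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "MaterialParameters":
        return cls(**json.loads(s))


@dataclass(frozen=True)
class DeformationState:
    F: np.ndarray
    J: float
    F_bar: np.ndarray
    E: np.ndarray
    E_bar: np.ndarray


@dataclass(frozen=True)
class FiberFrame:
    """Orthonormal triad with e1 = N the local fiber direction."""

    N: np.ndarray
    e2: np.ndarray
    e3: np.ndarray

    def __post_init__(self):
        R = self.rotation
        if not np.allclose(R.T @ R, _I3, atol=1e-12):
            raise ValueError("fiber frame is not orthonormal")

    @property
    def rotation(self) -> np.ndarray:
        """Columns (N, e2, e3): maps fiber-frame components to global."""
        return np.column_stack([self.N, self.e2, self.e3])

    @classmethod
    def from_fiber_direction(cls, n) -> "FiberFrame":
        n = np.asarray(n, dtype=float)
        n = n / np.linalg.norm(n)
        helper = np.array([0.0, 0.0, 1.0])
        if abs(n @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        e2 = np.cross(helper, n)
        e2 /= np.linalg.norm(e2)
        e3 = np.cross(n, e2)
        return cls(N=n, e2=e2, e3=e3)


def decompose_deformation(F) -> DeformationState:
    """Split F into volumetric/isochoric parts and form both strain tensors."""
    F = np.asarray(F, dtype=float)
    if F.shape != (3, 3):
        raise ValueError("F must be 3x3")
    J = float(np.linalg.det(F))
    if J <= 0:
        raise InvalidDeformationError(f"det(F) = {J} must be positive")
    F_bar = J ** (-1.0 / 3.0) * F
    E = 0.5 * (F.T @ F - _I3)
    E_bar = 0.5 * (F_bar.T @ F_bar - _I3)
    return DeformationState(F=F, J=J, F_bar=F_bar, E=E, E_bar=E_bar)


def _Q_and_dQ(E_fib: np.ndarray, p: MaterialParameters):
    """Anisotropy exponent Q and its symmetric-tensor derivative, fiber frame.

    The derivative is the matrix M with dQ = M : dE for symmetric dE, i.e.
    off-diagonal entries carry half the independent-component derivative.
    """
    e = E_fib
    Q = (p.B1 * e[0, 0] ** 2
         + p.B2 * (e[1, 1] ** 2 + e[2, 2] ** 2 + e[1, 2] ** 2)
         + p.B3 * (e[0, 1] ** 2 + e[0, 2] ** 2))
    M = np.array([
        [2 * p.B1 * e[0, 0], p.B3 * e[0, 1], p.B3 * e[0, 2]],
        [p.B3 * e[0, 1], 2 * p.B2 * e[1, 1], p.B2 * e[1, 2]],
        [p.B3 * e[0, 2], p.B2 * e[1, 2], 2 * p.B2 * e[2, 2]],
    ])
    return Q, M


def passive_strain_energy(state: DeformationState, p: MaterialParameters,
                          frame: FiberFrame | None = None) -> tuple[float, float]:
    """(W_dev, W_vol) in kPa; both are non-negative."""
    R = _I3 if frame is None else frame.rotation
    E_fib = R.T @ state.E_bar @ R
    Q, _ = _Q_and_dQ(E_fib, p)
    W_dev = p.c * (np.exp(Q) - 1.0)
    J = state.J
    W_vol = 0.5 * p.K * ((J * J - 1.0) / 2.0 - np.log(J))
    return float(W_dev), float(W_vol)


def passive_dev_second_pk(state: DeformationState, p: MaterialParameters,
                          frame: FiberFrame | None = None) -> np.ndarray:
    """dW_dev/dEbar in global components (symmetric-tensor gradient)."""
    R = _I3 if frame is None else frame.rotation
    E_fib = R.T @ state.E_bar @ R
    Q, M = _Q_and_dQ(E_fib, p)
    return p.c * np.exp(Q) * (R @ M @ R.T)


def volumetric_pressure(J: float, p: MaterialParameters) -> float:
    """dW_vol/dJ = (K/2) (J - 1/J); zero at J = 1."""
    return 0.5 * p.K * (J - 1.0 / J)


def active_second_pk(E, frame: FiberFrame, p: MaterialParameters) -> np.ndarray:
    """Active fiber stress S_act = Ta(Ef)/(2Ef+1) * N(x)N (kPa)."""
    E = np.asarray(E, dtype=float)
    N = frame.N
    Ef = float(N @ E @ N)
    stretch_sq = 2.0 * Ef + 1.0
    if stretch_sq <= 0:
        raise FiberCompressionError(f"2*Ef + 1 = {stretch_sq} <= 0")
    Ta = p.T_Ca * (1.0 + p.beta * (np.sqrt(stretch_sq) - 1.0))
    return (Ta / stretch_sq) * np.outer(N, N)


def total_cauchy_stress(state: DeformationState, frame: FiberFrame,
                        p: MaterialParameters) -> np.ndarray:
    """Total Cauchy stress: isochoric passive + volumetric pressure + active."""
    J = state.J
    S_dev = passive_dev_second_pk(state, p, frame)
    T_pass = state.F_bar @ S_dev @ state.F_bar.T / J
    T_vol = volumetric_pressure(J, p) * _I3
    S_act = active_second_pk(state.E, frame, p)
    T_act = state.F @ S_act @ state.F.T / J
    return T_pass + T_vol + T_act


# -- batch CSV interface -------------------------------------------------------

_F_COLS = [f"F{i}{j}" for i in (1, 2, 3) for j in (1, 2, 3)]
_T_COLS = [f"T{i}{j}" for i in (1, 2, 3) for j in (1, 2, 3)]


def batch_cauchy_stress(table: pd.DataFrame, p: MaterialParameters,
                        frame: FiberFrame) -> pd.DataFrame:
    """Evaluate T for each row of F components; returns F and T columns."""
    missing = [c for c in _F_COLS if c not in table.columns]
    if missing:
        raise ValueError(f"missing F columns: {missing}")
    out = []
    for _, row in table.iterrows():
        F = row[_F_COLS].to_numpy(dtype=float).reshape(3, 3)
        T = total_cauchy_stress(decompose_deformation(F), frame, p)
        out.append(T.ravel())
    res = pd.DataFrame(out, columns=_T_COLS, index=table.index)
    return pd.concat([table[_F_COLS], res], axis=1)
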