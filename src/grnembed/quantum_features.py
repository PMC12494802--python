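"""Statevector simulation of the angle-encoding feature circuit.

Per node embedding, the first ``n_qubits`` values become rotation angles:
each qubit q gets ``RY(theta_q)`` then ``RZ(theta_q)``, a CNOT chain
``q0 -> q1 -> ... -> q_{n-1}`` entangles the register, and the Pauli-Z
expectation of every qubit is read out exactly (no shot noise).  The
resulting per-node feature vector lives in ``[-1, 1]^{n_qubits}``.

Bit-order convention: qubit 0 is the MOST significant bit of the basis
index, i.e. amplitude ``psi[b]`` belongs to the computational basis state
whose qubit-q bit is ``(b >> (n - 1 - q)) & 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CircuitSpec",
    "QuantumFeatureMatrix",
    "init_state",
    "apply_ry",
    "apply_rz",
    "apply_cnot",
    "encode_vector",
    "pauli_z_expectation",
    "quantum_feature_matrix",
]

MAX_QUBITS = 12


@dataclass
class CircuitSpec:
    """Configuration of the angle-encoding circuit.

    ``angle_source`` lists which embedding columns supply the angles
    (default: the first ``n_qubits``).  ``angle_transform`` is either
    ``raw`` (values used directly as radians) or ``scaled_pi`` (each
    selected column linearly rescaled to ``[-pi, pi]`` over the matrix
    being encoded).  ``entangle`` disables the CNOT chain when False,
    which reduces each readout to ``cos(theta_q)`` exactly.
    """

    n_qubits: int = 8
    angle_source: tuple[int, ...] | None = None
    angle_transform: str = "raw"
    entangle: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.n_qubits <= MAX_QUBITS:
            raise ValueError(f"n_qubits must be in [1, {MAX_QUBITS}]")
        if self.angle_transform not in ("raw", "scaled_pi"):
            raise ValueError(f"unknown angle_transform: {self.angle_transform!r}")
        if self.angle_source is not None and len(self.angle_source) != self.n_qubits:
            raise ValueError("angle_source must list exactly n_qubits columns")

    def source_columns(self) -> tuple[int, ...]:
        return self.angle_source if self.angle_source is not None else tuple(range(self.n_qubits))


@dataclass
class QuantumFeatureMatrix:
    """n_nodes x n_qubits matrix of Pauli-Z expectations in [-1, 1]."""

    values: np.ndarray
    model_tag: str = "QUANTUM"


def _n_qubits_of(state: np.ndarray) -> int:
    n = int(np.log2(state.size))
    if 2**n != state.size:
        raise ValueError("statevector length must be a power of two")
    return n


def init_state(n_qubits: int) -> np.ndarray:
    """|0...0> statevector of length 2**n_qubits."""
    if n_qubits < 1:
        raise ValueError("n_qubits must be >= 1")
    state = np.zeros(2**n_qubits, dtype=complex)
    state[0] = 1.0
    return state


def _apply_single(state: np.ndarray, qubit: int, gate: np.ndarray) -> np.ndarray:
    n = _n_qubits_of(state)
    if not 0 <= qubit < n:
        raise ValueError(f"qubit index {qubit} out of range for {n} qubits")
    psi = state.reshape((2,) * n)
    out = np.tensordot(gate, psi, axes=([1], [qubit]))
    out = np.moveaxis(out, 0, qubit)
    return np.ascontiguousarray(out).reshape(-1)


def apply_ry(state: np.ndarray, qubit: int, theta: float) -> np.ndarray:
    """Rotation about Y: [[cos t/2, -sin t/2], [sin t/2, cos t/2]]."""
    c, s = np.cos(theta / 2.0), np.sin(theta / 2.0)
    return _apply_single(state, qubit, np.array([[c, -s], [s, c]], dtype=complex))

def apply_rz(state: np.ndarray, qubit: int, theta: float) -> np.ndarray:
    """Rotation about Z: diag(e^{-i t/2}, e^{i t/2})."""
    phase = np.exp(-1j * theta / 2.0)
    return _apply_single(state, qubit, np.array([[phase, 0], [0, np.conj(phase)]]))


def apply_cnot(state: np.ndarray, control: int, target: int) -> np.ndarray:
    """Flip the target bit of every basis state whose control bit is 1."""
    if control == target:
        raise ValueError("control and target must differ")
    n = _n_qubits_of(state)
    for q in (control, target):
        if not 0 <= q < n:
            raise ValueError(f"qubit index {q} out of range for {n} qubits")
    psi = state.reshape((2,) * n).copy()
    moved = np.moveaxis(psi, (control, target), (0, 1))
    moved[1] = np.flip(moved[1], axis=0).copy()
    return psi.reshape(-1)


def pauli_z_expectation(state: np.ndarray, qubit: int) -> float:
    """<Z_qubit> = P(bit 0) - P(bit 1); always in [-1, 1]."""
    n = _n_qubits_of(state)
    if not 0 <= qubit < n:
        raise ValueError(f"qubit index {qubit} out of range for {n} qubits")
    probs = np.abs(state.reshape((2,) * n)) ** 2
    axes = tuple(a for a in range(n) if a != qubit)
    marginal = probs.sum(axis=axes)
    return float(marginal[0] - marginal[1])


def encode_vector(angles: np.ndarray, spec: CircuitSpec) -> np.ndarray:
    """Run the encoding circuit for one angle vector; returns the statevector.

    ``angles`` must already hold the n_qubits rotation angles in radians
    (column selection / rescaling is handled by
    :func:`quantum_feature_matrix`).
    """
    angles = np.asarray(angles, dtype=float).ravel()
    if angles.size < spec.n_qubits:
        raise ValueError(
            f"need {spec.n_qubits} angles, got {angles.size}"
        )
    state = init_state(spec.n_qubits)
    for q in range(spec.n_qubits):
        state = apply_ry(state, q, angles[q])
        state = apply_rz(state, q, angles[q])
    if spec.entangle:
        for q in range(spec.n_qubits - 1):
            state = apply_cnot(state, q, q + 1)
    return state


def _matrix_angles(embeddings: np.ndarray, spec: CircuitSpec) -> np.ndarray:
    cols = spec.source_columns()
    if embeddings.shape[1] < max(cols) + 1:
        raise ValueError(
            f"embeddings have {embeddings.shape[1]} columns; circuit needs column {max(cols)}"
        )
    angles = np.asarray(embeddings, dtype=float)[:, list(cols)]
    if spec.angle_transform == "scaled_pi":
        lo = angles.min(axis=0)
        hi = angles.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        angles = (angles - lo) / span * (2 * np.pi) - np.pi
    return angles


def quantum_feature_matrix(
    embeddings: np.ndarray, spec: CircuitSpec | None = None
) -> QuantumFeatureMatrix:
    """Row-wise circuit encoding + all-qubit Pauli-Z readout."""
    spec = spec or CircuitSpec()
    angles = _matrix_angles(np.asarray(embeddings, dtype=float), spec)
    values = np.empty((angles.shape[0], spec.n_qubits))
    for i in range(angles.shape[0]):
        state = encode_vector(angles[i], spec)
        values[i] = [pauli_z_expectation(state, q) for q in range(spec.n_qubits)]
    return QuantumFeatureMatrix(values=values)
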