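"""Decomposition of a Saupe tensor into principal order parameters,
alignment-frame Euler angles, and axial/rhombic anisotropy.

Conventions (documented because the field is not unanimous):

* Principal values are ordered by magnitude, |Szz'| >= |Syy'| >= |Sxx'|, with
  magnitude ties broken by signed value descending.
* ``rotation`` maps the molecular frame to the principal frame: the columns
  are the principal axes expressed in molecular coordinates, so
  ``rotation @ diag(principal) @ rotation.T`` reconstructs the tensor.
* Euler angles are active ZYZ rotations in degrees, canonicalized to
  alpha, gamma in (-180, 180] and beta in [0, 180].  A symmetric tensor does
  not distinguish a principal axis from its negative, so the frame carries a
  4-fold degeneracy (180-degree flips about each principal axis);
  :func:`euler_angles` returns the whole equivalence class.
* Da(pair) = 1/2 * Dmax(pair, 1 A) * Szz'  (Hz at unit distance);
  R = (2/3) * (Sxx' - Syy') / Szz', which lies in [0, 2/3] under the
  magnitude ordering above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import PairType, SaupeTensor, get_pair_type

__all__ = ["TensorDecomposition", "diagonalize", "euler_angles", "anisotropy",
           "euler_to_matrix", "tensor_from_principal"]


def euler_to_matrix(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Active ZYZ rotation matrix Rz(alpha) @ Ry(beta) @ Rz(gamma), degrees."""
    a, b, g = np.deg2rad([alpha, beta, gamma])

    def rz(t):
        c, s = np.cos(t), np.sin(t)
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

    def ry(t):
        c, s = np.cos(t), np.sin(t)
        return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])

    return rz(a) @ ry(b) @ rz(g)


def tensor_from_principal(principal, alpha: float, beta: float, gamma: float) -> SaupeTensor:
    """Build the molecular-frame tensor with the given principal values
    (Sxx', Syy', Szz') and ZYZ Euler angles in degrees."""
    principal = np.asarray(principal, dtype=float)
    if abs(principal.sum()) > 1e-10 * max(1.0, np.abs(principal).max()):
        raise ValueError("principal values must sum to zero (traceless tensor)")
    R = euler_to_matrix(alpha, beta, gamma)
    return SaupeTensor.from_matrix(R @ np.diag(principal) @ R.T)


@dataclass(frozen=True)
class TensorDecomposition:
    principal: tuple[float, float, float]  # (Sxx', Syy', Szz'), |.| ascending
    rotation: np.ndarray  # proper rotation, molecular -> principal (columns = axes)
    euler: tuple[float, float, float]  # ZYZ, degrees, canonical branch
    euler_degenerate: bool  # True when beta in {0, 180} (only alpha+gamma defined)

    @property
    def szz(self) -> float:
        return self.principal[2]

    def reconstruct(self) -> SaupeTensor:
        return SaupeTensor.from_matrix(
            self.rotation @ np.diag(self.principal) @ self.rotation.T
        )


def _matrix_to_zyz(R: np.ndarray) -> tuple[float, float, float, bool]:
    """ZYZ angles (degrees) of a proper rotation; flags the gimbal case."""
    beta = np.degrees(np.arccos(np.clip(R[2, 2], -1.0, 1.0)))
    if min(beta, 180.0 - beta) < 1e-7:
        # sin(beta) ~ 0: only alpha + gamma (beta=0) or alpha - gamma
        # (beta=180) is defined.  Fix gamma = 0 and read alpha off the
        # upper-left block (which is Rz(alpha) or Rz(alpha)@Ry(180)).
        if R[2, 2] > 0:
            alpha = np.degrees(np.arctan2(R[1, 0], R[0, 0]))
            return _wrap(alpha), 0.0, 0.0, True
        alpha = np.degrees(np.arctan2(-R[1, 0], -R[0, 0]))
        return _wrap(alpha), 180.0, 0.0, True
    alpha = np.degrees(np.arctan2(R[1, 2], R[0, 2]))
    gamma = np.degrees(np.arctan2(R[2, 1], -R[2, 0]))
    return _wrap(alpha), beta, _wrap(gamma), False


def _wrap(angle: float) -> float:
    """Wrap to (-180, 180]."""
    a = (angle + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def diagonalize(tensor: SaupeTensor) -> TensorDecomposition:
    """Diagonalize a Saupe tensor into its principal frame.

    Eigenvalues are sorted by magnitude ascending into (Sxx', Syy', Szz');
    magnitude ties break by signed value descending.  The eigenvector matrix
    is made proper (det = +1) by flipping one axis if necessary.
    """
    vals, vecs = np.linalg.eigh(tensor.matrix)
    order = sorted(range(3), key=lambda i: (abs(vals[i]), -vals[i]))
    vals = vals[order]
    vecs = vecs[:, order]
    if np.linalg.det(vecs) < 0:
        vecs[:, 0] = -vecs[:, 0]
    alpha, beta, gamma, degenerate = _matrix_to_zyz(vecs)
    return TensorDecomposition(
        principal=tuple(float(v) for v in vals),
        rotation=vecs,
        euler=(alpha, beta, gamma),
        euler_degenerate=degenerate,
    )


#: Frame-degeneracy generators: 180-degree rotations about each principal axis.
_FRAME_FLIPS = (
    np.diag([1.0, 1.0, 1.0]),
    np.diag([1.0, -1.0, -1.0]),
    np.diag([-1.0, 1.0, -1.0]),
    np.diag([-1.0, -1.0, 1.0]),
)


def euler_angles(decomp: TensorDecomposition) -> list[tuple[float, float, float]]:
    """The 4-member equivalence class of ZYZ Euler triples for a decomposition.

    All members recompose to the same tensor; the first is the canonical
    branch stored on the decomposition itself.
    """
    triples = []
    for flip in _FRAME_FLIPS:
        a, b, g, _ = _matrix_to_zyz(decomp.rotation @ flip)
        triples.append((a, b, g))
    # canonical member first
    triples.sort(key=lambda t: (t != decomp.euler,))
    return triples


def anisotropy(
    decomp: TensorDecomposition, pairs
) -> tuple[dict[str, float], float]:
    """Axial (Da, per pair, Hz at 1 A) and rhombic (R) anisotropy components.

    Da(pair) = 1/2 * dmax_unit(pair) * Szz';  R = (2/3)(Sxx' - Syy')/Szz'.
    """
    sxx, syy, szz = decomp.principal
    if szz == 0.0:
        raise ZeroDivisionError("isotropic tensor: Szz' = 0, rhombicity undefined")
    rhombicity = (2.0 / 3.0) * (sxx - syy) / szz
    da = {}
    for pair in pairs:
        p: PairType = get_pair_type(pair) if isinstance(pair, str) else pair
        da[p.name] = 0.5 * p.dmax_unit * szz
    return da, float(rhombicity)
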