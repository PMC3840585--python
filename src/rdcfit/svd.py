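"""Assembly and SVD solution of the linear RDC system.

Eliminating szz through the traceless property reduces each coupling to a
linear equation in the 5 free tensor elements:

    [x^2-z^2, y^2-z^2, 2xy, 2xz, 2yz] . s5 = D * r^3 / Dmax

Stacking the selected, observed rows gives an n x 5 system A x = b solved in
the least-squares sense by singular value decomposition; rank deficiency
(fewer than 5 informative directions) yields the minimum-norm solution plus a
machine-readable degeneracy warning rather than a failure, since sparse
fragments are a legitimate use case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import RDCSet, SaupeTensor

__all__ = ["LinearSystem", "SvdSolution", "DegenerateSystemWarning",
           "design_row", "build_system", "solve"]

#: Relative singular-value cutoff below which directions are treated as null.
RANK_RCOND = 1e-12


class DegenerateSystemWarning(UserWarning):
    """The linear system is rank-deficient / under-determined."""


class EmptySystemError(ValueError):
    """No selected, observed rows to build a system from."""


@dataclass(frozen=True)
class LinearSystem:
    A: np.ndarray  # n x 5 design matrix, dimensionless
    b: np.ndarray  # n-vector of normalized couplings D*r^3/Dmax
    row_index: tuple[int, ...]  # 1-based equation number per row
    scale: np.ndarray = None  # dmax/r^3 per row (Hz), for back-transforming

    @property
    def n(self) -> int:
        return self.A.shape[0]


@dataclass(frozen=True)
class SvdSolution:
    tensor: SaupeTensor
    residual_rms: float  # Hz
    singular_values: np.ndarray  # 5, descending
    rank: int
    n_equations: int
    warnings: tuple[str, ...] = ()


def design_row(v) -> np.ndarray:
    """The 5-element design row for a unit interaction vector."""
    v = np.asarray(v, dtype=float)
    if abs(np.linalg.norm(v) - 1.0) > 1e-8:
        raise ValueError(f"design_row requires a unit vector, got |v| = {np.linalg.norm(v)}")
    x, y, z = v
    return np.array([x * x - z * z, y * y - z * z, 2 * x * y, 2 * x * z, 2 * y * z])


def build_system(rdcs: RDCSet) -> LinearSystem:
    """Assemble A x = b from the selected, non-missing rows of ``rdcs``."""
    rows = rdcs.usable()
    if not rows:
        raise EmptySystemError("no selected, observed equations to fit")
    A = np.array([design_row(d.vector.v) for d in rows])
    scale = np.array([d.dmax_over_r3 for d in rows])
    b = np.array([d.d_obs for d in rows]) / scale
    return LinearSystem(A=A, b=b, row_index=tuple(d.index for d in rows), scale=scale)


def solve(system: LinearSystem) -> SvdSolution:
    """Minimum-norm least-squares order tensor for ``system`` via SVD.

    The residual RMS is reported in Hz by back-transforming each row residual
    through its dmax/r^3 scale, so it compares directly with per-row errors.
    """
    A, b = system.A, system.b
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    smax = s[0] if s.size else 0.0
    if smax == 0.0:
        raise np.linalg.LinAlgError("degenerate geometry: all-zero design matrix")
    keep = s > RANK_RCOND * smax
    rank = int(keep.sum())
    x = Vt[keep].T @ ((U[:, keep].T @ b) / s[keep])
    tensor = SaupeTensor.from_s5(x)
    resid_hz = (A @ x - b) * system.scale
    residual_rms = float(np.sqrt(np.mean(resid_hz**2)))
    sv = np.zeros(5)
    sv[: s.size] = s
    msgs = []
    if system.n < 5 or rank < 5:
        msgs.append(
            f"under-determined system (n={system.n}, rank={rank}): minimum-norm solution"
        )
        warnings.warn(msgs[-1], DegenerateSystemWarning, stacklevel=2)
    return SvdSolution(
        tensor=tensor,
        residual_rms=residual_rms,
        singular_values=np.sort(sv)[::-1],
        rank=rank,
        n_equations=system.n,
        warnings=tuple(msgs),
    )


def solve_rdcset(rdcs: RDCSet) -> SvdSolution:
    """Convenience: build and solve in one step."""
    return solve(build_system(rdcs))
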