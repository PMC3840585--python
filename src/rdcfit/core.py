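"""Domain types and the forward residual-dipolar-coupling model.

A residual dipolar coupling (RDC) between two nuclei i and j reports the
orientationally averaged dipole-dipole interaction under partial molecular
alignment:

    D_ij = (Dmax_ij / r^3) * v . S . v^T                       (Hz)

where ``v`` is the unit vector joining the nuclei, ``r`` their separation in
Angstrom, ``S`` the symmetric traceless Saupe order tensor (5 independent
elements), and ``Dmax_ij`` the maximum observable coupling for that nucleus
pair at 1.0 Angstrom separation.  This module provides the value types shared
by the whole package and the forward model used everywhere else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "MISSING",
    "PairType",
    "PAIR_TYPES",
    "get_pair_type",
    "InteractionVector",
    "RDCDatum",
    "RDCSet",
    "SaupeTensor",
    "compute_dmax",
    "make_vector",
    "back_calculate",
]

#: Sentinel value marking an unobserved coupling in data tables.
MISSING = 999.0


class UnknownPairTypeError(KeyError):
    """Raised when a nucleus-pair name cannot be resolved."""


@dataclass(frozen=True)
class PairType:
    """A nucleus pair with its gyromagnetic ratios and unit-distance Dmax.

    ``dmax_unit`` is the maximum observable dipolar coupling (Hz) at a
    separation of 1.0 Angstrom; it carries the sign of -gamma_i*gamma_j, so
    pairs involving 15N (negative gamma) have the opposite sign from pure
    13C/1H pairs.
    """

    name: str
    gamma_i: float  # rad s^-1 T^-1
    gamma_j: float  # rad s^-1 T^-1
    dmax_unit: float  # Hz at r = 1.0 A


# CODATA 2018 / SI-2019 exact values.
MU0 = 1.25663706212e-6  # magnetic permeability of free space, N A^-2
PLANCK_H = 6.62607015e-34  # Planck constant, J s (exact)
GAMMA = {
    "1H": 267.52218744e6,
    "13C": 67.2828e6,
    "15N": -27.126e6,
}  # gyromagnetic ratios, rad s^-1 T^-1


def _dmax_unit(gamma_i: float, gamma_j: float) -> float:
    # Dmax = -mu0 * gi * gj * h / (8 pi^3 r^3) with r = 1.0 A = 1e-10 m.
    return -MU0 * gamma_i * gamma_j * PLANCK_H / (8.0 * math.pi**3 * 1e-30)


def _pair(name: str, iso_i: str, iso_j: str) -> PairType:
    gi, gj = GAMMA[iso_i], GAMMA[iso_j]
    return PairType(name=name, gamma_i=gi, gamma_j=gj, dmax_unit=_dmax_unit(gi, gj))


#: The six built-in pair types.  Dmax magnitudes agree with published
#: normalization tables (N-H ~ +24.36 kHz, C-H ~ -60.4 kHz, H-H ~ -240 kHz
#: at 1.0 A).
PAIR_TYPES: dict[str, PairType] = {
    p.name.lower(): p
    for p in (
        _pair("N-H", "15N", "1H"),
        _pair("C-N", "13C", "15N"),
        _pair("C-H", "13C", "1H"),
        _pair("H-H", "1H", "1H"),
        _pair("Ca-Ha", "13C", "1H"),
        _pair("Ca-C", "13C", "13C"),
    )
}


def get_pair_type(name: str) -> PairType:
    """Resolve a pair type by name, case-insensitively."""
    try:
        return PAIR_TYPES[name.lower()]
    except KeyError:
        raise UnknownPairTypeError(
            f"unknown pair type {name!r}; known: {sorted(p.name for p in PAIR_TYPES.values())}"
        ) from None


def compute_dmax(pair: PairType | str, r: float) -> float:
    """Maximum dipolar coupling (Hz) for ``pair`` at separation ``r`` (A).

    Scales as 1/r^3; at r = 1.0 it returns the pair's tabulated unit
    constant.
    """
    if isinstance(pair, str):
        pair = get_pair_type(pair)
    if not r > 0:
        raise ValueError(f"invalid geometry: internuclear distance must be positive, got {r}")
    return pair.dmax_unit / r**3


@dataclass(frozen=True)
class InteractionVector:
    """The geometry of one internuclear vector: endpoints, length, direction."""

    coords_i: tuple[float, float, float]  # A
    coords_j: tuple[float, float, float]  # A
    r: float  # A
    v: tuple[float, float, float]  # unit vector i -> j

    def as_array(self) -> np.ndarray:
        return np.asarray(self.v, dtype=float)


def make_vector(coords_i, coords_j) -> InteractionVector:
    """Build an :class:`InteractionVector` from two Cartesian positions (A).

    The direction is i -> j; the physics is antipodally symmetric so the
    choice is a reproducibility convention only.
    """
    ci = np.asarray(coords_i, dtype=float)
    cj = np.asarray(coords_j, dtype=float)
    d = cj - ci
    r = float(np.linalg.norm(d))
    if r == 0.0:
        raise ValueError("zero-length vector: coincident nuclear coordinates")
    v = d / r
    return InteractionVector(
        coords_i=tuple(ci.tolist()), coords_j=tuple(cj.tolist()), r=r, v=tuple(v.tolist())
    )


@dataclass(frozen=True)
class RDCDatum:
    """One dipolar-coupling observation (or an unobserved placeholder)."""

    vector: InteractionVector
    d_obs: float  # Hz; meaningless when missing is True
    error: float  # Hz, >= 0
    dmax: float  # Hz at 1.0 A, per-row value (file overrides built-in table)
    index: int  # 1-based equation number
    label: str = ""
    missing: bool = False

    def __post_init__(self):
        if self.error < 0:
            raise ValueError(f"equation {self.index}: error must be >= 0, got {self.error}")

    @property
    def dmax_over_r3(self) -> float:
        return self.dmax / self.vector.r**3


@dataclass
class RDCSet:
    """Ordered couplings for one alignment medium plus a selection mask."""

    data: list[RDCDatum]
    selection: np.ndarray = None  # boolean, one flag per datum
    medium_label: str = ""

    def __post_init__(self):
        if self.selection is None:
            self.selection = np.ones(len(self.data), dtype=bool)
        else:
            self.selection = np.asarray(self.selection, dtype=bool)
        if self.selection.shape != (len(self.data),):
            raise ValueError("selection mask must have exactly one flag per datum")

    def __len__(self) -> int:
        return len(self.data)

    def __iter__(self):
        return iter(self.data)

    def selected(self) -> list[RDCDatum]:
        """Selected data, in file order (missing rows included)."""
        return [d for d, s in zip(self.data, self.selection) if s]

    def usable(self) -> list[RDCDatum]:
        """Selected, non-missing data — the rows that enter the linear system."""
        return [d for d, s in zip(self.data, self.selection) if s and not d.missing]

    def with_selection(self, mask) -> "RDCSet":
        return RDCSet(data=self.data, selection=np.asarray(mask, dtype=bool),
                      medium_label=self.medium_label)

    def with_observations(self, d_obs: np.ndarray) -> "RDCSet":
        """Copy with replaced observed values (missing flags preserved)."""
        d_obs = np.asarray(d_obs, dtype=float)
        if d_obs.shape != (len(self.data),):
            raise ValueError("need one observation per datum")
        data = [replace(d, d_obs=float(x)) for d, x in zip(self.data, d_obs)]
        return RDCSet(data=data, selection=self.selection.copy(),
                      medium_label=self.medium_label)


@dataclass(frozen=True)
class SaupeTensor:
    """Symmetric traceless order tensor, stored as its 5 independent elements
    ``(sxx, syy, sxy, sxz, syz)``; ``szz = -sxx - syy`` by construction."""

    s5: tuple[float, float, float, float, float]

    @classmethod
    def from_s5(cls, s5) -> "SaupeTensor":
        s5 = tuple(float(x) for x in s5)
        if len(s5) != 5:
            raise ValueError("s5 must have exactly 5 elements (sxx, syy, sxy, sxz, syz)")
        return cls(s5=s5)

    @classmethod
    def from_matrix(cls, m) -> "SaupeTensor":
        m = np.asarray(m, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("order tensor matrix must be 3x3")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("order tensor matrix must be symmetric")
        if abs(np.trace(m)) > 1e-10 * max(1.0, float(np.abs(m).max())):
            raise ValueError("order tensor matrix must be traceless")
        return cls(s5=(m[0, 0], m[1, 1], m[0, 1], m[0, 2], m[1, 2]))

    @classmethod
    def zero(cls) -> "SaupeTensor":
        return cls(s5=(0.0, 0.0, 0.0, 0.0, 0.0))

    @property
    def matrix(self) -> np.ndarray:
        """The 3x3 realization with szz filled in from the traceless property."""
        sxx, syy, sxy, sxz, syz = self.s5
        szz = -sxx - syy
        return np.array([[sxx, sxy, sxz], [sxy, syy, syz], [sxz, syz, szz]])

    def rotated(self, rot: np.ndarray) -> "SaupeTensor":
        """The same alignment expressed in a rotated molecular frame."""
        rot = np.asarray(rot, dtype=float)
        return SaupeTensor.from_matrix(rot @ self.matrix @ rot.T)


def back_calculate(tensor: SaupeTensor, datum: RDCDatum) -> float:
    """Predicted coupling (Hz): ``(dmax/r^3) * v . S . v^T``."""
    v = datum.vector.as_array()
    return float(datum.dmax_over_r3 * (v @ tensor.matrix @ v))
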