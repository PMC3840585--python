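"""Synthetic RDC data generators for validation studies.

Everything here reproduces, on synthetic geometry, the statistical structure
of the classic validation protocols for order-tensor software:

* couplings computed from reference alignment tensors on quasi-uniform or
  random vector sets, with optional uniform or Gaussian noise;
* two-state jump averaging (a region exchanging between two conformations,
  observed couplings are the population-weighted average);
* multi-conformer ensemble averaging restricted to designated mobile
  regions — a stand-in for a molecular-dynamics trajectory of a protein
  whose loops move while the core is rigid.

The default reference tensors are the two alignment media used throughout
the package's validation suite:

    M1: principal values (-3, -5, 8) x 1e-4, Euler (0, 0, 0)
    M2: principal values (2, 5, -7) x 1e-4, Euler (-40, -50, 60) deg (ZYZ)

magnitudes typical of experimentally observed protein alignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import RDCDatum, RDCSet, SaupeTensor, back_calculate, get_pair_type, make_vector
from .tensor import tensor_from_principal

__all__ = [
    "MEDIUM_TENSORS", "DynamicsModel", "make_vectors", "simulate_rdc",
    "average_rdc", "make_validation_dataset", "ValidationDataset",
]

#: Reference alignment tensors (molecular frame) for the two synthetic media.
MEDIUM_TENSORS: dict[str, SaupeTensor] = {
    "M1": tensor_from_principal((-3e-4, -5e-4, 8e-4), 0.0, 0.0, 0.0),
    "M2": tensor_from_principal((2e-4, 5e-4, -7e-4), -40.0, -50.0, 60.0),
}

#: Bond length (A) used for generated vectors; amide N-H scale.
DEFAULT_BOND_LENGTH = 1.02


def make_vectors(n: int, scheme: str = "fibonacci", seed: int | None = None):
    """``n`` unit vectors: quasi-uniform Fibonacci spiral or seeded random."""
    if n < 1:
        raise ValueError("need n >= 1 vectors")
    if scheme == "fibonacci":
        k = np.arange(n)
        golden = (1 + 5**0.5) / 2
        z = 1 - (2 * k + 1) / n
        theta = 2 * np.pi * k / golden
        rho = np.sqrt(np.clip(1 - z * z, 0.0, None))
        dirs = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    elif scheme == "random":
        rng = np.random.default_rng(seed)
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return [make_vector((0.0, 0.0, 0.0), tuple(DEFAULT_BOND_LENGTH * d))
            for d in dirs]


def _noise_draws(noise, n: int, rng) -> tuple[np.ndarray, float]:
    """Noise samples and the error-column value they imply."""
    if noise is None or noise == "none":
        return np.zeros(n), 0.0
    kind, width = noise
    if kind == "uniform":
        return rng.uniform(-width, width, size=n), float(width)
    if kind == "gaussian":
        return rng.normal(0.0, width, size=n), float(width)
    raise ValueError(f"unknown noise model {noise!r}")


def simulate_rdc(
    tensor: SaupeTensor,
    vectors,
    pair="N-H",
    noise=None,
    seed: int | None = None,
    medium_label: str = "",
    error: float | None = None,
) -> RDCSet:
    """Couplings back-calculated from ``tensor`` on ``vectors``, plus noise.

    ``noise`` is ``None``, ``("uniform", w)`` (draws in [-w, +w]) or
    ``("gaussian", sigma)``.  The error column defaults to the noise width.
    """
    vectors = list(vectors)
    if not vectors:
        raise ValueError("need at least one vector")
    pt = get_pair_type(pair) if isinstance(pair, str) else pair
    rng = np.random.default_rng(seed)
    draws, err = _noise_draws(noise, len(vectors), rng)
    if error is not None:
        err = error
    data = []
    for k, (vec, eps) in enumerate(zip(vectors, draws)):
        clean = back_calculate(
            tensor,
            RDCDatum(vector=vec, d_obs=0.0, error=0.0, dmax=pt.dmax_unit, index=k + 1),
        )
        data.append(RDCDatum(
            vector=vec, d_obs=clean + eps, error=err, dmax=pt.dmax_unit,
            index=k + 1, label=f"{pt.name}_{k + 1}",
        ))
    return RDCSet(data=data, medium_label=medium_label)


@dataclass(frozen=True)
class DynamicsModel:
    """Discrete-state internal motion: couplings average over conformations.

    ``kind`` is ``static`` (one state), ``two_state`` (jump model) or
    ``ensemble_average`` (many conformers); ``states`` holds one vector list
    per conformation (identical ordering/labeling across states) and
    ``weights`` the state populations.
    """

    kind: str
    states: tuple  # of vector lists
    weights: tuple  # of floats summing to 1

    def __post_init__(self):
        if self.kind not in ("static", "two_state", "ensemble_average"):
            raise ValueError(f"unknown dynamics kind {self.kind!r}")
        w = np.asarray(self.weights, dtype=float)
        if len(self.states) != len(w):
            raise ValueError("one weight per state required")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be >= 0 and sum to 1")
        n = {len(s) for s in self.states}
        if len(n) > 1:
            raise ValueError("all states must have the same number of vectors")


def average_rdc(model: DynamicsModel, tensor: SaupeTensor, pair="N-H",
                medium_label: str = "") -> RDCSet:
    """Population-weighted average couplings under a dynamics model.

    Per equation: d_obs = sum_k w_k * back_calculate(S, state_k vector).
    A static model reduces exactly to noise-free :func:`simulate_rdc`.
    """
    pt = get_pair_type(pair) if isinstance(pair, str) else pair
    per_state = [
        np.array([d.d_obs for d in simulate_rdc(tensor, state, pt)])
        for state in model.states
    ]
    avg = np.zeros(len(model.states[0]))
    for w, values in zip(model.weights, per_state):
        avg += w * values
    reference = model.states[0]
    data = [
        RDCDatum(vector=vec, d_obs=float(v), error=0.0, dmax=pt.dmax_unit,
                 index=k + 1, label=f"{pt.name}_{k + 1}")
        for k, (vec, v) in enumerate(zip(reference, avg))
    ]
    return RDCSet(data=data, medium_label=medium_label)


def _rotation_about_random_axis(rng, angle_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    t = np.deg2rad(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def _rotate_vectors(vectors, rot) -> list:
    out = []
    for vec in vectors:
        d = rot @ vec.as_array()
        out.append(make_vector((0.0, 0.0, 0.0), tuple(vec.r * d)))
    return out


@dataclass
class ValidationDataset:
    """Synthetic two-mobile-region validation data: one RDCSet per medium,
    with the mobile rows annotated (1-based equation indices)."""

    media: dict[str, RDCSet]
    mobile_indices: list[int]
    region_slices: list[tuple[int, int]]  # [start, stop) equation index ranges
    tensors: dict[str, SaupeTensor]


def make_validation_dataset(
    n_rigid: int = 233,
    n_mobile_regions: int = 2,
    region_size: int = 33,
    conformers_per_region: int = 100,
    noise_w: float = 1.0,
    rotation_angle_deg: float = 60.0,
    pairs: tuple = ("N-H", "Ca-Ha"),
    tensors: dict[str, SaupeTensor] | None = None,
    seed: int = 0,
) -> ValidationDataset:
    """Build the localized-validation scenario: a mostly rigid vector set
    with mobile regions whose couplings are conformer averages.

    Defaults emulate a ~300-residue protein with two mobile loop regions,
    couplings for the {N-H, Ca-Ha} vector pair per residue in two alignment
    media, conformers generated by rigid rotation of each region about a
    random axis (default 60 degrees), and +/-1 Hz uniform noise on every
    observation.  Rigid rows get static couplings from the reference tensor;
    mobile rows get the conformer-averaged value; noise is added to all.
    """
    if min(n_rigid, n_mobile_regions, region_size, conformers_per_region) < 1:
        raise ValueError("all sizes must be >= 1")
    tensors = dict(tensors or MEDIUM_TENSORS)
    rng = np.random.default_rng(seed)
    n_res = n_rigid + n_mobile_regions * region_size
    # interleave mobile regions inside the chain, loop-like
    gap = n_res // (n_mobile_regions + 1)
    region_res = []
    for r in range(n_mobile_regions):
        start = (r + 1) * gap - region_size // 2
        region_res.append((start, start + region_size))

    def residue_is_mobile(i: int) -> int | None:
        for r, (a, b) in enumerate(region_res):
            if a <= i < b:
                return r
        return None

    per_pair_vectors = {
        p: make_vectors(n_res, scheme="random",
                        seed=int(rng.integers(2**31)))
        for p in pairs
    }
    # conformers: one rotation per (region, conformer), shared across pairs
    # and media — the region moves as a rigid body
    rotations = [
        [_rotation_about_random_axis(rng, rotation_angle_deg)
         for _ in range(conformers_per_region)]
        for _ in range(n_mobile_regions)
    ]

    # equation layout: residue-major, pair-minor → index = i*len(pairs)+p+1
    mobile_indices: list[int] = []
    region_slices: list[tuple[int, int]] = []
    for a, b in region_res:
        region_slices.append((a * len(pairs) + 1, b * len(pairs) + 1))
        mobile_indices.extend(range(a * len(pairs) + 1, b * len(pairs) + 1))

    media: dict[str, RDCSet] = {}
    for label, tensor in tensors.items():
        data = []
        for i in range(n_res):
            region = residue_is_mobile(i)
            for p_idx, p in enumerate(pairs):
                pt = get_pair_type(p)
                vec = per_pair_vectors[p][i]
                base = RDCDatum(vector=vec, d_obs=0.0, error=0.0,
                                dmax=pt.dmax_unit, index=0)
                if region is None:
                    d_obs = back_calculate(tensor, base)
                else:
                    vals = []
                    for rot in rotations[region]:
                        rvec = _rotate_vectors([vec], rot)[0]
                        vals.append(back_calculate(
                            tensor,
                            RDCDatum(vector=rvec, d_obs=0.0, error=0.0,
                                     dmax=pt.dmax_unit, index=0),
                        ))
                    d_obs = float(np.mean(vals))
                idx = i * len(pairs) + p_idx + 1
                data.append(RDCDatum(
                    vector=vec, d_obs=d_obs, error=noise_w, dmax=pt.dmax_unit,
                    index=idx,
                    label=f"res{i + 1}_{p}" + ("" if region is None else "_mobile"),
                ))
        noise = rng.uniform(-noise_w, noise_w, size=len(data))
        from dataclasses import replace

        data = [replace(d, d_obs=d.d_obs + e) for d, e in zip(data, noise)]
        media[label] = RDCSet(data=data, medium_label=label)
    return ValidationDataset(
        media=media, mobile_indices=mobile_indices,
        region_slices=region_slices, tensors=tensors,
    )
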