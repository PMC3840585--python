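"""Scikit-learn style estimator over the SVD order-tensor fit.

The order-tensor fit is a linear regression from internuclear unit vectors
to observed couplings, so it composes naturally with sklearn tooling
(pipelines, cross-validation, ``clone``).  The estimator is a thin shell:
all numerics live in :mod:`rdcfit.svd`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .core import RDCDatum, RDCSet, SaupeTensor, get_pair_type, make_vector
from .svd import build_system, solve
from .tensor import anisotropy, diagonalize

__all__ = ["SaupeTensorRegressor"]


class SaupeTensorRegressor(RegressorMixin, BaseEstimator):
    """Least-squares Saupe order tensor from RDC observations.

    Parameters
    ----------
    pair : str, default "N-H"
        Nucleus pair; sets the maximum-coupling constant Dmax.
    bond_length : float, default 1.02
        Internuclear distance in Angstrom used to scale Dmax (couplings
        scale as 1/r^3).

    Attributes
    ----------
    tensor_ : SaupeTensor
        The fitted order tensor.
    s5_ : ndarray of shape (5,)
        Its five independent elements (sxx, syy, sxy, sxz, syz).
    singular_values_ : ndarray of shape (5,)
        Singular values of the design matrix, descending.
    rank_ : int
    residual_rms_ : float
        Root-mean-square misfit in Hz.

    Examples
    --------
    >>> from rdcfit.synthetic import MEDIUM_TENSORS, make_vectors
    >>> from rdcfit.core import back_calculate, RDCDatum
    >>> reg = SaupeTensorRegressor()
    >>> X = [v.v for v in make_vectors(20)]
    >>> # y would be the measured couplings, in Hz
    """

    def __init__(self, pair: str = "N-H", bond_length: float = 1.02):
        self.pair = pair
        self.bond_length = bond_length

    def _to_rdcset(self, X, y) -> RDCSet:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must be an (n, 3) array of unit vectors")
        pt = get_pair_type(self.pair)
        data = []
        for k, (v, d) in enumerate(zip(X, y)):
            vec = make_vector((0.0, 0.0, 0.0), tuple(self.bond_length * v))
            data.append(RDCDatum(vector=vec, d_obs=float(d), error=0.0,
                                 dmax=pt.dmax_unit, index=k + 1))
        return RDCSet(data=data)

    def fit(self, X, y):
        """Fit the order tensor to couplings ``y`` (Hz) observed along the
        unit vectors ``X`` of shape (n, 3)."""
        y = np.asarray(y, dtype=float)
        solution = solve(build_system(self._to_rdcset(X, y)))
        self.tensor_ = solution.tensor
        self.s5_ = np.asarray(solution.tensor.s5)
        self.singular_values_ = solution.singular_values
        self.rank_ = solution.rank
        self.residual_rms_ = solution.residual_rms
        self.n_features_in_ = 3
        return self

    def predict(self, X):
        """Back-calculated couplings (Hz) for unit vectors ``X``."""
        if not hasattr(self, "tensor_"):
            raise AttributeError("this SaupeTensorRegressor is not fitted yet")
        X = np.asarray(X, dtype=float)
        pt = get_pair_type(self.pair)
        scale = pt.dmax_unit / self.bond_length**3
        m = self.tensor_.matrix
        return scale * np.einsum("ni,ij,nj->n", X, m, X)

    def decomposition(self):
        """Principal-frame decomposition of the fitted tensor."""
        return diagonalize(self.tensor_)

    def anisotropy(self, pairs=("C-N", "N-H", "C-H", "H-H")):
        """(Da by pair, rhombicity) of the fitted tensor."""
        return anisotropy(self.decomposition(), pairs)
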