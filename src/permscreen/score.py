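"""GLM score statistics for binary treatment vectors.

Three routes compute the same statistic

    z = x' a / sqrt(x' W x  -  x' W Z (Z' W Z)^{-1} Z' W x)

with a_i = w_i * (Y_i / mu_i - 1) = (Y_i - mu_i) / (1 + mu_i / theta):

* :class:`ScorePrecompute` / :func:`score_stat` — the fast spectral path,
  O(t q) per treatment set of size t after an O(n q^2) precomputation;
* :func:`score_stat_dense` — direct evaluation with an explicit matrix
  inverse (reference);
* :func:`score_stat_qr_oracle` — the classical QR-decomposition evaluation
  (reference).

The references exist to cross-check the fast path and are used by tests and
benchmarks only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nb_glm import NullFit

__all__ = [
    "ScorePrecompute",
    "DegenerateTreatmentError",
    "RankDeficiencyError",
    "precompute",
    "score_stat",
    "score_stat_many",
    "score_stat_dense",
    "score_stat_qr_oracle",
]


class DegenerateTreatmentError(ValueError):
    """Treatment set empty, full, or with nonpositive score variance."""


class RankDeficiencyError(ValueError):
    """Z' W Z is numerically singular."""


@dataclass
class ScorePrecompute:
    """Factors enabling O(t q) evaluation of the score statistic.

    ``a`` is the numerator kernel w * working_resid, ``D`` has rows
    ``w_i * Z_i`` and ``S`` maps a q-vector v to ``Lambda^{-1/2} Q' v`` so that
    ``||S v||^2 = v' (Z'WZ)^{-1} v``.
    """

    a: np.ndarray
    w: np.ndarray
    D: np.ndarray
    S: np.ndarray
    ztwz: np.ndarray

    @property
    def n(self) -> int:
        return len(self.a)


def precompute(fit: NullFit, Z: np.ndarray) -> ScorePrecompute:
    """Spectral factorization of Z'WZ plus the per-cell kernels."""
    Z = np.asarray(Z, dtype=float)
    w = fit.w
    a = w * fit.working_resid
    D = Z * w[:, None]
    ztwz = Z.T @ D
    evals, Q = np.linalg.eigh((ztwz + ztwz.T) / 2.0)
    if evals.min() <= 0:
        raise RankDeficiencyError("Z'WZ has a nonpositive eigenvalue")
    S = Q.T / np.sqrt(evals)[:, None]
    recon = (Q * evals) @ Q.T
    if np.max(np.abs(recon - ztwz)) > 1e-8 * max(1.0, np.max(np.abs(ztwz))):
        raise RankDeficiencyError("spectral reconstruction of Z'WZ failed")
    return ScorePrecompute(a=a, w=w, D=D, S=S, ztwz=ztwz)


def _variance(pc: ScorePrecompute, sw: float, dsum: np.ndarray) -> float:
    return sw - float(np.sum((pc.S @ dsum) ** 2))


def score_stat(x_idx: np.ndarray, pc: ScorePrecompute) -> float:
    """Score statistic for the treatment cells given by sorted indices."""
    x_idx = np.asarray(x_idx)
    t = len(x_idx)
    if t == 0 or t >= pc.n:
        raise DegenerateTreatmentError("treatment set must be a nonempty strict subset")
    num = float(pc.a[x_idx].sum())
    var = _variance(pc, float(pc.w[x_idx].sum()), pc.D[x_idx].sum(axis=0))
    if var <= 0:
        raise DegenerateTreatmentError(f"nonpositive score variance ({var:g})")
    return num / np.sqrt(var)


def score_stat_many(idx_matrix: np.ndarray, pc: ScorePrecompute) -> np.ndarray:
    """Vectorized :func:`score_stat` over a (B, t) matrix of index sets.

    Index sets with nonpositive variance yield NaN rather than raising, so a
    permutation batch never aborts.
    """
    idx_matrix = np.asarray(idx_matrix)
    num = pc.a[idx_matrix].sum(axis=1)
    sw = pc.w[idx_matrix].sum(axis=1)
    dsum = pc.D[idx_matrix].sum(axis=1)  # (B, q)
    l = dsum @ pc.S.T
    var = sw - np.einsum("bq,bq->b", l, l)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, num / np.sqrt(np.maximum(var, 1e-300)), np.nan)
    return z


def score_stat_dense(x: np.ndarray, fit: NullFit, Z: np.ndarray) -> float:
    """Direct evaluation with an explicit (Z'WZ)^{-1}; test oracle."""
    x = np.asarray(x, dtype=float)
    Z = np.asarray(Z, dtype=float)
    w = fit.w
    a = w * fit.working_resid
    num = float(x @ a)
    wx = w * x
    ztwx = Z.T @ wx
    ztwz = Z.T @ (Z * w[:, None])
    quad = float(ztwx @ np.linalg.inv(ztwz) @ ztwx)
    var = float(x @ wx) - quad
    if var <= 0:
        raise DegenerateTreatmentError(f"nonpositive score variance ({var:g})")
    return num / np.sqrt(var)


def score_stat_qr_oracle(x: np.ndarray, fit: NullFit, Z: np.ndarray) -> float:
    """QR-decomposition evaluation via the thin QR of W^{1/2} Z; test oracle."""
    x = np.asarray(x, dtype=float)
    Z = np.asarray(Z, dtype=float)
    w = fit.w
    sw = np.sqrt(w)
    Q, _ = np.linalg.qr(Z * sw[:, None])
    u = sw * x
    num = float(x @ (w * fit.working_resid))
    var = float(u @ u) - float(np.sum((Q.T @ u) ** 2))
    if var <= 0:
        raise DegenerateTreatmentError(f"nonpositive score variance ({var:g})")
    return num / np.sqrt(var)
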