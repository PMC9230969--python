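"""Rigid-body superposition (Kabsch), RMSD and the TM-score function.

The TM-score of an aligned residue set is

    TM = (1 / L_norm) * sum_i 1 / (1 + (d_i / d0)^2)

where d_i are the CA-CA distances of aligned pairs after optimal
superposition and d0 = max(0.5, 1.24 * (L_norm - 15)^(1/3) - 1.8) Angstroms
is the length-dependent distance scale that makes the score length-
independent.  Unaligned residues contribute zero, so TM is in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

D0_MIN = 0.5


class DegenerateGeometryError(ValueError):
    """Superposition target is rank-deficient (too few or collinear points)."""


@dataclass
class RigidTransform:
    """Proper rotation R plus translation t; maps x -> R @ x + t."""

    R: np.ndarray
    t: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.R.T + self.t

    def __post_init__(self):
        self.R = np.asarray(self.R, float)
        self.t = np.asarray(self.t, float)
        if abs(np.linalg.det(self.R) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_pairs: int
    tm_by_a: float | None = None
    tm_by_b: float | None = None

    @property
    def tm_avg(self) -> float:
        return 0.5 * (self.tm_by_a + self.tm_by_b)


def d0_of(L_norm: int) -> float:
    """TM-score distance scale for a normalising length, clamped at 0.5 A."""
    if L_norm < 1:
        raise ValueError("L_norm must be >= 1")
    raw = 1.24 * np.cbrt(max(L_norm - 15, 0)) - 1.8 if L_norm > 15 else -1.8
    return max(D0_MIN, raw)


def tm_score(pair_distances: np.ndarray, L_norm: int) -> float:
    """TM-score of aligned pairs at distances ``pair_distances`` (Angstroms)."""
    d = np.asarray(pair_distances, float)
    if L_norm < len(d):
        raise ValueError("L_norm must be >= number of aligned pairs")
    d0 = d0_of(L_norm)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / L_norm)


def kabsch_fit(coords_a: np.ndarray, coords_b: np.ndarray,
               L_norm_a: int | None = None, L_norm_b: int | None = None) -> SuperpositionResult:
    """Least-squares superposition of ``coords_b`` onto ``coords_a``.

    Returns the proper rotation/translation minimising the sum of squared
    pair distances (reflections excluded), the minimised RMSD, and — when
    the normalising lengths are given — TM-scores under both normalisations.
    """
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (n, 3)")
    n = len(a)
    if n < 3:
        raise DegenerateGeometryError("need at least 3 point pairs")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    H = (b - cb).T @ (a - ca)
    if np.linalg.matrix_rank(H) < 2:
        raise DegenerateGeometryError("rank-deficient covariance (collinear points)")
    U, S, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    moved = b @ R.T + t
    d = np.linalg.norm(moved - a, axis=1)
    rmsd = float(np.sqrt(np.mean(d ** 2)))
    tm_a = tm_score(d, L_norm_a) if L_norm_a is not None else None
    tm_b = tm_score(d, L_norm_b) if L_norm_b is not None else None
    return SuperpositionResult(RigidTransform(R, t), rmsd, n, tm_a, tm_b)
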