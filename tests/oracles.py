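"""Independent brute-force oracles used by the tests.

These deliberately share no code with the implementation: the alignment
oracle enumerates every monotone pairing, and the superposition oracle
scans a rotation grid and polishes numerically.
"""

from itertools import combinations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def gap_runs(indices, length):
    """Number of maximal unmatched blocks in a sequence of ``length``
    residues of which ``indices`` are matched."""
    matched = np.zeros(length, dtype=bool)
    matched[list(indices)] = True
    runs = 0
    prev = True
    for m in matched:
        if not m and prev:
            runs += 1
        prev = m
    return runs


def pairing_score(S, rows, cols, gap_open):
    la, lb = S.shape
    s = sum(S[i, j] for i, j in zip(rows, cols))
    return s + gap_open * (gap_runs(rows, la) + gap_runs(cols, lb))


def brute_force_align(S, gap_open=-0.6):
    """Best score over all monotone pairings (including the empty one)."""
    la, lb = S.shape
    best = gap_open * ((la > 0) + (lb > 0))  # empty pairing
    for k in range(1, min(la, lb) + 1):
        for rows in combinations(range(la), k):
            for cols in combinations(range(lb), k):
                sc = pairing_score(S, rows, cols, gap_open)
                if sc > best:
                    best = sc
    return best


def _rmsd_for_angles(angles, a, b):
    R = Rotation.from_euler("zyx", angles).as_matrix()
    moved = (b - b.mean(axis=0)) @ R.T
    target = a - a.mean(axis=0)
    return np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1)))


def grid_refine_rmsd(a, b, coarse_deg=20.0):
    """Minimum RMSD over rotations: dense Euler grid then local refinement."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    grid = np.deg2rad(np.arange(-180.0, 180.0, coarse_deg))
    half = np.deg2rad(np.arange(-90.0, 90.1, coarse_deg))
    best, best_angles = np.inf, None
    for z in grid:
        for y in half:
            for x in grid:
                r = _rmsd_for_angles((z, y, x), a, b)
                if r < best:
                    best, best_angles = r, (z, y, x)
    res = minimize(_rmsd_for_angles, best_angles, args=(a, b),
                   method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
    return min(best, float(res.fun))
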