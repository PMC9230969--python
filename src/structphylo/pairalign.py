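"""Sequence-independent pairwise structural alignment.

The aligner follows the classic iterative scheme of the TM-align family:
starting from several deterministic initial residue pairings (gapless
threadings, a sequence-identity alignment, and fragment seeds from the
best-superposing 20-residue windows), it alternates rigid superposition on
the current pairing with a global dynamic-programming realignment under the
TM-score residue weight 1/(1 + (d_ij/d0)^2), and keeps the candidate with
the highest length-averaged TM-score.  Everything is deterministic: fixed
candidate order, fixed tie-breaks, no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.spatial.distance import cdist

from structphylo.structio import DistanceMatrix, StructureModel
from structphylo.superpose import SuperpositionResult, d0_of, kabsch_fit, tm_score

WINDOW = 20  # fragment-seed window length (residues)


@dataclass
class AlignParams:
    """Controls for the iterative aligner.

    gap_open is charged once per maximal gap run on the TM-term score scale,
    with free extension (no separate extension penalty); terminal runs pay
    it too.  outlier_cut (Angstroms) enables optional
    refine-trim cycles that drop far pairs before the final RMSD — it
    emulates the RMSD of interactive superposition tools and never touches
    the TM-score.
    """

    gap_open: float = -0.6
    max_iter: int = 20
    conv_tol: float = 1e-5
    outlier_cut: float | None = None

    def __post_init__(self):
        if self.gap_open > 0:
            raise ValueError("gap_open must be <= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class PairwiseStructAlignment:
    id_a: str
    id_b: str
    pairing: list  # [(i_in_a, j_in_b), ...] strictly increasing in both
    result: SuperpositionResult
    converged: bool
    n_iter: int
    rmsd_trimmed: float | None = None
    n_pairs_trimmed: int | None = None


@njit(cache=True)
def _gotoh_fill_traceback(S, gap_open):
    """Three-state global DP: each maximal gap run costs ``gap_open`` once
    and extends for free (the TM-align family convention).  Traceback
    prefers match, then a gap in the second model (consuming the first
    model's residue), then a gap in the first."""
    la, lb = S.shape
    NEG = -1e18
    M = np.full((la + 1, lb + 1), NEG)
    Ix = np.full((la + 1, lb + 1), NEG)  # gap in b: consumes a
    Iy = np.full((la + 1, lb + 1), NEG)  # gap in a: consumes b
    # predecessor state per cell: 0=M, 1=Ix, 2=Iy, -1=start
    pM = np.full((la + 1, lb + 1), -1, dtype=np.int8)
    pX = np.full((la + 1, lb + 1), -1, dtype=np.int8)
    pY = np.full((la + 1, lb + 1), -1, dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        Ix[i, 0] = gap_open
        pX[i, 0] = 0 if i == 1 else 1
    for j in range(1, lb + 1):
        Iy[0, j] = gap_open
        pY[0, j] = 0 if j == 1 else 2
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            # match state
            best, arg = M[i - 1, j - 1], 0
            if Ix[i - 1, j - 1] > best:
                best, arg = Ix[i - 1, j - 1], 1
            if Iy[i - 1, j - 1] > best:
                best, arg = Iy[i - 1, j - 1], 2
            M[i, j] = best + S[i - 1, j - 1]
            pM[i, j] = arg
            # gap in b (vertical)
            best, arg = M[i - 1, j] + gap_open, 0
            if Ix[i - 1, j] > best:
                best, arg = Ix[i - 1, j], 1
            if Iy[i - 1, j] + gap_open > best:
                best, arg = Iy[i - 1, j] + gap_open, 2
            Ix[i, j] = best
            pX[i, j] = arg
            # gap in a (horizontal)
            best, arg = M[i, j - 1] + gap_open, 0
            if Ix[i, j - 1] + gap_open > best:
                best, arg = Ix[i, j - 1] + gap_open, 1
            if Iy[i, j - 1] > best:
                best, arg = Iy[i, j - 1], 2
            Iy[i, j] = best
            pY[i, j] = arg
    state = 0
    score = M[la, lb]
    if Ix[la, lb] > score:
        score, state = Ix[la, lb], 1
    if Iy[la, lb] > score:
        score, state = Iy[la, lb], 2
    out_i = np.empty(min(la, lb), dtype=np.int64)
    out_j = np.empty(min(la, lb), dtype=np.int64)
    k = 0
    i, j = la, lb
    while i > 0 or j > 0:
        if state == 0:
            k += 1
            out_i[len(out_i) - k] = i - 1
            out_j[len(out_j) - k] = j - 1
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            state = pX[i, j]
            i -= 1
        else:
            state = pY[i, j]
            j -= 1
    return score, out_i[len(out_i) - k:], out_j[len(out_j) - k:]


@njit(cache=True)
def _nw_linear_fill_traceback(S, gap):
    """Plain global DP with a per-column linear gap penalty (used only for
    the sequence-identity seed, where free gap extension would degenerate
    into a longest-common-subsequence match)."""
    la, lb = S.shape
    H = np.empty((la + 1, lb + 1))
    for i in range(la + 1):
        H[i, 0] = i * gap
    for j in range(lb + 1):
        H[0, j] = j * gap
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            best = H[i - 1, j - 1] + S[i - 1, j - 1]
            if H[i - 1, j] + gap > best:
                best = H[i - 1, j] + gap
            if H[i, j - 1] + gap > best:
                best = H[i, j - 1] + gap
            H[i, j] = best
    out_i = np.empty(min(la, lb), dtype=np.int64)
    out_j = np.empty(min(la, lb), dtype=np.int64)
    k = 0
    i, j = la, lb
    while i > 0 and j > 0:
        if H[i, j] == H[i - 1, j - 1] + S[i - 1, j - 1]:
            k += 1
            out_i[len(out_i) - k] = i - 1
            out_j[len(out_j) - k] = j - 1
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] + gap:
            i -= 1
        else:
            j -= 1
    return H[la, lb], out_i[len(out_i) - k:], out_j[len(out_j) - k:]


def dp_align(score_matrix: np.ndarray, gap_open: float = -0.6):
    """Monotone pairing maximising total score minus gap-run penalties.

    Each maximal run of gapped residues (per model, terminal runs included)
    costs ``gap_open`` once; extending a run is free.  Returns
    (pairing, score).  Ties resolve toward lower indices in the first model
    then the second (diagonal-preferring traceback).
    """
    S = np.ascontiguousarray(score_matrix, dtype=np.float64)
    if not np.all(np.isfinite(S)):
        raise ValueError("score matrix must be finite")
    score, ii, jj = _gotoh_fill_traceback(S, float(gap_open))
    return list(zip(ii.tolist(), jj.tolist())), float(score)


def _threading_offsets(la: int, lb: int):
    """Gapless threadings of the shorter chain onto the longer."""
    lo, hi = min(la, lb), max(la, lb)
    step = max(1, int(np.ceil(hi / 20)))
    offsets = sorted(set(list(range(0, hi - lo + 1, step)) + [hi - lo]))
    pairings = []
    for off in offsets:
        if la >= lb:
            pairings.append([(off + k, k) for k in range(lo)])
        else:
            pairings.append([(k, off + k) for k in range(lo)])
    return pairings


def _seq_identity_pairing(a: StructureModel, b: StructureModel, gap_open: float):
    sa = np.frombuffer(a.seq.encode(), dtype=np.uint8)
    sb = np.frombuffer(b.seq.encode(), dtype=np.uint8)
    S = (sa[:, None] == sb[None, :]).astype(np.float64)
    _, ii, jj = _nw_linear_fill_traceback(S, float(gap_open))
    return list(zip(ii.tolist(), jj.tolist()))


def _fragment_seeds(a: StructureModel, b: StructureModel, n_best: int = 3):
    """Diagonal threadings through the best-superposing 20-residue windows."""
    la, lb = a.L, b.L
    if la < WINDOW or lb < WINDOW:
        return []
    sa = max(1, (la - WINDOW) // 12)
    sb = max(1, (lb - WINDOW) // 12)
    cands = []
    for i0 in range(0, la - WINDOW + 1, sa):
        wa = a.coords[i0 : i0 + WINDOW]
        for j0 in range(0, lb - WINDOW + 1, sb):
            wb = b.coords[j0 : j0 + WINDOW]
            rmsd = kabsch_fit(wa, wb).rmsd
            cands.append((rmsd, i0, j0))
    cands.sort()
    pairings = []
    for rmsd, i0, j0 in cands[:n_best]:
        shift = i0 - j0  # extend the register maximally in both directions
        i_start = max(0, shift)
        j_start = i_start - shift
        n = min(la - i_start, lb - j_start)
        pairings.append([(i_start + k, j_start + k) for k in range(n)])
    return pairings


def initial_pairings(a: StructureModel, b: StructureModel,
                     gap_open: float = -0.6) -> list:
    """Deterministic candidate pairings seeding the iterative aligner."""
    cands = _threading_offsets(a.L, b.L)
    seqp = _seq_identity_pairing(a, b, gap_open)
    if len(seqp) >= 3:
        cands.append(seqp)
    cands.extend(_fragment_seeds(a, b))
    seen, out = set(), []
    for p in cands:
        key = tuple(p)
        if key not in seen and len(p) >= 3:
            seen.add(key)
            out.append(p)
    return out


def _score_matrix(coords_a, coords_b_moved, d0):
    D = cdist(coords_a, coords_b_moved)
    return 1.0 / (1.0 + (D / d0) ** 2)


def _fit_on_pairing(a, b, pairing):
    idx_a = [i for i, _ in pairing]
    idx_b = [j for _, j in pairing]
    return kabsch_fit(a.coords[idx_a], b.coords[idx_b], L_norm_a=a.L, L_norm_b=b.L)


def _focused_fit(a, b, pairing, d0):
    """Superposition weighted toward the well-fitting subset of pairs.

    Starting from the all-pairs Kabsch fit, re-fit a few times on the pairs
    closer than max(d0, 3.5) A (falling back to the closest half), so a
    rigid common core dominates the transform even when much of the pairing
    crosses divergent or inserted regions.  TM-scores over the full pairing
    are evaluated under this transform; the plain all-pairs fit still
    defines the reported RMSD.
    """
    pa = a.coords[[i for i, _ in pairing]]
    pb = b.coords[[j for _, j in pairing]]
    # initial transform: the all-pairs fit competes against fits on
    # contiguous windows of the pairing; when much of the pairing crosses
    # unrelated regions, one window sits inside the true rigid core and
    # wins on full-pairing TM
    n = len(pairing)
    fit = kabsch_fit(pa, pb)
    best_tm = tm_score(np.linalg.norm(fit.transform.apply(pb) - pa, axis=1),
                       max(a.L, b.L))
    if n >= 60:
        w = max(30, n // 8)
        for s in range(0, n - w + 1, w):
            try:
                wfit = kabsch_fit(pa[s:s + w], pb[s:s + w])
            except Exception:
                continue
            t = tm_score(np.linalg.norm(wfit.transform.apply(pb) - pa, axis=1),
                         max(a.L, b.L))
            if t > best_tm:
                best_tm, fit = t, wfit
    final_cut = max(d0, 3.5)
    # annealed cuts: lock onto the dominant rigid subset even from a poor
    # initial transform, then tighten to the TM-relevant scale
    cuts = [8 * final_cut, 4 * final_cut, 2 * final_cut,
            final_cut, final_cut, final_cut]
    floor = max(20, len(pairing) // 8) if len(pairing) > 30 else 3
    for cut in cuts:
        d = np.linalg.norm(fit.transform.apply(pb) - pa, axis=1)
        keep = d < cut
        if keep.sum() < floor:
            k = min(floor, len(d) - 1)
            keep = d <= np.partition(d, k)[k]
        if keep.all():
            continue
        try:
            fit = kabsch_fit(pa[keep], pb[keep])
        except Exception:
            break
    d = np.linalg.norm(fit.transform.apply(pb) - pa, axis=1)
    tm_a = tm_score(d, a.L)
    tm_b = tm_score(d, b.L)
    return SuperpositionResult(fit.transform, float(np.sqrt(np.mean(d ** 2))),
                               len(pairing), tm_a, tm_b)


def iterate_align(a: StructureModel, b: StructureModel,
                  params: AlignParams | None = None) -> PairwiseStructAlignment:
    """Iterative superposition/realignment; best candidate by tm_avg."""
    params = params or AlignParams()
    d0_iter = d0_of(min(a.L, b.L))
    best = None
    for start in initial_pairings(a, b, params.gap_open):
        pairing = start
        fit = _focused_fit(a, b, pairing, d0_iter)
        best_pairing, best_fit = pairing, fit
        prev_tm = fit.tm_avg
        converged = False
        n_iter = 0
        for n_iter in range(1, params.max_iter + 1):
            moved = fit.transform.apply(b.coords)
            S = _score_matrix(a.coords, moved, d0_iter)
            new_pairing, _ = dp_align(S, params.gap_open)
            if len(new_pairing) < 3:
                break
            new_fit = _focused_fit(a, b, new_pairing, d0_iter)
            if new_fit.tm_avg > best_fit.tm_avg:
                best_pairing, best_fit = new_pairing, new_fit
            if new_pairing == pairing or abs(new_fit.tm_avg - prev_tm) < params.conv_tol:
                converged = True
                break
            pairing, fit, prev_tm = new_pairing, new_fit, new_fit.tm_avg
        cand = PairwiseStructAlignment(a.id, b.id, best_pairing, best_fit, converged, n_iter)
        if best is None or cand.result.tm_avg > best.result.tm_avg:
            best = cand
    if best is None:
        raise ValueError("no viable initial pairing (models too short?)")
    # sharpening stage: once the global basin is found, re-iterate with a
    # tighter distance scale so near-register solutions snap to the exact
    # register; kept only when the standard-scale TM improves
    d0_sharp = max(2.0, 0.5 * d0_iter)
    pairing, fit = best.pairing, best.result
    for _ in range(params.max_iter // 2):
        S = _score_matrix(a.coords, fit.transform.apply(b.coords), d0_sharp)
        new_pairing, _ = dp_align(S, params.gap_open)
        if len(new_pairing) < 3 or new_pairing == pairing:
            break
        new_fit = _focused_fit(a, b, new_pairing, d0_iter)
        if new_fit.tm_avg <= fit.tm_avg:
            break
        pairing, fit = new_pairing, new_fit
    if fit.tm_avg > best.result.tm_avg:
        best = PairwiseStructAlignment(a.id, b.id, pairing, fit,
                                       best.converged, best.n_iter)
    # reported RMSD: least-squares over the full final pairing
    best.result = SuperpositionResult(
        best.result.transform, _fit_on_pairing(a, b, best.pairing).rmsd,
        best.result.n_pairs, best.result.tm_by_a, best.result.tm_by_b,
    )
    if params.outlier_cut is not None:
        best.rmsd_trimmed, best.n_pairs_trimmed = _outlier_trimmed_rmsd(
            a, b, best.pairing, params.outlier_cut
        )
    return best


def _outlier_trimmed_rmsd(a, b, pairing, cut, max_cycles: int = 5):
    """Refine-trim cycles dropping pairs beyond ``cut`` Angstroms; RMSD only."""
    pairs = list(pairing)
    fit = _fit_on_pairing(a, b, pairs)
    for _ in range(max_cycles):
        idx_a = [i for i, _ in pairs]
        idx_b = [j for _, j in pairs]
        d = np.linalg.norm(fit.transform.apply(b.coords[idx_b]) - a.coords[idx_a], axis=1)
        keep = d <= cut
        if keep.all() or keep.sum() < 3:
            break
        pairs = [p for p, k in zip(pairs, keep) if k]
        fit = _fit_on_pairing(a, b, pairs)
    return fit.rmsd, len(pairs)


def tm_matrix(models: list, params: AlignParams | None = None) -> DistanceMatrix:
    """Symmetric matrix of pairwise tm_avg; diagonal 1 by convention."""
    ids = [m.id for m in models]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate model ids")
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    n = len(models)
    M = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            aln = iterate_align(models[i], models[j], params)
            M[i, j] = M[j, i] = aln.result.tm_avg
    return DistanceMatrix(ids, M)
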