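"""Progressive multiple structure alignment and conserved-core extraction.

Models are merged pairwise along an NJ guide tree computed from 1 - TM
distances.  At internal nodes, sub-alignments are aligned to each other
through pseudo-structures: per-column mean CA coordinates over the members
present in the column.  After the root merge, every model is superposed
into a common frame (reference = lexicographically first model id) and the
frames are refined for a few rounds.

The conserved core is then read off per column: a column belongs to the
core when it is fully occupied and the maximum pairwise CA distance among
its members, measured in the final common frame, is below the threshold
(4 A by default) — the same criterion used to colour the conserved
magenta regions of structural alignments of sheath proteins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from structphylo.pairalign import AlignParams, iterate_align
from structphylo.phylo import PhyloTree, nj_tree, tm_to_distance
from structphylo.structio import DistanceMatrix, SequenceRecord, StructureModel
from structphylo.superpose import RigidTransform, kabsch_fit

GAP = -1


@dataclass
class CoreCriterion:
    """Column rule for conserved-core membership."""

    max_pairwise_dist: float = 4.0
    require_full_occupancy: bool = True

    def __post_init__(self):
        if self.max_pairwise_dist <= 0:
            raise ValueError("max_pairwise_dist must be positive")


@dataclass
class MultipleStructAlignment:
    model_ids: list
    columns: np.ndarray  # (n_columns, n_models) residue index or GAP
    frames: dict  # model_id -> RigidTransform into the common frame
    models: dict  # model_id -> StructureModel
    col_maxdist: np.ndarray = field(default=None)
    core_mask: np.ndarray = field(default=None)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def column_coords(self, col: int) -> np.ndarray:
        """Common-frame CA coordinates of members present in a column."""
        out = []
        for k, mid in enumerate(self.model_ids):
            idx = self.columns[col, k]
            if idx != GAP:
                out.append(self.frames[mid].apply(self.models[mid].coords[idx]))
        return np.array(out)

    def validate(self) -> None:
        """Assert the column-order invariant for every model."""
        for k in range(len(self.model_ids)):
            occ = self.columns[self.columns[:, k] != GAP, k]
            if np.any(np.diff(occ) <= 0):
                raise AssertionError(f"column order violated for {self.model_ids[k]}")

    def core_intervals(self) -> dict:
        """Per-model core residues as 0-based half-open intervals."""
        out = {}
        for k, mid in enumerate(self.model_ids):
            idx = sorted(
                int(self.columns[c, k])
                for c in range(self.n_columns)
                if self.core_mask[c] and self.columns[c, k] != GAP
            )
            ivs, start = [], None
            prev = None
            for i in idx:
                if start is None:
                    start = prev = i
                elif i == prev + 1:
                    prev = i
                else:
                    ivs.append((start, prev + 1))
                    start = prev = i
            if start is not None:
                ivs.append((start, prev + 1))
            out[mid] = ivs
        return out

    def to_json(self, path) -> None:
        payload = {
            "model_ids": self.model_ids,
            "columns": [
                [None if v == GAP else int(v) for v in row] for row in self.columns
            ],
            "col_maxdist": [None if np.isnan(v) else round(float(v), 4)
                            for v in self.col_maxdist],
            "core_mask": [bool(v) for v in self.core_mask],
            "frames": {
                mid: {"R": tr.R.tolist(), "t": tr.t.tolist()}
                for mid, tr in self.frames.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# internal sub-alignment used during the progressive merge
# ---------------------------------------------------------------------------

class _SubAlignment:
    def __init__(self, ids, columns, frames, models):
        self.ids = ids            # ordered member ids
        self.columns = columns    # (ncol, nmember) int
        self.frames = frames      # id -> RigidTransform (into sub frame)
        self.models = models

    @classmethod
    def leaf(cls, model: StructureModel):
        cols = np.arange(model.L, dtype=int).reshape(-1, 1)
        ident = RigidTransform(np.eye(3), np.zeros(3))
        return cls([model.id], cols, {model.id: ident}, {model.id: model})

    def pseudo_model(self, tag: str) -> StructureModel:
        """Column-averaged coordinates with a majority-consensus sequence
        (the consensus lets the sequence-identity seed work at internal
        merge nodes, where structures alone can be ambiguous)."""
        coords = np.empty((len(self.columns), 3))
        seq = []
        for c, row in enumerate(self.columns):
            pts, letters = [], []
            for mid, idx in zip(self.ids, row):
                if idx != GAP:
                    pts.append(self.frames[mid].apply(self.models[mid].coords[idx]))
                    letters.append(self.models[mid].seq[idx])
            coords[c] = np.mean(pts, axis=0)
            seq.append(max(sorted(set(letters)), key=letters.count))
        return StructureModel(tag, "".join(seq), coords)


def _merge_two(A: _SubAlignment, B: _SubAlignment, params: AlignParams) -> _SubAlignment:
    pa = A.pseudo_model("_a")
    pb = B.pseudo_model("_b")
    aln = iterate_align(pa, pb, params)
    R, t = aln.result.transform.R, aln.result.transform.t
    new_frames = dict(A.frames)
    for mid, tr in B.frames.items():
        new_frames[mid] = RigidTransform(R @ tr.R, R @ tr.t + t)
    # interleave columns: between paired columns, unpaired A columns first
    na, nb = len(A.columns), len(B.columns)
    gap_a = np.full(len(A.ids), GAP, dtype=int)
    gap_b = np.full(len(B.ids), GAP, dtype=int)
    rows = []
    ia = ib = 0
    for ca, cb in aln.pairing:
        while ia < ca:
            rows.append(np.concatenate([A.columns[ia], gap_b])); ia += 1
        while ib < cb:
            rows.append(np.concatenate([gap_a, B.columns[ib]])); ib += 1
        rows.append(np.concatenate([A.columns[ca], B.columns[cb]]))
        ia, ib = ca + 1, cb + 1
    while ia < na:
        rows.append(np.concatenate([A.columns[ia], gap_b])); ia += 1
    while ib < nb:
        rows.append(np.concatenate([gap_a, B.columns[ib]])); ib += 1
    return _SubAlignment(A.ids + B.ids, np.array(rows, dtype=int), new_frames,
                         {**A.models, **B.models})


def guide_tree(tm: DistanceMatrix) -> PhyloTree:
    """NJ guide tree on 1 - TM distances (merge order only)."""
    return nj_tree(tm_to_distance(tm))


def progressive_merge(models: list, guide: PhyloTree,
                      params: AlignParams | None = None,
                      max_refine_rounds: int = 10,
                      refine_tol: float = 0.01) -> MultipleStructAlignment:
    """Merge models along the guide tree, then refine a common frame."""
    params = params or AlignParams()
    by_id = {m.id: m for m in models}
    leaf_ids = set(guide.leaf_labels)
    if leaf_ids != set(by_id):
        raise ValueError(
            f"guide-tree leaves {sorted(leaf_ids)} do not match models {sorted(by_id)}"
        )

    def build(node) -> _SubAlignment:
        if node.is_leaf():
            return _SubAlignment.leaf(by_id[node.taxon.label])
        subs = [build(ch) for ch in node.child_nodes()]
        acc = subs[0]
        for nxt in subs[1:]:
            acc = _merge_two(acc, nxt, params)
        return acc

    sub = build(guide.dtree.seed_node)
    order = sorted(sub.ids)
    perm = [sub.ids.index(mid) for mid in order]
    columns = sub.columns[:, perm]
    msa = MultipleStructAlignment(order, columns, dict(sub.frames), dict(by_id))
    _refine_frames(msa, max_refine_rounds, refine_tol)
    msa.validate()
    _compute_col_maxdist(msa)
    return msa


def _refine_frames(msa: MultipleStructAlignment, max_rounds: int, tol: float) -> None:
    ref = msa.model_ids[0]  # lexicographically first (ids are sorted)
    # re-express every frame relative to the reference model
    Rr, tr = msa.frames[ref].R, msa.frames[ref].t
    Rinv, tinv = Rr.T, -Rr.T @ tr
    for mid in msa.model_ids:
        f = msa.frames[mid]
        msa.frames[mid] = RigidTransform(Rinv @ f.R, Rinv @ f.t + tinv)
    full = np.all(msa.columns != GAP, axis=1)
    if not full.any():
        return
    prev_mean = None
    for _ in range(max_rounds):
        placed = {
            mid: msa.frames[mid].apply(msa.models[mid].coords) for mid in msa.model_ids
        }
        for k, mid in enumerate(msa.model_ids):
            if mid == ref:
                continue
            idx_self = msa.columns[full, k]
            targets = np.empty((int(full.sum()), 3))
            for r, c in enumerate(np.nonzero(full)[0]):
                pts = [
                    placed[other][msa.columns[c, kk]]
                    for kk, other in enumerate(msa.model_ids) if other != mid
                ]
                targets[r] = np.mean(pts, axis=0)
            fit = kabsch_fit(targets, msa.models[mid].coords[idx_self])
            msa.frames[mid] = fit.transform
            placed[mid] = fit.transform.apply(msa.models[mid].coords)
        _compute_col_maxdist(msa)
        mean_now = float(np.nanmean(msa.col_maxdist[full]))
        if prev_mean is not None and abs(mean_now - prev_mean) < tol:
            break
        prev_mean = mean_now


def _compute_col_maxdist(msa: MultipleStructAlignment) -> None:
    md = np.full(msa.n_columns, np.nan)
    placed = {mid: msa.frames[mid].apply(msa.models[mid].coords) for mid in msa.model_ids}
    for c in range(msa.n_columns):
        pts = [
            placed[mid][msa.columns[c, k]]
            for k, mid in enumerate(msa.model_ids)
            if msa.columns[c, k] != GAP
        ]
        if len(pts) >= 2:
            P = np.array(pts)
            diff = P[:, None, :] - P[None, :, :]
            md[c] = float(np.sqrt((diff ** 2).sum(-1)).max())
        else:
            md[c] = 0.0
    msa.col_maxdist = md


def core_columns(msa: MultipleStructAlignment,
                 crit: CoreCriterion | None = None) -> np.ndarray:
    """Boolean core mask per column under the occupancy + distance rule."""
    crit = crit or CoreCriterion()
    if msa.col_maxdist is None:
        _compute_col_maxdist(msa)
    occupancy = np.sum(msa.columns != GAP, axis=1)
    if crit.require_full_occupancy:
        occ_ok = occupancy == len(msa.model_ids)
    else:
        occ_ok = occupancy >= 2
    mask = occ_ok & (msa.col_maxdist < crit.max_pairwise_dist)
    msa.core_mask = mask
    return mask


def trim_to_core(msa: MultipleStructAlignment, sequences: list) -> list:
    """Core-trimmed gapped sequence alignment (one row per model)."""
    if msa.core_mask is None:
        raise ValueError("core mask not computed; call core_columns first")
    by_id = {r.id: r for r in sequences}
    for mid in msa.model_ids:
        if mid not in by_id:
            raise ValueError(f"no sequence provided for model {mid}")
        if len(by_id[mid].seq) != msa.models[mid].L:
            raise ValueError(
                f"sequence length mismatch for model {mid}: "
                f"{len(by_id[mid].seq)} vs {msa.models[mid].L} residues"
            )
    core_cols = np.nonzero(msa.core_mask)[0]
    out = []
    for k, mid in enumerate(msa.model_ids):
        row = []
        for c in core_cols:
            idx = msa.columns[c, k]
            row.append("-" if idx == GAP else by_id[mid].seq[idx])
        out.append(SequenceRecord(mid, "".join(row)))
    return out
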