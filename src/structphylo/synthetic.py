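"""Synthetic structure families with known evolutionary truth.

The generator emulates the salient features of a contractile-sheath protein
family: a rigid conserved core whose N-terminal and C-terminal thirds pack
against each other in space (so the core is sequence-discontinuous), a
middle section elsewhere, structural divergence that scales with tree
branch length, and lineage-specific insertions of compact accessory
("decoy") domains displaced away from the core.  All geometry is an
idealised CA trace: serpentine slabs of extended strands and ideal helices
resampled to exact 3.8 A consecutive CA spacing.  Decoy domains are
two-layer slabs of short paired strands — geometric stand-ins for Ig-like
beta-sandwiches; the test surface is recovery of domain counts and
boundaries, not fold identity.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import random
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from structphylo.phylo import PhyloTree
from structphylo.structio import (
    AA_ALPHABET,
    SequenceRecord,
    StructureModel,
    write_fasta,
    write_pdb,
)

CA_STEP = 3.8
HELIX_RADIUS = 2.28   # gives a 3.8 A CA-CA chord at 100 deg/residue, 1.5 A rise
HELIX_RISE = 1.5
HELIX_TURN = np.deg2rad(100.0)


@dataclass
class SimulationParams:
    """Study conditions for a synthetic family.

    noise_sigma is the per-coordinate Gaussian jitter (A) per unit branch
    length; branch_length sets every edge of the built-in tree shapes.
    domain_plan maps each taxon (sorted leaf order) to a list of
    (insertion_point, decoy_length, offset_vector-or-None); None uses the
    default plan where taxon i carries i mod 4 decoys.
    """

    n_taxa: int = 6
    tree_shape: str = "ladder"  # "ladder", "yule", or a Newick string
    core_length: int = 300
    noise_sigma: float = 0.5
    branch_length: float = 1.4
    decoy_length: int = 55
    mut_rate: float = 0.1  # substitutions per site per unit branch length
    domain_plan: dict | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        if self.core_length < 80:
            raise ValueError("core_length must be >= 80")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth sufficient to score every downstream stage."""

    true_tree: PhyloTree
    # taxon -> array: position k holds the chain index of core residue k
    true_core_map: dict
    # taxon -> list of (start, end, label) half-open residue intervals
    true_domains: dict
    params: SimulationParams = None

    def n_true_domains(self, taxon: str) -> int:
        labels = {lab for _, _, lab in self.true_domains[taxon]}
        return 1 + len({l for l in labels if l != "core"})

    def true_columns(self) -> np.ndarray:
        """Core homology map as an MSA column table (taxa in sorted order)."""
        taxa = sorted(self.true_core_map)
        return np.stack([self.true_core_map[t] for t in taxa], axis=1)


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def _resample_chain(path: np.ndarray, n_points: int, step: float = CA_STEP) -> np.ndarray:
    """Place points along a polyline with exact Euclidean spacing ``step``.

    Each point is the first position further along the polyline whose
    straight-line distance from the previous point equals ``step``.  If the
    polyline runs out, the chain is extended along the final direction.
    """
    pts = [path[0]]
    seg, lo = 0, 0.0
    while len(pts) < n_points:
        cur = pts[-1]
        placed = False
        s, u0 = seg, lo
        while s < len(path) - 1:
            a, b = path[s], path[s + 1]
            d = b - a
            f = a + u0 * d - cur
            # |f + u'*d| = step with u' in [0, 1-u0]
            aa = float(d @ d)
            if aa < 1e-12:
                s, u0 = s + 1, 0.0
                continue
            bb = 2.0 * float(f @ d)
            cc = float(f @ f) - step * step
            disc = bb * bb - 4 * aa * cc
            if disc >= 0:
                root = (-bb + np.sqrt(disc)) / (2 * aa)
                if 1e-12 < root <= 1.0 - u0 + 1e-12:
                    u = u0 + root
                    pts.append(a + u * d)
                    seg, lo = s, u
                    placed = True
                    break
            s, u0 = s + 1, 0.0
        if not placed:
            direction = path[-1] - path[-2]
            direction = direction / np.linalg.norm(direction)
            pts.append(cur + step * direction)
            seg, lo = len(path) - 2, 1.0
    return np.array(pts[:n_points])


def _helix_polyline(start: np.ndarray, axis: np.ndarray, length: float,
                    radius: float = HELIX_RADIUS, phase: float = 0.0) -> np.ndarray:
    """Densely sampled ideal helix around an axis segment."""
    axis = axis / np.linalg.norm(axis)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    rise_per_rad = HELIX_RISE / HELIX_TURN
    n_dense = max(2, int(length / 0.2))
    ts = np.linspace(0.0, length, n_dense)
    theta = phase + ts / rise_per_rad
    return (start[None, :] + ts[:, None] * axis[None, :]
            + radius * (np.cos(theta)[:, None] * u[None, :]
                        + np.sin(theta)[:, None] * v[None, :]))


def _slab_waypoints(origin: np.ndarray, n_strands: int, strand_len: float,
                    y_step: float, reverse_y: bool = False) -> list:
    """Serpentine of antiparallel strands along x in a single z layer."""
    pts = []
    x0, y0, z0 = origin
    for s in range(n_strands):
        y = y0 + (-(s * y_step) if reverse_y else s * y_step)
        if s % 2 == 0:
            pts += [np.array([x0, y, z0]), np.array([x0 + strand_len, y, z0])]
        else:
            pts += [np.array([x0 + strand_len, y, z0]), np.array([x0, y, z0])]
    return pts


def build_core_scaffold(core_length: int = 300, seed: int = 0) -> StructureModel:
    """Self-avoiding CA trace whose N- and C-terminal thirds pack together.

    The N-terminal third is a serpentine strand slab in the z = 0 layer, the
    C-terminal third the matching slab at z = 5.5 directly above it, and the
    middle third a pair of antiparallel ideal helices displaced in x; loops
    route around the slabs.  Deterministic per seed (the seed draws the
    amino-acid sequence and a sub-0.1 A waypoint dither).
    """
    rng = np.random.default_rng(seed)
    n_third = core_length // 3
    y_step = 5.5
    # keep the slab footprint roughly square so small cores stay compact
    strand_len = float(np.clip(np.sqrt(n_third * CA_STEP * y_step), 20.0, 60.0))
    unit = strand_len + y_step
    n_strands = max(2, int(np.ceil(n_third * CA_STEP / unit)))
    y_top = (n_strands - 1) * y_step
    # helix layer on top of the sandwich: short parallel helices whose
    # cylinders rest ~4 A above the C slab so the whole core is one
    # compact block; the count adapts to the middle-third size (odd, so
    # the zigzag exits at the bottom edge)
    total_axis = n_third * CA_STEP / 4.25 * HELIX_RISE
    n_h = max(1, min(5, round(total_axis / 27.0)))
    if n_h % 2 == 0:
        n_h += 1
    helix_len = max(8.0, total_axis / n_h)
    hx = np.linspace(5.0, strand_len - 4.0, n_h) if n_h > 1 \
        else np.array([strand_len / 2.0])
    hz = 12.0

    way = []
    way += _slab_waypoints(np.array([0.0, 0.0, 0.0]), n_strands, strand_len, y_step)
    end_n = way[-1]
    # loop over the slab top edge up to the first helix
    way += [np.array([end_n[0], y_top + 7.0, 2.0]),
            np.array([hx[0], y_top + 6.0, hz])]
    # zigzag helix layer: odd helices run -y, even run +y
    y_hi, y_lo = y_top + 2.0, y_top + 2.0 - helix_len
    for k in range(n_h):
        if k % 2 == 0:
            way += list(_helix_polyline(np.array([hx[k], y_hi, hz]),
                                        np.array([0.0, -1.0, 0.0]), helix_len))
            if k + 1 < n_h:
                way += [np.array([(hx[k] + hx[k + 1]) / 2, y_lo - 5.0, hz])]
        else:
            way += list(_helix_polyline(np.array([hx[k], y_lo, hz]),
                                        np.array([0.0, 1.0, 0.0]), helix_len))
            if k + 1 < n_h:
                way += [np.array([(hx[k] + hx[k + 1]) / 2, y_hi + 5.0, hz])]
    # n_h is odd, so the last helix ends at y_lo; route around the slab edge
    # (x beyond the strands, then y below them) into the C slab, which
    # ascends in y directly above the N slab
    way += [np.array([strand_len + 7.0, y_lo - 6.0, 9.0]),
            np.array([strand_len + 7.0, -6.0, 5.5]),
            np.array([-4.0, -6.0, 5.5]),
            np.array([0.0, 0.0, 5.5])]
    way += _slab_waypoints(np.array([0.0, 0.0, 5.5]), n_strands, strand_len, y_step)
    way = np.array(way)
    way = way + rng.uniform(-0.05, 0.05, size=way.shape)
    coords = _resample_chain(way, core_length)
    seq = "".join(rng.choice(list(AA_ALPHABET), size=core_length))
    return StructureModel("core_scaffold", seq, coords)


def _decoy_domain(length: int, rng: np.random.Generator) -> np.ndarray:
    """Compact two-layer slab of short paired strands, centred at origin,
    in a random orientation."""
    strand_len = 17.0
    y_step = 5.0
    per_layer = max(2, int(np.ceil(length * CA_STEP / 2.0 / (strand_len + y_step))))
    way = _slab_waypoints(np.array([0.0, 0.0, 0.0]), per_layer, strand_len, y_step)
    top = way[-1].copy()
    way += [top + np.array([-5.0, 2.5, 2.5]), np.array([0.0, 0.0, 5.0])]
    way += _slab_waypoints(np.array([0.0, 0.0, 5.0]), per_layer, strand_len, y_step)
    coords = _resample_chain(np.array(way), length)
    coords -= coords.mean(axis=0)
    # random proper rotation via QR
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return coords @ Q.T


def _repair_chain(coords: np.ndarray, n_sweeps: int = 5) -> np.ndarray:
    """Deterministic bond-length relaxation toward 3.8 A spacing.

    Each sweep distributes every bond-length correction equally to the
    bond's two endpoints (Jacobi style), so residues stay centred on their
    jittered positions and no register drift accumulates along the chain —
    a one-directional renormalisation would slowly slide the whole chain
    within its own path and decouple geometric from label homology.
    """
    out = coords.copy()
    for _ in range(n_sweeps):
        v = out[1:] - out[:-1]
        d = np.linalg.norm(v, axis=1)
        d[d < 1e-9] = 1e-9
        corr = 0.5 * ((d - CA_STEP) / d)[:, None] * v
        delta = np.zeros_like(out)
        delta[:-1] += corr
        delta[1:] -= corr
        out += delta
    return out


# ---------------------------------------------------------------------------
# trees and evolution
# ---------------------------------------------------------------------------

def _taxon_names(n: int) -> list:
    width = max(2, len(str(n)))
    return [f"t{str(i + 1).zfill(width)}" for i in range(n)]


def _make_tree(params: SimulationParams) -> PhyloTree:
    names = _taxon_names(params.n_taxa)
    bl = params.branch_length
    if params.tree_shape.lstrip().startswith("("):
        return PhyloTree.from_newick(params.tree_shape)
    if params.tree_shape == "ladder":
        nwk = f"({names[0]}:{bl},{names[1]}:{bl})"
        for nm in names[2:]:
            nwk = f"({nwk}:{bl},{nm}:{bl})"
        return PhyloTree.from_newick(nwk + ";")
    if params.tree_shape == "yule":
        import dendropy
        from dendropy.simulate import treesim
        tns = dendropy.TaxonNamespace(names)
        dt = treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=params.n_taxa,
            taxon_namespace=tns, rng=random.Random(params.seed),
        )
        for e in dt.preorder_edge_iter():
            if e.length is not None:
                e.length = params.branch_length * max(0.05, e.length)
        return PhyloTree(dt)
    raise ValueError(f"unknown tree_shape {params.tree_shape!r}")


def _default_plan(params: SimulationParams) -> dict:
    names = _taxon_names(params.n_taxa)
    plan = {}
    for i, nm in enumerate(names):
        n_dec = i % 4
        plan[nm] = [
            (int(params.core_length * (j + 1) / (n_dec + 1)), params.decoy_length, None)
            for j in range(n_dec)
        ]
    return plan


DECOY_OFFSET_RADIUS = 60.0  # A from the insertion-point residue


def _random_direction(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _mutate_seq(seq: str, p: float, rng: np.random.Generator) -> str:
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < p)[0]
    for i in hits:
        choices = [a for a in AA_ALPHABET if a != chars[i]]
        chars[i] = choices[rng.integers(len(choices))]
    return "".join(chars)


def evolve_family(scaffold: StructureModel, params: SimulationParams):
    """Evolve the scaffold along a tree; returns (models, SyntheticTruth).

    Along each branch, independent Gaussian jitter of standard deviation
    noise_sigma * branch_length is added per coordinate, followed by one
    pass of chain-geometry repair; sequences mutate at mut_rate per site
    per unit branch length.  At each leaf the planted decoy domains are
    spliced in, displaced so they never come within 4 A of the rest of
    the chain.
    """
    rng = np.random.default_rng(params.seed)
    tree = _make_tree(params)
    plan = params.domain_plan if params.domain_plan is not None else _default_plan(params)

    models, core_maps, domain_maps = [], {}, {}

    def descend(node, coords, seq):
        for child in node.child_nodes():
            bl = child.edge.length or 0.0
            c = coords + rng.normal(0.0, params.noise_sigma * bl, size=coords.shape) \
                if params.noise_sigma * bl > 0 else coords.copy()
            c = _repair_chain(c) if params.noise_sigma * bl > 0 else c
            s = _mutate_seq(seq, min(0.95, params.mut_rate * bl), rng)
            if child.is_leaf():
                _emit_leaf(child.taxon.label, c, s)
            else:
                descend(child, c, s)

    def _emit_leaf(name, core_coords, core_seq):
        insertions = sorted(plan.get(name, []), key=lambda x: -x[0])
        coords = core_coords
        seq = core_seq
        core_map = np.arange(len(core_coords))
        intervals = []  # (start, end, label) assembled at the end
        placed_decoys = []
        for rank, (pos, dlen, offset) in enumerate(insertions):
            local = _decoy_domain(dlen, rng)
            base = core_coords[min(pos, len(core_coords) - 1)]
            off = (np.asarray(offset, float) if offset is not None
                   else DECOY_OFFSET_RADIUS * _random_direction(rng))
            # aim for clear spatial separation (beyond the 8 A residue-contact
            # scale, so a planted domain can never fuse with its neighbours);
            # below 4 A it is a hard collision
            from scipy.spatial.distance import cdist

            cand = best_cand = None
            best_dmin = -1.0
            for attempt in range(10):
                cand = local + base + off * (1.0 + 0.25 * attempt)
                obstacles = [coords] + placed_decoys
                dmin = min(cdist(cand, ob).min() for ob in obstacles)
                if dmin > best_dmin:
                    best_dmin, best_cand = dmin, cand
                if dmin >= 12.0:
                    break
            cand = best_cand
            if best_dmin < 4.0:
                raise RuntimeError(f"{name}: decoy at {pos} collides after 10 re-offsets")
            if best_dmin < 12.0:
                warnings.warn(f"{name}: decoy at {pos} only {best_dmin:.1f} A "
                              "from the rest of the chain")
            placed_decoys.append(cand)
            dseq = "".join(rng.choice(list(AA_ALPHABET), size=dlen))
            coords = np.concatenate([coords[:pos], cand, coords[pos:]])
            seq = seq[:pos] + dseq + seq[pos:]
            core_map = np.where(core_map >= pos, core_map + dlen, core_map)
            intervals.append((pos, pos + dlen, rank))  # positions in pre-shift frame
        # shift decoy intervals for insertions applied later (i.e. at lower pos)
        final_ivs = []
        for k, (s0, e0, rank) in enumerate(intervals):
            shift = sum(e - s for (s, e, _) in intervals[k + 1:])  # later = lower pos
            final_ivs.append((s0 + shift, e0 + shift, f"decoy{len(intervals) - 1 - k}"))
        decoy_ivs = sorted(final_ivs)
        core_ivs = []
        prev = 0
        for s0, e0, _ in decoy_ivs:
            if s0 > prev:
                core_ivs.append((prev, s0, "core"))
            prev = e0
        if prev < len(coords):
            core_ivs.append((prev, len(coords), "core"))
        models.append(StructureModel(name, seq, coords))
        core_maps[name] = core_map
        domain_maps[name] = sorted(core_ivs + decoy_ivs)

    descend(tree.dtree.seed_node, scaffold.coords, scaffold.seq)
    models.sort(key=lambda m: m.id)
    truth = SyntheticTruth(tree, core_maps, domain_maps, params)
    return models, truth


def simulate_family(params: SimulationParams):
    """Convenience wrapper: scaffold + evolve with the same seed."""
    scaffold = build_core_scaffold(params.core_length, params.seed)
    return evolve_family(scaffold, params)


# ---------------------------------------------------------------------------
# dataset emission
# ---------------------------------------------------------------------------

def emit_dataset(models: list, truth: SyntheticTruth, outdir, force: bool = False) -> list:
    """Write one PDB + one FASTA per taxon, the truth tree (Newick), a truth
    interval table (TSV) and a manifest (JSON).  Returns the paths written."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} is not empty (use force=True)")
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for m in models:
        p = outdir / f"{m.id}.pdb"
        write_pdb(m, p)
        written.append(p)
        f = outdir / f"{m.id}.fasta"
        write_fasta([SequenceRecord(m.id, m.seq)], f)
        written.append(f)
    tree_path = outdir / "true_tree.nwk"
    tree_path.write_text(truth.true_tree.to_newick() + "\n")
    written.append(tree_path)
    truth_path = outdir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("taxon\tlabel\tstart\tend\n")
        for taxon in sorted(truth.true_domains):
            for s, e, lab in truth.true_domains[taxon]:
                fh.write(f"{taxon}\t{lab}\t{s}\t{e}\n")
    written.append(truth_path)
    manifest = outdir / "manifest.json"
    p = truth.params
    manifest.write_text(json.dumps({
        "seed": p.seed, "n_taxa": p.n_taxa, "tree_shape": p.tree_shape,
        "core_length": p.core_length, "noise_sigma": p.noise_sigma,
        "branch_length": p.branch_length, "decoy_length": p.decoy_length,
        "mut_rate": p.mut_rate,
    }, indent=1))
    written.append(manifest)
    return written
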