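# structphylo

Structure-based evolutionary analysis of contractile-tail sheath proteins
(and structurally conserved protein families generally), for researchers who
want to infer relationships between proteins whose sequences have diverged
beyond reliable sequence alignment but whose folds have not.

Tail sheath proteins (TShPs) of myoviruses, phage-tail-like bacteriocins,
anti-feeding prophages and the bacterial type VI secretion system share a
rigid structural core — composed of both N-terminal and C-terminal parts of
the chain — onto which different lineages have accreted accessory domains
(typically Ig-like β-sandwiches). This package implements the full
desk-scale analysis of such a family from single-chain CA models:

1. **Pairwise structural alignment** — sequence-independent, iterative
   superposition/dynamic-programming alignment scored by the TM-score

   TM = (1/L_norm) Σᵢ 1 / (1 + (dᵢ/d₀)²),  d₀ = max(0.5, 1.24·(L_norm−15)^⅓ − 1.8) Å

   with dᵢ the CA–CA distances of aligned pairs after optimal (Kabsch)
   superposition. The symmetric matrix of length-averaged TM-scores over
   all model pairs drives everything downstream.
2. **Structure phylogeny** — BioNJ (or plain NJ) on distances d = 1 − TM,
   midpoint-rooted.
3. **Multiple structure alignment and conserved core** — progressive
   merging along an NJ guide tree; the conserved core is the set of
   alignment columns occupied by every model whose maximum pairwise CA
   distance in the common frame is below 4 Å.
4. **Core-trimmed sequence phylogeny** — NJ on p-distances over the
   core-trimmed sequence alignment, with Felsenstein bootstrap supports,
   plus Robinson–Foulds comparison against the structure tree.
5. **Domain architecture** — recursive spectral bisection of the CA
   contact graph into compact (possibly sequence-discontinuous) domains;
   the domain most similar to a one-domain reference is the "main domain",
   and models are typed 1 (core only), 2 (core + one accessory domain) or
   3 (three or more domains).

A synthetic structure-evolution generator with complete ground truth
(true tree, true residue homology, true domain boundaries) makes every
stage testable end to end without any external data.

## Worked example

```sh
python analysis/01_simulate_family.py
python analysis/02_structure_tree.py
```

prints, among other things:

```
pairwise TM-score matrix (tm_avg):
      t01  t02  t03  t04  t05  t06
  t01 1.000  0.889  0.826  0.775  0.924  0.847
  ...
BioNJ structure tree: (t04:0.167324,(((t01:0.0221017,t02:0.0893022):0.01021,...
RF distance to the true tree: 0 (normalized 0.000)
```

The TM-scores fall with divergence time and with accessory-domain load
(TM is normalised by full chain length, so a 465-residue three-decoy model
can score at most ~0.82 against the 300-residue core-only model even with a
perfect core superposition). RF = 0 means the BioNJ tree on 1 − TM
recovered the simulated topology exactly. Continuing with

```sh
python analysis/03_core_and_sequence_tree.py
python analysis/04_domain_architecture.py
```

extracts the conserved core (281 of 575 alignment columns at the 4 Å rule,
against 300 residues of true core), builds the core-trimmed NJ tree with
1000 bootstrap replicates (all internal edges at support 1.000, RF = 0 to
the structure tree), and recovers the planted domain counts for 6/6 models
with the core identified as the main domain in each.

The same machinery is scriptable per stage (`structphylo simulate`,
`align-pair`, `tm-matrix`, `align-multi`, `tree-struct`, `tree-seq`,
`compare-trees`, `domains`, `run --config run.yaml`).

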