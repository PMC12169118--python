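# quatmap

Quaternary B-cell epitope mapping on multimeric protein structures.

Therapeutic proteins of non-human origin — the motivating case is uricase
(urate oxidase), a homotetrameric enzyme used against hyperuricemia — elicit
anti-drug antibodies. Besides linear epitopes (contiguous stretches) and
conformational epitopes (spatially adjacent residues of one folded chain),
multimers present **quaternary epitopes**: antibody-binding surfaces that
exist only in the assembled complex because residues from *different chains*
jointly compose them. `quatmap` implements the analysis chain to find them:

- **Propensity profiles** — classical sliding-window B-cell scales
  (Parker hydrophilicity, Karplus–Schulz flexibility, Emini accessibility,
  Kolaskar–Tongaonkar antigenicity, Chou–Fasman beta-turn).
- **Consensus linear epitopes** — external predictor score tracks
  (BepiPred 1/2/3, Ellipro, SEMA, …) thresholded at their published
  operating points; a region is consensus when called by ≥ 2 predictors.
- **Structural superposition** — Smith–Waterman/BLOSUM62 sequence matching
  followed by Kabsch least-squares Cα superposition with RMSD reporting.
- **Residue interaction networks** — contact graphs at a 6 Å Cα cutoff,
  with the cross-chain (interface) subnetwork isolated; SIF export.
- **Quaternary epitope localization** — the core step: residues on *other*
  chains within a 6 Å radius of conformational-epitope seeds, clustered by
  the seed↔neighbor contact relation into inter-chain epitope clusters, plus
  a geometry audit (`verify`) for published cluster tables.
- **Synthetic data** — toy multimers with planted inter-chain contacts and
  score tracks with planted regions, so the whole pipeline is testable with
  no downloads.

The central quantity is simple: residue *r* belongs to a quaternary cluster
around seed set *S* when `min over s in S, chain(s) != chain(r) of
d(r, s) <= 6 Å`, with `d` the minimum heavy-atom (or Cα) distance; a
cluster's internal audit value is `max over members r of min over members
r' on another chain of d(r, r')`, which by construction never exceeds the
selection radius.

## Worked example

Simulate a tetramer with two planted inter-chain contact patches, then map
quaternary epitopes seeded from chain A:

```sh
quatmap simulate --n-chains 4 --residues-per-chain 20 \
    --patch "A:3-5=B:3-5@5.0" --patch "A:14-15=D:10-11@4.5" \
    --seed 2 --out complex.pdb
# -> 9 planted cross-chain contact(s)

printf 'chain\tnumber\nA\t3\nA\t4\nA\t5\nA\t14\nA\t15\n' > seeds.tsv
quatmap quatmap --structure complex.pdb --seeds seeds.tsv --out-prefix demo
# -> 4 quaternary cluster(s)
cat demo.clusters.txt
```

```
SER.3.A, SER.3.B
LEU.4.A, LEU.4.B
LYS.5.A, LYS.5.B
LEU.14.A, LYS.15.A, GLU.10.D, ALA.11.D
```

Each row is one inter-chain cluster in `NAME.number.chain` notation. The
A:3–B:3, A:4–B:4 and A:5–B:5 pairs stay separate clusters because at a 5 Å
patch distance the diagonal to the neighboring pair is √(3.8² + 5²) ≈ 6.3 Å,
outside the 6 Å radius; the A/D patch at 4.5 Å chains together (≈ 5.9 Å
diagonals) into one four-residue cluster. The audit confirms every cluster
obeys the radius:

```sh
quatmap verify --structure complex.pdb --clusters demo.clusters.txt
```

```
cluster 0: max-min cross-chain distance 5.00 A OK
cluster 1: max-min cross-chain distance 5.00 A OK
cluster 2: max-min cross-chain distance 5.00 A OK
cluster 3: max-min cross-chain distance 4.50 A OK
```

The same audit runs against the published uricase cluster listings shipped
with the package: `quatmap verify --structure data/pdb/4d12.pdb --published
4D12`. Other stages are available as `quatmap profile`, `quatmap consensus`,
`quatmap rin`, `quatmap interface`, `quatmap align` and `quatmap fasta`, or
all at once from a YAML config via `quatmap pipeline` (see
`quatmap.pipeline` for the schema). `docs/methods.md` describes the models,
parameters and their defaults.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Generates a seed-derived synthetic homotetramer and predictor tracks, runs
every pipeline stage on them (profiles, consensus, RIN + interface,
quaternary clustering), audits the geometry of the clusters it produced,
and writes the result JSON to `--out`.
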