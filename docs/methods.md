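# Methods

`quatmap` maps the epitope landscape of multimeric proteins — the motivating
system is uricase (urate oxidase), a homotetrameric therapeutic enzyme whose
immunogenicity is shaped not only by linear and conformational B-cell
epitopes but by *quaternary* epitopes: surfaces that exist only in the
assembled multimer because residues from different chains jointly compose
them. The package implements the full analysis chain on PDB-format input:
sequence-propensity profiling, consensus linear-epitope calling from
external predictor scores, sequence-guided structural superposition,
residue-interaction-network (RIN) construction with interface extraction,
and proximity-based quaternary-epitope clustering.

## Coordinate model

Structures are parsed from PDB text (via biotite) into a minimal
chain→residue→atom model. Author residue numbering — the numbers printed in
the ATOM records, insertion codes included — is the coordinate system
everywhere; published cluster tables reference residues as
`NAME.number.chain` labels in author numbers, and residues are matched by
chain + number only (printed residue names are advisory; published listings
contain spellings like `VSL`, `THRR`, `ILEU`). Waters and non-polymer
heteroatoms are excluded; altloc duplicates resolve to the
highest-occupancy conformer (ties: first seen); nonstandard residues (e.g.
MSE) become `X` in sequences but stay addressable. Labels that omit the
chain (they occur in one published listing) inherit the next explicit chain
in their row. No biological-assembly expansion is performed: the file's
coordinates are the universe, and the tool reports which chains are present.

## Propensity profiles

Five classical per-residue scales ship as data files with citations: Parker
hydrophilicity, Karplus–Schulz flexibility, Emini surface-accessibility
fractions, Kolaskar–Tongaonkar antigenicity, Chou–Fasman beta-turn. Mean
scales use an odd sliding window (default 7, the classical choice; the
sources for this analysis chain do not state their window lengths, so all
are configurable); the Emini method multiplies the six fractions of a
hexapeptide and normalizes by 0.37⁶ so an average-accessibility window
scores exactly 1, assigning the value to the 4th residue. Window-truncated
end positions carry no score. Unknown residues contribute the scale mean so
one `X` does not blank a whole window. Kolaskar calls are scores strictly
above the mean of the sequence's defined scores (per-protein adaptive
threshold); a flat profile therefore calls nothing. Flexibility is an
unweighted windowed mean (the original center-weighting is not applied; no
weighting detail is fixed by the analysis being reproduced).

## Consensus epitope calling

External predictors are ingested, never re-run. Score tables (TSV:
position, residue, score; positions contiguous from 1) are thresholded at
the predictors' published operating points — BepiPred-1 0.35, BepiPred-2
0.5, BepiPred-3 0.15, Ellipro 0.5, SEMA 1.1 — with `score ≥ threshold`
(inclusive, the common predictor convention). A position is consensus when
≥ 2 predictors call it; maximal runs of consensus positions become regions
annotated with their peak support. No gap bridging is applied (regions are
exact true-runs). Conformational predictors address residues by chain +
author number instead of sequence position; per-predictor residue sets
combine by union (default) or by the same ≥ k consensus rule — these sets
seed the quaternary search.

## Structural superposition

Chains are aligned by Smith–Waterman local alignment under BLOSUM62
(shipped as a data file; `X` scores 0 against everything) with affine gaps
costing `open + extend·L` (defaults 11/1). Tie-breaks are fixed so results
are reproducible: best cell at the smallest (row, column), traceback
preferring diagonal > up > left. Matched Cα pairs are superposed by the
Kabsch least-squares rotation (SVD with sign correction, so mirror-image
inputs still yield a proper rotation, det = +1). Iterative pruning of pairs
beyond a distance cutoff (2 Å when enabled) is available but off by
default, keeping the superposition a pure function of the alignment. Fewer
than 3 Cα pairs, or collinear point sets, are geometry errors.

## Residue interaction networks

Nodes are residues; an edge joins residues within the cutoff — 6 Å between
Cα atoms by default, the stated construction for this analysis; an
`any_heavy` mode (minimum over heavy-atom pairs) is provided because
atom-zone selections are the natural reading of a radius around an epitope.
Sequence-adjacent pairs are kept but flagged. The interface subnetwork
keeps exactly the inter-chain edges and their incident nodes. Export is SIF
plus edge/node attribute tables, deterministically ordered.

## Quaternary-epitope localization

Given conformational-epitope seeds (typically on one chain), every residue
on a *different* chain within the radius (default 6 Å, `any_heavy`) of a
seed is selected; seeds and neighbors are grouped as connected components
of the seed↔neighbor contact relation, components confined to one chain are
discarded, and partnerless seeds drop out. Connected components are the
minimal grouping assumption that yields multiple clusters per structure;
"adjacent chain" means any different chain. By construction every cluster's
worst-case cross-chain separation — the max over members of the min
distance to a member on another chain, computed by
`verify_cluster_geometry` — is ≤ the radius; the same quantity audits
published cluster tables. A monomer can never produce a cluster.

The published cluster listings for the four uricase structures 4D12, 2YZE,
4MB8 and 5M98 ship as package data. Auditing them requires the real
coordinate files, which cannot be redistributed here and cannot be fetched
offline; `tests/test_acceptance.py` looks for `data/pdb/<id>.pdb` under the
repository root (or attempts an RCSB download) and reports a failure, not a
skip, when the coordinates are unavailable — the audit is then genuinely
unverified.

## Synthetic data

`make_toy_complex` emits lattice-like, deliberately non-physical complexes:
straight Cα traces at 3.8 Å spacing, chains 100 Å apart, except where a
contact patch relocates residues of one chain to exactly the requested
distance from their partners; each residue carries a pseudo-Cβ 1.5 Å off
the trace so `any_heavy` mode has work to do. The returned ground truth is
recomputed from the emitted coordinates by a brute-force scan, so it is
self-consistent and includes incidental contacts (e.g. a relocated residue
landing √(3.8²+d²) from its partner's sequence neighbor). Patches closer
than 1 Å, conflicting relocations, or out-of-range indices are spec errors.
`make_synthetic_tracks` plants positive regions (score 1 vs 0, threshold
0.5) and flips positions at the requested noise rate. All randomness flows
through one integer seed; identical specs reproduce identical bytes. What a
green synthetic test establishes is the correctness of distance logic,
clustering and consensus combination — not anything about real protein
geometry, sterics or predictor behavior.

## Numerical and testing choices

- Distances are exact Euclidean; neighbor search uses a k-d tree whose
  results are checked against O(n²) brute force in tests.
- Cluster recovery tests compare against connected components of the
  generator's ground-truth contact list (an oracle independent of the
  geometry code), not a hardcoded per-patch grouping — whether adjacent
  patch pairs chain together legitimately depends on the patch distance.
- The Smith–Waterman oracle enumerates every order-preserving set of match
  pairs with affine gap costs; the exhaustive stratum covers all pairs to
  length 3, longer pairs (to 6) are sampled (the full length-≤6
  cross-product, ~30M pairs, is out of budget).
- Kabsch recovery is validated over 1000 random rigid motions (RMSD ≤ 1e-8);
  scipy's rotation machinery generates the motions but never computes the
  fit.
- Hypothesis property tests run derandomized so CI results are stable.

## Known limitations

- External predictor internals (BepiPred, DiscoTope, SEMA, Ellipro) are out
  of scope; their scores are inputs.
- No biological-assembly generation, structure repair, hydrogen placement,
  solvent-accessibility weighting, or immunogenicity ranking.
- T-cell epitopes are not addressed.
- The synthetic generator makes no attempt at sequence–structure
  consistency or physical realism.
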