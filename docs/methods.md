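# Methods

## The model

`sspr` predicts whether a single amino-acid substitution (AAS) in a protein
is pathogenic or benign from sequence alone, by treating the local sequence
context as a chemical structure:

1. **Peptide window.** For a substitution at position *p*, the peptide of
   odd length *PL* centred on *p* is cut from the protein, with the
   alternate residue applied at the centre. Interior positions get
   (*PL* − 1)/2 residues on each side; near a sequence edge the deficit is
   borrowed from the other side so the window keeps its full length, and
   only proteins shorter than *PL* yield truncated windows. Keeping the
   window length constant keeps the descriptor vocabulary comparable across
   training examples.
2. **Molecular graph.** The window is assembled from per-residue heavy-atom
   templates chained by C′–N peptide bonds (each join displaces the leaving
   hydroxyl oxygen). Explicit hydrogens are added until every atom reaches
   its standard valence (C 4, N 3, O 2, S 2), counting bond orders, so
   terminal amine/carboxyl and interior amide protonation fall out of the
   same rule. Fragments carry neutral free termini (H₂N–…–COOH) and fixed
   neutral side-chain protonation states (Asp/Glu as COOH, Lys NH₂, Arg
   neutral guanidine, His with the proton on Nε2); charge states and capping
   are deliberate fixed conventions, configurable only by editing the
   template file. No 3D geometry, stereochemistry or pH dependence is
   modelled — descriptors use topology only, and SD-file coordinates are
   zero-filled placeholders.
3. **MNA descriptors.** Each non-hydrogen atom yields one descriptor per
   level: level 0 is the element label; level *k* is
   `label(d₁,…,dₙ)` over the level-(*k* − 1) descriptors of all bonded
   neighbours (hydrogens included as neighbours), sorted lexicographically.
   The molecule is represented by the *set* of distinct descriptors at the
   chosen level. Atom labels are bare element symbols and bond orders are
   ignored by the descriptors; a level-*L* model uses exactly the level-*L*
   set (a union-of-levels variant is easy to add behind the same interface
   but is not the default).
4. **Classifier.** A PASS-style naive-Bayes model. Training counts, per
   descriptor *d*, the number of examples containing it (*n_d*) and how many
   of those are pathogenic (*n_d,path*). A query scores

   S = mean over its descriptors of ( 2·(n_d,path + 1)/(n_d + 2) − 1 ),

   i.e. Laplace-smoothed per-descriptor evidence averaged arithmetically;
   unseen descriptors contribute exactly 0 and S ∈ (−1, 1). Pa and Pi are
   tie-corrected class-conditional ECDF functionals of S against the stored
   training scores (ties count half), and Confidence = Pa − Pi; positive
   confidence classifies the substitution pathogenic. Half-weighted ties
   make the training-score separation identical to the tie-corrected
   Mann–Whitney AUC, and the symmetric smoothing makes confidence exactly
   antisymmetric under relabelling the two classes.

## Validation

Model quality is the probability that a random pathogenic example outscores
a random benign one, ties half-weighted — numerically the ROC AUC — computed
from average ranks. Leave-one-out cross-validation uses an exact shortcut:
removing one example only decrements the counts of the descriptors it
contains, so its held-out score is computable from the full-data counts;
this equals a retrain-from-scratch bit-exactly (tested). 5-fold
cross-validation is stratified by class (several realistic datasets have
minority classes small enough that unstratified folds could empty a class)
and seeded; folds are drawn from a canonical, input-order-independent sort
of the examples, so the AUC depends only on the example multiset and the
seed.

Model selection scans windows × levels. The canonical axes are odd peptide
lengths 5–31 (14 values) and descriptor levels 5–15 (11 values), 154 cells,
each scored by leave-one-out AUC; the best cell is the argmax with ties
broken toward the smaller window, then the smaller level (prefer the simpler
model, keep builds deterministic). Cells whose dataset cannot satisfy the
LOO preconditions are marked invalid and excluded. Threshold-0
classification metrics (balanced accuracy, Matthews correlation, F-measure)
are computed on out-of-fold confidences, with MCC defined as 0 when a
confusion marginal vanishes and F as 0 when precision + recall is 0.

## Data curation

The variant loader consumes a flat CSV
(`gene,position,ref,alt,label,allele_frequency`), rejecting rows whose
reference residue disagrees with the protein sequence, non-missense rows and
non-standard residues, with row-indexed diagnostics; duplicate
(gene, position, alt) rows keep their first occurrence. Two curation rules
apply: unlabelled variants whose population allele frequency *strictly*
exceeds the per-gene disease frequency are relabelled benign
("benign by frequency"); and a gene should contribute at least 75 labelled
variants — advisory in the library, enforced by the training command.
Remaining unlabelled variants are excluded from training.

## Synthetic study conditions

The generator emulates a ClinVar/gnomAD-style extract for one gene: a
uniform-random sequence of 120 residues; 200 distinct substitutions drawn
uniformly over (position, alternate) pairs; ground truth planted by a
motif rule — a substitution is pathogenic iff it falls inside the functional
motif (positions 41–71, width 31) *and* replaces the residue with something
outside the conservative {A, S, T, V, I, L, M} group (inside a functional
motif, only conservative replacements are tolerated). Labels are flipped
with probability `label_noise` to emulate annotation error. Allele
frequencies are log-uniform: 10⁻⁴–10⁻² for truly benign variants (above the
default disease frequency of 10⁻⁵, so the frequency rule has signal) and
10⁻⁹–10⁻⁶ for pathogenic ones. An optional `unknown_fraction` masks benign
labels so the supplementation rule can be exercised end to end. Everything
derives from a single seeded generator; identical specs give byte-identical
output.

What the generator does *not* emulate: real proteins' composition bias and
domain structure, epistasis between sites, recurrent/founder variants,
annotation biases that correlate with position, and multi-gene panels.
Passing the recovery tests therefore shows the machinery can learn a
position-and-residue-type rule through the graph/descriptor/Bayes stack —
not that it attains any particular accuracy on clinical data.

The demonstration configuration used by the reporting script is
PL = 31 (the window must span the planted motif for the signal to be fully
visible) and MNA level 9 (mid-range of the model axis). Under these
conditions the noise-free leave-one-out AUC is ≈ 0.91–0.94 across seeds and
degrades monotonically as label noise rises to 0.3.

## Numerical and representation choices

- **Descriptor keys.** Rendered MNA strings grow roughly like
  (mean degree)^level because the neighbourhood recursion re-enters the atom
  it came from; at level 15 on a 31-residue peptide graph a single rendered
  descriptor would occupy megabytes. Descriptor sets therefore store
  canonical *keys*: the exact text when it is at most 96 characters,
  otherwise a `#`-prefixed 128-bit blake2b hash of the canonical structure.
  Keys are content-determined, so they agree across graphs, atom orderings,
  processes and model serialisation; full texts remain available for
  inspection at small levels. Canonical child ordering is computed per level
  from (label, child-rank) signatures, which reproduces lexicographic string
  order exactly — at a fixed level no rendered descriptor can be a proper
  prefix of another, and `)` sorts before `,`.
- **Bit-reproducibility.** Score summation iterates descriptors in sorted
  order (never in hash order), so scores, AUCs and reports are identical
  across processes; models serialise to JSON and reload to bit-identical
  predictions.
- **Degenerate inputs.** Single-class training sets, empty descriptor sets,
  mixed descriptor levels, LOO with a class of one, and k-fold with a class
  smaller than k are all rejected with specific errors; grid cells that
  trip these become invalid rather than failing the whole scan.
- **Problem sizes.** Tests and the reporting script run at the default study
  conditions (n = 200 variants, 120-residue protein) and complete in about a
  minute; the full 154-cell grid at these sizes takes roughly 40 s.

## Known limitations

- Bare element labels (no ring/charge marks) and ignored bond orders mean
  some chemically distinct environments share descriptors; extended atom
  marks would refine this without changing the interfaces.
- The exact estimator of the original PASS-family software is unpublished;
  the smoothed-evidence + ECDF construction here honours every stated
  contract (Pa, Pi probabilities, Confidence = Pa − Pi, sign = class) but is
  one member of that family. The scorer sits behind a small interface and
  can be swapped.
- The canonical window-length range is odd 5–31. One source statement
  suggests 7–31, but only 5–31 yields the canonical 14 × 11 = 154 grid;
  5–31 is adopted and not resolved silently.
- No ClinVar/gnomAD clients, transcript handling, review-status filtering or
  nucleotide-level logic: the loader consumes pre-extracted tables only.
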