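# sspr

Sequence–structure–property models for predicting the pathogenicity of
single amino-acid substitutions (missense variants).

Most missense predictors work on sequence profiles or structures. `sspr`
instead treats the *local chemistry* of a substitution as the object of
interest: the peptide window of odd length *PL* centred on the substituted
residue is converted to an explicit-hydrogen molecular graph, described by
multilevel neighborhoods-of-atoms (MNA) descriptors, and classified by a
PASS-style naive-Bayes model. It is aimed at anyone who wants an
interpretable, dependency-light baseline for per-gene variant classification
— e.g. for genes of inborn errors of immunity, where per-gene training sets
of 75+ labelled variants are attainable from ClinVar plus frequency-based
benign supplementation from gnomAD.

## The model in brief

For a substitution, each non-hydrogen atom of the window graph yields one
descriptor per level: level 0 is the element symbol, level *k* is
`label(d₁,…,dₙ)` over the sorted level-(*k*−1) descriptors of all bonded
neighbours. A molecule is the set *D* of its distinct level-*L* descriptors.
Training counts per descriptor *d* the examples containing it (*n_d*) and
the pathogenic ones among them (*n_d,path*); a query scores

    S = mean_{d ∈ D} ( 2 (n_d,path + 1) / (n_d + 2) − 1 ),

and Pa (probability "pathogenic") and Pi (probability "benign") are
tie-corrected ECDFs of S against the per-class training scores, giving

    Confidence = Pa − Pi  ∈ [−1, 1],   Confidence > 0 ⇒ pathogenic.

Accuracy is reported as IAP — the probability that a random pathogenic
example outscores a random benign one, numerically the ROC AUC — under
leave-one-out (exact fast path) and stratified 5-fold cross-validation.
Model selection scans the canonical grid of 14 odd window lengths (5–31) ×
11 MNA levels (5–15) = 154 configurations by leave-one-out AUC. See
`docs/methods.md` for assumptions, parameter choices and limitations.

## Worked example

The package ships a synthetic-data generator that emulates a ClinVar/gnomAD
extract with a planted rule: substitutions inside a functional motif that
replace the residue with a non-conservative type are pathogenic. Build the
inputs, train, and predict:

```python
from sspr import SyntheticSpec, generate_synthetic
protein, variants = generate_synthetic(SyntheticSpec(seed=7, gene="DEMO1"))
# write protein.fasta, variants.csv (gene,position,ref,alt,label,allele_frequency)
# and genes.csv (gene,disease_frequency,omim_id,uniprot_id) from these objects
```

```sh
sspr train --fasta protein.fasta --variants variants.csv \
    --gene-config genes.csv --pl 31 --level 9 --out model.json
```

prints the training report (counts, configuration, leave-one-out AUC):

```json
{"auc_loo": 0.9217407902271426, "gene": "DEMO1", "level": 9,
 "n_benign": 169, "n_descriptors": 9461, "n_pathogenic": 31,
 "pl": 31, "seed": 0, "version": "0.1.0"}
```

With a query file (`<gene> <position> <substitution>` per line)

```
DEMO1 48 H
DEMO1 1 N
```

```sh
sspr predict --model model.json --queries queries.txt --out pred.csv
```

```
gene,omim_id,uniprot_id,position,substitution,confidence,model_auc
DEMO1,102700,P00813,48,H,0.46774193548387094,0.9217407902271426
DEMO1,102700,P00813,1,N,-0.9911242603550295,0.9217407902271426
```

Position 48 lies inside the planted motif and His is a non-conservative
replacement: confidence +0.468 ⇒ predicted pathogenic. Position 1 is outside
the motif: confidence −0.991 ⇒ confidently benign. `model_auc` is the
leave-one-out AUC of the deployed model (0.922 here).

`sspr grid` writes the full 154-cell model-selection report
(`pl,level,auc_loo,valid`) and prints the best cell; the library equivalents
are `sspr.grid_search`, `sspr.loo_auc`, `sspr.kfold_auc` and
`sspr.classification_metrics`.

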