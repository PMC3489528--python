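# psmrescore

Cross-validated, semi-supervised SVM rescoring of peptide-spectrum matches
(PSMs) from shotgun proteomics, with target-decoy false discovery rate
estimation.

## The problem

Search engines match tandem mass spectra against a protein database and
score each peptide-spectrum match with a raw similarity score. Raw scores
separate correct from incorrect matches imperfectly, partly because
confounding variables (precursor charge state, peptide length, ...)
correlate with the score independently of match correctness. Matching the
same spectra against a *decoy* database of biologically infeasible
(shuffled/reversed) sequences gives an empirical model of incorrect
matches, which serves two purposes here:

1. **Error-rate estimation.** For a score threshold *t*,

   FDR(*t*) = π₀ · #{decoys ≥ *t*} / #{targets ≥ *t*},

   where π₀ is the expected fraction of incorrect matches among targets.
   The *q*-value of a PSM is the minimum FDR over all thresholds that
   accept it.

2. **Semi-supervised learning.** Decoys are known negatives; targets
   passing a stringent q-value cut are provisional positives. A
   self-training linear SVM iterates: score PSMs → select positives at
   q ≤ 0.01 → fit a weighted soft-margin SVM (positives vs. all decoys) →
   rescore. The learned combination of PSM features separates classes far
   better than any single raw score.

Training and evaluating on the same PSMs would overfit and make the
estimated error rates anti-conservative, so the learning is wrapped in a
**three-fold cross-validation over spectra**: each fold is scored by a
model trained — hyperparameters included, via a nested three-fold grid
search — only on the other two folds. Because the three models' raw scores
are not comparable, each fold's scores are affinely normalized (the score
at the within-fold q = 0.01 threshold ↦ 0, the decoy median ↦ −1) before
merging and a final target-decoy analysis.

The package is for proteomics tool builders and method developers who want
a transparent, fully tested reference implementation of this scheme, plus
a simulation harness that *demonstrates* (with known ground truth) why the
cross-validation is load-bearing.

## Worked example

Generate one synthetic dataset at study scale — 2500 target and 2500 decoy
PSMs, 50 i.i.d. N(0, 1) features, an offset of 10.0 added to feature 1 of
1000 targets (the synthetic "correct" matches) — and rescore it:

```python
from psmrescore import (SimulationConfig, generate_dataset,
                        rescore_dataset, LearnerConfig)

data, is_correct = generate_dataset(SimulationConfig(), seed=1)
result = rescore_dataset(data, LearnerConfig(seed=1))

print(f"pi0 estimate:            {result.pi0:.3f}")
print(f"targets at q <= 0.01:    {result.n_significant(0.01)}")

accepted = result.table.query("not is_decoy and qvalue <= 0.01")["psm_id"]
truth = dict(zip(data.psm_ids, is_correct))
fdp = sum(not truth[p] for p in accepted) / len(accepted)
print(f"true fraction incorrect: {fdp:.4f}")

for p in result.norm_params:
    print(f"fold {p.fold}: q=0.01 anchor -> {p.apply(p.s_star):+.1f}, "
          f"decoy median -> {p.apply(p.m_decoy):+.1f}")
```

This prints:

```
pi0 estimate:            0.603
targets at q <= 0.01:    1009
true fraction incorrect: 0.0089
fold 1: q=0.01 anchor -> +0.0, decoy median -> -1.0
fold 2: q=0.01 anchor -> +0.0, decoy median -> -1.0
fold 3: q=0.01 anchor -> +0.0, decoy median -> -1.0
```

Reading the numbers: 1500 of the 2500 targets are noise by construction,
and the π₀ estimate recovers that fraction (0.603 ≈ 0.6). A perfectly
calibrated analysis at q ≤ 0.01 would accept 1000/(1 − 0.01) ≈ 1010
targets; the pipeline accepts 1009, and the realized fraction of truly
incorrect matches among them (0.0089) agrees with the estimated q. The
per-fold normalization anchors hold exactly.

Real PSM tables go through the command line instead:

```bash
psmrescore rescore --pin psms.pin --out psms.rescored.tsv --seed 1
psmrescore simulate --out curves/ --datasets 10 --seed 1        # Fig-style curves
psmrescore simulate --out curves/ --datasets 10 --seed 1 --no-cv
```

`--pin` takes the standard tab-delimited PSM feature table
(`SpecId  Label  ScanNr  <features...>  Peptide  Proteins`, label +1 for
targets, −1 for decoys); the output lists every PSM with its normalized
SVM score and q-value. `--no-cv` disables cross-validation (training and
scoring on the same PSMs) and exists only to demonstrate the resulting
inflation of significant counts — on pure-noise datasets it "discovers"
dozens of confident PSMs where the validated pipeline correctly finds
none.

## Scope

The package starts from feature tables: database searching, decoy database
construction, target-decoy competition and protein inference are upstream
concerns. Note that the package validates the *learning* procedure; the
underlying assumption that decoy features mimic incorrect-target features
can only be validated with known-content mixture experiments.
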