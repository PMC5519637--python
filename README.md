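# wavebeat

Arrhythmia beat classification from low-dimensional wavelet features.

Automatic ECG beat classification must distinguish beat morphologies —
normal (N), atrial premature (A), left/right bundle branch block (L/R),
premature ventricular (V) and paced (P) — from single-lead recordings in
which normal beats outnumber everything else roughly 7:3.  `wavebeat`
implements a classical, fully inspectable pipeline for this problem and,
just as importantly, makes explicit the difference between the two ways
such pipelines are usually evaluated: *beat-based* cross-validation
(beats from the same patient may appear in both training and test folds)
and *record-based* cross-validation (test beats come only from patients
the classifier has never seen).

## The pipeline

1. **Segmentation.** Each annotated R-peak anchors a fixed window of
   *T₁* = 0.25 s before and *T₂* = 0.45 s after the peak — 0.7 s,
   covering P wave, QRS complex and T wave; 252 samples at 360 Hz.
2. **Wavelet multiresolution analysis.** Each window is decomposed to 8
   dyadic levels with the `bior6.8` biorthogonal wavelet.  Detail level
   *j* covers the band [fs/2^(j+1), fs/2^j]; at 360 Hz the retained
   details cD1…cD8 span 0.70–180 Hz while the final approximation cA8
   (0–0.70 Hz, baseline drift) is discarded.  The raw feature vector is
   the concatenation cD1‖cD2‖…‖cD8 (365 values for a 252-sample window
   under the symmetric extension mode).
3. **PCA.** A principal-component basis is fitted on the training fold
   only and every beat is projected to its first *k* = 12 scores (or the
   smallest *k* whose cumulative contributory ratio reaches a threshold).
4. **One-vs-one SVM.** For *n* classes, *n(n−1)/2* binary soft-margin
   RBF classifiers (C = 10, γ = 0.1 on standardized scores) each cast
   one vote; a beat is assigned to the class with the vote maximum

   φ(C, S) = Σₚ ν(p, C, S),  ν(p, C, S) = 1 if hyperplane *p* picks C,

   with a deterministic, documented tie-break.
5. **Evaluation.** Per beat type H, TP/TN/FP/FN are read off the
   confusion matrix and

   SEN = ΣTP/(ΣTP+ΣFN), SPE = ΣTN/(ΣTN+ΣFP),
   ACC = (ΣTP+ΣTN)/(ΣTP+ΣTN+ΣFP+ΣFN),

   per class and micro-averaged, as mean ± SD over 10 folds.

A built-in generator (`wavebeat.synth`) produces multi-record synthetic
ECGs — Gaussian-bump morphologies per class, per-subject morphology
variation, white noise, baseline wander, ~70 % class-N imbalance — and
writes them in the same WFDB-style header/signal/annotation layout the
reader consumes, so the whole pipeline runs without external data.

## Worked example

```python
from wavebeat import SynthConfig, generate_dataset, PipelineSettings, run_cv

cfg = SynthConfig(n_records=20, beats_per_record=150,
                  between_subject_sd=0.3, noise_sd=0.05, seed=1)
dataset = generate_dataset(cfg)

settings = PipelineSettings(n_folds=10, pca_components=12)
for scheme in ("beat", "record"):
    result = run_cv(dataset, scheme, settings, seed=1)
    sen, _, _ = result.mean_sd("sen")
    acc, sd, _ = result.mean_sd("acc")
    print(f"{scheme:>6}-based: micro SEN {100*sen:5.2f}%  "
          f"micro ACC {100*acc:5.2f}% (SD {100*sd:.2f})")
```

prints

```
  beat-based: micro SEN 98.44%  micro ACC 99.48% (SD 0.19)
record-based: micro SEN 79.03%  micro ACC 93.01% (SD 5.49)
```

The gap is the point: with 3000 beats from 20 synthetic subjects the
classifier looks nearly perfect when folds mix subjects, and loses ~6
accuracy points (and ~19 sensitivity points) when every test beat comes
from unseen subjects — the within-patient protocol overstates how well
the features transfer to new individuals.

The same pipeline is scriptable from the shell:

```sh
wavebeat simulate --seed 1 --out data/
wavebeat extract  --data data/ --out features.csv
wavebeat evaluate --features features.csv --scheme both --seed 1 --out results/run
wavebeat report results/run_beat.json
```

Real MIT-BIH-style records (`.hea` + format 16/212 `.dat` + `.atr`) are
read by the same `extract` command; the bundled
`wavebeat.cv.mitdb_record_assignment()` reproduces the standard record
division for subject-independent 10-fold evaluation.

## Layout

| module | role |
|---|---|
| `wavebeat.io` | WFDB-family record/annotation reading & writing, label mapping, feature CSVs |
| `wavebeat.segment` | R-peak-anchored fixed-window segmentation |
| `wavebeat.wmra` | 8-level wavelet decomposition, feature assembly, subband bookkeeping |
| `wavebeat.pca` | component fitting, contributory-ratio selection, projection |
| `wavebeat.ovo_svm` | pairwise RBF classifiers, majority voting, tie-breaks |
| `wavebeat.metrics` | confusion bookkeeping, SEN/SPE/ACC per class and micro |
| `wavebeat.cv` | stratified & subject-grouped folds, leakage-free per-fold fitting, aggregation |
| `wavebeat.synth` | multi-subject synthetic ECG generator |
| `wavebeat.cli` | `simulate` / `extract` / `evaluate` / `sweep` / `report` |

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
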