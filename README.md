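# neuropref

EEG-based recognition of consumer preference ("like" vs. "dislike") from
frontal band-power asymmetry — a complete, testable pipeline for
neuromarketing-style BCI studies.

## What it does

Given multichannel EEG trials recorded while a participant views product
stimuli (14-channel Emotiv EPOC+ montage, 128 Hz, 4 s per trial), the
package:

1. **Preprocesses** the signals: common average reference, resampling to
   128 Hz, 4–45 Hz zero-phase band-pass, ICA-based artifact rejection
   (components with extreme kurtosis) and Savitzky–Golay smoothing.
2. **Extracts features** two ways:
   - *DWT*: level-4 Daubechies-4 wavelet decomposition into A4, D4, D3,
     D2, D1 (delta/theta/alpha/beta/gamma at 128 Hz), summarized by 12
     statistics per coefficient series — 12 × 5 × 14 = **840 features**.
   - *Welch PSD*: mean spectral power in theta (4–8), alpha (8–13), beta
     (13–30) and gamma (30–40 Hz) per channel — 4 × 14 = **56 features**.
3. **Computes preference indices** from frontal (AF3, F3, AF4, F4) band
   powers:
   - approach–withdrawal: AW = (α(F4) − α(F3)) / (α(F4) + α(F3))
   - effort: (θ(F4) − θ(F3)) / (θ(F4) + θ(F3))
   - choice (beta and gamma): (ln b(AF3) − ln b(AF4)) / (ln b(AF3) + ln b(AF4))
   - four valence variants, e.g. v1 = β(AF3,F3)/α(AF3,F3) − β(AF4,F4)/α(AF4,F4)
4. **Derives valence-based labels** by rescaling a valence variant onto a
   1–9 rank scale per subject (ranks 1–5 → dislike, 6–9 → like) and
   quantifies agreement with subjective self-report via Cohen's kappa.
5. **Benchmarks classifiers** — a three-hidden-layer feed-forward network
   (ReLU, Adam, dropout 0.5; hinge / binary / categorical cross-entropy
   heads), SVM, random forest (500 trees) and KNN — over the grid
   {DWT, PSD} × {no indices, + valence, + all indices}, with min–max
   normalization fitted on the training split and a stratified 20% holdout.

A synthetic-EEG generator produces dataset-shaped trials (25 subjects × 42
stimuli = 1050 epochs) in which a latent like/dislike state modulates the
left/right frontal alpha/beta contrast with configurable effect size, so
the entire pipeline is exercisable and verifiable without any external
recordings.

## Worked example

```python
from neuropref import SynthConfig, synth_dataset, all_indices_trial, cohens_kappa
from neuropref.preference_indices import index_table, valence_labels
from neuropref.classify_eval import run_experiment_grid
from neuropref.core_io import RunConfig

cfg = SynthConfig(n_subjects=5, trials_per_subject=20,
                  asymmetry_effect=2.0, noise_sd=0.5, seed=7)
epochs, labels, truth = synth_dataset(cfg)
print(f"{len(epochs)} trials from {cfg.n_subjects} subjects")

idx = all_indices_trial(epochs[0])
print(f"first trial ({epochs[0].subjective_label}): "
      f"AW={idx.aw:+.3f}  valence_v1={idx.valence_v1:+.3f}")

table = index_table(epochs)
vlab = valence_labels(table, "valence_v1")
print(f"subjective vs valence-label kappa: "
      f"{cohens_kappa(table['subjective_label'], vlab):.3f}")

rc = RunConfig(); rc.seed = 7
reports = run_experiment_grid(epochs, rc, families=("psd",),
                              classifiers=("rf", "svm", "knn"))
for (fam, fset, algo), rep in reports.items():
    print(f"{fam:>3} {fset:<12} {algo:<4} accuracy={rep.accuracy:.2f}")
```

Output:

```
100 trials from 5 subjects
first trial (dislike): AW=-0.803  valence_v1=-0.636
subjective vs valence-label kappa: 1.000
psd no_indices   rf   accuracy=1.00
psd no_indices   svm  accuracy=1.00
psd no_indices   knn  accuracy=1.00
psd valence_only rf   accuracy=1.00
psd valence_only svm  accuracy=1.00
psd valence_only knn  accuracy=1.00
psd all_indices  rf   accuracy=1.00
psd all_indices  svm  accuracy=1.00
psd all_indices  knn  accuracy=1.00
```

The first trial is a "dislike": its left frontal alpha exceeds the right
(AW < 0) and its left beta/alpha ratio is below the right (v1 < 0), exactly
the asymmetry the generator plants. With a strong planted effect (d = 2)
and low noise the valence-derived labels agree perfectly with the
subjective ones (κ = 1) and every classifier separates the classes on the
holdout.

## Command line

```bash
neuropref synth --outdir data/ --seed 1 -d 2.0        # write EEG matrices + labels
neuropref preprocess --indir data/ --outdir clean/    # conditioning chain
neuropref features --indir clean/ --out psd.csv --method psd
neuropref indices --indir clean/ --out indices.csv --valence-eq 5
neuropref grid --indir clean/ --out grid.csv --seed 1 # full benchmark
```

EEG trials are plain delimited text matrices (channels × samples,
orientation auto-detected), labels and features are CSV; configuration is
YAML (`neuropref grid --config run.yaml`), with defaults matching the
pipeline above.

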