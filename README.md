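# bremtool

Resource-efficient EEG emotion classification via multi-entropy fusion.
A single EEG channel is decomposed into the five brain rhythms (delta,
theta, alpha, beta, gamma) with a four-level db4 discrete wavelet
transform; six entropies (approximate, fuzzy, sample, permutation,
singular-spectrum, spectral) are extracted per rhythm and fused into the
5×6 **Brain Rhythm Entropy Matrix (BREM)**. Classification compares a test
BREM against one positive and one negative template BREM under a choice of
similarity measure (DTW, mutual information, Spearman correlation, Jaccard
dissimilarity), and a leave-one-out template-cycling protocol cycles every
(negative, positive) trial pair as templates to score a subject. A
synthetic two-class EEG generator makes the whole pipeline testable
without any dataset download.

## Library overview

| module | contents |
| --- | --- |
| `bremtool.rhythms` | `EEGSignal`, `decompose_rhythms` (db-wavelet band reconstruction) |
| `bremtool.entropies` | `EntropyConfig` plus the six entropy estimators |
| `bremtool.brem` | `build_brem`, `fuse_region`, the Table-style region map |
| `bremtool.similarity` | `dtw_distance`, `mutual_information`, `spearman_similarity`, `jaccard_dissimilarity` |
| `bremtool.classify` | `segment_trial`, `classify_by_template`, `loocv_template_evaluation`, `grid_search_best`, `anova_feature_screen` |
| `bremtool.synthetic` | `SyntheticConfig`, `generate_subject`, `preset("strong" / "null")` |
| `bremtool.io` | HDF5 / delimited-text trial stores, report round-trip |

```python
import numpy as np
from bremtool import EEGSignal, build_brem, loocv_template_evaluation
from bremtool.synthetic import preset, generate_subject

trials = generate_subject(preset("strong", seed=1, trial_s=5.0))
report = loocv_template_evaluation(trials, "dtw", window_s=5.0, channel="O2")
print(report.mean_accuracy, report.n_pairs)   # 384 template pairs
```

## Command line

The `bremtool` umbrella command exposes each stage:

```sh
bremtool simulate --preset strong --seed 7 --trial-s 5 --out trials.h5
bremtool evaluate --trials trials.h5 --method dtw --window 5 \
    --channel O2 --out report.csv
bremtool decompose --input trial.csv --fs 128 --out rhythms.csv
bremtool entropy --input rhythm.csv --feature se
bremtool brem --input trial.csv --fs 128 --channel O2 --window 0:5 --out brem.csv
bremtool similarity --a brem_a.csv --b brem_b.csv --method dtw
```

`--verbose` (on the umbrella command) enables debug logging to stderr;
`evaluate --grid-search` searches all (channel, segment) cells first.

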