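# emovid

Facial-emotion recognition from smartphone-style selfie videos, reduced to
per-frame facial action-unit (AU) time series.

## The problem

Psychotherapeutic smartphone apps that ask patients to express emotions need
to recognize those expressions automatically. The recognition problem here is
richer than the classic six basic emotions: 16 therapeutically relevant
categories — 4 negative (anger, anxiety, disgust, sadness) and 12 positive
(confidence, contentment, courage, excitement, gratitude, happiness, joy,
love, pride, relaxation, resolve, tranquility) — posed in short selfie
recordings. Each recording has three phases: preparation (moving the phone
into place), an emotional phase in which the subject utters a sentence while
displaying the target emotion, and disengagement.

`emovid` implements the full modelling pipeline for this setting:

* **Feature contract** — OpenFace-style per-frame CSVs: 17 AU intensities
  (0–5) plus 18 AU presences (0/1), a 35-dim appearance vector per frame at
  30 fps; optional 2048-dim deep features; gap filling when face detection
  fails (carry the last detected frame forward, drop leading/trailing gaps).
* **Segmentation** — the emotional phase is the longest continuous nonsilent
  segment of the audio energy envelope, extended by 1 s, detected with a
  relative-threshold energy gate with gap merging.
* **Partitioning** — speaker-independent splits homogenized by recognition
  difficulty: each subject is scored by the 16-class UAR of an SVM trained on
  all other subjects (leave-one-subject-out) over time-averaged AU features,
  then subjects are dealt out in a 3-train/1-validation/1-test round-robin in
  descending score order.
* **Models** — an SVM baseline (RBF kernel, C=1, gamma='scale', standard
  scaling) on video-level means, and recurrent sequence classifiers: a
  1-directional stacked GRU (3 layers, hidden size 35) with one of three
  pooling heads — average, learned-context attention, or depthwise 1-D
  convolution (kernel 3, same padding) — followed by an MLP (2×24 ReLU) with
  softmax output. Training uses Adam (lr 0.001, batch 64), cross-entropy,
  and early stopping on validation UAR with patience 30. The recurrent
  models and backpropagation are implemented directly in NumPy.
* **Evaluation** — accuracy, unweighted average recall
  (UAR = (1/K) Σ_i A_ii / Σ_j A_ij over the confusion matrix A), per-class
  one-vs-rest balanced accuracy, Cohen's and Fleiss' κ with the conventional
  verbal bands, percentile bootstrap CIs (1000 replicates) and exact
  one-sided binomial tests against chance.
* **Synthetic corpus generator** — seeded corpora with the same structure
  (16 emotions with a 2.5:1 negative:positive count imbalance, per-subject
  offsets, three-phase timeline, audio envelope active only during speech) so
  the whole pipeline is testable without access to private video data.

## Worked example

```python
import emovid
from emovid.models import ModelConfig, train_model, predict_records
from emovid.partitioning import loso_difficulty_scores, assign_splits, split_records
from emovid.segmentation import segment_record
from emovid.evaluation import evaluate_predictions

# 132 synthetic videos of 15 subjects, trimmed to the emotional phase
corpus = [segment_record(r) for r in emovid.generate_corpus(emovid.SyntheticConfig(seed=0))]

# difficulty-homogenized speaker-independent splits
splits = split_records(corpus, assign_splits(loso_difficulty_scores(corpus)))
print({k: len(v) for k, v in splits.items()})
# {'train': 79, 'validation': 27, 'test': 26}

cfg = ModelConfig(task="binary", head="attention", max_epochs=200, patience=30, seed=0)
model = train_model(splits["train"], splits["validation"], cfg)
pred = predict_records(model, splits["test"])
truth = [r.label.valence for r in splits["test"]]
report = evaluate_predictions(truth, pred, ("negative", "positive"), chance_p0=0.5)
print(f"test UAR {report.uar:.3f}, accuracy {report.accuracy:.3f}, "
      f"kappa {report.cohen_kappa:.2f} ({report.kappa_label})")
# test UAR 1.000, accuracy 1.000, kappa 1.00 (almost perfect)
```

The binary valence task on the default synthetic corpus is nearly separable,
so a healthy model should reach a test UAR at or near 1.0; the 16-class task
on the same 132-video corpus is much harder (one or two test videos per
class) and lands well above the 6.25% chance level but below perfection.

The same pipeline is available from the shell:

```bash
emovid simulate --seed 0 --out data/
emovid split data/manifest.csv --out splits.csv
emovid train data/manifest.csv --splits splits.csv --task binary --head attention --out model.npz
emovid evaluate data/manifest.csv --model model.npz --splits splits.csv --out report.json
emovid run-all --seed 0 --out results/   # whole grid in one go
```

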