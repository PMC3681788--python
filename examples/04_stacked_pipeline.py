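"""End-to-end stacked pipeline on a synthetic corpus.

Generates an annotated training corpus and a held-out test corpus, trains
the three kernel classifiers, combines them with a Ranking-SVM level-1
learner via stacked generalization, and reports test-set metrics.
"""

from ddikernels import evaluation, stacking
from ddikernels.fixtures import SyntheticConfig, generate_instances_and_snapshot

train, snapshot = generate_instances_and_snapshot(
    SyntheticConfig(n_sentences=50, seed=11, noise_rate=0.0))
test, _ = generate_instances_and_snapshot(
    SyntheticConfig(n_sentences=30, seed=99, noise_rate=0.0))
print(f"train: {len(train)} candidate pairs "
      f"({sum(i.label == 'positive' for i in train)} positive)")
print(f"test:  {len(test)} candidate pairs "
      f"({sum(i.label == 'positive' for i in test)} positive)")

learners = stacking.default_learners(snapshot=snapshot)
model = stacking.train_stacked(train, learner_kind="ranksvm", J=5, seed=1,
                               learners=learners)
print("level-1 weights per kernel:",
      {l.name: round(float(w), 3)
       for l, w in zip(model.level0, model.level1.weights)})

labels, scores = stacking.predict_stacked(model, test)
report = evaluation.evaluate([i.label for i in test], labels, scores)
print("held-out metrics:", report.as_dict())
print("\nOn noise-free synthetic data the planted cue/parse signal is fully"
      "\nrecoverable, so precision, recall and AUC reach their ceilings;"
      "\nthe learned weights show how much each kernel contributed.")
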