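"""Train the network on synthetic active-G4 data and evaluate it.

Generates 201-bp positive sequences carrying a planted canonical-G4
pattern (G3-4 N1-7 x4) with high chromatin accessibility, GC-matched
negatives with low accessibility, trains a reduced-size model and reports
held-out discrimination metrics.
"""

from g4net import ModelSpec, SyntheticConfig, evaluate, generate_dataset, train

config = SyntheticConfig(n_pos=1000, n_neg=1000, seed=1)
dataset, _ = generate_dataset(config)
print(f"dataset: {len(dataset)} examples, "
      f"{dataset.split.count('train')} train / "
      f"{dataset.split.count('validation')} validation / "
      f"{dataset.split.count('test')} test")

spec = ModelSpec(n_kernels=64, epochs=10)  # reduced from the full 900-kernel spec
model = train(spec, dataset, seed=1)
print(f"final training loss {model.training_history[-1]['loss']:.4f}, "
      f"validation accuracy {model.training_history[-1]['val_acc']:.3f}")

test = dataset.subset("test")
scores = model.predict([e.sequence for e in test],
                       [e.accessibility for e in test])
metrics = evaluate(scores, [e.label for e in test])
print(f"held-out AUROC {metrics['auroc']:.3f}, AUPR {metrics['aupr']:.3f}, "
      f"accuracy {metrics['accuracy']:.3f}, FDR {metrics['fdr']:.3f}")
print("AUROC near 1 means the model separates active-G4 windows from "
      "matched background almost perfectly under these synthetic conditions.")
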