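"""Train a width-reduced model on a simulated donor dataset and evaluate.

Protocol: categorical cross-entropy, SGD with Nesterov momentum 0.9,
initial learning rate 0.01 halved every 5 epochs, batch 64; the epoch with
the best validation accuracy supplies the final weights. (The reference
full-width configuration trains for 20 epochs with 3 repeats; this example
runs a shorter single run on a ~400-example fixture so it finishes in
about a minute on a laptop CPU.)
"""

import resplice as rs

splits, manifest = rs.make_fixture("tiny", "donor", seed=0)
print(f"dataset: {manifest['split_sizes']} (window length "
      f"{manifest['window_length']}, balanced classes)")

encoded = rs.encode_splits(splits)
config = rs.TrainingConfig(epochs=5, repeats=1, seed=0)
result = rs.fit(rs.NetworkSpec.reduced(), encoded, config)

for rec in result.runs[0].history:
    print(f"  epoch {rec.epoch:2d}  lr {rec.lr:.4f}  "
          f"loss {rec.loss:.4f}  val acc {rec.val_acc:.3f}")
print(f"checkpoint: epoch {result.runs[0].selected_epoch} "
      f"(best validation accuracy)")

report = rs.evaluate_model(result.network, *encoded["test"])
row = report.as_percent()
print("\ntest metrics (%):")
for name in ("acc", "pre", "sn", "sp", "err", "f1", "auc"):
    print(f"  {name:>3}: {row[name]}")
print("\nAcc/Pre/Sn/Sp/F1 derive from the confusion matrix with splice site")
print("as the positive class; Err = 100 - Acc; AUC is the ROC area from the")
print("softmax site probability. Larger fixtures (make_fixture('small', ...))")
print("reach validation AUC >= 0.95 under the same protocol.")
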