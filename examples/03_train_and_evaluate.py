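"""Run the full pipeline on synthetic data and report held-out metrics.

Clean → balanced 7:3 split → GloVe embedding → BLSTM-CNN training with
early stopping → evaluation on the held-out partition.  With fully
separated classes the held-out auROC should be well above 0.9; runtime is
a couple of minutes on one core.
"""

import lncsense as ln

records = ln.simulate_dataset(
    ln.SyntheticConfig(n_per_class=250, separation=1.0, seed=4)
)
cfg = ln.desk_scale_config(seed=4)
result = ln.run_experiment(records, cfg)

print("held-out metrics (positive class = mRNA):")
for name, value in result.metrics.items():
    print(f"  {name:10s} {value:.4f}")
print(f"epochs run: {len(result.training_log)}; "
      f"final train loss {result.training_log[-1]['train_loss']:.4f}")

print("\nauROC near 1 means the network recovered the planted coding signal; "
      "precision/recall/F1/accuracy are computed at the 0.5 threshold.")
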