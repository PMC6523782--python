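"""Generate a small labelled synthetic dataset and inspect its class signal.

The generator plants an open reading frame with third-position G/C codon
bias into the mRNA class; the `separation` knob scales the bias.  The
total-variation distance between class-averaged k-mer frequency vectors is
a model-free readout of how much signal a classifier could exploit.
"""

import lncsense as ln

for sep in (0.0, 0.5, 1.0):
    cfg = ln.SyntheticConfig(n_per_class=100, length_median=400.0, separation=sep, seed=1)
    records = ln.simulate_dataset(cfg)
    div = ln.kmer_frequency_divergence(records, k=3)
    print(f"separation={sep:.1f}: {len(records)} records, "
          f"3-mer frequency TV divergence = {div:.4f}")

print("\nA divergence near 0 means the classes are indistinguishable (chance "
      "classification); larger values mean more compositional signal.")
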