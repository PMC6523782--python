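# lncsense

Sequence-only discrimination of long non-coding RNAs (lncRNAs) from
messenger RNAs (mRNAs), for transcriptomics workflows where no annotation,
ORF caller or protein database is available — e.g. triaging novel
transcripts from RNA-seq assemblies.

## Method

Transcripts are tokenized into k-mers with a sliding window (width *k*,
step *s*; defaults k = s = 6, so a sequence becomes a string of hexamer
indices in 1..4096).  A GloVe model is fitted to the k-mer co-occurrence
matrix X (symmetric context window, diameter 15) by minimising

    J = Σ_{X_ij≠0} f(X_ij) (w_i·w̃_j + b_i + b̃_j − log X_ij)²,
    f(x) = (x/x_max)^α for x < x_max, else 1

giving each k-mer a D-dimensional vector (D = 100).  The supervised
classifier embeds the token sequence (padded/truncated to 1000 tokens),
runs a bidirectional LSTM (80 units per direction), three stages of 1-D
convolution + ReLU + max-pooling (100/80/80 filters of length 10/8/8,
pools 4/2/2), and a logistic head p(mRNA | x) = σ(β·c + b), trained by
mini-batch gradient descent on the cross-entropy with early stopping.
Evaluation reports precision, recall, F1, accuracy and trapezoidal auROC
with mRNA as the positive class.  Everything — including backpropagation —
is double-precision NumPy, checked against brute-force references and
finite differences in the test suite.

A synthetic transcript generator (planted ORF with third-position G/C
codon bias, strength set by a `separation` knob in [0, 1]) makes every
stage testable without downloads; see `docs/methods.md` for what it does
and does not emulate.

## Worked example

```python
import lncsense as ln

records = ln.simulate_dataset(ln.SyntheticConfig(n_per_class=250, separation=1.0, seed=4))
result = ln.run_experiment(records, ln.desk_scale_config(seed=4))
for name, value in result.metrics.items():
    print(f"{name:10s} {value:.4f}")
```

prints (held-out 7:3 split, positive class = mRNA):

```
precision  0.9286
recall     0.8667
f1         0.8966
accuracy   0.9000
auroc      0.9548
```

auROC ≈ 0.96 means the network recovered the planted coding signal from
sequence alone; at `separation=0` the classes are identically distributed
and the same run sits at auROC ≈ 0.5.  The `examples/` directory has one
short script per capability (simulation, embedding, training, ablation).

The same pipeline is available from the shell:

```bash
lncsense simulate --n-per-class 250 --separation 1.0 --seed 4 --out data/
lncsense embed --pos data/mrna.fa --neg data/lncrna.fa --k 4 -s 4 -D 32 \
    --x-max 50 --max-iters 200 --out emb/
lncsense train --pos data/mrna.fa --neg data/lncrna.fa \
    --embeddings emb/embeddings.npz --max-len 128 --hidden 24 \
    --conv-filters 24,16,16 --adam --learning-rate 5e-4 --epochs 30 --out run/
lncsense predict --model run/model.npz --fasta data/mrna.fa --out pred.tsv
lncsense evaluate --pred pred.tsv --labels data/labels.tsv
lncsense sweep --param k --values 3,4,5 --out sweep.tsv
```

Full-scale defaults (k = 6, D = 100, 1000-token inputs, SGD 1e-4 ×
12 epochs, batch 128) are the configuration intended for corpora of tens
of thousands of transcripts; the desk-scale configuration used above
scales the vocabulary and network with small corpora (`docs/methods.md`
explains each choice).

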