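# beoff

Cas9-dependent off-target activity of base editors: screen quantification,
specificity statistics, and off:on-target ratio prediction.

Adenine and cytosine base editors (ABE/CBE) convert single bases inside a
small window of the protospacer, but the Cas9 module tolerates mismatches
and 1–2-bp bulges between the gRNA and the DNA, so similar genomic sites
get edited too. `beoff` is for researchers who need to rank those candidate
sites: it turns pooled gRNA–target pair screens into per-site editing
efficiencies, summarises how mutation type and position shape specificity,
and trains a sequence model that predicts the **off:on-target ratio**

    r = efficiency(off-target) / efficiency(on-target)

for any gRNA/candidate pair, including gapped (bulge) alignments.

## The model

A pair is globally aligned, and both gapped sequences are indexed over the
vocabulary `{<pad>:0, A:1, C:2, G:3, T:4, -:5}`. Two embedding tables with
shared initialisation settings map them to matrices E1, E2 ∈ R^{T×m}, fused
by summation E = E1 + E2. A two-layer bidirectional LSTM produces
per-position states H = {h_0, …, h_{L−1}}; three pooled views —

- h_Last: the final forward and backward states,
- F_MaxPool = max_t h_t,
- F_AttentionPool = Σ_t α_t h_t with α = softmax(vᵀ tanh(W h_t + b)) over
  non-pad positions,

are concatenated, c = [h_Last; F_MaxPool; F_AttentionPool], and a fully
connected head with a sigmoid yields o = σ(f(c)) ∈ (0, 1). Training
minimises a mean squared error weighted by inverse within-batch prevalence
of each mutation type; splits keep every gRNA group (one on-target plus all
its designed variants) on a single side. Two post-processing rules apply at
prediction time: a candidate identical to its on-target returns 1, and a
candidate without an editable base (A for ABE, C for CBE) in the editing
window returns 0. Integrated gradients on the embedding layer attribute the
prediction to alignment positions. Hand-crafted-feature baselines (linear,
ridge, MLP, XGBoost with positional 1-mers, composition, GC and
nearest-neighbor RNA/DNA duplex energies, tuned by a Tree-structured Parzen
Estimator) provide the reference comparison.

See `docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

```python
>>> from beoff import align_pair, encode_sequence, classify_mutation_type
>>> ag, ao = align_pair("ACGCTTCATCAATGTTGGGATGG", "ACGCTCATCAAAAGTTGGATGG")
>>> print(ag); print(ao)
ACGCTTCATC-AATGTTGGGATGG
ACGC-TCATCAAAAGTT-GGATGG
>>> classify_mutation_type(ag, ao)
'mix'
>>> encode_sequence(ao).tolist()
[1, 2, 3, 2, 5, 4, 2, 1, 4, 2, 1, 1, 1, 1, 3, 4, 4, 5, 3, 3, 1, 4, 3, 3]
```

The guide (here 20-nt protospacer + `TGG` PAM) picks up one RNA bulge (`-`
in the off-target), one DNA bulge (`-` in the guide) and one substitution —
a mixed-mutation off-target. Gaps encode as `5`, and the integer vectors
are what the model consumes.

End-to-end on synthetic data from the shell:

```bash
beoff simulate --out sim --seed 11 --n-groups 12 --editor ABE
beoff screen-quant --design sim/design.tsv --fastq1 sim/reads_rep1.fastq \
    --fastq2 sim/reads_rep2.fastq --editor ABE --out quant
beoff analyze --table quant/efficiency_table.tsv --out analysis
```

`analyze` prints the headline summary of the quantified screen; for the
session above:

```
{"n_offtarget_records": 144, "mean_off_on_ratio": 0.6484723110726561, "mean_1mis_ratio": 0.829129606690648}
```

— the number of off-target pairs passing the 100-valid-read filter, their
mean off:on ratio, and the 1-mismatch mean. `beoff train` fits the model on
one group-disjoint fold, `beoff predict` scores a pair table or a
Cas-OFFinder candidate list, and `beoff attribute` writes per-position
integrated-gradients scores.

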