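# igsom — interconnected growing self-organizing maps

`igsom` models the joint acquisition of auditory and semantic categories
with two dynamically growing self-organizing lattices — an auditory map
trained on 24-Bark × time activation matrices of spoken syllables, and a
semantic map trained on binary word-feature vectors — connected by
trainable, forgettable associative links. It is aimed at computational
neuroscientists and phoneticians studying early lexical acquisition:
unlike a fixed-size SOM, each map starts from four nodes and grows at its
boundary wherever a node's accumulated quantization error E_acc exceeds a
growth threshold T_grow, so new knowledge extends the lattice instead of
overwriting it.

The core update rules, for BMU *b* of input *x* and nodes *i* in its
lattice neighbourhood:

```
ω_i(t+1) = ω_i(t) + R_learn(t) · exp(−d²_ib / 2σ(t)²) · (x − ω_i(t))
R_learn(t+1) = α · (1 − Q/n(t)) · R_learn(t)        σ(t+1) = β · σ(t)
ω_link(t+1) = ω_link(t) + L                          (L = 0.1)
Δω_link = (N_link(t) − N_link(t−1)) / N_link(t)      ω_link ← ω_link · (1 − Δω_link)
```

Training interleaves four regimes — growing, reinforcing (tokens confused
on the maps), reviewing (the full token set) and reinforcing-by-link
(tokens implicated in incorrect auditory→semantic winner links) — with
multiplicative link forgetting at every phase end. A non-mutating checking
pass measures node densities, boundary ratios and perceiving-path link
accuracy. Because the original recordings and hand-built feature set are
not distributed, a synthetic-data module generates corpora with the same
statistical structure (formant-like syllable templates, hierarchical
binary semantics, bijective sound–meaning pairing); the audio
preprocessing pipeline (derivative filter, release alignment, Hamming/FFT
spectrogram, dB conversion, Bark pooling) handles real annotated WAV
recordings when you have them.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
import igsom

# a reduced corpus: 10 syllables x 3 realizations, 3 semantic categories
corpus = igsom.generate_corpus(igsom.SyntheticConfig(
    n_syllables=10, n_words=10, n_semantic_categories=3, time_frames=20,
    features_per_category=5, features_per_word=3, seed=11))
config = igsom.ScheduleConfig(fundamental_cycles=5, seed=11)
model = igsom.IGsomModel.initialize(
    corpus.audio_dimension, corpus.semantic_dimension, config.seed)

reports = igsom.run_fundamental_training(model, corpus.tokens, config)
last = reports[-1].summary
print(len(reports), "steps")
print("semantic map:", last["semantic"])
print("link accuracy:", round(last["link_accuracy"], 3))
```

prints

```
11 steps
semantic map: MapSummary(total_nodes=49, solid_nodes=10,
    boundary_ratio=0.46938775510204084, avg_items_per_solid=1.0,
    max_items_per_node=1)
link accuracy: 0.72
```

— after one growing phase and five reinforcing/reviewing cycles the
semantic map has grown from 4 to 49 nodes, every one of the 10 words
occupies its own node (`avg_items_per_solid=1.0`), under half the nodes
remain on the boundary, and 72 % of the solid auditory nodes carry a
winner link to the correct word's node.

The same workflow is available from the shell:

```
igsom synth --config config.yaml --out corpus/
igsom train --corpus corpus/ --config config.yaml --out run/
igsom check --model run/model_experiment.json --corpus corpus/ --out report.tsv
igsom export-plots --metrics run/metrics.csv --out plots/
igsom preprocess --wav-dir wavs/ --annotations annotations.tsv --out repr/
```

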