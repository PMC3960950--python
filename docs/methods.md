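# Methods

## The model

The package implements an interconnected pair of growing self-organizing
maps (I-GSOM): an auditory map and a semantic map, each a Kohonen-style
lattice that grows from four nodes, joined by weighted associative links.
It is a neurocomputational model of how auditory categories (syllable
sounds), semantic categories (word meanings) and the associations between
them might be acquired jointly during early language acquisition, before
phonological representations exist.

### The growing lattice

Each map lives on an open integer grid. Four nodes are initialized at the
2×2 block (0,0)…(1,1) with uniform-random weights in [0,1] and zero
accumulated error. For an input x the best-matching unit (BMU) is the node
minimizing Euclidean distance; ties break lexicographically by (row, col)
so every operation is deterministic.

Each BMU accumulates its quantization error E_acc. When a BMU's E_acc
exceeds the growth threshold T_grow:

* if it is a *boundary* node (≥ 1 free von-Neumann neighbour), new nodes
  grow at **all** free adjacent positions. A new node's weight extrapolates
  across the BMU from the opposite neighbour, w = clamp(2·w_bmu − w_opp);
  if no opposite neighbour exists, from the first other direct neighbour in
  (row, col) order; an isolated BMU's weight is copied. The BMU's E_acc is
  reset to 0 after growth — the source text is silent here, and the reset
  prevents a saturated node from re-growing on every subsequent token.
* if it is interior, *error distribution* runs instead: E_acc(BMU) ← T_grow/2
  and each direct neighbour gains γ·T_grow.

Weight updates follow ω_i ← ω_i + R_learn·h·(x − ω_i) with a Gaussian
neighbourhood kernel h = exp(−d²/2σ²). We take d as the **lattice**
distance between node i and the BMU, the standard SOM reading; the source
prose literally defines d as the weight-to-input distance, which would make
h constant over the neighbourhood and leave "neighbourhood size" without a
unit. Nodes with d ≤ ceil(σ) participate (σ is real-valued, so a cutoff
must be chosen; ceil keeps at least the 4-neighbourhood while σ ≥ 1).

Schedules: per iteration, σ ← β·σ and R_learn ← α·φ(n)·R_learn with
φ(n) = 1 − Q/n and Q = 3.8 (maps start with four nodes, so φ > 0 from the
start; a defensive floor of 0.01 guards the impossible n ≤ Q case). The
learning rate therefore decays very fast while a map is small and
approaches a pure α-decay as it grows.

### Token presentation

One training token is a paired (flattened 24×T auditory activation, binary
semantic vector). Presenting it: reset R_learn and σ to the phase's initial
values, find the BMU once per map, run the growth check once per map, and
for each non-growing map run the inner loop while σ ≥ 1 — at defaults
(σ₀ = 2, β = 0.9) exactly 7 iterations. Per iteration and map: if
E_acc ≤ T_grow, update weights and accumulate the pre-update BMU-to-input
distance (the quantization error that selected the BMU, as in the original
GSOM; the source is ambiguous about pre- vs post-update measurement);
a saturated interior BMU distributes error instead. The associative link
between the two BMUs is reinforced once per iteration (weight += L = 0.1,
created at 0.1 if absent) — once, not once per map, since one
co-activation is one association event.

### Phases, forgetting, schedules

A phase presents an ordered token list sequentially, then applies link
forgetting: every link weight is multiplied by (1 − Δω) with
Δω = (N_link(t) − N_link(t−1))/N_link(t), where N_link = |auditory|·|semantic|
is the possible-link count (16 initially). Forgetting is multiplicative, so
it preserves the relative order of link weights and scales total link mass
exactly; a phase without growth forgets nothing.

Training parameters per phase (R_learn, σ₀, T_grow, α, β, γ):

| phase               | R_learn | σ₀ | T_grow | α   | β   | γ   |
|---------------------|---------|----|--------|-----|-----|-----|
| growing / reviewing | 0.5     | 2  | 2      | 0.9 | 0.9 | 0.5 |
| reinforcing / by-link | 0.8   | 2  | 1      | 0.9 | 0.9 | 0.5 |

**Fundamental training** = 1 growing phase on all tokens + 15 cycles of
(reinforcing on selected tokens, reviewing on all tokens) = 31 steps.
Reinforcing selects every pair whose audio BMU or semantic BMU hosts more
than 4 distinct items or sits at mean represented distance > 2.5
(duplicates removed, original order kept; an empty selection skips the
phase). **Experiments** continue for 15 cycles from the fundamentally
trained model; with link training enabled, each cycle prepends a
reinforcing-by-link phase on the tokens whose audio BMU carries an
incorrect winner link.

### Checking

Checking never mutates the model. Every token is assigned to its BMU on
both maps; per-node densities count distinct syllable ids (auditory) and
word ids (semantic). Whether the three realizations of a syllable count as
one item or three is ambiguous in the source; we count distinct syllables
by default and expose `count_realizations`. Only the perceiving path
(auditory → semantic) is checked: for each solid auditory node the
maximum-weight outgoing link is the winner; it is correct iff its target
hosts a word paired with a syllable represented at the source node, and a
node with no eligible link counts as incorrect. Accuracy is
correct / marked.

The top-20% link filter restricts winner-search to the highest-weight
fifth of all links ("weak weights have less influence on the selection of
winner links"). We use it where it defines the reinforcing-by-link
*selection*, but record the per-cycle experiment accuracy **unfiltered in
both arms**: applying the filter to one arm only confounds the training
effect with a measurement change, and the link phase by construction keeps
creating fresh weak links that push the top-20% cutoff upward. The filter
remains available (`link_check_fraction`, default off for plain checking).

## Audio preprocessing

Annotated mono waveforms become 24×T activations: first difference
(a 6 dB/oct high-pass suppressing F0), release-aligned zero-padding to the
corpus-maximal pre-/post-release spans, per-signal [0,1] amplitude
normalization (which makes the pipeline exactly invariant to positive
rescaling of a waveform), magnitude spectra over 256-sample Hamming frames
every 45 samples zero-padded to a 2048-point FFT (≈5.8 ms windows, ≈1 ms
hop at 44.1 kHz), 20·log₁₀(v/2·10⁻⁵) clipped into [60, 100] dB and locally
renormalized, pooling into Zwicker's 24 critical bands (band = mean of its
member bins; bins ≥ 15.5 kHz discarded) and time groups of 10 frames (the
final partial group averaged over its own size), and one last local
normalization. A constant signal normalizes to all-zeros (silence
semantics). Column count is corpus-determined — representations are
comparable only within one corpus; the reference corpus geometry gives
24 × 57 = 1368 activations.

## The synthetic corpus generator

No recordings or feature lists are distributed with the original study, so
a generator stands in for them; its defaults are the study conditions
(70 syllables × 3 realizations, 70 words, 9 categories, 24×57 activations,
a bijective sound–meaning pairing shared by all realizations of a
syllable).

*Auditory side.* Syllables mix V/CV/CCV types in roughly 5:45:20
proportion over 5 vowels and 9 consonants. A template is a 24×57 matrix of
Gaussian-profile horizontal bands: two vowel formant-analog rows (height
encodes the vowel), consonant-class onset patterns (plosive burst-like
triple, nasal murmur pair, lateral pair) shifted by a place-of-articulation
offset plus a voicing-bar row so that every consonant — not just every
class — is distinguishable, a 3-column linear formant transition, and
active spans ordered V < CV < CCV so duration is a usable cue.
Realizations add Gaussian noise (σ = 0.02) and a ±1-column time jitter,
clipped to [0,1]; at these defaults every realization is nearest its own
template. The noise level was chosen as a small fraction of the unit
activation range, matching clean single-speaker recordings.

*Semantic side.* Each word activates its category's shared feature block
(20 features), its own word-specific bits (4) and a sparse 5% sample of
other categories' shared features, then the singleton-pruning rule runs:
features occurring once are dropped in column order unless the drop would
leave two words with identical vectors. The surviving dimensionality is
corpus-dependent (≈180 at defaults). The block structure is an invention
that reproduces the reported within-category < between-category distance
structure; the real feature list was hand-built and is unavailable.

*What the generator does not emulate:* speaker variability, coarticulation
beyond the single linear transition, corpus word-frequency weighting
(presentation is uniform), and the semantics of real German nouns. Passing
tests therefore demonstrate the algorithm's behaviour under
cleanly-clustered conditions, not performance on natural recordings.

## Numerical and design choices

* Grid coordinates: (row, col) integers, (0,0) top-left of the initial
  block; purely internal.
* All tie-breaks (BMU, winner link, filter cutoff) are lexicographic, so
  two runs with the same seeds are bit-identical; model archives are JSON
  with exact float round-trip.
* New-node weights and all map weights are clamped to [0,1]; with inputs
  in [0,1] the update rule is a convex combination and needs no clamping.
* Growth is checked once per token (the algorithmic reading), not once per
  inner iteration; "each token is trained several times" is realized by
  the σ-driven inner loop alone.
* Empty reinforcing / reinforcing-by-link selections skip their phase
  (small corpora reach this regularly; the forgetting rate is then 0).
* Problem sizes used by the test suite and the acceptance script: the
  reduced corpus (10 syllables × 3, 3 categories, 24×20) for unit-level
  schedule tests and parameter recovery with 5 reinforcing/reviewing
  cycles; the full default corpus (70×3, 31 steps + 15 experiment cycles,
  three seeds × both experiment arms) for the headline quantities.

## Known limitations

* Link accuracy at the default synthetic scale plateaus in the low 80s
  (percent): the winner-take-most weight updates keep audio BMU
  assignments churning between phases, so some winner links always lag
  one phase behind. The reinforcing-by-link benefit is directionally
  reproduced but smaller than in the original study.
* Single-syllable tokens only; all tokens in a corpus must share one
  vector length.
* The production path (semantic → auditory) is not checked, matching the
  modeled study; no speaker normalization, no hexagonal or interior
  growth.
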