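# Methods

## Problem and model

The package addresses symptom-only prediagnosis: given a binary
symptom vector κ ∈ {0,1}^N (component 1 = gender, 1 for male), assign
a main disease category, then a subclass type, then a specific
disease. Two classifiers are implemented from first principles and
composed into a three-level cascade.

### Hierarchical label codec

Codes are decimal-positional over a `code_base` N: category
N·10+b, subclass (N·10+b)·10+j, disease ((N·10+b)·10+j)·10+t. The
suffix indices j and t are capped at 9 (one digit); b may reach 10,
and level membership is resolved by taxonomy lookup rather than digit
counting so that, e.g., a 10th category code remains unambiguous.
`code_base` is a free field rather than being tied to the symptom
count: the packaged worked example has 11 symptoms but uses base 10,
which is the only base that reproduces its printed codes (101, 1011,
10111). The same example's record table carries an internally
inconsistent pair of leaf codes for the carcinoma case
(1013/10131 vs the 10111 placement described in the accompanying
text); the fixture follows the textual placement and this note
records the discrepancy rather than resolving it.

### Neural network

One hidden layer of Y = 10 + N + Γ sigmoid units and a softmax output
layer of Γ units, cross-entropy loss. Thresholds are the weights of
clamped −1 units (input unit N+1 and hidden unit Y+1), so each layer
is a single matrix product and the bias gradients fall out of the
same outer products as the weight gradients. The output error signal
is δ_q = yo_q − d_q (using Σ_q d_q = 1 for one-hot targets) and the
hidden signal is σ_p = (Σ_q δ_q ϖ_pq)·ho_p(1−ho_p). Both layers are
updated by **gradient descent**, W ← W − η·∂e/∂W. Where source
formulations of such update rules disagree in sign between layers,
descent on the cross-entropy is the only choice under which training
minimises the loss; correctness is pinned by a finite-difference
oracle and a loss-decrease property test rather than by convention.

Choices the model statement leaves open, fixed here:

- initialisation: i.i.d. uniform(−0.5, 0.5) per weight, seeded;
- learning rate η = 0.1 by default; per-sample (stochastic) updates
  in a freshly shuffled order each epoch — the update rules are
  inherently per-sample, so no batch mode is offered;
- stopping: `epochs` cap (default 200) with early stop once the mean
  epoch loss improves by < 1e-6 for 10 consecutive epochs;
- numerical guards: softmax with max-subtraction, sign-split sigmoid,
  logarithms clipped at 1e-12;
- per-sample loss weights multiply the sample's loss and hence its
  gradient.

### Linear SVM

Per class a hyperplane f(x) = ωᵀx + c, fitted as a soft-margin SVM:
min ½‖ω‖² + C Σ w_k ξ_k subject to y_k f(x_k) ≥ 1 − ξ_k. The
intercept is folded into the regulariser as an always-on feature (the
standard linear-SVM treatment), which turns the dual into a pure
box-constrained QP solved by cyclic dual coordinate ascent with
closed-form single-variable updates; stopping on the largest
projected-gradient violation (`tol`). Hard margins are approximated
by C = 10⁴; at that penalty the solver attains all training margins
≥ 1 − 1e-6 on separable data and reproduces a reference QP solver's
predictions (asserted in tests). Per-sample weights enter as
individual box bounds C·w_k. Decision rule: member iff f(κ) > 0; a
score of exactly 0 is resolved as nonmember (the rule's strict
inequalities leave the boundary undefined).

Multiclass is one-against-the-rest with the class of interest mapped
to +1. Two identification modes exist because the sequential
formulation (scan planes in taxonomy order, stop at the first that
fires, "quit out" with no answer if none does) is order-dependent and
partial: `sequential` reproduces it faithfully, including `None`
outcomes; `argmax` (the cascade default) returns the class with the
largest raw score and always answers. Both are surfaced rather than
silently merged; they provably agree whenever exactly one plane fires.

### Cascade

`train_cascade` expands records into the three-level relation list
and trains: NT on all main-level entries, NT−b on category b's
entries, NT−(b,j) on subclass (b,j)'s entries. Conditioning uses the
*predicted* parent by default (a pure cascade); `conditioning:
"given"` lets per-case studies assume the parent level known. Nodes
with a single populated child become pass-throughs (no model; the
only child is emitted); a root with fewer than two populated
categories is an error, since no triage is possible. Per-node RNG
seeds derive from (config seed, level, parent code), so a node's
training is independent of which other nodes exist — this is what
makes the leave-one-out shortcut below exact.

Concurrence cases (two or three co-occurring disease types) are
classified combination-as-class: each declared combination is one
label of an ordinary flat classifier. True multi-label prediction is
out of scope.

## Evaluation

Leave-one-out cross-validation; reports always recompute accuracy as
(n_test − n_wrong)/n_test from the counts (printed percentages in
comparable studies are not always consistent with their own counts,
so nothing is ever hard-coded). A fold is *degenerate* when removing
the test record leaves its class unrepresented or the task with fewer
than two classes; degenerate folds count as wrong and are flagged,
not raised. `None` predictions (sequential SVM mode) count as wrong.

Full-path LOOCV exploits the cascade structure: removing one record
only changes the training sets of the main node and of that record's
own subclass and disease nodes, so each fold retrains exactly three
nodes and reuses the rest — an exact, not approximate, shortcut.

The binary task ("identify disease X within its subclass") scopes the
record set to the target's siblings. `weighted_comparison` normalises
the weight vector to mean 1 before use so that any uniform weighting
is exactly equivalent to the unweighted run for both back-ends (for
the SVM this pins the effective C·w scale; for the network it keeps
the effective learning rate unchanged).

## Synthetic data

No record corpus is publicly available for this problem, so the
generator emulates the structure the method assumes; it makes no
attempt to match any real dataset's marginals.

Structure: the non-gender symptoms are partitioned into per-category
"organ-system" pools. Each subclass draws a core of
round(overlap · max profile size) symptoms from its category pool,
cores disjoint within a category — the core acts as the subclass's
signature. Each disease profile of size s (uniform in
`profile_size_range`) takes round(overlap·s) symptoms from its
subclass core and the rest from the category pool, where roughly half
of these distinctive symptoms preferentially reuse symbols already
claimed by earlier siblings. Records set the profile flags, toggle
every non-gender flag independently with probability `flip_noise`,
and draw gender from a per-disease prevalence (uniform in
`gender_bias`). Concurrence records take the union of one sampled
leaf profile per member subclass before applying noise.

This construction makes difficulty grow down the hierarchy, as it
does clinically: categories differ by whole symptom pools (easy),
sibling subclasses differ by disjoint signatures within a shared pool
(harder), sibling diseases share their signature and collide on
distinctive symptoms (hardest). Consequences verified by tests: with
`within_subclass_overlap=0` sibling profiles are disjoint; with
`global_disjoint=True` all profiles are disjoint and the noise-free
cascade is exact; LOOCV accuracy is monotone decreasing in flip
noise; and on the reference preset the mean level-wise accuracies
order main ≥ subclass ≥ specific-disease, with binary one-vs-rest
above the multiclass task.

The reference preset is the generator default: B = 3
main categories (a digestive/respiratory/urinary analogue), 3–4
subclasses each, 2–6 diseases per subclass, 40 symptoms, profiles of
4–7 symptoms, overlap 0.4, flip noise 0.08, 12 records per disease.
What passing on this preset does **not** show: real consultation data
have correlated symptom noise, heavy class imbalance, symptom
frequencies spanning orders of magnitude, and free-text extraction
errors — none of which the Bernoulli flip model emulates. Results on
the preset characterise the method's behaviour, not clinical
performance.

## Reference task sizes

The benchmark tasks (in `symdx.benchmarks`) keep leave-one-out
retraining at desk scale while mirroring the per-task sample counts
of typical triage studies: the main-level task uses 3 records per
disease (~130 cases), the subclass task one category at 6 per disease
(~80–170 cases), the leaf-level multiclass and binary tasks one
subclass at the full 12 per disease (~25–70 cases). Level-task
networks train 30 epochs, the noise-free cascade 60; the stochastic
properties average 5 generator seeds. The weighted-loss comparison
puts weights uniform in [1, 3] on a random 20% of samples and uses
the SVM back-end.

## Known limitations

- The SVM is strictly linear, as the method prescribes; no kernels or
  probability calibration.
- The network offers no momentum, regularisation, or adaptive
  optimisers — exactly one hidden layer and plain η-steps.
- Cascade errors compound: a wrong main-category prediction makes the
  lower levels unreachable or wrong by construction ("predicted"
  conditioning); use "given" conditioning to study levels in
  isolation.
- Codes constrain subclass and disease counts to 9 per parent; the
  scheme cannot represent wider fan-outs without changing base.
- LOOCV retrains per fold; corpora beyond a few hundred records per
  task become expensive. The flat tasks have no retraining shortcut.
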