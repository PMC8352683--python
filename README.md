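# symdx — symptom-only disease prediagnosis

`symdx` implements a hierarchical triage method for assigning a
consulting case to a disease category, subtype, and specific disease
from **binary symptom flags alone** — the situation of online
consultations and hospital front-desk triage, where no examination or
pathology data exist yet. It is aimed at clinical-informatics
researchers studying how far symptom-only classification can be pushed
at each level of a disease hierarchy.

## The method

Diseases live in a three-level tree: B main categories (digestive,
respiratory, …), T(b) subclass types per category, T^(b,j) specific
diseases per subclass. With a code base N, codes are built by
appending one decimal digit per level:

    category b:        N·10 + b
    subclass (b,j):    (N·10 + b)·10 + j
    disease (b,j,t):   ((N·10 + b)·10 + j)·10 + t

A case record is a binary vector x ∈ {0,1}^N (component 1 is gender,
treated as a pseudo-symptom) plus a leaf code; it expands into a
three-row *data-relationship list* pairing the same symptoms with the
main, subclass, and disease codes. Each level of the hierarchy gets
its own classifier, either of:

- **a single-hidden-layer backpropagation network**, written from
  scratch: Y = 10 + N + Γ sigmoid hidden units, softmax outputs,
  cross-entropy loss e = −Σ_q d_q ln yo_q, thresholds carried as
  weights of constant −1 bias units, trained by per-sample gradient
  descent with output error signal δ_q = yo_q − d_q;
- **a one-vs-rest linear SVM**, also from scratch: per class a
  hyperplane f(x) = ωᵀx + c from the soft-margin dual
  min ½αᵀQα − eᵀα, 0 ≤ α_k ≤ C·w_k, solved by dual coordinate
  ascent, with per-sample loss weights w_k as individual box bounds.

Diagnosis is a cascade: the main-level model NT picks a category, the
per-category model NT−b picks a subtype, the per-subclass model
NT−(b,j) picks a disease. Co-occurring diseases (a patient with two
or three disease types at once) are handled by declaring each
combination as one composite class. Evaluation is leave-one-out
cross-validation with reports in the counts-and-accuracy layout of a
triage study.

No public symptom-record corpus accompanies the method, so the
package ships a synthetic generator that emulates the structure the
method assumes: per-disease characteristic symptom subsets drawn from
organ-system pools, configurable sibling overlap, independent
Bernoulli flip noise, and per-disease gender prevalence. See
`docs/methods.md` for what the generator does and does not emulate.

## Worked example

```python
from symdx import worked_example_fixture

taxonomy, record, entries = worked_example_fixture()
print(taxonomy.encode(1), taxonomy.encode(1, 1), taxonomy.encode(1, 1, 1))
print([(e.code, e.level) for e in entries])
```

prints

```
101 1011 10111
[(101, 'main'), (1011, 'subclass'), (10111, 'disease')]
```

— the 11-symptom taxonomy's tumor-disease category (code 101), its
benign-tumor subtype (1011), squamous cell carcinoma (10111), and the
three-entry expansion of a case whose symptoms are gender=male,
fever, ulcer, pain and tumor.

Training and evaluating on synthetic records:

```python
from symdx import (disjoint_config, generate_taxonomy, generate_records,
                   train_cascade, diagnose, loocv, CascadeConfig)

cfg = disjoint_config(seed=1)                # 27 diseases, clean profiles
tax, profiles = generate_taxonomy(cfg)
records = generate_records(tax, profiles, cfg)
model = train_cascade(records, tax, backend="svm",
                      config=CascadeConfig(seed=3))
print(diagnose(model, records[0].symptoms).path)
print(loocv(records, tax, backend="svm", level="path",
            config=CascadeConfig(seed=3)).accuracy)
```

prints

```
(561, 5611, 56111)
1.0
```

— the held-out full code path is recovered for every record: on
noise-free, disjoint symptom profiles the cascade is perfect, for
either back-end. Accuracy then degrades down the hierarchy once
sibling diseases share symptoms and records carry flip noise (see the
reference tasks in `symdx.benchmarks`).

The same operations are available from the shell:

```
symdx generate --seed 5 --out records.csv --taxonomy-out tax.json
symdx train --records records.csv --taxonomy tax.json --backend svm --out model/
symdx predict --model model/ --symptoms "symptom_3,symptom_7" --gender male
symdx loocv --records records.csv --taxonomy tax.json --level main
```

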