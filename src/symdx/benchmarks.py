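"""Reference evaluation tasks on the synthetic study conditions.

These are the canned experiments the package uses to characterise the
triage method: level-wise LOOCV tasks on the reference generator
preset (mirroring a hospital study that tests main-category triage on
the full corpus, subclass triage within one category, and specific-
disease identification within one subclass), the noise-free sanity
run, and the weighted-vs-unweighted loss comparison.

Task slice sizes are chosen to keep leave-one-out retraining at desk
scale: roughly 130 cases at the main level, one category (~80-170
cases) at the subclass level, and one subclass (~25-70 cases) at the
leaf level — the same order as the per-task sample counts of typical
triage studies.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from symdx.cascade import CascadeConfig
from symdx.evaluation import binary_case_eval, loocv, weighted_comparison
from symdx.synthetic import (
    disjoint_config,
    generate_records,
    generate_taxonomy,
    reference_config,
)

MAIN_TASK_RECORDS_PER_DISEASE = 3
SUBCLASS_TASK_RECORDS_PER_DISEASE = 6


def reference_level_accuracies(seed: int, backend: str,
                               epochs: int = 30) -> dict[str, float]:
    """LOOCV accuracy of the four reference tasks for one generator seed.

    Returns ``{"main": ..., "subclass": ..., "disease": ..., "binary": ...}``:
    main-category triage over the whole corpus, subclass triage within
    the first category, specific-disease multiclass identification
    within the largest subclass, and one-vs-rest identification of that
    subclass's first disease.
    """
    cfg = reference_config(seed=seed)
    tax, prof = generate_taxonomy(cfg)
    recs_main = generate_records(tax, prof, dataclasses.replace(
        cfg, n_per_disease=MAIN_TASK_RECORDS_PER_DISEASE))
    recs_sub = generate_records(tax, prof, dataclasses.replace(
        cfg, n_per_disease=SUBCLASS_TASK_RECORDS_PER_DISEASE))
    recs_full = generate_records(tax, prof, cfg)
    config = CascadeConfig(epochs=epochs, seed=seed)

    first_cat = tax.codes_at("main")[0]
    big_sub = max(tax.codes_at("subclass"),
                  key=lambda c: len(tax.children_of(c)))
    target = tax.children_of(big_sub)[0]
    return {
        "main": loocv(recs_main, tax, backend=backend, level="main",
                      config=config).accuracy,
        "subclass": loocv(recs_sub, tax, backend=backend, level="subclass",
                          config=config, parent_code=first_cat).accuracy,
        "disease": loocv(recs_full, tax, backend=backend, level="disease",
                         config=config, parent_code=big_sub).accuracy,
        "binary": binary_case_eval(recs_full, tax, target, backend=backend,
                                   config=config).accuracy,
    }


def noise_free_path_accuracy(seed: int, backend: str,
                             epochs: int = 60) -> float:
    """Full-path LOOCV accuracy on noise-free, globally disjoint
    profiles (27 diseases, 5 records each)."""
    cfg = disjoint_config(seed=seed, n_per_disease=5)
    tax, prof = generate_taxonomy(cfg)
    records = generate_records(tax, prof, cfg)
    config = CascadeConfig(epochs=epochs, seed=seed)
    return loocv(records, tax, backend=backend, level="path",
                 config=config).accuracy


def reference_weighted_accuracies(seed: int,
                                  backend: str = "svm") -> tuple[float, float, int]:
    """Unweighted and weighted LOOCV accuracy on the reference binary
    task for one seed.

    Weights emulate clinically assigned relevance: 20% of the cases
    carry a weight drawn uniformly from [1, 3], the rest weight 1.
    Returns (accuracy_unweighted, accuracy_weighted, n_test).
    """
    cfg = reference_config(seed=seed)
    tax, prof = generate_taxonomy(cfg)
    records = generate_records(tax, prof, cfg)
    big_sub = max(tax.codes_at("subclass"),
                  key=lambda c: len(tax.children_of(c)))
    target = tax.children_of(big_sub)[0]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    weights = np.ones(len(records))
    chosen = rng.random(len(records)) < 0.2
    weights[chosen] = rng.uniform(1.0, 3.0, size=int(chosen.sum()))
    rep_plain, rep_weighted, _ = weighted_comparison(
        records, tax, target, weights, backend=backend,
        config=CascadeConfig(seed=seed))
    return rep_plain.accuracy, rep_weighted.accuracy, rep_plain.n_test
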