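"""Synthetic taxonomies and symptom records.

No public symptom-record corpus accompanies the triage method, so the
package carries a generator that reproduces the statistical structure
the method assumes: every disease has a small characteristic symptom
subset ("profile"), sibling diseases under one subclass share a
configurable fraction of their profiles, records are the profile flags
corrupted by independent Bernoulli flips, and gender acts as a
pseudo-symptom with a per-disease prevalence.

Symptoms are organised so that difficulty grows down the hierarchy,
as it does clinically: every disease draws from its main category's
own organ-system symptom pool (categories are easy to tell apart),
sibling subclasses carry disjoint signature cores within that pool
(harder), and sibling diseases share their subclass core and collide
on distinctive symptoms (specific diseases are hardest).

The module also ships the small worked-example fixture — an
11-symptom, 10-category taxonomy with a tumor subtree and one
squamous-cell-carcinoma case — used to pin down the code arithmetic.
"""

from __future__ import annotations

import csv
import json
import warnings as _warnings
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np

from symdx.cascade import ConcurrenceClass
from symdx.errors import ConfigError
from symdx.taxonomy import (
    CaseRecord,
    Category,
    Disease,
    DiseaseTaxonomy,
    RelationEntry,
    Subclass,
    expand_record,
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the record generator.

    Defaults are the reference study preset: three main
    categories (a digestive / respiratory / urinary analogue), 3-4
    subclasses each, 2-6 diseases per subclass, 40 symptoms (gender
    included), per-disease profiles of 4-7 symptoms of which 40% are
    shared with siblings, 8% flip noise, and 12 records per disease.
    """

    B: int = 3
    t_b_range: tuple[int, int] = (3, 4)
    t_bj_range: tuple[int, int] = (2, 6)
    n_symptoms: int = 40
    profile_size_range: tuple[int, int] = (4, 7)
    within_subclass_overlap: float = 0.4
    flip_noise: float = 0.08
    gender_bias: tuple[float, float] = (0.2, 0.8)
    n_per_disease: int = 12
    seed: int = 0
    global_disjoint: bool = False  # force profiles disjoint across ALL leaves

    def __post_init__(self):
        if self.B < 1:
            raise ConfigError("need at least one main category")
        for lo, hi in (self.t_b_range, self.t_bj_range, self.profile_size_range):
            if not 1 <= lo <= hi:
                raise ConfigError(f"range ({lo}, {hi}) is empty or nonpositive")
        if self.t_b_range[1] > 9 or self.t_bj_range[1] > 9:
            raise ConfigError("subclass/disease counts are capped at 9 by the code scheme")
        for p in (self.within_subclass_overlap, self.flip_noise,
                  *self.gender_bias):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        if self.n_symptoms - 1 < self.profile_size_range[1]:
            raise ConfigError("n_symptoms must exceed the largest profile size")
        if self.n_per_disease < 1:
            raise ConfigError("n_per_disease must be at least 1")
        if self.global_disjoint and self.within_subclass_overlap > 0:
            raise ConfigError("global_disjoint requires zero sibling overlap")


def reference_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """The reference preset with an adjustable seed."""
    return GeneratorConfig(seed=seed, **overrides)


def disjoint_config(seed: int = 0, n_per_disease: int = 5) -> GeneratorConfig:
    """Noise-free 3x3x3 taxonomy with globally disjoint 2-symptom
    profiles — every leaf is perfectly identifiable from clean flags."""
    return GeneratorConfig(
        B=3, t_b_range=(3, 3), t_bj_range=(3, 3), n_symptoms=56,
        profile_size_range=(2, 2), within_subclass_overlap=0.0,
        flip_noise=0.0, gender_bias=(0.5, 0.5),
        n_per_disease=n_per_disease, seed=seed, global_disjoint=True,
    )


@dataclass(frozen=True)
class SymptomProfiles:
    """Ground truth behind a generated taxonomy: per-leaf characteristic
    symptom index sets (vector positions; gender excluded) and per-leaf
    gender prevalence."""

    profiles: dict[int, frozenset[int]]
    gender_prevalence: dict[int, float]


def _rng_for(config: GeneratorConfig, stream: int) -> np.random.Generator:
    # independent deterministic streams for taxonomy vs record noise
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def generate_taxonomy(config: GeneratorConfig) -> tuple[DiseaseTaxonomy, SymptomProfiles]:
    """Draw a taxonomy and the per-disease symptom profiles.

    Sibling diseases share ``within_subclass_overlap`` of their profile
    through a per-subclass core; at zero overlap sibling profiles are
    strictly disjoint.  Raises :class:`ConfigError` when the symptom
    pool cannot host the requested structure.
    """
    rng = _rng_for(config, 0)
    n_sym = config.n_symptoms
    pool = np.arange(1, n_sym)  # non-gender vector positions

    categories = []
    profiles: dict[int, frozenset[int]] = {}
    prevalence: dict[int, float] = {}

    # organ-system pools: a near-equal partition of the symptom list,
    # from which each category's subclass cores are drawn
    perm = rng.permutation(pool)
    cat_pools = np.array_split(perm, config.B)
    global_free = set(pool.tolist())  # for the globally-disjoint mode

    n_subs = rng.integers(config.t_b_range[0], config.t_b_range[1] + 1,
                          size=config.B)
    tax_skeleton = []
    for b in range(1, config.B + 1):
        sub_counts = rng.integers(config.t_bj_range[0], config.t_bj_range[1] + 1,
                                  size=int(n_subs[b - 1]))
        tax_skeleton.append([int(c) for c in sub_counts])

    code_base = n_sym  # mirror the convention that codes build on N
    s_lo, s_hi = config.profile_size_range
    core_size = int(round(config.within_subclass_overlap * s_hi))

    for b in range(1, config.B + 1):
        cat_pool = sorted(int(v) for v in cat_pools[b - 1])
        # subclass cores are disjoint within the category: the core acts as
        # the subclass's signature, so sibling subclasses stay more
        # distinguishable than sibling diseases (which share their core)
        core_free = list(rng.permutation(cat_pool))
        subclasses = []
        for j, n_dis in enumerate(tax_skeleton[b - 1], start=1):
            if core_size > len(core_free):
                raise ConfigError(
                    f"category {b} symptom pool ({len(cat_pool)} symptoms) "
                    f"cannot host {len(tax_skeleton[b - 1])} disjoint "
                    f"{core_size}-symptom subclass cores"
                )
            core = [int(v) for v in core_free[:core_size]]
            core_free = core_free[core_size:]
            sub_used = set(core)
            sub_profiles: set[frozenset[int]] = set()
            diseases = []
            for t in range(1, n_dis + 1):
                size = int(rng.integers(s_lo, s_hi + 1))
                n_shared = min(int(round(config.within_subclass_overlap * size)),
                               len(core))
                for _attempt in range(20):
                    shared = list(rng.choice(core, size=n_shared, replace=False)) \
                        if n_shared else []
                    n_private = size - n_shared
                    if config.global_disjoint:
                        # profiles disjoint across the whole taxonomy
                        candidates = sorted(global_free)
                    elif config.within_subclass_overlap == 0:
                        # siblings strictly disjoint; stay inside the category
                        candidates = sorted(set(cat_pool) - sub_used)
                    else:
                        # organ-system structure: distinctive symptoms come
                        # from the category pool; sibling collisions beyond
                        # the shared core are allowed and encouraged (the
                        # leaf level is meant to be the hardest)
                        candidates = sorted(set(cat_pool) - set(shared))
                    if n_private > len(candidates):
                        raise ConfigError(
                            f"symptom pool exhausted at disease ({b},{j},{t}): "
                            f"need {n_private} fresh symptoms, "
                            f"{len(candidates)} left"
                        )
                    if (config.global_disjoint
                            or config.within_subclass_overlap == 0):
                        private = list(rng.choice(candidates, size=n_private,
                                                  replace=False)) if n_private else []
                    else:
                        # half of the distinctive symptoms preferentially
                        # reuse symbols already claimed by earlier siblings
                        reusable = sorted((sub_used - set(shared) - set(core))
                                          & set(candidates))
                        n_reuse = min(int(rng.binomial(n_private, 0.5)),
                                      len(reusable))
                        private = list(rng.choice(reusable, size=n_reuse,
                                                  replace=False)) if n_reuse else []
                        fresh_pool = sorted(set(candidates) - set(private))
                        n_fresh = n_private - n_reuse
                        private += list(rng.choice(fresh_pool, size=n_fresh,
                                                   replace=False)) if n_fresh else []
                    profile = frozenset(int(v) for v in shared + private)
                    if profile not in sub_profiles:
                        break
                else:
                    raise ConfigError(
                        f"cannot draw a distinct profile for disease ({b},{j},{t})"
                    )
                sub_profiles.add(profile)
                sub_used.update(private)
                global_free.difference_update(private)
                code = ((code_base * 10 + b) * 10 + j) * 10 + t
                profiles[code] = profile
                prevalence[code] = float(rng.uniform(*config.gender_bias))
                diseases.append(Disease(t=t, name=f"disease_{b}_{j}_{t}"))
            subclasses.append(Subclass(j=j, name=f"subclass_{b}_{j}",
                                       diseases=tuple(diseases)))
        categories.append(Category(b=b, name=f"category_{b}",
                                   subclasses=tuple(subclasses)))

    symptom_names = ("gender",) + tuple(f"symptom_{i}" for i in range(1, n_sym))
    taxonomy = DiseaseTaxonomy(code_base=code_base,
                               symptom_names=symptom_names,
                               categories=tuple(categories))
    return taxonomy, SymptomProfiles(profiles=profiles,
                                     gender_prevalence=prevalence)


def _noisy_flags(profile: frozenset[int], gender_p: float, n_sym: int,
                 flip: float, rng: np.random.Generator) -> tuple[int, ...]:
    flags = np.zeros(n_sym, dtype=int)
    flags[list(profile)] = 1
    if flip > 0:
        toggle = rng.random(n_sym - 1) < flip
        flags[1:] ^= toggle.astype(int)
    flags[0] = int(rng.random() < gender_p)
    return tuple(int(v) for v in flags)


def generate_records(taxonomy: DiseaseTaxonomy,
                     profiles: SymptomProfiles,
                     config: GeneratorConfig) -> list[CaseRecord]:
    """Draw ``n_per_disease`` records per leaf: profile flags, then
    independent Bernoulli(flip_noise) toggles on every non-gender flag,
    gender from the disease's prevalence."""
    rng = _rng_for(config, 1)
    leaves = taxonomy.codes_at("disease")
    missing = [c for c in leaves if c not in profiles.profiles]
    if missing:
        raise ConfigError(f"profiles missing for leaves {missing[:5]}")
    records = []
    for code in leaves:
        for _ in range(config.n_per_disease):
            flags = _noisy_flags(profiles.profiles[code],
                                 profiles.gender_prevalence[code],
                                 taxonomy.n_symptoms, config.flip_noise, rng)
            records.append(CaseRecord(symptoms=flags, disease_code=code))
    return records


def generate_concurrence_records(taxonomy: DiseaseTaxonomy,
                                 profiles: SymptomProfiles,
                                 combos: Sequence[ConcurrenceClass],
                                 config: GeneratorConfig,
                                 n_per_combo: int | None = None
                                 ) -> list[tuple[tuple[int, ...], ConcurrenceClass]]:
    """Draw composite cases for declared subclass-code combinations.

    Each record picks one leaf disease per member subclass, takes the
    union of their profiles, then applies flip noise.  Emits a warning
    when two declared combinations cover identical symptom sets at
    zero noise (inherently confusable).
    """
    rng = _rng_for(config, 2)
    n = n_per_combo if n_per_combo is not None else config.n_per_disease
    combo_unions = {}
    for combo in combos:
        union = set()
        for sub_code in combo.member_codes:
            if taxonomy.level_of(sub_code) != "subclass":
                raise ConfigError(
                    f"concurrence member {sub_code} is not a subclass code"
                )
            for leaf in taxonomy.children_of(sub_code):
                union |= profiles.profiles[leaf]
        combo_unions[combo.key] = union
    if config.flip_noise == 0:
        keys = list(combo_unions)
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                if combo_unions[a] == combo_unions[b]:
                    _warnings.warn(
                        f"combinations {a} and {b} cover identical symptom "
                        "sets at zero noise and cannot be told apart"
                    )
    out = []
    for combo in combos:
        members = sorted(combo.member_codes)
        for _ in range(n):
            union: set[int] = set()
            gender_ps = []
            for sub_code in members:
                leaves = taxonomy.children_of(sub_code)
                leaf = int(rng.choice(leaves))
                union |= profiles.profiles[leaf]
                gender_ps.append(profiles.gender_prevalence[leaf])
            flags = _noisy_flags(frozenset(union), float(np.mean(gender_ps)),
                                 taxonomy.n_symptoms, config.flip_noise, rng)
            out.append((flags, combo))
    return out


# -- packaged worked example ------------------------------------------


def worked_example_fixture() -> tuple[DiseaseTaxonomy, CaseRecord, list[RelationEntry]]:
    """The 11-symptom, 10-category labelling example.

    Returns the taxonomy (code base 10, tumor subtree populated:
    subclasses 1011-1013, diseases 10111-10115), the squamous-cell-
    carcinoma case whose symptoms are gender, fever, ulcer, pain and
    tumor, and its three-entry relation-list expansion.
    """
    data = resources.files("symdx") / "data"
    taxonomy = DiseaseTaxonomy.from_dict(
        json.loads((data / "worked_example_taxonomy.json").read_text())
    )
    with (data / "worked_example_records.csv").open(newline="") as fh:
        rows = list(csv.reader(fh))
    flags = tuple(int(v) for v in rows[1][:-1])
    record = CaseRecord(symptoms=flags, disease_code=int(rows[1][-1]))
    return taxonomy, record, expand_record(taxonomy, record)
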