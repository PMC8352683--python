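"""Hierarchical disease-code taxonomy and case-record handling.

Diseases are organised in a three-level tree: B main categories, T(b)
subclass types per category, and T^(b,j) specific diseases per
subclass.  Codes are built multiplicatively from a ``code_base`` N:

    category  b       ->  N*10 + b
    subclass  (b, j)  ->  (N*10 + b)*10 + j
    disease   (b,j,t) ->  ((N*10 + b)*10 + j)*10 + t

so each level appends one decimal digit; j and t are therefore capped
at 9, while b may reach 10 (category codes stay unambiguous because
membership is resolved by taxonomy lookup, never by digit counting).

A case record pairs a binary symptom vector with a leaf disease code.
Component 1 of every symptom vector is gender, treated as a default
pseudo-symptom (1 = male, 0 = female).  Expanding a record yields the
three-entry data-relationship list pairing the same symptoms with the
record's main-category, subclass, and disease codes.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Literal, Sequence

from symdx.errors import CodeRangeError, RecordParseError, UnknownCodeError

Level = Literal["main", "subclass", "disease"]

GENDER_INDEX = 0  # position of the gender pseudo-symptom in every vector


@dataclass(frozen=True)
class Disease:
    t: int
    name: str


@dataclass(frozen=True)
class Subclass:
    j: int
    name: str
    diseases: tuple[Disease, ...] = ()


@dataclass(frozen=True)
class Category:
    b: int
    name: str
    subclasses: tuple[Subclass, ...] = ()


@dataclass(frozen=True)
class DiseaseTaxonomy:
    """Three-level disease tree plus the governing symptom list.

    Parameters
    ----------
    code_base:
        The integer N entering the code arithmetic.  Held separately
        from the symptom count: the two usually coincide but the code
        scheme does not require it.
    symptom_names:
        Ordered symptom labels; index 0 is the gender pseudo-symptom.
    categories:
        The main disease categories with their nested subtrees.
    """

    code_base: int
    symptom_names: tuple[str, ...]
    categories: tuple[Category, ...] = ()

    def __post_init__(self):
        if self.code_base < 1:
            raise CodeRangeError("code_base must be a positive integer")
        if not self.symptom_names:
            raise CodeRangeError("taxonomy needs at least one symptom (gender)")
        for i, cat in enumerate(self.categories, start=1):
            if cat.b != i:
                raise CodeRangeError(
                    f"category indices must run 1..B consecutively, got b={cat.b} at position {i}"
                )
            for jj, sub in enumerate(cat.subclasses, start=1):
                if sub.j != jj or sub.j > 9:
                    raise CodeRangeError(
                        f"subclass index j={sub.j} under category {cat.b} must run 1..T(b) with T(b) <= 9"
                    )
                for tt, dis in enumerate(sub.diseases, start=1):
                    if dis.t != tt or dis.t > 9:
                        raise CodeRangeError(
                            f"disease index t={dis.t} under subclass ({cat.b},{sub.j}) "
                            "must run 1..T(b,j) with T(b,j) <= 9"
                        )
        codes = [c for c, _ in self._walk()]
        if len(codes) != len(set(codes)):
            raise CodeRangeError("code collision: taxonomy codes are not unique")

    # -- structure ----------------------------------------------------

    @property
    def n_symptoms(self) -> int:
        return len(self.symptom_names)

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    def _walk(self) -> Iterable[tuple[int, tuple[int, ...]]]:
        """Yield (code, path) for every registered node, parents first."""
        for cat in self.categories:
            yield self.encode(cat.b), (cat.b,)
            for sub in cat.subclasses:
                yield self.encode(cat.b, sub.j), (cat.b, sub.j)
                for dis in sub.diseases:
                    yield self.encode(cat.b, sub.j, dis.t), (cat.b, sub.j, dis.t)

    @cached_property
    def _by_code(self) -> dict[int, tuple[int, ...]]:
        return {code: path for code, path in self._walk()}

    # -- code arithmetic ----------------------------------------------

    def encode(self, b: int, j: int | None = None, t: int | None = None) -> int:
        """Encode a level path (b [, j [, t]]) into its integer code."""
        if not 1 <= b <= self.n_categories:
            raise CodeRangeError(
                f"main-category index b={b} out of range 1..{self.n_categories}"
            )
        code = self.code_base * 10 + b
        if j is None:
            if t is not None:
                raise CodeRangeError("disease index t given without subclass index j")
            return code
        subclasses = self.categories[b - 1].subclasses
        if not 1 <= j <= len(subclasses):
            raise CodeRangeError(
                f"subclass index j={j} out of range 1..{len(subclasses)} under category {code}"
            )
        code = code * 10 + j
        if t is None:
            return code
        diseases = subclasses[j - 1].diseases
        if not 1 <= t <= len(diseases):
            raise CodeRangeError(
                f"disease index t={t} out of range 1..{len(diseases)} under subclass {code}"
            )
        return code * 10 + t

    def decode(self, code: int) -> tuple[Level, list[int]]:
        """Return (level, ancestor codes root-first) for a registered code."""
        path = self._by_code.get(code)
        if path is None:
            raise UnknownCodeError(f"code {code} is not registered in the taxonomy")
        level: Level = ("main", "subclass", "disease")[len(path) - 1]
        ancestors = [self.encode(*path[:depth]) for depth in range(1, len(path))]
        return level, ancestors

    def level_of(self, code: int) -> Level:
        return self.decode(code)[0]

    def parent_of(self, code: int) -> int | None:
        ancestors = self.decode(code)[1]
        return ancestors[-1] if ancestors else None

    def children_of(self, code: int) -> list[int]:
        """Codes one level below ``code``, in taxonomy order."""
        path = self._by_code.get(code)
        if path is None:
            raise UnknownCodeError(f"code {code} is not registered in the taxonomy")
        if len(path) == 1:
            subs = self.categories[path[0] - 1].subclasses
            return [self.encode(path[0], s.j) for s in subs]
        if len(path) == 2:
            dis = self.categories[path[0] - 1].subclasses[path[1] - 1].diseases
            return [self.encode(path[0], path[1], d.t) for d in dis]
        return []

    def codes_at(self, level: Level) -> list[int]:
        depth = {"main": 1, "subclass": 2, "disease": 3}[level]
        return [c for c, p in self._by_code.items() if len(p) == depth]

    def all_codes(self) -> list[int]:
        return list(self._by_code)

    def name_of(self, code: int) -> str:
        path = self._by_code.get(code)
        if path is None:
            raise UnknownCodeError(f"code {code} is not registered in the taxonomy")
        node = self.categories[path[0] - 1]
        if len(path) >= 2:
            node = node.subclasses[path[1] - 1]
        if len(path) == 3:
            node = node.diseases[path[2] - 1]
        return node.name

    # -- serialisation ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "code_base": self.code_base,
            "symptoms": list(self.symptom_names),
            "categories": [
                {
                    "b": cat.b,
                    "name": cat.name,
                    "subclasses": [
                        {
                            "j": sub.j,
                            "name": sub.name,
                            "diseases": [
                                {"t": d.t, "name": d.name} for d in sub.diseases
                            ],
                        }
                        for sub in cat.subclasses
                    ],
                }
                for cat in self.categories
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "DiseaseTaxonomy":
        categories = tuple(
            Category(
                b=c["b"],
                name=c["name"],
                subclasses=tuple(
                    Subclass(
                        j=s["j"],
                        name=s["name"],
                        diseases=tuple(
                            Disease(t=d["t"], name=d["name"])
                            for d in s.get("diseases", [])
                        ),
                    )
                    for s in c.get("subclasses", [])
                ),
            )
            for c in payload["categories"]
        )
        return cls(
            code_base=payload["code_base"],
            symptom_names=tuple(payload["symptoms"]),
            categories=categories,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "DiseaseTaxonomy":
        return cls.from_dict(json.loads(Path(path).read_text()))


# -- case records -----------------------------------------------------


def validate_flags(flags: Sequence[int], n_symptoms: int) -> tuple[int, ...]:
    """Check a symptom vector: right length, every component 0 or 1."""
    flags = tuple(int(v) for v in flags)
    if len(flags) != n_symptoms:
        raise RecordParseError(
            f"symptom vector has length {len(flags)}, taxonomy declares {n_symptoms}"
        )
    if any(v not in (0, 1) for v in flags):
        raise RecordParseError(f"symptom flags must be 0/1, got {flags}")
    return flags


@dataclass(frozen=True)
class CaseRecord:
    """One consultation case: binary symptom flags plus a leaf disease code."""

    symptoms: tuple[int, ...]
    disease_code: int


@dataclass(frozen=True)
class RelationEntry:
    """One row of the data-relationship list: symptoms paired with a code
    at one of the three hierarchy levels."""

    symptoms: tuple[int, ...]
    code: int
    level: Level


def expand_record(taxonomy: DiseaseTaxonomy, record: CaseRecord) -> list[RelationEntry]:
    """Expand a leaf-labelled case into its three-level relation entries.

    The returned list always has exactly three entries sharing the
    record's symptom vector: main-category code, subclass code, and
    the disease code itself, in that order.
    """
    level, ancestors = taxonomy.decode(record.disease_code)
    if level != "disease":
        raise UnknownCodeError(
            f"record code {record.disease_code} is a {level} code, expected a leaf disease code"
        )
    flags = validate_flags(record.symptoms, taxonomy.n_symptoms)
    codes = ancestors + [record.disease_code]
    levels: list[Level] = ["main", "subclass", "disease"]
    return [RelationEntry(flags, c, lv) for c, lv in zip(codes, levels)]


def read_records(path: str | Path, taxonomy: DiseaseTaxonomy) -> list[CaseRecord]:
    """Read case records from CSV (columns: symptom names then ``disease``)."""
    records: list[CaseRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise RecordParseError("empty file: missing header row", row=0)
        expected = list(taxonomy.symptom_names) + ["disease"]
        if header != expected:
            raise RecordParseError(
                f"header mismatch: expected {expected}, got {header}", row=0
            )
        for i, row in enumerate(reader, start=1):
            if len(row) != len(expected):
                raise RecordParseError(
                    f"expected {len(expected)} fields, got {len(row)}", row=i
                )
            try:
                flags = validate_flags([_parse_flag(v, i) for v in row[:-1]],
                                       taxonomy.n_symptoms)
                code = int(row[-1])
            except RecordParseError:
                raise
            except ValueError as exc:
                raise RecordParseError(str(exc), row=i) from exc
            try:
                level = taxonomy.level_of(code)
            except UnknownCodeError as exc:
                raise RecordParseError(f"unknown disease code {code}", row=i) from exc
            if level != "disease":
                raise RecordParseError(
                    f"code {code} is not a leaf disease code", row=i
                )
            records.append(CaseRecord(flags, code))
    return records


def _parse_flag(token: str, row: int) -> int:
    if token not in ("0", "1"):
        raise RecordParseError(f"symptom flag must be the literal 0 or 1, got {token!r}",
                               row=row)
    return int(token)


def write_records(path: str | Path, records: Iterable[CaseRecord],
                  taxonomy: DiseaseTaxonomy) -> None:
    """Write case records as CSV, inverse of :func:`read_records`."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(taxonomy.symptom_names) + ["disease"])
        for rec in records:
            flags = validate_flags(rec.symptoms, taxonomy.n_symptoms)
            taxonomy.decode(rec.disease_code)
            writer.writerow(list(flags) + [rec.disease_code])
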