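"""Constrained all-subsets enumeration of candidate survival models.

Candidate models are built from a timing block (``d`` always present, ``d2``
optional), freshwater covariates ``{t, f}``, marine covariates
``{T, U, E, V}``, a binary climate index ``I``, and one of three year-level
random-effect structures.  Each model is classified into a cumulative
covariate grouping (``MT`` < ``MT-FW`` < ``MT-FW-M`` < ``MT-FW-M-C``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

#: Canonical covariate order used everywhere a design matrix is assembled.
FIXED_ORDER: tuple[str, ...] = ("d", "d2", "t", "f", "T", "U", "E", "V", "I")

FRESHWATER: tuple[str, ...] = ("t", "f")
MARINE: tuple[str, ...] = ("T", "U", "E", "V")
CLIMATE: tuple[str, ...] = ("I",)

#: Year-level random structures: intercept only; intercept + slope on d;
#: intercept + slopes on d and d2.
RANDOM_STRUCTURES: tuple[str, ...] = ("R0", "R1", "R2")

GROUPING_ORDER: tuple[str, ...] = ("MT", "MT-FW", "MT-FW-M", "MT-FW-M-C")


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: a fixed-effect covariate set plus a random structure.

    Parameters
    ----------
    fixed_set
        Subset of :data:`FIXED_ORDER`; must contain ``d``, and may contain
        ``d2`` only if ``d`` is present (always true by the first rule).
    random_structure
        One of ``"R0"`` (year intercept), ``"R1"`` (intercept + slope on d),
        ``"R2"`` (intercept + slopes on d and d2).
    """

    fixed_set: frozenset[str]
    random_structure: str

    def __post_init__(self) -> None:
        unknown = self.fixed_set - set(FIXED_ORDER)
        if unknown:
            raise ValueError(f"unknown covariates in fixed_set: {sorted(unknown)}")
        if "d" not in self.fixed_set:
            raise ValueError("every candidate model must include the timing covariate 'd'")
        if "d2" in self.fixed_set and "d" not in self.fixed_set:
            raise ValueError("'d2' requires 'd'")
        if self.random_structure not in RANDOM_STRUCTURES:
            raise ValueError(
                f"random_structure must be one of {RANDOM_STRUCTURES}, got {self.random_structure!r}"
            )

    @property
    def fixed_names(self) -> tuple[str, ...]:
        """Fixed covariates in canonical order (excluding the intercept)."""
        return tuple(c for c in FIXED_ORDER if c in self.fixed_set)

    @property
    def n_random(self) -> int:
        """Number of variance components implied by the random structure."""
        return {"R0": 1, "R1": 2, "R2": 3}[self.random_structure]

    @property
    def grouping(self) -> str:
        return classify_grouping(self)

    @property
    def label(self) -> str:
        return "+".join(self.fixed_names) + f"|{self.random_structure}"

    def _bitmask(self) -> int:
        return sum(1 << i for i, c in enumerate(FIXED_ORDER) if c in self.fixed_set)

    def sort_key(self) -> tuple[int, int, int]:
        return (
            GROUPING_ORDER.index(self.grouping),
            self._bitmask(),
            RANDOM_STRUCTURES.index(self.random_structure),
        )

    def to_dict(self) -> dict:
        return {
            "fixed_set": list(self.fixed_names),
            "random_structure": self.random_structure,
            "grouping": self.grouping,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(frozenset(d["fixed_set"]), d["random_structure"])


def classify_grouping(spec: ModelSpec) -> str:
    """Assign the cumulative covariate grouping of a candidate model.

    ``MT-FW-M-C`` if the climate index is present; else ``MT-FW-M`` if any
    marine covariate is present; else ``MT-FW`` if any freshwater covariate
    is present; else ``MT`` (timing only).
    """
    s = spec.fixed_set
    if s & set(CLIMATE):
        return "MT-FW-M-C"
    if s & set(MARINE):
        return "MT-FW-M"
    if s & set(FRESHWATER):
        return "MT-FW"
    return "MT"


@dataclass
class ModelSpace:
    """An ordered, duplicate-free list of candidate models."""

    specs: list[ModelSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.specs)) != len(self.specs):
            raise ValueError("duplicate model specifications")
        for s in self.specs:
            if "d" not in s.fixed_set:
                raise ValueError("model space contains a spec without 'd'")

    @property
    def M(self) -> int:
        return len(self.specs)

    def __len__(self) -> int:
        return len(self.specs)

    def __iter__(self):
        return iter(self.specs)

    def __getitem__(self, i):
        return self.specs[i]

    def grouping_counts(self) -> dict[str, int]:
        counts = {g: 0 for g in GROUPING_ORDER}
        for s in self.specs:
            counts[s.grouping] += 1
        return counts

    def to_dict(self) -> dict:
        return {
            "M": self.M,
            "specs": [dict(index=i, **s.to_dict()) for i, s in enumerate(self.specs)],
        }


def _subsets(items: Sequence[str]) -> list[frozenset[str]]:
    out = []
    for r in range(len(items) + 1):
        out.extend(frozenset(c) for c in itertools.combinations(items, r))
    return out


def enumerate_models(
    freshwater: Iterable[str] = FRESHWATER,
    marine: Iterable[str] = MARINE,
    climate: Iterable[str] = CLIMATE,
    random_structures: Iterable[str] = RANDOM_STRUCTURES,
) -> ModelSpace:
    """Enumerate every candidate model under the hierarchy constraints.

    The space is the cross product of timing sets ``{d}`` and ``{d, d2}``,
    all subsets of the freshwater/marine/climate covariate pools, and the
    random structures; with the full pools this yields
    2 x 4 x 16 x 2 x 3 = 768 models.  Restricting the pools (e.g.
    ``marine=()``) produces reduced spaces for scaled-down pipelines.

    The ordering is canonical — lexicographic by (grouping, covariate
    bitmask, random structure) — so repeated calls return an identical list.
    """
    freshwater, marine, climate = tuple(freshwater), tuple(marine), tuple(climate)
    if set(freshwater) - set(FRESHWATER):
        raise ValueError(f"freshwater pool must be a subset of {FRESHWATER}")
    if set(marine) - set(MARINE):
        raise ValueError(f"marine pool must be a subset of {MARINE}")
    if set(climate) - set(CLIMATE):
        raise ValueError(f"climate pool must be a subset of {CLIMATE}")

    timing_sets = [frozenset({"d"}), frozenset({"d", "d2"})]
    specs = [
        ModelSpec(timing | fw | m | c, r)
        for timing in timing_sets
        for fw in _subsets(freshwater)
        for m in _subsets(marine)
        for c in _subsets(climate)
        for r in random_structures
    ]
    specs.sort(key=ModelSpec.sort_key)
    return ModelSpace(specs)
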