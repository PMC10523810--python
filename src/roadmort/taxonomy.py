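"""ICD-10 code sets and classification for road traffic mortality analysis.

Nonspecific ("garbage") cause-of-death codes are too vague to assign a
specific underlying cause and must be redistributed before cause-specific
analysis. Five categories sit at nested levels of the cause hierarchy::

    all causes  >  injuries  >  unintentional injuries  >  transport  >  road traffic
    R95-R99        Y34,Y87.2,    X59                        V99,Y85.9      V87.0-V87.8,
                   Y89.9                                                   V89.2

Each category carries a *denominator* set (the hierarchy level against which
its share is measured) and a *target* set (the specific causes its deaths
are redistributed into). Road traffic deaths are V01-V89 at the 3-character
level; the level-5 garbage codes (road traffic crashes of unspecified user
type) are road-traffic deaths themselves and redistribute into occupant and
motorcyclist codes only.

The code sets live in a versioned YAML registry bundled with the package
(``data/code_registry.yaml``) so users can align them with GBD/WHO variants.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd
import yaml


class InvalidCodeError(ValueError):
    """A string that is not a syntactically valid ICD-10 code."""


class RegistryError(ValueError):
    """The code registry violates a structural invariant."""


_CODE_RE = re.compile(r"^[A-Z][0-9]{2}(\.[0-9])?$")


def validate_code(code: str) -> str:
    """Validate and normalize an ICD-10 code string.

    Accepts 3-character codes ("X59") and 4-character codes with an explicit
    decimal ("V87.3"); returns the uppercase form. Raises
    :class:`InvalidCodeError` naming the offending string otherwise.
    """
    if not isinstance(code, str):
        raise InvalidCodeError(f"not a string: {code!r}")
    c = code.strip().upper()
    if not _CODE_RE.match(c):
        raise InvalidCodeError(f"malformed ICD-10 code: {code!r}")
    return c


class NonspecificCategory(enum.Enum):
    """The five garbage-code categories, plus NONE for specific codes."""

    ILL_DEFINED = "ill_defined"
    UNDETERMINED_INTENT = "undetermined_intent"
    UNSPEC_UNINTENTIONAL = "unspec_unintentional"
    UNSPEC_TRANSPORT = "unspec_transport"
    UNSPEC_RT = "unspec_rt"
    NONE = "none"


#: Cascade order: outermost hierarchy level first.
GARBAGE_CASCADE: tuple[NonspecificCategory, ...] = (
    NonspecificCategory.ILL_DEFINED,
    NonspecificCategory.UNDETERMINED_INTENT,
    NonspecificCategory.UNSPEC_UNINTENTIONAL,
    NonspecificCategory.UNSPEC_TRANSPORT,
    NonspecificCategory.UNSPEC_RT,
)


class RoadUserGroup(enum.Enum):
    PEDESTRIAN = "pedestrian"
    PEDAL_CYCLIST = "pedal_cyclist"
    MOTORCYCLIST = "motorcyclist"
    OCCUPANT = "occupant"
    OTHER_RT = "other_rt"
    NON_RT = "non_rt"


_Ranges = tuple[tuple[str, str], ...]


def _parse_entry(entry: str) -> tuple[str, str] | frozenset[str]:
    """Parse one registry entry: a code, a 3-char range, or a 4-char range."""
    entry = entry.strip().upper()
    if "-" in entry:
        lo, hi = (p.strip() for p in entry.split("-", 1))
        if "." in lo or "." in hi:
            lo, hi = validate_code(lo), validate_code(hi)
            if lo[:3] != hi[:3]:
                raise RegistryError(f"4-character range must share a stem: {entry}")
            stem = lo[:3]
            return frozenset(
                f"{stem}.{d}" for d in range(int(lo[4]), int(hi[4]) + 1)
            )
        return (validate_code(lo), validate_code(hi))
    return frozenset({validate_code(entry)})


def _parse_ranges(entries: Iterable[str]) -> tuple[_Ranges, frozenset[str]]:
    ranges: list[tuple[str, str]] = []
    codes: set[str] = set()
    for e in entries:
        parsed = _parse_entry(e)
        if isinstance(parsed, tuple):
            ranges.append(parsed)
        else:
            codes |= parsed
    return tuple(ranges), frozenset(codes)


def _stem_in(stem: str, ranges: _Ranges) -> bool:
    return any(lo <= stem <= hi for lo, hi in ranges)


@dataclass(frozen=True)
class CodeSetRegistry:
    """Immutable registry of garbage, denominator, target and group code sets."""

    garbage: Mapping[NonspecificCategory, frozenset[str]]
    denominator_ranges: Mapping[NonspecificCategory, _Ranges]
    target_ranges: Mapping[NonspecificCategory, _Ranges]
    group_ranges: Mapping[RoadUserGroup, _Ranges]
    road_traffic_ranges: _Ranges
    version: int = 1
    # parents whose .0-.8 children are all garbage: the bare 3-char code
    # (reported without a 4th character) is classified into that category
    _garbage_parents: Mapping[str, NonspecificCategory] = field(default_factory=dict)

    def __post_init__(self) -> None:
        parents: dict[str, NonspecificCategory] = {}
        seen: dict[str, NonspecificCategory] = {}
        for cat, codes in self.garbage.items():
            for c in codes:
                if c in seen:
                    raise RegistryError(
                        f"code {c} in both {seen[c].name} and {cat.name}"
                    )
                seen[c] = cat
            stems = {c[:3] for c in codes if len(c) == 5}
            for stem in stems:
                if all(f"{stem}.{d}" in codes for d in range(9)):
                    parents[stem] = cat
        object.__setattr__(self, "_garbage_parents", parents)
        # every garbage code must lie inside its own denominator
        for cat, codes in self.garbage.items():
            for c in codes:
                if not _stem_in(c[:3], self.denominator_ranges[cat]):
                    raise RegistryError(
                        f"{c} ({cat.name}) outside its denominator ranges"
                    )

    # -- scalar classification ------------------------------------------------

    def classify(self, code: str) -> NonspecificCategory:
        """Return the garbage category containing *code*, else NONE.

        A bare 3-character code matches a category holding 4-character codes
        only when the category covers its .0-.8 children (the .9 child may be
        a residual treated as specific), so "V87" is level-5 garbage while
        "Y87" is specific.
        """
        c = validate_code(code)
        for cat, codes in self.garbage.items():
            if c in codes:
                return cat
        if len(c) == 5:
            parent = c[:3]
            for cat, codes in self.garbage.items():
                if parent in codes:
                    return cat  # child of a wholly-garbage 3-char code
        else:
            cat = self._garbage_parents.get(c)
            if cat is not None:
                return cat
        return NonspecificCategory.NONE

    def road_user_group(self, code: str) -> RoadUserGroup:
        """Road-user group of a *specific* code; garbage codes are rejected."""
        c = validate_code(code)
        cat = self.classify(c)
        if cat is not NonspecificCategory.NONE:
            raise ValueError(
                f"{c} is a nonspecific code ({cat.name}); it has no road-user group"
            )
        stem = c[:3]
        for group in (
            RoadUserGroup.PEDESTRIAN,
            RoadUserGroup.PEDAL_CYCLIST,
            RoadUserGroup.MOTORCYCLIST,
            RoadUserGroup.OCCUPANT,
            RoadUserGroup.OTHER_RT,
        ):
            if _stem_in(stem, self.group_ranges[group]):
                return group
        return RoadUserGroup.NON_RT

    def is_road_traffic(self, code: str) -> bool:
        """True for V01-V89 at the 3-character level, including the level-5
        garbage codes (road-traffic deaths of unspecified user)."""
        c = validate_code(code)
        return _stem_in(c[:3], self.road_traffic_ranges)

    # -- predicates used by redistribution ------------------------------------

    def in_denominator(self, category: NonspecificCategory, code: str) -> bool:
        return _stem_in(validate_code(code)[:3], self.denominator_ranges[category])

    def in_target(self, category: NonspecificCategory, code: str) -> bool:
        """Target predicate: inside the category's target ranges AND specific."""
        c = validate_code(code)
        return (
            _stem_in(c[:3], self.target_ranges[category])
            and self.classify(c) is NonspecificCategory.NONE
        )

    @property
    def all_garbage(self) -> frozenset[str]:
        out: set[str] = set()
        for codes in self.garbage.values():
            out |= codes
        return frozenset(out)


def _load_yaml(path=None) -> dict:
    if path is None:
        ref = resources.files("roadmort.data").joinpath("code_registry.yaml")
        return yaml.safe_load(ref.read_text())
    with open(path) as fh:
        return yaml.safe_load(fh)


def load_registry(path: str | None = None) -> CodeSetRegistry:
    """Load a :class:`CodeSetRegistry` from YAML (package default if *path* is None)."""
    raw = _load_yaml(path)
    garbage: dict[NonspecificCategory, frozenset[str]] = {}
    for name, entries in raw["garbage_sets"].items():
        cat = NonspecificCategory[name]
        codes: set[str] = set()
        for e in entries:
            parsed = _parse_entry(str(e))
            if isinstance(parsed, tuple):
                raise RegistryError(
                    f"garbage set {name} may not contain 3-char ranges: {e}"
                )
            codes |= parsed
        garbage[cat] = frozenset(codes)

    def ranges_of(section: str) -> dict[NonspecificCategory, _Ranges]:
        out = {}
        for name, entries in raw[section].items():
            rngs, singles = _parse_ranges(str(e) for e in entries)
            rngs = rngs + tuple((c[:3], c[:3]) for c in singles)
            out[NonspecificCategory[name]] = rngs
        return out

    groups = {}
    for name, entries in raw["road_user_groups"].items():
        rngs, singles = _parse_ranges(str(e) for e in entries)
        groups[RoadUserGroup[name]] = rngs + tuple((c[:3], c[:3]) for c in singles)
    rt_rngs, rt_singles = _parse_ranges(str(e) for e in raw["road_traffic"])
    return CodeSetRegistry(
        garbage=garbage,
        denominator_ranges=ranges_of("denominators"),
        target_ranges=ranges_of("targets"),
        group_ranges=groups,
        road_traffic_ranges=rt_rngs + tuple((c[:3], c[:3]) for c in rt_singles),
        version=int(raw.get("version", 1)),
    )


@lru_cache(maxsize=1)
def default_registry() -> CodeSetRegistry:
    """The registry bundled with the package (cached)."""
    return load_registry(None)


# -- vectorized helpers over pandas Series of codes ---------------------------


def categorize(causes: pd.Series, registry: CodeSetRegistry) -> pd.Series:
    """Per-row :class:`NonspecificCategory` for a Series of cause codes."""
    mapping = {c: registry.classify(c) for c in causes.unique()}
    return causes.map(mapping)


def group_series(causes: pd.Series, registry: CodeSetRegistry) -> pd.Series:
    """Per-row :class:`RoadUserGroup`; garbage codes map to ``pd.NA``."""
    mapping = {}
    for c in causes.unique():
        if registry.classify(c) is NonspecificCategory.NONE:
            mapping[c] = registry.road_user_group(c)
        else:
            mapping[c] = pd.NA
    return causes.map(mapping)


def road_traffic_mask(causes: pd.Series, registry: CodeSetRegistry) -> pd.Series:
    mapping = {c: registry.is_road_traffic(c) for c in causes.unique()}
    return causes.map(mapping).astype(bool)


def denominator_mask(
    causes: pd.Series, category: NonspecificCategory, registry: CodeSetRegistry
) -> pd.Series:
    mapping = {c: registry.in_denominator(category, c) for c in causes.unique()}
    return causes.map(mapping).astype(bool)


def target_mask(
    causes: pd.Series, category: NonspecificCategory, registry: CodeSetRegistry
) -> pd.Series:
    mapping = {c: registry.in_target(category, c) for c in causes.unique()}
    return causes.map(mapping).astype(bool)
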