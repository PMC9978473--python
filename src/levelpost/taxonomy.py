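"""Lymph node level taxonomy: names, label values, laterality, mirror pairs,
and craniocaudal exclusivity chains.

The taxonomy is the single source of truth for which integer label values are
legal in a label volume, which levels are left/right counterparts (for
mirroring augmentation), and which levels are craniocaudally adjacent and
therefore mutually exclusive on any one CT slice (for slice-plane adjustment).

The shipped default covers the 20 neck levels commonly delineated for nodal
clinical target volumes — the midline levels Ia, VIa, VIb and VIIa plus the
bilateral levels Ib, II, III, IVa, IVb, V, VIIb and VIII — mapped to the
contiguous label values 1-20 with background 0 (21 classes in total).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from .errors import ValidationError

LATERALITIES = ("left", "right", "midline")

DEFAULT_TAXONOMY_RESOURCE = "default_taxonomy.json"


@dataclass(frozen=True)
class LevelEntry:
    """One lymph node level: a name, an integer label value and a laterality."""

    name: str
    label_value: int
    laterality: str


@dataclass(frozen=True)
class LevelTaxonomy:
    """Validated level model.

    Parameters
    ----------
    entries
        The level definitions. Label values must be unique positive integers
        distinct from ``background_value``.
    background_value
        Label value of the background class (fixed at 0 in the default).
    mirror_pairs
        ``(left_name, right_name)`` tuples. Every left-laterality entry must
        appear in exactly one pair, matched with a right-laterality entry;
        midline entries appear in none.
    exclusivity_chains
        Ordered lists of level names, cranial to caudal. Members of one chain
        are mutually exclusive on any single CT slice.
    """

    entries: tuple[LevelEntry, ...]
    background_value: int = 0
    mirror_pairs: tuple[tuple[str, str], ...] = ()
    exclusivity_chains: tuple[tuple[str, ...], ...] = ()
    _by_name: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        self._validate()
        object.__setattr__(self, "_by_name", {e.name: e for e in self.entries})

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate level names: {dup}")
        values = [e.label_value for e in self.entries]
        for e in self.entries:
            if e.label_value <= 0:
                raise ValidationError(
                    f"label value for {e.name!r} must be positive, got {e.label_value}"
                )
            if e.label_value == self.background_value:
                raise ValidationError(
                    f"label value for {e.name!r} equals background value {self.background_value}"
                )
            if e.laterality not in LATERALITIES:
                raise ValidationError(
                    f"laterality for {e.name!r} must be one of {LATERALITIES}, got {e.laterality!r}"
                )
        if len(set(values)) != len(values):
            dup = sorted({v for v in values if values.count(v) > 1})
            offenders = [e.name for e in self.entries if e.label_value in dup]
            raise ValidationError(
                f"duplicate label values {dup} shared by entries {offenders}"
            )

        by_name = {e.name: e for e in self.entries}
        paired: set[str] = set()
        for left, right in self.mirror_pairs:
            for nm in (left, right):
                if nm not in by_name:
                    raise ValidationError(f"mirror pair references unknown level {nm!r}")
                if nm in paired:
                    raise ValidationError(f"level {nm!r} appears in more than one mirror pair")
                paired.add(nm)
            if by_name[left].laterality != "left" or by_name[right].laterality != "right":
                raise ValidationError(
                    f"mirror pair ({left!r}, {right!r}) must pair a left with a right level"
                )
        for e in self.entries:
            if e.laterality in ("left", "right") and e.name not in paired:
                raise ValidationError(f"lateral level {e.name!r} missing from mirror_pairs")
            if e.laterality == "midline" and e.name in paired:
                raise ValidationError(f"midline level {e.name!r} must not appear in mirror_pairs")

        for chain in self.exclusivity_chains:
            seen: set[str] = set()
            for nm in chain:
                if nm not in by_name:
                    raise ValidationError(f"exclusivity chain references unknown level {nm!r}")
                if nm in seen:
                    raise ValidationError(f"level {nm!r} appears twice in one exclusivity chain")
                seen.add(nm)

    # -- lookups ----------------------------------------------------------

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries)

    @property
    def label_values(self) -> tuple[int, ...]:
        return tuple(e.label_value for e in self.entries)

    @property
    def n_levels(self) -> int:
        return len(self.entries)

    @property
    def n_classes(self) -> int:
        """Number of prediction classes including background."""
        return len(self.entries) + 1

    def entry(self, name: str) -> LevelEntry:
        try:
            return self._by_name[name]
        except KeyError:
            raise ValidationError(f"unknown level name {name!r}") from None

    def label_for(self, name: str) -> int:
        return self.entry(name).label_value

    def name_for(self, label_value: int) -> str:
        for e in self.entries:
            if e.label_value == label_value:
                return e.name
        raise ValidationError(f"unknown label value {label_value}")

    def chains_as_labels(self) -> tuple[tuple[int, ...], ...]:
        """Exclusivity chains expressed as label values, cranial to caudal."""
        return tuple(
            tuple(self.label_for(nm) for nm in chain) for chain in self.exclusivity_chains
        )

    def mirror_label_map(self) -> dict[int, int]:
        """Label permutation swapping left and right counterparts.

        Midline labels and background map to themselves.
        """
        mapping = {self.background_value: self.background_value}
        for e in self.entries:
            mapping[e.label_value] = e.label_value
        for left, right in self.mirror_pairs:
            lv, rv = self.label_for(left), self.label_for(right)
            mapping[lv], mapping[rv] = rv, lv
        return mapping

    def valid_values(self) -> frozenset[int]:
        return frozenset(self.label_values) | {self.background_value}


def _taxonomy_from_dict(doc: dict) -> LevelTaxonomy:
    try:
        entries = tuple(
            LevelEntry(str(e["name"]), int(e["label_value"]), str(e["laterality"]))
            for e in doc["entries"]
        )
        mirror_pairs = tuple((str(a), str(b)) for a, b in doc.get("mirror_pairs", []))
        chains = tuple(tuple(str(n) for n in c) for c in doc.get("exclusivity_chains", []))
        background = int(doc.get("background_value", 0))
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"taxonomy document missing or malformed field: {exc}") from exc
    return LevelTaxonomy(
        entries=entries,
        background_value=background,
        mirror_pairs=mirror_pairs,
        exclusivity_chains=chains,
    )


def load_taxonomy(path: str | Path | None = None) -> LevelTaxonomy:
    """Load a taxonomy from a JSON file, or the shipped default when ``path`` is None.

    Raises
    ------
    ValidationError
        If any taxonomy invariant fails (duplicate label values, dangling
        chain or mirror-pair names, bad lateralities).
    json.JSONDecodeError
        If the file is not valid JSON.
    """
    if path is None:
        text = (
            resources.files("levelpost").joinpath("data", DEFAULT_TAXONOMY_RESOURCE).read_text()
        )
    else:
        text = Path(path).read_text()
    return _taxonomy_from_dict(json.loads(text))
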