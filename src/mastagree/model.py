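"""Core data model: class levels, result records, panel registry, datasets.

Results from a MAST (multiple allergen simultaneous test) analyzer are
semi-quantitative: each (patient, allergen) reading is a class level 0-6,
where higher classes indicate a stronger specific-IgE signal.  Different
analyzers label shared allergens with slightly different spellings, so all
allergen names pass through a registry-backed canonicalization step before
any two datasets are compared.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping

CLASS_MIN = 0
CLASS_MAX = 6


class Panel(str, Enum):
    """Panel type an allergen belongs to."""

    FOOD = "food"
    INHALANT = "inhalant"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class MastError(Exception):
    """Base class for all package-specific errors."""


class ClassLevelError(MastError, ValueError):
    """Class level outside the 0-6 scale or not an integer."""


class UnknownAllergenError(MastError, KeyError):
    """Allergen name not resolvable through the registry."""


class UnknownAnalyzerError(MastError, KeyError):
    """Analyzer id not present in the registry."""


class DuplicateRecordError(MastError, ValueError):
    """Two records share (patient, analyzer, panel, allergen)."""


_WS = re.compile(r"\s+")


def normalize_name(raw: str) -> str:
    """Lower-case, trim and collapse internal whitespace.

    This is the canonical-form convention for allergen names; registry
    aliases are keyed on normalized names.
    """
    if raw is None or not str(raw).strip():
        raise ValueError("allergen name must be non-empty")
    return _WS.sub(" ", str(raw).strip()).lower()


def validate_class_level(value: object) -> int:
    """Coerce *value* to an int class level, enforcing the 0-6 range."""
    try:
        level = int(value)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise ClassLevelError(f"class level {value!r} is not an integer")
    if isinstance(value, float) and not float(value).is_integer():
        raise ClassLevelError(f"class level {value!r} is not an integer")
    if not CLASS_MIN <= level <= CLASS_MAX:
        raise ClassLevelError(
            f"class level {level} outside allowed range {CLASS_MIN}-{CLASS_MAX}"
        )
    return level


@dataclass(frozen=True)
class ResultRecord:
    """One analyzer reading: a class level for (patient, analyzer, panel, allergen)."""

    patient_id: str
    analyzer_id: str
    panel: Panel
    allergen: str
    class_level: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "panel", Panel(self.panel))
        object.__setattr__(self, "class_level", validate_class_level(self.class_level))

    @property
    def key(self) -> tuple[str, str, Panel, str]:
        return (self.patient_id, self.analyzer_id, self.panel, self.allergen)


class PanelRegistry:
    """Registered analyzer panels plus an allergen-name alias map.

    Parameters
    ----------
    panels:
        ``analyzer_id -> {panel -> iterable of allergen names}``.  Names are
        normalized on ingestion.
    aliases:
        ``raw name -> canonical name``; both sides are normalized.  Alias
        targets must be registered in at least one panel.
    """

    def __init__(
        self,
        panels: Mapping[str, Mapping[Panel | str, Iterable[str]]],
        aliases: Mapping[str, str] | None = None,
    ) -> None:
        self._panels: dict[str, dict[Panel, frozenset[str]]] = {}
        for analyzer, by_panel in panels.items():
            self._panels[str(analyzer)] = {
                Panel(panel): frozenset(normalize_name(a) for a in names)
                for panel, names in by_panel.items()
            }
        self._known: frozenset[str] = frozenset(
            a for by_panel in self._panels.values() for names in by_panel.values() for a in names
        )
        self._aliases: dict[str, str] = {}
        for raw, target in (aliases or {}).items():
            src, dst = normalize_name(raw), normalize_name(target)
            if dst not in self._known:
                raise UnknownAllergenError(
                    f"alias target {dst!r} is not a registered allergen"
                )
            if src in self._known and src != dst:
                raise ValueError(
                    f"alias source {src!r} is itself a registered canonical name"
                )
            self._aliases[src] = dst

    @property
    def analyzers(self) -> tuple[str, ...]:
        return tuple(self._panels)

    def has_analyzer(self, analyzer_id: str) -> bool:
        return analyzer_id in self._panels

    def allergens(self, analyzer_id: str, panel: Panel | str) -> frozenset[str]:
        if analyzer_id not in self._panels:
            raise UnknownAnalyzerError(f"unknown analyzer {analyzer_id!r}")
        return self._panels[analyzer_id].get(Panel(panel), frozenset())

    def is_registered(self, analyzer_id: str, panel: Panel | str, allergen: str) -> bool:
        return normalize_name(allergen) in self.allergens(analyzer_id, panel)

    def canonicalize(self, raw: str) -> str:
        """Resolve *raw* to its canonical allergen name.

        Idempotent: canonical names map to themselves.  Raises
        :class:`UnknownAllergenError` for names absent from both the alias
        map and every registered panel.
        """
        name = normalize_name(raw)
        name = self._aliases.get(name, name)
        if name not in self._known:
            raise UnknownAllergenError(f"unknown allergen {raw!r}")
        return name

    def check_counts(self, expected: Mapping[str, Mapping[Panel | str, int]]) -> list[str]:
        """Soft consistency check of panel sizes against expected counts.

        Returns human-readable warnings; never raises.  Panel contents are
        not fully enumerable from public sources, so mismatches are advisory.
        """
        warnings: list[str] = []
        for analyzer, by_panel in expected.items():
            for panel, count in by_panel.items():
                if not self.has_analyzer(analyzer):
                    warnings.append(f"analyzer {analyzer!r} not registered")
                    continue
                actual = len(self.allergens(analyzer, panel))
                if actual != count:
                    warnings.append(
                        f"{analyzer}/{Panel(panel).value}: {actual} allergens "
                        f"registered, expected {count}"
                    )
        return warnings


def canonicalize_allergen(raw: str, registry: PanelRegistry) -> str:
    """Resolve a raw allergen label to its canonical name via *registry*."""
    return registry.canonicalize(raw)


@dataclass(frozen=True)
class Dataset:
    """An immutable collection of validated result records."""

    records: tuple[ResultRecord, ...]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ResultRecord]:
        return iter(self.records)

    @staticmethod
    def build(
        records: Iterable[ResultRecord],
        registry: PanelRegistry | None = None,
        provenance: str = "",
    ) -> "Dataset":
        """Validate uniqueness (and registry membership, if given) and freeze.

        Allergen names are canonicalized through *registry* when provided.
        """
        out: list[ResultRecord] = []
        seen: set[tuple[str, str, Panel, str]] = set()
        for rec in records:
            if registry is not None:
                if not registry.has_analyzer(rec.analyzer_id):
                    raise UnknownAnalyzerError(f"unknown analyzer {rec.analyzer_id!r}")
                canonical = registry.canonicalize(rec.allergen)
                if canonical not in registry.allergens(rec.analyzer_id, rec.panel):
                    raise UnknownAllergenError(
                        f"allergen {canonical!r} not in {rec.analyzer_id!r} "
                        f"{rec.panel.value} panel"
                    )
                if canonical != rec.allergen:
                    rec = ResultRecord(
                        rec.patient_id, rec.analyzer_id, rec.panel, canonical, rec.class_level
                    )
            else:
                rec = ResultRecord(
                    rec.patient_id,
                    rec.analyzer_id,
                    rec.panel,
                    normalize_name(rec.allergen),
                    rec.class_level,
                )
            if rec.key in seen:
                raise DuplicateRecordError(
                    f"duplicate record for patient={rec.patient_id!r} "
                    f"analyzer={rec.analyzer_id!r} panel={rec.panel.value} "
                    f"allergen={rec.allergen!r}"
                )
            seen.add(rec.key)
            out.append(rec)
        return Dataset(records=tuple(out), provenance=provenance)

    def analyzers(self) -> tuple[str, ...]:
        return tuple(sorted({r.analyzer_id for r in self.records}))

    def patients(self) -> tuple[str, ...]:
        return tuple(sorted({r.patient_id for r in self.records}))


def registry_from_records(records: Iterable[ResultRecord]) -> PanelRegistry:
    """Build a minimal registry that registers exactly what *records* use.

    Useful for validating synthetic datasets whose allergens are not part of
    the shipped default registry.
    """
    panels: dict[str, dict[Panel, set[str]]] = {}
    for rec in records:
        panels.setdefault(rec.analyzer_id, {}).setdefault(rec.panel, set()).add(
            normalize_name(rec.allergen)
        )
    return PanelRegistry(panels)
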