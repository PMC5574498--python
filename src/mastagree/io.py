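"""Long-format file I/O for analyzer results and registry configs.

Result files are delimited text (comma by default, tab for ``.tsv``/``.tab``)
with header columns ``patient_id, analyzer, panel, allergen, class``.
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path
from typing import Literal

import pandas as pd
import yaml

from .model import (
    ClassLevelError,
    Dataset,
    Panel,
    PanelRegistry,
    ResultRecord,
    UnknownAllergenError,
    UnknownAnalyzerError,
    validate_class_level,
)

RESULT_COLUMNS = ("patient_id", "analyzer", "panel", "allergen", "class")

_TAB_EXTENSIONS = {".tsv", ".tab"}


def _sep_for(path: os.PathLike | str) -> str:
    return "\t" if Path(path).suffix.lower() in _TAB_EXTENSIONS else ","


def read_results(
    path: os.PathLike | str,
    registry: PanelRegistry,
    on_unknown_allergen: Literal["error", "drop"] = "error",
) -> Dataset:
    """Read a long-format results file into a validated :class:`Dataset`.

    Allergen names are canonicalized through *registry*; rows are validated
    for class-level range, analyzer membership, and uniqueness of
    (patient, analyzer, panel, allergen).  Row order is irrelevant.

    Parameters
    ----------
    on_unknown_allergen:
        ``"error"`` (default) raises on allergens the registry cannot
        resolve; ``"drop"`` warns and skips those rows.
    """
    if on_unknown_allergen not in ("error", "drop"):
        raise ValueError(f"on_unknown_allergen must be 'error' or 'drop', got {on_unknown_allergen!r}")
    frame = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    missing = [c for c in RESULT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    records: list[ResultRecord] = []
    rows = frame[list(RESULT_COLUMNS)].itertuples(index=False, name=None)
    for idx, (patient_id, analyzer, panel, raw_allergen, raw_class) in enumerate(
        rows, start=2
    ):  # header is row 1
        try:
            level = validate_class_level(raw_class)
        except ClassLevelError as exc:
            raise ClassLevelError(f"{path}, row {idx}: {exc}") from None
        analyzer = str(analyzer)
        if not registry.has_analyzer(analyzer):
            raise UnknownAnalyzerError(f"{path}, row {idx}: unknown analyzer {analyzer!r}")
        try:
            allergen = registry.canonicalize(str(raw_allergen))
        except UnknownAllergenError:
            if on_unknown_allergen == "drop":
                warnings.warn(
                    f"{path}, row {idx}: dropping unknown allergen {raw_allergen!r}",
                    stacklevel=2,
                )
                continue
            raise UnknownAllergenError(
                f"{path}, row {idx}: unknown allergen {raw_allergen!r}"
            ) from None
        records.append(
            ResultRecord(
                patient_id=str(patient_id),
                analyzer_id=analyzer,
                panel=Panel(str(panel)),
                allergen=allergen,
                class_level=level,
            )
        )
    return Dataset.build(records, registry=registry, provenance=str(path))


def write_results(dataset: Dataset, path: os.PathLike | str) -> None:
    """Write *dataset* in long format; read_results round-trips it."""
    frame = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "analyzer": r.analyzer_id,
                "panel": r.panel.value,
                "allergen": r.allergen,
                "class": r.class_level,
            }
            for r in dataset
        ],
        columns=list(RESULT_COLUMNS),
    )
    frame.to_csv(path, sep=_sep_for(path), index=False)


def load_registry(path: os.PathLike | str) -> PanelRegistry:
    """Load a :class:`PanelRegistry` from a YAML config.

    Expected layout::

        analyzers:
          smart2:
            food: [cat, milk, ...]
            inhalant: [cat, house dust, ...]
        aliases:
          "d. farinae": dermatophagoides farinae
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if "analyzers" not in doc:
        raise ValueError(f"{path}: registry config must contain an 'analyzers' mapping")
    return PanelRegistry(doc["analyzers"], aliases=doc.get("aliases"))


def dump_registry(registry: PanelRegistry, path: os.PathLike | str) -> None:
    """Write *registry* back out as a YAML config."""
    doc = {
        "analyzers": {
            analyzer: {
                panel.value: sorted(registry.allergens(analyzer, panel))
                for panel in Panel
                if registry.allergens(analyzer, panel)
            }
            for analyzer in registry.analyzers
        },
        "aliases": dict(getattr(registry, "_aliases")),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True, allow_unicode=True)
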