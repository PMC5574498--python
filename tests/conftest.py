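from __future__ import annotations

import pytest

from mastagree import (
    Dataset,
    Panel,
    PanelRegistry,
    ResultRecord,
    default_registry,
)


@pytest.fixture(scope="session")
def registry() -> PanelRegistry:
    return default_registry()


@pytest.fixture()
def tiny_registry() -> PanelRegistry:
    return PanelRegistry(
        {
            "A": {Panel.FOOD: ["cat", "milk", "dermatophagoides farinae"]},
            "B": {Panel.FOOD: ["cat", "milk", "dermatophagoides farinae"]},
        },
        aliases={"d. farinae": "dermatophagoides farinae"},
    )


def make_dataset(rows, registry=None) -> Dataset:
    """rows: iterable of (patient, analyzer, panel, allergen, class)."""
    return Dataset.build(
        [ResultRecord(p, a, Panel(pan), alg, c) for p, a, pan, alg, c in rows],
        registry=registry,
    )


@pytest.fixture()
def paired_dataset(tiny_registry) -> Dataset:
    rows = [
        ("P1", "A", "food", "cat", 3),
        ("P1", "B", "food", "cat", 3),
        ("P2", "A", "food", "cat", 0),
        ("P2", "B", "food", "cat", 0),
        ("P3", "A", "food", "cat", 2),
        ("P3", "B", "food", "cat", 0),
        ("P1", "A", "food", "milk", 4),  # one-sided: no B reading
    ]
    return make_dataset(rows, tiny_registry)
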