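"""Synthetic paired class-level data with controlled agreement structure.

The generator is parameterized directly by the quantities the analysis
pipeline estimates: per-allergen positivity prevalence on analyzer A, a
target Cohen's kappa, and a signed prevalence difference (which maps to the
directional propensity statistic).  The 2x2 joint cell probabilities are
obtained by inverting the kappa definition analytically, so parameter
recovery can be tested exactly.

Class magnitudes are drawn relative to a single generative cutoff ``t``:
negatives uniform on ``{0, ..., t-1}``, positives from a truncated
geometric on ``{t, ..., 6}``.  Sweeping other cutoffs over synthetic data
therefore exercises monotonicity properties, not calibrated agreement
values.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .agreement import CUTOFF_MAX, validate_cutoff
from .model import CLASS_MAX, Dataset, MastError, Panel, ResultRecord, normalize_name

DEFAULT_GENERATIVE_CUTOFF = 2


class InfeasibleSpecError(MastError, ValueError):
    """Requested (prevalence, kappa, delta) imply a cell outside [0, 1]."""


@dataclass(frozen=True)
class AllergenSimSpec:
    """Generative parameters for one allergen.

    ``prevalence_a`` is P(positive on analyzer A) at the generative cutoff;
    ``propensity_delta`` is ``prevalence_a - prevalence_b``;
    ``kappa_target`` the desired chance-corrected agreement;
    ``class_shape`` the success parameter of the truncated geometric over
    positive classes (larger -> positives concentrate at the cutoff class).
    """

    allergen: str
    prevalence_a: float
    kappa_target: float
    propensity_delta: float = 0.0
    class_shape: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "allergen", normalize_name(self.allergen))
        if not 0.0 <= self.prevalence_a <= 1.0:
            raise InfeasibleSpecError(f"prevalence_a {self.prevalence_a} outside [0, 1]")
        if not -1.0 < self.kappa_target <= 1.0:
            raise InfeasibleSpecError(f"kappa_target {self.kappa_target} outside (-1, 1]")
        if not 0.0 < self.class_shape <= 1.0:
            raise InfeasibleSpecError(f"class_shape {self.class_shape} outside (0, 1]")

    @property
    def prevalence_b(self) -> float:
        return self.prevalence_a - self.propensity_delta


def generate_joint(spec: AllergenSimSpec) -> tuple[float, float, float, float]:
    """Invert the kappa definition into 2x2 cell probabilities.

    Returns ``(p_pp, p_pn, p_np, p_nn)``.  With marginals pA, pB the chance
    agreement is ``p_e = pA pB + (1-pA)(1-pB)``; the observed agreement
    implied by the kappa target is ``p_o = kappa (1 - p_e) + p_e``, and the
    both-positive cell is ``p_pp = (p_o + pA + pB - 1) / 2``.  Raises
    :class:`InfeasibleSpecError` naming the violated cell if any cell falls
    outside [0, 1].
    """
    pa = spec.prevalence_a
    pb = spec.prevalence_b
    if not 0.0 <= pb <= 1.0:
        raise InfeasibleSpecError(
            f"{spec.allergen}: implied prevalence_b {pb:.4f} outside [0, 1]"
        )
    p_e = pa * pb + (1.0 - pa) * (1.0 - pb)
    p_o = spec.kappa_target * (1.0 - p_e) + p_e
    p_pp = (p_o + pa + pb - 1.0) / 2.0
    p_pn = pa - p_pp
    p_np = pb - p_pp
    p_nn = 1.0 - pa - pb + p_pp
    cells = {"p_pp": p_pp, "p_pn": p_pn, "p_np": p_np, "p_nn": p_nn}
    eps = 1e-12
    for name, value in cells.items():
        if value < -eps or value > 1.0 + eps:
            raise InfeasibleSpecError(
                f"{spec.allergen}: cell {name} = {value:.6f} outside [0, 1] for "
                f"prevalence_a={pa}, kappa_target={spec.kappa_target}, "
                f"propensity_delta={spec.propensity_delta}"
            )
        cells[name] = min(max(value, 0.0), 1.0)
    return cells["p_pp"], cells["p_pn"], cells["p_np"], cells["p_nn"]


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one synthetic paired dataset."""

    n_patients: int
    panel: Panel
    analyzer_a: str
    analyzer_b: str
    allergens: tuple[AllergenSimSpec, ...]
    cutoff: int = DEFAULT_GENERATIVE_CUTOFF
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        object.__setattr__(self, "panel", Panel(self.panel))
        object.__setattr__(self, "allergens", tuple(self.allergens))
        validate_cutoff(self.cutoff)
        if not self.allergens:
            raise ValueError("at least one allergen spec is required")
        names = [a.allergen for a in self.allergens]
        if len(set(names)) != len(names):
            raise ValueError("allergen names must be unique")


def _allergen_stream(seed: int, allergen: str) -> np.random.Generator:
    # Substream keyed on (seed, allergen name) so adding an allergen to a
    # config does not perturb the draws of the others.
    digest = hashlib.sha256(allergen.encode("utf-8")).digest()
    key = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def _truncated_geometric_probs(shape: float, size: int) -> np.ndarray:
    probs = shape * (1.0 - shape) ** np.arange(size)
    if probs.sum() == 0.0:  # shape == 1 edge handled by construction
        probs = np.ones(size)
    return probs / probs.sum()


def simulate(config: SimConfig) -> Dataset:
    """Draw a paired dataset; identical config (incl. seed) => identical output.

    For every patient and allergen a joint positivity cell is drawn from
    :func:`generate_joint`; class levels then respect the generative cutoff
    exactly (negatives < cutoff <= positives).
    """
    t = config.cutoff
    n = config.n_patients
    width = max(4, len(str(n)))
    patient_ids = [f"P{i:0{width}d}" for i in range(1, n + 1)]
    records: list[ResultRecord] = []
    n_pos_classes = CLASS_MAX - t + 1
    for spec in config.allergens:
        probs = generate_joint(spec)
        rng = _allergen_stream(config.seed, spec.allergen)
        cells = rng.choice(4, size=n, p=probs)
        a_positive = (cells == 0) | (cells == 1)
        b_positive = (cells == 0) | (cells == 2)
        tail = _truncated_geometric_probs(spec.class_shape, n_pos_classes)
        neg_a = rng.integers(0, t, size=n)
        pos_a = t + rng.choice(n_pos_classes, size=n, p=tail)
        neg_b = rng.integers(0, t, size=n)
        pos_b = t + rng.choice(n_pos_classes, size=n, p=tail)
        class_a = np.where(a_positive, pos_a, neg_a)
        class_b = np.where(b_positive, pos_b, neg_b)
        for pid, ca, cb in zip(patient_ids, class_a, class_b):
            records.append(
                ResultRecord(pid, config.analyzer_a, config.panel, spec.allergen, int(ca))
            )
            records.append(
                ResultRecord(pid, config.analyzer_b, config.panel, spec.allergen, int(cb))
            )
    return Dataset.build(
        records,
        provenance=f"simulated(seed={config.seed}, n={n}, panel={config.panel.value})",
    )


def load_sim_config(path: os.PathLike | str, seed: int | None = None) -> SimConfig:
    """Load a :class:`SimConfig` from YAML; *seed* overrides the file's seed."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    allergens = tuple(
        AllergenSimSpec(
            allergen=entry["allergen"],
            prevalence_a=float(entry["prevalence_a"]),
            kappa_target=float(entry["kappa_target"]),
            propensity_delta=float(entry.get("propensity_delta", 0.0)),
            class_shape=float(entry.get("class_shape", 0.5)),
        )
        for entry in doc["allergens"]
    )
    return SimConfig(
        n_patients=int(doc["n_patients"]),
        panel=Panel(doc["panel"]),
        analyzer_a=str(doc["analyzer_a"]),
        analyzer_b=str(doc["analyzer_b"]),
        allergens=allergens,
        cutoff=int(doc.get("cutoff", DEFAULT_GENERATIVE_CUTOFF)),
        seed=int(doc["seed"] if seed is None else seed),
    )


# --- deterministic reference fixtures -------------------------------------
#
# Small worked-example datasets whose 2x2 table at cutoff 2 has exactly the
# stated cell counts.  Used by tests and the acceptance report.

_FIXTURE_TABLES: dict[str, dict] = {
    # (n_pp, n_pn, n_np, n_nn) at cutoff 2
    "dfarinae_food": dict(
        analyzer_a="alloscreen", analyzer_b="smart2", panel=Panel.FOOD,
        allergen="dermatophagoides farinae", table=(21, 1, 1, 20),
    ),
    "dpteronyssinus_food": dict(
        analyzer_a="alloscreen", analyzer_b="smart2", panel=Panel.FOOD,
        allergen="dermatophagoides pteronyssinus", table=(22, 0, 0, 21),
    ),
    "barleymeal_food": dict(
        analyzer_a="alloscreen", analyzer_b="smart2", panel=Panel.FOOD,
        allergen="barley meal", table=(1, 1, 0, 41),
    ),
    "cladosporium_food": dict(
        analyzer_a="alloscreen", analyzer_b="smart2", panel=Panel.FOOD,
        allergen="cladosporium herbarum", table=(0, 1, 0, 42),
    ),
    "dog_inhalant": dict(
        analyzer_a="alloscreen", analyzer_b="smart2", panel=Panel.INHALANT,
        allergen="dog", table=(0, 1, 1, 88),
    ),
    "housedust_food_smart_vs_rida": dict(
        analyzer_a="smart2", analyzer_b="rida", panel=Panel.FOOD,
        allergen="house dust", table=(0, 8, 0, 22),
    ),
    "housedust_inhalant_smart_vs_rida": dict(
        analyzer_a="smart2", analyzer_b="rida", panel=Panel.INHALANT,
        allergen="house dust", table=(0, 24, 0, 55),
    ),
    "dfarinae_inhalant_protia_vs_rida": dict(
        analyzer_a="protia", analyzer_b="rida", panel=Panel.INHALANT,
        allergen="dermatophagoides farinae", table=(11, 16, 0, 66),
    ),
}

# Single-analyzer positivity fixtures: (analyzer, panel, allergen,
# n_patients, count at class >= 1, count at class >= 2).
_POSITIVITY_FIXTURES: dict[str, dict] = {
    "acarussiro_inhalant_positivity": dict(
        analyzer="smart2", panel=Panel.INHALANT, allergen="acarus siro",
        n_patients=90, n_class1=18, n_class2plus=11,
    ),
    "apple_inhalant_positivity": dict(
        analyzer="smart2", panel=Panel.INHALANT, allergen="apple",
        n_patients=90, n_class1=8, n_class2plus=4,
    ),
}


def fixture_names() -> tuple[str, ...]:
    return tuple(sorted((*_FIXTURE_TABLES, *_POSITIVITY_FIXTURES)))


def reference_fixture(name: str) -> Dataset:
    """Return a small deterministic dataset for a named worked example.

    Paired fixtures reproduce an exact 2x2 table at cutoff 2 (concordant
    positives as (3, 3), one-sided positives as (3, 0)/(0, 3), concordant
    negatives as (0, 0)).  Positivity fixtures yield exact positive counts
    at cutoffs 1 and 2 for a single analyzer.
    """
    if name in _FIXTURE_TABLES:
        info = _FIXTURE_TABLES[name]
        n_pp, n_pn, n_np, n_nn = info["table"]
        classes = (
            [(3, 3)] * n_pp + [(3, 0)] * n_pn + [(0, 3)] * n_np + [(0, 0)] * n_nn
        )
        records = []
        for i, (ca, cb) in enumerate(classes, start=1):
            pid = f"P{i:03d}"
            records.append(
                ResultRecord(pid, info["analyzer_a"], info["panel"], info["allergen"], ca)
            )
            records.append(
                ResultRecord(pid, info["analyzer_b"], info["panel"], info["allergen"], cb)
            )
        return Dataset.build(records, provenance=f"fixture:{name}")
    if name in _POSITIVITY_FIXTURES:
        info = _POSITIVITY_FIXTURES[name]
        n1, n2 = info["n_class1"], info["n_class2plus"]
        if not 0 <= n2 <= n1 <= info["n_patients"]:
            raise ValueError(f"fixture {name!r} has inconsistent counts")
        levels = [2] * n2 + [1] * (n1 - n2) + [0] * (info["n_patients"] - n1)
        records = [
            ResultRecord(f"P{i:03d}", info["analyzer"], info["panel"], info["allergen"], lvl)
            for i, lvl in enumerate(levels, start=1)
        ]
        return Dataset.build(records, provenance=f"fixture:{name}")
    raise KeyError(f"unknown fixture {name!r}; known: {', '.join(fixture_names())}")
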