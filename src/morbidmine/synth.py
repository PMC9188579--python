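"""Synthetic EHR-style data with planted multimorbidity structure.

The generator emits the same demographics/diagnosis CSV dialect the cohort
builder reads, with fully known ground truth:

* per-stratum patient counts (6 races with unequal, Caucasian-dominant
  sizes; 2 age bands; 2 obesity classes),
* sparse background diagnosis prevalences per eligible category,
* *planted clusters*: sets of 2-4 categories switched on jointly with
  probability ``q`` per patient in designated strata, so the expected
  joint prevalence has the closed form q' = q + (1-q) * prod(p_i)
  (items independent given the cluster is off),
* deliberately invalid patients, each violating exactly one inclusion
  criterion, so the exclusion cascade is checkable to the exact count,
* BMI values drawn per obesity class from truncated normals whose
  locations mirror typical without-obesity (~25) and with-obesity (~34)
  medians.

A :class:`GroundTruthLedger` records everything planted;
:func:`ledger_check` replays it against pipeline output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from datetime import date, timedelta
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    AGE_BANDS,
    DEFAULT_WINDOW,
    ELDERLY,
    FINAL_RACES,
    MIDDLE_AGED,
    OBESITY_CLASSES,
    WITH_OBESITY,
    WITHOUT_OBESITY,
    StratumKey,
)
from .compare import DISTINCT, SHARED_ALL, SHARED_SOME

__all__ = [
    "PlantedCluster",
    "SynthConfig",
    "GroundTruthLedger",
    "LedgerReport",
    "default_config",
    "small_config",
    "generate",
    "ledger_check",
]


@dataclass(frozen=True)
class PlantedCluster:
    """A multi-disease cluster planted in selected strata.

    When active (probability ``q`` per patient), every item in ``items``
    is added to the patient's chart.  Items also fire independently at
    their background rates, so the expected joint prevalence in a target
    stratum is ``q + (1 - q) * prod(background_i)``.
    """

    items: tuple[str, ...]
    q: float
    races: tuple[str, ...]
    design_class: str
    age_bands: tuple[str, ...] = AGE_BANDS
    obesity_classes: tuple[str, ...] = OBESITY_CLASSES

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0 and self.q != 1.0:
            raise ValueError("q must be in (0, 1]")
        if not 2 <= len(self.items) <= 4:
            raise ValueError("clusters hold 2-4 items")
        if self.design_class not in (SHARED_ALL, SHARED_SOME, DISTINCT):
            raise ValueError(f"unknown design_class {self.design_class!r}")

    def strata(self) -> list[StratumKey]:
        return [
            StratumKey(r, a, o)
            for r, a, o in product(self.races, self.age_bands, self.obesity_classes)
        ]

    def expected_prevalence(self, background: Mapping[str, float]) -> float:
        """Closed-form joint prevalence q' in a target stratum."""
        indep = math.prod(background.get(i, 0.0) for i in self.items)
        return self.q + (1.0 - self.q) * indep


def _default_clusters() -> tuple[PlantedCluster, ...]:
    return (
        PlantedCluster(("E78", "I10"), 0.30, FINAL_RACES, SHARED_ALL),
        PlantedCluster(("E11", "E78", "I10"), 0.12, FINAL_RACES, SHARED_ALL),
        PlantedCluster(
            ("F17", "I10"), 0.20, ("African American", "Native American"), SHARED_SOME
        ),
        PlantedCluster(
            ("K21", "M54"),
            0.15,
            ("African American", "Asian/Pacific Islander", "Biracial", "Native American"),
            SHARED_SOME,
        ),
        PlantedCluster(("D64", "N18"), 0.15, ("African American",), DISTINCT),
        PlantedCluster(("F32", "F41"), 0.15, ("Caucasian",), DISTINCT),
    )


def _default_background() -> dict[str, float]:
    # Sparse chronic-condition background; pairwise joint rates are far
    # below the 5% mining threshold, so noise alone yields no patterns.
    return {
        "E03": 0.010,
        "E11": 0.020,
        "E78": 0.020,
        "E87": 0.005,
        "D64": 0.005,
        "F17": 0.010,
        "F32": 0.010,
        "F41": 0.010,
        "G47": 0.010,
        "I10": 0.030,
        "I25": 0.010,
        "I50": 0.005,
        "J44": 0.005,
        "K21": 0.010,
        "M25": 0.010,
        "M54": 0.010,
        "N18": 0.005,
    }


@dataclass(frozen=True)
class SynthConfig:
    """Everything the generator needs; defaults define the study conditions."""

    #: Patients per race in EACH (age band, obesity class) cell.
    cell_sizes: Mapping[str, int] = field(
        default_factory=lambda: {
            "Caucasian": 6000,
            "African American": 2400,
            "Asian/Pacific Islander": 1400,
            "Hispanic": 1100,
            "Native American": 1000,
            "Biracial": 800,
        }
    )
    background: Mapping[str, float] = field(default_factory=_default_background)
    #: Ineligible codes emitted as chart noise (never enter transactions).
    noise_items: Mapping[str, float] = field(
        default_factory=lambda: {"Z51": 0.08, "R06": 0.05}
    )
    clusters: tuple[PlantedCluster, ...] = field(default_factory=_default_clusters)
    #: (location, scale) of the BMI normal per obesity class, truncated so
    #: the class constraint (mean >= 30 vs < 30) holds by construction.
    bmi_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {WITH_OBESITY: (34.0, 3.0), WITHOUT_OBESITY: (25.5, 2.2)}
    )
    bmi_measurements: tuple[int, int] = (1, 3)  # uniform count range
    mean_encounters: float = 7.0  # shifted Poisson: 1 + Poisson(mean - 1)
    #: Fraction (of the valid-patient total) of extra invalid patients per reason.
    invalid_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "age": 0.01,
            "bmi": 0.01,
            "race": 0.01,
            "no_icd10": 0.01,
            "icd9": 0.01,
        }
    )
    window: tuple[date, date] = DEFAULT_WINDOW
    dot_probability: float = 0.5  # chance a code is emitted as a dotted sub-code
    seed: int = 20160101

    def __post_init__(self) -> None:
        probs = list(self.background.values()) + [c.q for c in self.clusters]
        probs += list(self.noise_items.values()) + list(self.invalid_fractions.values())
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if any(n < 1 for n in self.cell_sizes.values()):
            raise ValueError("stratum sizes must be >= 1")


def default_config(seed: int = 20160101) -> SynthConfig:
    return SynthConfig(seed=seed)


def small_config(seed: int = 20160101, scale: float = 0.1) -> SynthConfig:
    """The default conditions at reduced per-stratum size (quick runs/tests)."""
    cfg = default_config(seed)
    sizes = {r: max(50, int(n * scale)) for r, n in cfg.cell_sizes.items()}
    return replace(cfg, cell_sizes=sizes)


@dataclass
class GroundTruthLedger:
    """Exactly what was planted, for replay against pipeline output."""

    seed: int
    n_valid: int
    stratum_sizes: dict[str, int]  # "race|age_band|obesity_class" -> n
    exclusions: dict[str, int]  # reason -> planted count
    clusters: list[dict]  # items, q, design_class, strata, expected_prevalence
    min_support_hint: float = 0.05

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruthLedger":
        with open(path) as fh:
            return cls(**json.load(fh))


def _stratum_id(key: StratumKey) -> str:
    return f"{key.race}|{key.age_band}|{key.obesity_class}"


def _draw_bmi(
    rng: np.random.Generator, obesity_class: str, n: int, cfg: SynthConfig
) -> np.ndarray:
    """Truncated-normal draws inside the class's valid band."""
    loc, scale = cfg.bmi_params[obesity_class]
    lo, hi = (30.0, 206.0) if obesity_class == WITH_OBESITY else (18.5, 29.9)
    out = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        draw = rng.normal(loc, scale, todo.size)
        ok = (draw >= lo) & (draw <= hi)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return np.round(out, 1)


def _emit_code(rng: np.random.Generator, category: str, dot_p: float) -> str:
    """Raw chart string for a category: sometimes a dotted sub-code."""
    if rng.random() < dot_p:
        return f"{category}.{rng.integers(0, 10)}"
    return category


def generate(
    config: SynthConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruthLedger]:
    """Generate (demographics, diagnoses, ground-truth ledger).

    Deterministic for a fixed config (including its seed).  Demographics
    are long-format (one row per BMI measurement); diagnoses are one row
    per patient-encounter-code.
    """
    cfg = config or default_config()
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.window
    n_days = (hi - lo).days + 1

    bg_items = sorted(cfg.background)
    bg_p = np.array([cfg.background[i] for i in bg_items])
    noise_codes = sorted(cfg.noise_items)
    noise_p = np.array([cfg.noise_items[i] for i in noise_codes])

    demo_rows: list[tuple] = []
    dx_rows: list[tuple] = []
    stratum_sizes: dict[str, int] = {}
    pid_counter = 0

    def next_pid() -> str:
        nonlocal pid_counter
        pid_counter += 1
        return f"P{pid_counter:07d}"

    def add_patient_rows(
        pid: str,
        race_label: str,
        age: int,
        bmis: Sequence[float],
        categories: Sequence[str],
        *,
        icd9_extra: bool = False,
        out_of_window: bool = False,
    ) -> None:
        for b in bmis:
            demo_rows.append((pid, race_label, age, b))
        n_enc = 1 + rng.poisson(max(cfg.mean_encounters - 1.0, 0.0))
        enc_days = rng.integers(0, n_days, n_enc)
        if out_of_window:
            enc_dates = [lo - timedelta(days=int(d) + 1) for d in enc_days]
        else:
            enc_dates = [lo + timedelta(days=int(d)) for d in enc_days]
        which = rng.integers(0, n_enc, len(categories))
        for cat, e in zip(categories, which):
            dx_rows.append(
                (
                    pid,
                    f"{pid}-e{e + 1}",
                    enc_dates[e].isoformat(),
                    _emit_code(rng, cat, cfg.dot_probability),
                    "ICD10",
                )
            )
        if icd9_extra:
            e = int(rng.integers(0, n_enc))
            dx_rows.append(
                (pid, f"{pid}-e{e + 1}", enc_dates[e].isoformat(), "250.00", "ICD9")
            )

    # ----- valid patients, stratum by stratum (deterministic order) -----
    races = sorted(cfg.cell_sizes)
    for age_band, obesity, race in product(AGE_BANDS, OBESITY_CLASSES, races):
        n = int(cfg.cell_sizes[race])
        key = StratumKey(race, age_band, obesity)
        stratum_sizes[_stratum_id(key)] = n

        if age_band == MIDDLE_AGED:
            ages = rng.integers(45, 65, n)
        else:
            ages = rng.integers(65, 91, n)

        item_matrix = rng.random((n, len(bg_items))) < bg_p
        for cluster in cfg.clusters:
            if key in cluster.strata():
                active = rng.random(n) < cluster.q
                for item in cluster.items:
                    item_matrix[active, bg_items.index(item)] = True
        noise_matrix = rng.random((n, len(noise_codes))) < noise_p

        n_bmi = rng.integers(
            cfg.bmi_measurements[0], cfg.bmi_measurements[1] + 1, n
        )
        for i in range(n):
            pid = next_pid()
            bmis = _draw_bmi(rng, obesity, int(n_bmi[i]), cfg)
            cats = [bg_items[j] for j in np.flatnonzero(item_matrix[i])]
            cats += [noise_codes[j] for j in np.flatnonzero(noise_matrix[i])]
            if not cats:
                # Criterion 4 asks for >= 1 diagnosis code, eligible or not.
                cats = [noise_codes[0]] if noise_codes else ["Z51"]
            add_patient_rows(pid, race, int(ages[i]), bmis, cats)

    n_valid = pid_counter

    # ----- invalid patients: one violated criterion each -----
    exclusions: dict[str, int] = {}
    bad_race_labels = ["", "Other", "Mid-Eastern Indian"]
    for reason in sorted(cfg.invalid_fractions):
        count = int(round(cfg.invalid_fractions[reason] * n_valid))
        exclusions[reason] = count
        for i in range(count):
            pid = next_pid()
            age = int(rng.integers(45, 91))
            race = FINAL_RACES[int(rng.integers(0, len(FINAL_RACES)))]
            obesity = WITH_OBESITY if rng.random() < 0.5 else WITHOUT_OBESITY
            bmis = _draw_bmi(rng, obesity, 1, cfg)
            cats = [bg_items[int(rng.integers(0, len(bg_items)))]]
            if reason == "age":
                add_patient_rows(pid, race, int(rng.integers(18, 45)), bmis, cats)
            elif reason == "bmi":
                bad = np.round(rng.uniform(207.0, 240.0, 1), 1)
                add_patient_rows(pid, race, age, bad, cats)
            elif reason == "race":
                label = bad_race_labels[i % len(bad_race_labels)]
                add_patient_rows(pid, label, age, bmis, cats)
            elif reason == "no_icd10":
                add_patient_rows(pid, race, age, bmis, cats, out_of_window=True)
            elif reason == "icd9":
                add_patient_rows(pid, race, age, bmis, cats, icd9_extra=True)
            else:  # pragma: no cover - config validation catches this
                raise ValueError(f"unknown invalid-record reason {reason!r}")

    demographics = pd.DataFrame(
        demo_rows, columns=["patient_id", "race", "age", "bmi"]
    )
    diagnoses = pd.DataFrame(
        dx_rows, columns=["patient_id", "encounter_id", "date", "code", "code_system"]
    )

    ledger = GroundTruthLedger(
        seed=cfg.seed,
        n_valid=n_valid,
        stratum_sizes=stratum_sizes,
        exclusions=exclusions,
        clusters=[
            {
                "items": list(c.items),
                "q": c.q,
                "design_class": c.design_class,
                "strata": [_stratum_id(k) for k in c.strata()],
                "expected_prevalence": c.expected_prevalence(cfg.background),
            }
            for c in cfg.clusters
        ],
    )
    return demographics, diagnoses, ledger


# ---------------------------------------------------------------------------
# Ledger replay
# ---------------------------------------------------------------------------

@dataclass
class LedgerReport:
    ok: bool
    failures: list[str]
    n_checks: int


def ledger_check(
    ledger: GroundTruthLedger,
    *,
    exclusion_counts: Mapping[str, int],
    patterns_by_stratum: Mapping[StratumKey, Sequence],
    comparisons_by_cell: Mapping[tuple[str, str], Sequence],
    min_support: float = 0.05,
) -> LedgerReport:
    """Replay the ground truth against pipeline output.

    Checks (a) per-reason exclusion counts match the planting exactly,
    (b) every planted cluster whose expected prevalence clears the support
    threshold with a 3-standard-error margin was mined in each target
    stratum, and (c) the designed sharing class is reproduced by the
    cross-race classification in every covered cell.
    """
    failures: list[str] = []
    n_checks = 0

    for reason, planted in sorted(ledger.exclusions.items()):
        n_checks += 1
        got = int(exclusion_counts.get(reason, 0))
        if got != planted:
            failures.append(f"exclusions[{reason}]: planted {planted}, pipeline {got}")

    mined_sets = {
        key: {tuple(p.items) for p in pats}
        for key, pats in patterns_by_stratum.items()
    }
    for cl in ledger.clusters:
        items = tuple(sorted(cl["items"]))
        qp = float(cl["expected_prevalence"])
        for sid in cl["strata"]:
            race, band, obesity = sid.split("|")
            key = StratumKey(race, band, obesity)
            n = ledger.stratum_sizes.get(sid, 0)
            if n == 0:
                continue
            se = math.sqrt(qp * (1.0 - qp) / n)
            if qp < min_support + 3.0 * se:
                continue  # ambiguous planting: recovery not guaranteed
            n_checks += 1
            if items not in mined_sets.get(key, set()):
                failures.append(f"cluster {items} not mined in stratum {sid}")

        cells = {
            (band, obesity)
            for sid in cl["strata"]
            for _, band, obesity in [sid.split("|")]
        }
        for cell in sorted(cells):
            comps = comparisons_by_cell.get(cell, [])
            match = next((c for c in comps if tuple(c.items) == items), None)
            n_checks += 1
            if match is None:
                failures.append(f"cluster {items} absent from classification in {cell}")
            elif match.class_label != cl["design_class"]:
                failures.append(
                    f"cluster {items} in {cell}: designed {cl['design_class']}, "
                    f"classified {match.class_label}"
                )
    return LedgerReport(ok=not failures, failures=failures, n_checks=n_checks)
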