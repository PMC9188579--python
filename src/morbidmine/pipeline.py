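"""End-to-end pipeline: cohort -> per-stratum mining -> cross-race
classification -> prevalence statistics, with deterministic CSV outputs.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .cohort import (
    DEFAULT_WINDOW,
    FINAL_RACES,
    StratumKey,
    TransactionSet,
    build_cohort,
    build_transactions,
    cohort_summary,
    exclusion_counts,
)
from .compare import PatternComparison, classify_patterns, count_summary
from .icd import ChapterFilter, default_filter
from .mining import FrequentPattern, MinerConfig, mine_frequent_itemsets
from .stats import (
    DegenerateTableError,
    g_test,
    kruskal_wallis,
    median_bmi_summary,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "load_tables"]


@dataclass(frozen=True)
class RunConfig:
    """Effective configuration of one analysis run (fully serializable)."""

    window: tuple[date, date] = DEFAULT_WINDOW
    min_support: float = 0.05
    min_pattern_size: int = 2
    chapter_filter: ChapterFilter = field(default_factory=default_filter)
    race_list: tuple[str, ...] = FINAL_RACES
    ci_level: float = 0.95
    williams: bool = False
    drop_empty_transactions: bool = False
    display_min_prevalence: float | None = None

    def to_dict(self) -> dict:
        return {
            "window": [self.window[0].isoformat(), self.window[1].isoformat()],
            "min_support": self.min_support,
            "min_pattern_size": self.min_pattern_size,
            "chapter_filter": self.chapter_filter.to_strings(),
            "race_list": list(self.race_list),
            "ci_level": self.ci_level,
            "williams": self.williams,
            "drop_empty_transactions": self.drop_empty_transactions,
            "display_min_prevalence": self.display_min_prevalence,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        kwargs: dict = {}
        if "window" in data:
            lo, hi = data["window"]
            kwargs["window"] = (date.fromisoformat(str(lo)), date.fromisoformat(str(hi)))
        if "chapter_filter" in data:
            cf = data["chapter_filter"]
            kwargs["chapter_filter"] = ChapterFilter.from_strings(
                cf.get("include", []), cf.get("exclude", [])
            )
        for key in (
            "min_support",
            "min_pattern_size",
            "ci_level",
            "williams",
            "drop_empty_transactions",
            "display_min_prevalence",
        ):
            if key in data:
                kwargs[key] = data[key]
        if "race_list" in data:
            kwargs["race_list"] = tuple(data["race_list"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_tables(demographics_path, diagnoses_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the two input CSVs (comment lines allowed)."""
    demo = pd.read_csv(demographics_path, comment="#", dtype={"patient_id": str})
    demo["race"] = demo["race"].fillna("")
    dx = pd.read_csv(
        diagnoses_path,
        comment="#",
        dtype={"patient_id": str, "encounter_id": str, "code": str, "code_system": str},
    )
    return demo, dx


@dataclass
class PipelineResult:
    """All outputs of one run, with frame/CSV accessors."""

    config: RunConfig
    cohort: pd.DataFrame
    exclusion_counts: dict[str, int]
    transaction_sets: dict[StratumKey, TransactionSet]
    patterns_by_stratum: dict[StratumKey, list[FrequentPattern]]
    comparisons_by_cell: dict[tuple[str, str], list[PatternComparison]]

    # ---- tabular views -------------------------------------------------

    def patterns_frame(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self.patterns_by_stratum):
            for p in self.patterns_by_stratum[key]:
                rows.append(
                    {
                        "race": key.race,
                        "age_band": key.age_band,
                        "obesity_class": key.obesity_class,
                        "items": ";".join(p.items),
                        "size": p.size,
                        "support_count": p.support_count,
                        "n_patients": p.n_patients,
                        "prevalence": round(p.prevalence, 6),
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "race",
                "age_band",
                "obesity_class",
                "items",
                "size",
                "support_count",
                "n_patients",
                "prevalence",
            ],
        )

    def classification_frame(self) -> pd.DataFrame:
        rows = []
        for cell in sorted(self.comparisons_by_cell):
            for c in self.comparisons_by_cell[cell]:
                row = {
                    "age_band": cell[0],
                    "obesity_class": cell[1],
                    "items": ";".join(c.items),
                    "class_label": c.class_label,
                    "races_frequent": ";".join(sorted(c.races_frequent)),
                }
                for race in self.config.race_list:
                    s = c.per_race[race]
                    tag = race.replace("/", "_").replace(" ", "_")
                    row[f"prev[{tag}]"] = round(s.prevalence, 6)
                    row[f"ci_lo[{tag}]"] = round(s.ci.lower, 6)
                    row[f"ci_hi[{tag}]"] = round(s.ci.upper, 6)
                    row[f"frequent[{tag}]"] = s.frequent
                rows.append(row)
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for cell in sorted(self.comparisons_by_cell):
            for s in count_summary(self.comparisons_by_cell[cell], self.config.race_list):
                rows.append(
                    {
                        "age_band": cell[0],
                        "obesity_class": cell[1],
                        "race": s.race,
                        "overall": s.overall_count,
                        "distinct": s.distinct_count,
                    }
                )
        return pd.DataFrame(
            rows, columns=["age_band", "obesity_class", "race", "overall", "distinct"]
        )

    def stats_frame(self) -> pd.DataFrame:
        """Per-pattern g-tests plus per-cell Kruskal-Wallis on mean BMI."""
        rows = []
        for cell in sorted(self.comparisons_by_cell):
            for c in self.comparisons_by_cell[cell]:
                table = [
                    [
                        c.per_race[r].support_count,
                        c.per_race[r].n_patients - c.per_race[r].support_count,
                    ]
                    for r in self.config.race_list
                    if c.per_race[r].n_patients > 0
                ]
                try:
                    res = g_test(table, williams=self.config.williams)
                    stat, df, p = res.statistic, res.df, res.p_value
                except (DegenerateTableError, ValueError):
                    stat, df, p = float("nan"), 0, float("nan")
                rows.append(
                    {
                        "age_band": cell[0],
                        "obesity_class": cell[1],
                        "test": "g_test",
                        "items": ";".join(c.items),
                        "statistic": round(stat, 6),
                        "df": df,
                        "p_value": p,
                    }
                )
        inc = self.cohort[self.cohort["included"]]
        for (band, obesity), grp in inc.groupby(["age_band", "obesity_class"], sort=True):
            groups = [
                g["mean_bmi"].to_numpy()
                for _, g in grp.groupby("race", sort=True)
                if len(g)
            ]
            if len(groups) >= 2:
                try:
                    res = kruskal_wallis(groups)
                    rows.append(
                        {
                            "age_band": band,
                            "obesity_class": obesity,
                            "test": "kruskal_wallis_bmi",
                            "items": "",
                            "statistic": round(res.statistic, 6),
                            "df": res.df,
                            "p_value": res.p_value,
                        }
                    )
                except ValueError:
                    pass
        return pd.DataFrame(
            rows,
            columns=["age_band", "obesity_class", "test", "items", "statistic", "df", "p_value"],
        )

    def exclusions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.exclusion_counts.items()), columns=["reason", "n_patients"]
        )

    # ---- persistence ---------------------------------------------------

    def write(self, outdir) -> dict[str, str]:
        """Write all output tables; every file carries the config hash.

        Returns the manifest mapping file name -> sha256 of contents.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        chash = self.config.config_hash()
        frames = {
            "cohort.csv": cohort_summary(self.cohort),
            "exclusions.csv": self.exclusions_frame(),
            "patterns.csv": self.patterns_frame(),
            "classification.csv": self.classification_frame(),
            "summary.csv": self.summary_frame(),
            "stats.csv": self.stats_frame(),
            "medians.csv": median_bmi_summary(self.cohort),
        }
        manifest: dict[str, str] = {}
        for name, frame in frames.items():
            buf = io.StringIO()
            buf.write(f"# config_hash: {chash}\n")
            frame.to_csv(buf, index=False)
            data = buf.getvalue()
            (outdir / name).write_text(data)
            manifest[name] = hashlib.sha256(data.encode()).hexdigest()
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(self.to_config_echo(), fh, sort_keys=True)
        with open(outdir / "MANIFEST.json", "w") as fh:
            json.dump({"config_hash": chash, "files": manifest}, fh, indent=2, sort_keys=True)
        return manifest

    def to_config_echo(self) -> dict:
        echo = self.config.to_dict()
        echo["config_hash"] = self.config.config_hash()
        return echo


def run_pipeline(
    demographics: pd.DataFrame,
    diagnoses: pd.DataFrame,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run cohort construction, mining, classification, and statistics."""
    config = config or RunConfig()
    cohort = build_cohort(demographics, diagnoses, window=config.window)
    excl = exclusion_counts(cohort)
    if not cohort["included"].any():
        raise ValueError(f"empty cohort after filters; exclusion counts: {excl}")

    txn_sets = build_transactions(
        cohort,
        diagnoses,
        config.chapter_filter,
        window=config.window,
        drop_empty=config.drop_empty_transactions,
    )
    miner_cfg = MinerConfig(min_support_fraction=config.min_support, min_itemset_size=1)
    patterns: dict[StratumKey, list[FrequentPattern]] = {}
    for key in sorted(txn_sets):
        patterns[key] = mine_frequent_itemsets(txn_sets[key], miner_cfg)
        logger.info(
            "stratum %s: n=%d, %d frequent itemsets",
            "|".join(key),
            txn_sets[key].n_patients,
            len(patterns[key]),
        )

    cells = sorted({(k.age_band, k.obesity_class) for k in txn_sets})
    comparisons: dict[tuple[str, str], list[PatternComparison]] = {}
    for cell in cells:
        pats = {
            k.race: patterns[k]
            for k in patterns
            if (k.age_band, k.obesity_class) == cell
        }
        txns = {
            k.race: txn_sets[k]
            for k in txn_sets
            if (k.age_band, k.obesity_class) == cell
        }
        comparisons[cell] = classify_patterns(
            pats,
            config.race_list,
            txns,
            min_size=config.min_pattern_size,
            ci_level=config.ci_level,
        )
    return PipelineResult(
        config=config,
        cohort=cohort,
        exclusion_counts=excl,
        transaction_sets=txn_sets,
        patterns_by_stratum=patterns,
        comparisons_by_cell=comparisons,
    )
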