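"""Human-readable report rendering: text tables and prevalence dot plots."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .compare import PatternComparison, report_filter

__all__ = ["render_table", "render_summary", "plot_cell", "write_report"]


def render_table(frame: pd.DataFrame, title: str) -> str:
    """Fixed-width text rendering of a result table."""
    body = frame.to_string(index=False) if len(frame) else "(empty)"
    rule = "=" * max(len(title), 8)
    return f"{title}\n{rule}\n{body}\n"


def render_summary(summary: pd.DataFrame) -> str:
    """Pattern-count summary pivoted to races x (cell, overall/distinct)."""
    if summary.empty:
        return render_table(summary, "Multimorbidity pattern counts")
    wide = summary.pivot_table(
        index="race",
        columns=["age_band", "obesity_class"],
        values=["overall", "distinct"],
        aggfunc="first",
        fill_value=0,
    )
    return "Multimorbidity pattern counts\n=============================\n" + wide.to_string() + "\n"


def plot_cell(
    comparisons: Sequence[PatternComparison],
    race_list: Sequence[str],
    path,
    *,
    min_display_prevalence: float | None = None,
    title: str = "",
) -> None:
    """Dot plot of per-race prevalence with exact CI bars for one cell.

    Races below the support threshold are drawn as open markers (the
    gray-sector analogue); the optional display cut drops low-prevalence
    patterns from the figure only.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shown = list(comparisons)
    if min_display_prevalence is not None:
        shown = report_filter(shown, min_display_prevalence)
    if not shown:
        return
    fig_h = max(2.0, 0.45 * len(shown))
    fig, ax = plt.subplots(figsize=(9, fig_h))
    colors = plt.cm.tab10.colors
    for y, comp in enumerate(shown):
        for k, race in enumerate(race_list):
            s = comp.per_race[race]
            yy = y + (k - len(race_list) / 2) * 0.09
            ax.errorbar(
                s.prevalence,
                yy,
                xerr=[[s.prevalence - s.ci.lower], [s.ci.upper - s.prevalence]],
                fmt="o" if s.frequent else "o",
                mfc=colors[k % 10] if s.frequent else "white",
                mec=colors[k % 10],
                ecolor=colors[k % 10],
                ms=4,
                lw=1,
                label=race if y == 0 else None,
            )
    ax.set_yticks(range(len(shown)))
    ax.set_yticklabels(["+".join(c.items) for c in shown], fontsize=7)
    ax.set_xlabel("prevalence")
    ax.set_title(title)
    ax.legend(fontsize=6, loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_report(
    results_dir,
    out_dir=None,
    *,
    min_display_prevalence: float | None = None,
) -> list[str]:
    """Render text tables (and plots if classification data is present)
    from a pipeline output directory.  Returns the files written."""
    results_dir = Path(results_dir)
    out_dir = Path(out_dir) if out_dir else results_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    sections = []
    for name, title in [
        ("cohort.csv", "Cohort by stratum"),
        ("exclusions.csv", "Exclusions by reason"),
        ("medians.csv", "Median BMI by stratum"),
        ("stats.csv", "Prevalence tests"),
    ]:
        f = results_dir / name
        if f.exists():
            sections.append(render_table(pd.read_csv(f, comment="#"), title))
    summary_f = results_dir / "summary.csv"
    if summary_f.exists():
        sections.append(render_summary(pd.read_csv(summary_f, comment="#")))
    text = "\n".join(sections)
    report_path = out_dir / "report.txt"
    report_path.write_text(text)
    written.append(str(report_path))

    cls_f = results_dir / "classification.csv"
    if cls_f.exists():
        cls = pd.read_csv(cls_f, comment="#")
        prev_cols = [c for c in cls.columns if c.startswith("prev[")]
        for (band, obesity), grp in cls.groupby(["age_band", "obesity_class"]):
            if min_display_prevalence is not None:
                grp = grp[grp[prev_cols].max(axis=1) >= min_display_prevalence]
            if grp.empty:
                continue
            png = out_dir / f"prevalence_{band}_{obesity}.png"
            _plot_from_frame(grp, prev_cols, png, f"{band}, {obesity}")
            written.append(str(png))
    return written


def _plot_from_frame(grp: pd.DataFrame, prev_cols: Iterable[str], path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grp = grp.reset_index(drop=True)
    fig_h = max(2.0, 0.45 * len(grp))
    fig, ax = plt.subplots(figsize=(9, fig_h))
    colors = plt.cm.tab10.colors
    for k, pcol in enumerate(prev_cols):
        tag = pcol[5:-1]
        lo = grp[f"ci_lo[{tag}]"]
        hi = grp[f"ci_hi[{tag}]"]
        freq = grp[f"frequent[{tag}]"]
        y = grp.index + (k - len(list(prev_cols)) / 2) * 0.09
        for i in grp.index:
            ax.errorbar(
                grp[pcol][i],
                y[i],
                xerr=[[grp[pcol][i] - lo[i]], [hi[i] - grp[pcol][i]]],
                fmt="o",
                mfc=colors[k % 10] if freq[i] else "white",
                mec=colors[k % 10],
                ecolor=colors[k % 10],
                ms=4,
                lw=1,
                label=tag if i == 0 else None,
            )
    ax.set_yticks(grp.index)
    ax.set_yticklabels(grp["items"], fontsize=7)
    ax.set_xlabel("prevalence")
    ax.set_title(title)
    ax.legend(fontsize=6, loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
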