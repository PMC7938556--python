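"""Composition analytics over the per-encounter criterion flags.

Given the eligible encounters' 7-bit flag matrix, this module computes the
descriptive outcome measures of a multi-criterion cohort definition:

* per-criterion counts and percentages of eligible encounters,
* exclusive combination counts (UpSet semantics: each encounter contributes
  to exactly one 7-bit pattern),
* overlap of every criterion's cohort with the diagnostic-code criterion,
  and the share of eligible encounters identified by diagnostic codes alone,
* the Pearson correlation matrix of the binary flags (the phi coefficient),
* per-year and per-district stratified summaries for consistency checks.

Raw values are retained everywhere; rounding (one decimal for marginal
percentages, whole percent for combination shares) is a display concern
handled by :func:`percent`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .criteria import CRITERION_LABELS, FLAG_COLUMNS

ONLY_DIAG_PATTERN = "0000010"  # pattern with only the diagnostic-code bit set


def percent(count: float, total: float, decimals: int = 1) -> float:
    """Percentage ``100*count/total`` rounded to ``decimals`` for display."""
    if total == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round(100.0 * count / total, decimals)


def pattern_of(row: pd.Series | np.ndarray) -> str:
    """7-character 0/1 pattern string, ordered c1..c7."""
    return "".join("1" if bool(v) else "0" for v in np.asarray(row, dtype=bool))


def pattern_label(pattern: str) -> str:
    return "+".join(c for c, bit in zip(FLAG_COLUMNS, pattern) if bit == "1") or "(none)"


@dataclass
class CompositionSummary:
    n_eligible: int
    per_criterion: dict  # criterion -> {"count": int, "percent": float|None}
    combos: dict  # pattern string -> count, descending count order
    n_unique_combos: int
    diag_overlap: dict  # criterion -> percent of that criterion's cohort with c6, or None
    diag_alone_pct: Optional[float]
    corr: Optional[pd.DataFrame]  # 7x7 phi matrix, NaN where undefined
    strata: dict = field(default_factory=dict)  # e.g. {"year": 2017, "lhd": "LHD1"}

    def to_dict(self) -> dict:
        corr = None
        if self.corr is not None:
            corr = {
                ci: {cj: (None if np.isnan(v) else float(v)) for cj, v in row.items()}
                for ci, row in self.corr.iterrows()
            }
        return {
            "strata": self.strata,
            "n_eligible": int(self.n_eligible),
            "per_criterion": self.per_criterion,
            "combos": {p: int(c) for p, c in self.combos.items()},
            "n_unique_combos": int(self.n_unique_combos),
            "diag_overlap": self.diag_overlap,
            "diag_alone_pct": self.diag_alone_pct,
            "corr": corr,
        }


def _eligible_only(flags: pd.DataFrame) -> pd.DataFrame:
    return flags[flags["eligible"]]


def criterion_frequencies(flags: pd.DataFrame) -> dict:
    """Count and percent of eligible encounters meeting each criterion.

    Percentages are reported to one decimal; with zero eligible encounters
    every percent is absent (None), never 0.
    """
    elig = _eligible_only(flags)
    n = len(elig)
    out = {}
    for c in FLAG_COLUMNS:
        count = int(elig[c].sum())
        out[c] = {"count": count, "percent": percent(count, n) if n else None}
    return out


def combination_counts(flags: pd.DataFrame) -> tuple[dict, int]:
    """Exclusive per-pattern counts over eligible encounters.

    Each encounter contributes to exactly one 7-bit pattern; patterns are
    returned sorted by descending count (ties by pattern string).
    """
    elig = _eligible_only(flags)
    if not len(elig):
        return {}, 0
    patterns = elig[FLAG_COLUMNS].apply(pattern_of, axis=1)
    counts = patterns.value_counts()
    ordered = dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
    return ordered, len(ordered)


def diag_overlap(flags: pd.DataFrame) -> tuple[dict, Optional[float]]:
    """Overlap of each criterion's cohort with the diagnostic-code criterion.

    For criterion c: percent of encounters meeting c that also meet c6.
    Criteria met by zero encounters report None.  ``diag_alone_pct`` is the
    percent of eligible encounters whose exact pattern is c6 only.
    """
    elig = _eligible_only(flags)
    n = len(elig)
    overlap = {}
    for c in FLAG_COLUMNS:
        denom = int(elig[c].sum())
        if denom == 0:
            overlap[c] = None
        else:
            overlap[c] = percent(int((elig[c] & elig["c6"]).sum()), denom)
    if n == 0:
        return overlap, None
    combos, _ = combination_counts(flags)
    alone = combos.get(ONLY_DIAG_PATTERN, 0)
    return overlap, percent(alone, n)


def flag_correlation(flags: pd.DataFrame) -> Optional[pd.DataFrame]:
    """Pearson correlation (phi) matrix of the 0/1 flags of eligible encounters.

    Constant columns yield NaN entries (undefined, not zero).  With fewer
    than two eligible rows the matrix is absent.
    """
    elig = _eligible_only(flags)
    if len(elig) < 2:
        return None
    mat = elig[FLAG_COLUMNS].astype(float)
    return mat.corr(method="pearson")


def summarise(flags: pd.DataFrame, strata: dict | None = None) -> CompositionSummary:
    """Full composition summary of one (sub)population of flags."""
    combos, n_unique = combination_counts(flags)
    overlap, alone = diag_overlap(flags)
    return CompositionSummary(
        n_eligible=int(flags["eligible"].sum()),
        per_criterion=criterion_frequencies(flags),
        combos=combos,
        n_unique_combos=n_unique,
        diag_overlap=overlap,
        diag_alone_pct=alone,
        corr=flag_correlation(flags),
        strata=strata or {},
    )


def consistency_report(
    flags: pd.DataFrame,
    encounters: pd.DataFrame,
    by: list[str] = ("year", "lhd"),
) -> tuple[list[CompositionSummary], pd.DataFrame]:
    """Stratified summaries plus a tidy long table for plotting.

    ``by`` names stratum keys drawn from the encounters table (``year``,
    ``lhd``).  Returns one summary per observed stratum level per key, and a
    long-format table (stratum_key, stratum, criterion, label, count,
    percent) across all strata.
    """
    unknown = set(by) - set(encounters.columns)
    if unknown:
        raise KeyError(f"unknown stratum key(s): {sorted(unknown)}")
    joined = flags.merge(encounters[["encounter_key", *by]], on="encounter_key", how="left")
    summaries: list[CompositionSummary] = []
    rows = []
    for key in by:
        for level, group in joined.groupby(key, sort=True):
            s = summarise(group, strata={key: level})
            summaries.append(s)
            for c, stats in s.per_criterion.items():
                rows.append({
                    "stratum_key": key, "stratum": level, "criterion": c,
                    "label": CRITERION_LABELS[c],
                    "count": stats["count"], "percent": stats["percent"],
                })
    tidy = pd.DataFrame(rows, columns=["stratum_key", "stratum", "criterion",
                                       "label", "count", "percent"])
    return summaries, tidy


def upset_plot(flags: pd.DataFrame, path, max_patterns: int = 20) -> None:
    """UpSet-style figure: combination bars over a membership-dot matrix.

    Shows the ``max_patterns`` most frequent exclusive patterns with the
    per-criterion marginal counts alongside.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    combos, _ = combination_counts(flags)
    freq = criterion_frequencies(flags)
    top = list(combos.items())[:max_patterns]
    if not top:
        raise ValueError("no eligible encounters to plot")
    patterns = [p for p, _ in top]
    counts = [c for _, c in top]

    fig, axes = plt.subplots(
        2, 2, figsize=(max(6, 0.5 * len(top) + 3), 6),
        gridspec_kw={"height_ratios": [2, 1], "width_ratios": [1, 3]},
        sharex="col",
    )
    axes[0, 0].axis("off")
    ax_bar, ax_marg, ax_dot = axes[0, 1], axes[1, 0], axes[1, 1]

    x = np.arange(len(top))
    ax_bar.bar(x, counts, color="0.2")
    ax_bar.set_ylabel("encounters")
    ax_bar.set_title("Exclusive criterion combinations")

    y = np.arange(len(FLAG_COLUMNS))
    marg = [freq[c]["count"] for c in FLAG_COLUMNS]
    ax_marg.barh(y, marg, color="0.5")
    ax_marg.set_yticks(y, [CRITERION_LABELS[c] for c in FLAG_COLUMNS], fontsize=7)
    ax_marg.invert_xaxis()
    ax_marg.set_xlabel("criterion total")

    for xi, p in enumerate(patterns):
        members = [i for i, bit in enumerate(p) if bit == "1"]
        ax_dot.scatter([xi] * len(FLAG_COLUMNS), y, s=30, color="0.85", zorder=1)
        ax_dot.scatter([xi] * len(members), members, s=40, color="0.1", zorder=2)
        if len(members) > 1:
            ax_dot.plot([xi, xi], [members[0], members[-1]], color="0.1", zorder=2)
    ax_dot.set_yticks(y, ["" for _ in y])
    ax_dot.set_xticks(x, ["" for _ in x])
    ax_dot.set_ylim(-0.5, len(FLAG_COLUMNS) - 0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_outputs(summary: CompositionSummary, out_dir) -> None:
    """Write composition_summary.json, combos.csv and correlation.csv."""
    import json
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "composition_summary.json").write_text(
        json.dumps(summary.to_dict(), indent=2) + "\n", encoding="utf-8"
    )
    combo_rows = [
        {
            "pattern": p,
            "label": pattern_label(p),
            "count": c,
            "percent": percent(c, summary.n_eligible, 0) if summary.n_eligible else None,
        }
        for p, c in summary.combos.items()
    ]
    pd.DataFrame(combo_rows, columns=["pattern", "label", "count", "percent"]).to_csv(
        out_dir / "combos.csv", index=False
    )
    if summary.corr is not None:
        summary.corr.to_csv(out_dir / "correlation.csv")
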