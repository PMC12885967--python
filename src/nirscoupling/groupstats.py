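"""Group-level aggregation and two-sample comparison of coupling indices.

Per-recording band-averaged coherence and semblance are aggregated per group
as mean +/- sample SD (n - 1 denominator) and compared across cohorts with an
independent two-sample t-test (Welch by default; pooled-variance optionally).
No multiple-testing correction is applied by default across the 16
pair x metric x contrast tests; a Holm adjustment is available behind a flag
and clearly labelled a deviation from the headline analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .coupling import PAIR_ORDER

__all__ = [
    "ComparisonResult",
    "validate_results",
    "summarize_groups",
    "compare_groups",
    "render_table",
    "METRICS",
    "CONTRASTS",
]

METRICS = ("coherence", "semblance")
CONTRASTS = (("young", "placebo"), ("placebo", "nimodipine"))
_METRIC_COLUMN = {"coherence": "band_coherence", "semblance": "band_semblance"}

REQUIRED_COLUMNS = ("animal_id", "group", "pair", "band_coherence", "band_semblance")


@dataclass
class ComparisonResult:
    pair: str
    metric: str
    contrast: tuple
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_statistic: float
    p_value: float
    welch: bool = True
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ConfigurationError(f"metric: {self.metric!r} not in {METRICS}")
        if self.sd_a < 0 or self.sd_b < 0:
            raise ConfigurationError("sd: must be >= 0")
        if self.n_a < 2 or self.n_b < 2:
            raise ConfigurationError("n: each arm needs n >= 2")
        if not (0.0 <= self.p_value <= 1.0):
            raise ConfigurationError("p_value: outside [0, 1]")


def validate_results(results: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(results.columns)
    if missing:
        raise ConfigurationError(f"results: missing columns {sorted(missing)}")
    dup = results.duplicated(subset=["animal_id", "pair"])
    if dup.any():
        raise ConfigurationError(
            f"results: duplicate (animal_id, pair) rows, e.g. "
            f"{results.loc[dup, ['animal_id', 'pair']].iloc[0].tolist()}"
        )
    return results


def summarize_groups(results: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sample SD and n per (metric, pair, group)."""
    validate_results(results)
    if results.empty:
        raise ConfigurationError("results: empty table")
    rows = []
    for metric in METRICS:
        col = _METRIC_COLUMN[metric]
        for pair in PAIR_ORDER:
            sub = results[results["pair"] == pair]
            for group, g in sub.groupby("group", sort=False):
                if g.empty:
                    raise ConfigurationError(f"group {group!r}: empty for pair {pair!r}")
                rows.append({
                    "metric": metric,
                    "pair": pair,
                    "group": group,
                    "mean": float(g[col].mean()),
                    "sd": float(g[col].std(ddof=1)) if len(g) > 1 else 0.0,
                    "n": int(len(g)),
                })
    return pd.DataFrame(rows)


def compare_groups(
    results: pd.DataFrame,
    contrast: tuple = ("young", "placebo"),
    welch: bool = True,
    adjust: str | None = None,
) -> list:
    """Independent two-sample t-test per (pair, metric) for one contrast.

    ``welch=False`` switches to the pooled-variance test.  ``adjust='holm'``
    adds Holm-adjusted p-values across the 8 tests of this contrast.
    """
    validate_results(results)
    label_a, label_b = contrast
    out = []
    for metric in METRICS:
        col = _METRIC_COLUMN[metric]
        for pair in PAIR_ORDER:
            sub = results[results["pair"] == pair]
            a = sub.loc[sub["group"] == label_a, col].to_numpy(dtype=float)
            b = sub.loc[sub["group"] == label_b, col].to_numpy(dtype=float)
            if a.size < 2 or b.size < 2:
                raise ConfigurationError(
                    f"contrast {contrast}: pair {pair!r} needs n >= 2 per arm "
                    f"(got {a.size} vs {b.size})"
                )
            if np.array_equal(a, b):
                t_stat, p = 0.0, 1.0
            else:
                t_stat, p = stats.ttest_ind(a, b, equal_var=not welch)
            out.append(ComparisonResult(
                pair=pair, metric=metric, contrast=tuple(contrast),
                mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)), n_a=int(a.size),
                mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)), n_b=int(b.size),
                t_statistic=float(t_stat), p_value=float(p), welch=welch,
            ))
    if adjust == "holm":
        from statsmodels.stats.multitest import multipletests

        pvals = [r.p_value for r in out]
        _, p_adj, *_ = multipletests(pvals, method="holm")
        for r, pa in zip(out, p_adj):
            r.p_adjusted = float(pa)
    elif adjust is not None:
        raise ConfigurationError(f"adjust: {adjust!r} not supported (use 'holm' or None)")
    return out


def _fmt_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def render_table(results: pd.DataFrame, comparisons: list) -> str:
    """Plain-text report with metric blocks, mean +/- SD cells and p columns.

    Rows are ordered oxCCO-HbO2, oxCCO-HHb, oxCCO-HbT, oxCCO-HbDiff within
    each metric block; p values below 0.001 render as '<0.001'.
    """
    summary = summarize_groups(results)
    groups = [g for g in ("young", "placebo", "nimodipine")
              if g in set(summary["group"])]
    by_key = {
        (c.metric, c.pair, c.contrast): c for c in comparisons
    }
    contrasts = sorted({c.contrast for c in comparisons},
                       key=lambda c: CONTRASTS.index(c) if c in CONTRASTS else 99)
    headers = ["Measurement"] + [g.capitalize() for g in groups] + [
        f"{a} vs {b}" for a, b in contrasts
    ]
    lines = []
    widths = None
    rows_out = [headers]
    for metric in METRICS:
        rows_out.append([metric.capitalize()] + [""] * (len(headers) - 1))
        for pair in PAIR_ORDER:
            row = [pair]
            for g in groups:
                cell = summary[(summary["metric"] == metric)
                               & (summary["pair"] == pair)
                               & (summary["group"] == g)]
                m, sd = float(cell["mean"].iloc[0]), float(cell["sd"].iloc[0])
                row.append(f"{m:.2f} ± {sd:.2f}")
            for contrast in contrasts:
                c = by_key.get((metric, pair, contrast))
                row.append(_fmt_p(c.p_value) if c else "")
            rows_out.append(row)
    widths = [max(len(r[i]) for r in rows_out) for i in range(len(headers))]
    for r in rows_out:
        lines.append("  ".join(cell.ljust(w) for cell, w in zip(r, widths)).rstrip())
    return "\n".join(lines) + "\n"


def comparisons_frame(comparisons: list) -> pd.DataFrame:
    """Tidy DataFrame view of a list of ComparisonResult."""
    return pd.DataFrame([{
        "pair": c.pair, "metric": c.metric,
        "contrast": f"{c.contrast[0]}-vs-{c.contrast[1]}",
        "mean_a": c.mean_a, "sd_a": c.sd_a, "n_a": c.n_a,
        "mean_b": c.mean_b, "sd_b": c.sd_b, "n_b": c.n_b,
        "t_statistic": c.t_statistic, "p_value": c.p_value,
        "welch": c.welch, "p_adjusted": c.p_adjusted,
    } for c in comparisons])
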