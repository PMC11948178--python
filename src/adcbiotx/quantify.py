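"""Fractional abundances and longitudinal biotransformation profiles.

Each species' deconvoluted peak intensity is divided by the summed intensity
of all species in its group (one chain of one sample at one time point), so
fractions in a group sum to 1.  Time courses aggregate per-subject fractions
into mean +/- sample standard deviation across biological replicates; time
points where a species was not observed enter as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


def fractional_abundance(intensities: Sequence[float]) -> np.ndarray:
    """Fractions I_i / sum(I).  An all-zero group returns all zeros with a
    warning (such points are plotted as zero)."""
    values = np.asarray(intensities, dtype=float)
    if np.any(values < 0):
        raise ValueError("intensities must be non-negative")
    total = values.sum()
    if total == 0:
        warnings.warn("all intensities are zero; fractions reported as zero")
        return np.zeros_like(values)
    return values / total


def percent_difference(new_value: float, old_value: float) -> float:
    """Signed percent difference: (new - old) / mean(new, old) * 100.

    Returns NaN when both values are zero (mean denominator undefined).
    """
    mean = (new_value + old_value) / 2.0
    if mean == 0:
        return float("nan")
    return (new_value - old_value) / mean * 100.0


def add_fractions(
    df: pd.DataFrame,
    group_cols: Sequence[str] = ("subject", "time_h", "chain"),
    value_col: str = "intensity",
) -> pd.DataFrame:
    """Attach a ``fraction`` column: within-group fractional abundance."""
    cols = [c for c in group_cols if c in df.columns]
    out = df.copy()
    totals = out.groupby(cols)[value_col].transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        out["fraction"] = np.where(totals > 0, out[value_col] / totals, 0.0)
    return out


@dataclass
class TimeCourse:
    """Longitudinal profile: per-subject fractions plus replicate statistics."""

    per_subject: pd.DataFrame  # species, subject, time_h, intensity, fraction
    summary: pd.DataFrame  # species, time_h, mean_fraction, sd_fraction, n_subjects


def aggregate_replicates(per_subject: pd.DataFrame) -> TimeCourse:
    """Mean and sample standard deviation (n-1; single subject -> sd 0) of
    fractional abundance per species x time point across subjects."""
    df = per_subject.copy()
    if "subject" not in df.columns:
        df["subject"] = "s1"
    grouped = df.groupby(["species", "time_h"])["fraction"]
    summary = grouped.agg(
        mean_fraction="mean",
        sd_fraction=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0,
        n_subjects="count",
    ).reset_index()
    summary["sd_fraction"] = summary["sd_fraction"].fillna(0.0)
    return TimeCourse(per_subject=df, summary=summary)


def build_timecourse(
    consolidated: pd.DataFrame,
    group_cols: Sequence[str] = ("subject", "time_h", "chain"),
) -> TimeCourse:
    """Fractions within (subject, time point, chain) groups, then replicate
    aggregation.  ``consolidated`` comes from :func:`adcbiotx.annotate.consolidate`."""
    return aggregate_replicates(add_fractions(consolidated, group_cols))


def export_timecourse(tc: TimeCourse, path: str | Path) -> Path:
    tc.summary.to_csv(path, index=False, float_format="%.6g")
    return Path(path)


def wide_matrix(tc: TimeCourse) -> pd.DataFrame:
    """Species x time-point matrix of mean fractional abundance."""
    return tc.summary.pivot(index="species", columns="time_h", values="mean_fraction")


def plot_timecourse(tc: TimeCourse, path: str | Path, title: str = "") -> Path:
    """Fractional abundance vs time with replicate error bars (PNG/PDF)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for species, grp in tc.summary.groupby("species"):
        ax.errorbar(
            grp["time_h"], grp["mean_fraction"], yerr=grp["sd_fraction"],
            marker="o", capsize=3, label=str(species),
        )
    ax.set_xlabel("time (h)")
    ax.set_ylabel("fractional abundance")
    ax.set_ylim(bottom=0)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7, loc="best")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)
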