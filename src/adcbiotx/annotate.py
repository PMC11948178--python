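"""Peak-to-proteoform matching with ppm accounting and review flags.

Deconvoluted neutral-mass peaks are matched against proteoform candidates
within a fixed absolute tolerance (3 Da by default, the conventional window
for intact ADC work on QTOF instruments).  All candidates within tolerance
are kept, ranked by |ppm| with ties broken toward the lower theoretical mass;
peaks with several plausible assignments are flagged for manual review rather
than auto-resolved — plausibility judgments about enzymatic cleavage
chemistry stay with the analyst.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .deconvolution import MassPeak
from .proteoform import ProteoformCandidate


def compute_ppm(observed: float, theoretical: float) -> float:
    """Signed mass accuracy: (observed - theoretical)/theoretical * 1e6."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return (observed - theoretical) / theoretical * 1e6


@dataclass(frozen=True)
class AnnotationRecord:
    peak: MassPeak
    candidate_label: str  # "" for unidentified peaks
    theo_mass: float  # NaN for unidentified
    delta_da: float
    ppm: float
    rank: int
    n_alternatives: int
    review_flag: bool
    chain_id: str = ""
    dar: int | None = None

    @property
    def identified(self) -> bool:
        return bool(self.candidate_label)


def match_peaks(
    peaks: Sequence[MassPeak],
    candidates: Sequence[ProteoformCandidate],
    tolerance_da: float = 3.0,
    scale: str = "average",
    window_chain_map: Mapping[str, str] | None = None,
) -> list[AnnotationRecord]:
    """Match each peak to all candidates within ``tolerance_da`` (inclusive).

    ``scale`` selects the theoretical mass scale ('average' for isotopically
    unresolved intact data, 'monoisotopic' otherwise).  When
    ``window_chain_map`` maps RT-window labels to chain ids, only that
    chain's candidates are considered for peaks from that window (LC window
    -> LC candidates).  Zero-match peaks yield an "unidentified" record.
    """
    if not candidates:
        raise ValueError("candidate set is empty")
    if tolerance_da <= 0:
        raise ValueError("tolerance must be positive")

    def theo(c: ProteoformCandidate) -> float:
        return c.theo_avg_mass if scale == "average" else c.theo_mono_mass

    records: list[AnnotationRecord] = []
    for peak in peaks:
        pool = candidates
        if window_chain_map and peak.rt_window in window_chain_map:
            chain = window_chain_map[peak.rt_window]
            pool = [c for c in candidates if c.chain_id == chain]
        hits = [
            (c, peak.neutral_mass - theo(c))
            for c in pool
            if abs(peak.neutral_mass - theo(c)) <= tolerance_da
        ]
        if not hits:
            records.append(
                AnnotationRecord(
                    peak=peak,
                    candidate_label="",
                    theo_mass=math.nan,
                    delta_da=math.nan,
                    ppm=math.nan,
                    rank=1,
                    n_alternatives=0,
                    review_flag=False,
                )
            )
            continue
        # |delta| ordering equals |ppm| ordering within one peak's 3 Da window
        # except for exact-Da ties, which break toward the lower mass
        hits.sort(key=lambda h: (abs(h[1]), theo(h[0])))
        n = len(hits)
        for rank, (c, delta) in enumerate(hits, start=1):
            records.append(
                AnnotationRecord(
                    peak=peak,
                    candidate_label=c.label,
                    theo_mass=theo(c),
                    delta_da=delta,
                    ppm=compute_ppm(peak.neutral_mass, theo(c)),
                    rank=rank,
                    n_alternatives=n,
                    review_flag=n > 1,
                    chain_id=c.chain_id,
                    dar=c.dar,
                )
            )
    return records


def annotations_frame(
    records: Sequence[AnnotationRecord],
    sample_id: str = "",
    rank1_only: bool = False,
) -> pd.DataFrame:
    """Tidy frame of annotation records (one row per peak x candidate)."""
    rows = []
    for r in records:
        if rank1_only and r.identified and r.rank != 1:
            continue
        rows.append(
            {
                "sample_id": sample_id,
                "observed_mass": r.peak.neutral_mass,
                "intensity": r.peak.intensity,
                "rt_window": r.peak.rt_window,
                "apex_rt": r.peak.apex_rt,
                "proposed_id": r.candidate_label,
                "chain": r.chain_id,
                "dar": r.dar,
                "theo_mass": r.theo_mass,
                "delta_da": r.delta_da,
                "ppm": r.ppm,
                "rank": r.rank,
                "n_alternatives": r.n_alternatives,
                "review_flag": r.review_flag,
            }
        )
    return pd.DataFrame(rows)


def consolidate(
    annotations: pd.DataFrame,
    min_timepoint_fraction: float = 0.5,
    mass_bin_da: float = 1.0,
) -> pd.DataFrame:
    """Keep species observed in at least ``min_timepoint_fraction`` of time
    points (boundary inclusive) and fill absences with zero intensity.

    ``annotations`` is a long frame with at least ``time_h``, ``intensity``
    and either ``proposed_id`` or ``observed_mass`` columns (rank-1 rows);
    unidentified peaks are binned by rounded mass (``mass:<m>``).  Returns one
    row per species x (time point, subject when present).
    """
    df = annotations.copy()
    if "proposed_id" in df.columns:
        unnamed = df["proposed_id"].isna() | (df["proposed_id"] == "")
        binned = (df["observed_mass"] / mass_bin_da).round() * mass_bin_da
        df["species"] = df["proposed_id"].where(~unnamed, "mass:" + binned.astype(int).astype(str))
    else:
        df["species"] = "mass:" + df["observed_mass"].round().astype(int).astype(str)

    time_points = sorted(df["time_h"].unique())
    present = (
        df[df["intensity"] > 0].groupby("species")["time_h"].nunique()
    )
    keep = present[present >= min_timepoint_fraction * len(time_points)].index
    df = df[df["species"].isin(keep)]

    group_cols = ["time_h"] + (["subject"] if "subject" in df.columns else [])
    carry = [c for c in ("chain", "rt_window") if c in df.columns]
    agg = (
        df.groupby(["species"] + group_cols, as_index=False)
        .agg({"intensity": "sum", **{c: "first" for c in carry}})
    )
    # complete grid with zeros where a species was not observed
    keys = df[group_cols].drop_duplicates() if group_cols else pd.DataFrame()
    full = (
        pd.MultiIndex.from_product(
            [sorted(keep)] + [sorted(df[c].unique()) for c in group_cols],
            names=["species"] + group_cols,
        )
        .to_frame(index=False)
    )
    out = full.merge(agg, how="left", on=["species"] + group_cols)
    out["intensity"] = out["intensity"].fillna(0.0)
    for c in carry:
        out[c] = out.groupby("species")[c].transform(lambda s: s.ffill().bfill())
    return out.sort_values(["species"] + group_cols).reset_index(drop=True)


ANNOTATION_COLUMNS = (
    "sample_id",
    "observed_mass",
    "intensity",
    "rt_window",
    "apex_rt",
    "proposed_id",
    "chain",
    "dar",
    "theo_mass",
    "delta_da",
    "ppm",
    "rank",
    "n_alternatives",
    "review_flag",
)


def export_annotations(
    records: Sequence[AnnotationRecord], path: str | Path, sample_id: str = ""
) -> Path:
    frame = annotations_frame(records, sample_id=sample_id)
    frame.to_csv(path, index=False, columns=list(ANNOTATION_COLUMNS), float_format="%.6f")
    return Path(path)


def read_annotations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=True)
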