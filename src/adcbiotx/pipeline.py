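"""End-to-end convenience wiring: runs -> peaks -> annotations -> time course.

Thin glue over the individual modules for the common study layout: one LC-MS
run per (subject, time point) sample, chain-specific RT windows, one
candidate set per chain, rank-1 annotations quantified as per-chain
fractional abundances with replicate statistics.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .annotate import annotations_frame, consolidate, match_peaks
from .deconvolution import DeconvConfig, PreprocessConfig, RTWindow, Spectrum, deconvolve_run
from .proteoform import ProteoformCandidate
from .quantify import TimeCourse, build_timecourse


def annotate_study(
    runs: Mapping[str, Sequence[Spectrum]],
    candidates: Sequence[ProteoformCandidate],
    windows: Sequence[RTWindow],
    window_chain_map: Mapping[str, str] | None = None,
    tolerance_da: float = 3.0,
    scale: str = "average",
    deconv_config: DeconvConfig = DeconvConfig(),
    preprocess_config: PreprocessConfig | None = PreprocessConfig(),
) -> pd.DataFrame:
    """Deconvolve and annotate every sample run; returns the rank-1 long
    annotation frame (one row per peak) across samples."""
    frames = []
    for sample_id, run in runs.items():
        peaks = deconvolve_run(run, windows, deconv_config, preprocess_config)
        records = match_peaks(
            peaks,
            candidates,
            tolerance_da=tolerance_da,
            scale=scale,
            window_chain_map=window_chain_map,
        )
        frames.append(annotations_frame(records, sample_id=sample_id, rank1_only=True))
    return pd.concat(frames, ignore_index=True)


def quantify_study(
    annotations: pd.DataFrame,
    manifest: pd.DataFrame,
    min_timepoint_fraction: float = 0.5,
    include_unidentified: bool = False,
) -> TimeCourse:
    """Join annotations with the sample manifest, keep reproducible species,
    and compute per-chain fractional-abundance time courses.

    ``manifest`` columns: sample_id, subject, time_h.  Unidentified peaks are
    excluded from the fractional-abundance denominator unless requested.
    """
    df = annotations.merge(manifest, on="sample_id", how="left")
    if df["time_h"].isna().any():
        missing = df.loc[df["time_h"].isna(), "sample_id"].unique()
        raise ValueError(f"samples missing from manifest: {list(missing)[:5]}")
    identified = df["proposed_id"].notna() & (df["proposed_id"] != "")
    if not include_unidentified:
        df = df[identified]
    consolidated = consolidate(df, min_timepoint_fraction=min_timepoint_fraction)
    return build_timecourse(consolidated)
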