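"""Charge-envelope deconvolution of intact electrospray spectra.

Multiply protonated proteoforms in the 20-80 kDa range appear as an envelope
of peaks at (M + z*p)/z across consecutive charge states z.  This module
replaces the proprietary maximum-entropy step of commercial packages with a
transparent greedy scheme:

1. score every candidate neutral mass M on a regular grid by summing the
   spectrum intensity interpolated at its predicted charge positions inside
   the configured m/z range;
2. accept the best-scoring mass whose support forms a dense, coherent block
   of consecutive charge states (genuine envelopes are contiguous; an n*M
   harmonic aligns only with every n-th charge) and that is not a divisor
   alias of a stronger 2M/3M explanation;
3. refine the mass from the measured per-charge apex positions, subtract the
   fitted envelope along the full physical charge ladder, and repeat until
   the residual score falls below threshold.

A dominance post-filter on harmonically related peak pairs is kept as a
final guard.  Isotope structure is not modelled — at this mass range it is
unresolved, so deconvolved masses live on the average-mass scale.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import minimum_filter1d

from .masses import PROTON_MASS


@dataclass
class Spectrum:
    """One scan: m/z array (strictly increasing) with intensities."""

    rt: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray
    mode: str = "profile"  # or "centroid"

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())


@dataclass(frozen=True)
class RTWindow:
    label: str
    start: float
    end: float

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("RT window start must precede end")

    def contains(self, rt: float) -> bool:
        return self.start <= rt <= self.end


@dataclass(frozen=True)
class MassPeak:
    neutral_mass: float
    intensity: float
    rt_window: str = ""
    apex_rt: float = float("nan")
    n_charges_supporting: int = 0


@dataclass(frozen=True)
class PreprocessConfig:
    baseline_window_mz: float = 20.0  # rolling-minimum window, m/z units
    noise_k: float = 5.0  # zero intensities below k x MAD
    #: drop surviving nonzero runs narrower than this many samples — an
    #: isolated detector noise spike is 1-2 samples wide, a genuine profile
    #: peak spans many
    min_peak_samples: int = 3


@dataclass(frozen=True)
class DeconvConfig:
    charge_range: tuple[int, int] = (10, 60)
    mz_range: tuple[float, float] = (1000.0, 5000.0)
    mass_range: tuple[float, float] = (20_000.0, 80_000.0)
    grid_step: float = 0.5
    min_supporting_charges: int = 3
    #: a charge state supports a candidate mass only above this fraction of the
    #: candidate's strongest charge (keeps noise gap-fillers from stitching the
    #: alternating support pattern of an n*M harmonic into a consecutive run)
    support_rel_intensity: float = 0.2
    #: supporting charges must fill at least this fraction of their charge
    #: span: a genuine envelope is contiguous (a single overlap nick is
    #: tolerated) while an n*M harmonic aligns only with every n-th charge
    min_support_density: float = 0.7
    #: the two longest consecutive charge runs together must carry at least
    #: this fraction of the candidate's total score, rejecting chance
    #: alignments of unrelated peak tails and noise-bridged harmonics
    min_run_coherence: float = 0.65
    #: reject a candidate when double/triple its mass scores more than this
    #: factor higher — the intensity then belongs to the larger mass and the
    #: candidate is its divisor alias (M/2 aligns with every even charge of M)
    alias_score_factor: float = 1.3
    rel_threshold: float = 0.10  # stop below this fraction of the initial best score
    max_peaks: int = 50
    resolution: float = 10_000.0  # FWHM resolving power used for envelope subtraction
    harmonic_dominance: float = 3.0
    harmonic_share: float = 0.5


# ---------------------------------------------------------------------------
# reading runs
# ---------------------------------------------------------------------------


def read_run(path: str | Path) -> list[Spectrum]:
    """Read an LC-MS run from mzML or the CSV spectrum dialect (columns rt,
    mz, intensity; one row per point, scans grouped by rt).  Spectra are
    returned sorted by retention time."""
    path = Path(path)
    if path.suffix.lower() == ".mzml":
        spectra = _read_mzml(path)
    else:
        spectra = _read_csv_run(path)
    if not spectra:
        raise ValueError(f"no spectra found in {path}")
    return sorted(spectra, key=lambda s: s.rt)


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"
_ACC_CENTROID = "MS:1000127"
_ACC_SCAN_START = "MS:1000016"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INTENSITY_ARRAY = "MS:1000515"
_ACC_64BIT = "MS:1000523"
_ACC_32BIT = "MS:1000521"
_ACC_ZLIB = "MS:1000574"


def _read_mzml(path: Path) -> list[Spectrum]:
    """Minimal reader for the mzML standard subset used in intact MS1 work:
    uncompressed or zlib binary arrays, 32/64-bit floats, scan start time in
    minutes or seconds, plain or indexed mzML."""
    import base64
    import zlib

    from lxml import etree

    tree = etree.parse(str(path))
    out = []
    for spec in tree.iter(f"{_MZML_NS}spectrum"):
        accessions = {
            cv.get("accession"): cv for cv in spec.iter(f"{_MZML_NS}cvParam")
        }
        mode = "centroid" if _ACC_CENTROID in accessions else "profile"
        rt = 0.0
        if _ACC_SCAN_START in accessions:
            cv = accessions[_ACC_SCAN_START]
            rt = float(cv.get("value"))
            if "second" in (cv.get("unitName") or ""):
                rt /= 60.0
        arrays: dict[str, np.ndarray] = {}
        for bda in spec.iter(f"{_MZML_NS}binaryDataArray"):
            accs = {cv.get("accession") for cv in bda.iter(f"{_MZML_NS}cvParam")}
            binary = bda.find(f"{_MZML_NS}binary")
            raw = base64.b64decode(binary.text or "")
            if _ACC_ZLIB in accs:
                raw = zlib.decompress(raw)
            dtype = "<f4" if _ACC_32BIT in accs else "<f8"
            values = np.frombuffer(raw, dtype=dtype).astype(float)
            if _ACC_MZ_ARRAY in accs:
                arrays["mz"] = values
            elif _ACC_INTENSITY_ARRAY in accs:
                arrays["intensity"] = values
        if "mz" not in arrays or "intensity" not in arrays:
            raise ValueError(f"spectrum in {path} lacks m/z or intensity array")
        order = np.argsort(arrays["mz"], kind="stable")
        out.append(
            Spectrum(
                rt=rt,
                mz=arrays["mz"][order],
                intensity=arrays["intensity"][order],
                mode=mode,
            )
        )
    return out


def _read_csv_run(path: Path) -> list[Spectrum]:
    import pandas as pd

    df = pd.read_csv(path)
    required = {"rt", "mz", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"CSV run must have columns {sorted(required)}")
    out = []
    for rt, group in df.groupby("rt", sort=True):
        g = group.sort_values("mz")
        out.append(
            Spectrum(
                rt=float(rt),
                mz=g["mz"].to_numpy(dtype=float),
                intensity=g["intensity"].to_numpy(dtype=float),
            )
        )
    return out


def write_csv_run(spectra: Sequence[Spectrum], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["rt", "mz", "intensity"])
        for s in spectra:
            for mz, inten in zip(s.mz, s.intensity):
                w.writerow([s.rt, f"{mz:.6f}", f"{inten:.6f}"])
    return path


# ---------------------------------------------------------------------------
# preprocessing and RT windows
# ---------------------------------------------------------------------------


def preprocess(spectrum: Spectrum, config: PreprocessConfig = PreprocessConfig()) -> Spectrum:
    """Rolling-minimum baseline subtraction followed by MAD noise gating.

    The baseline at each point is the minimum intensity within a window of
    ``baseline_window_mz`` m/z units; intensities below ``noise_k`` times the
    median absolute deviation of the baseline-subtracted signal are zeroed.
    Output intensities are non-negative.
    """
    if spectrum.mz.size == 0:
        return spectrum
    spacing = float(np.median(np.diff(spectrum.mz))) if spectrum.mz.size > 1 else 1.0
    half_pts = max(1, int(round(config.baseline_window_mz / max(spacing, 1e-9))))
    baseline = minimum_filter1d(spectrum.intensity, size=2 * half_pts + 1, mode="nearest")
    cleaned = spectrum.intensity - baseline
    # rolling-min subtraction leaves the noise sitting on a positive pedestal,
    # so the gate is k x MAD *above the post-subtraction median*
    center = float(np.median(cleaned))
    mad = float(np.median(np.abs(cleaned - center)))
    floor = center + config.noise_k * mad
    cleaned = np.where(cleaned >= floor, cleaned, 0.0)
    cleaned = np.maximum(cleaned, 0.0)
    if config.min_peak_samples > 1:
        cleaned = _drop_narrow_runs(cleaned, config.min_peak_samples)
    return replace(spectrum, intensity=cleaned)


def _drop_narrow_runs(values: np.ndarray, min_samples: int) -> np.ndarray:
    nz = values > 0
    edges = np.flatnonzero(np.diff(np.concatenate(([False], nz, [False])).astype(int)))
    out = values.copy()
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start < min_samples:
            out[start:stop] = 0.0
    return out


def sum_window(run: Sequence[Spectrum], window: RTWindow) -> Spectrum:
    """Intensity-summed composite spectrum over all scans inside the window.

    Scans are interpolated onto the m/z grid of the window's highest-TIC scan
    (identical grids — the common case — sum exactly).  The composite carries
    the apex scan's retention time.
    """
    scans = [s for s in run if window.contains(s.rt)]
    if not scans:
        raise ValueError(
            f"RT window {window.label} [{window.start}, {window.end}] contains no scans"
        )
    apex = max(scans, key=lambda s: s.tic)
    total = np.zeros_like(apex.intensity)
    for s in scans:
        if s.mz.shape == apex.mz.shape and np.array_equal(s.mz, apex.mz):
            total += s.intensity
        else:
            total += np.interp(apex.mz, s.mz, s.intensity, left=0.0, right=0.0)
    return Spectrum(rt=apex.rt, mz=apex.mz.copy(), intensity=total, mode=apex.mode)


# ---------------------------------------------------------------------------
# deconvolution
# ---------------------------------------------------------------------------


def deconvolve(
    spectrum: Spectrum,
    config: DeconvConfig = DeconvConfig(),
    rt_window_label: str = "",
) -> list[MassPeak]:
    """Greedy charge-envelope deconvolution of one (composite) spectrum.

    Returns neutral-mass peaks within ``config.mass_range`` sorted by
    decreasing intensity.  The reported intensity is the summed envelope
    intensity at extraction time; ``n_charges_supporting`` counts charge
    states contributing signal.
    """
    lo_mz, hi_mz = config.mz_range
    sel = (spectrum.mz >= lo_mz) & (spectrum.mz <= hi_mz)
    mz = spectrum.mz[sel]
    work = spectrum.intensity[sel].astype(float).copy()
    work0 = work.copy()  # untouched copy for alias arbitration
    if mz.size < 2 or work.sum() <= 0:
        return []

    z = np.arange(config.charge_range[0], config.charge_range[1] + 1)
    grid = np.arange(
        config.mass_range[0], config.mass_range[1] + config.grid_step, config.grid_step
    )
    # queries[i, j] = m/z of grid mass j at charge z[i]
    queries = (grid[None, :] + z[:, None] * PROTON_MASS) / z[:, None]
    in_range = (queries >= lo_mz) & (queries <= hi_mz)
    flat_queries = queries.ravel()

    def score_matrix() -> np.ndarray:
        s = np.interp(flat_queries, mz, work, left=0.0, right=0.0).reshape(queries.shape)
        s[~in_range] = 0.0
        return s

    s = score_matrix()
    total = s.sum(axis=0)
    threshold = config.rel_threshold * float(total.max())
    if threshold <= 0:
        return []

    sigma_factor = 1.0 / (config.resolution * 2.3548)  # FWHM -> sigma, relative
    peaks: list[tuple[MassPeak, np.ndarray]] = []
    for _ in range(config.max_peaks):
        supported = s > config.support_rel_intensity * s.max(axis=0, keepdims=True)
        support = supported.sum(axis=0)
        # a genuine proteoform is supported by a dense block of consecutive
        # charge states (one overlap nick tolerated); an n*M harmonic aligns
        # only with every n-th charge (low density) and chance alignments of
        # unrelated tails spread their score over many short runs
        density = _support_density(supported)
        top2_score = _top_two_run_scores(supported, s)
        # a contiguous envelope passes at min_supporting_charges; one with a
        # gap needs an extra corroborating charge on top of the density bound
        eligible = (
            (support >= config.min_supporting_charges)
            & (
                (density >= 1.0)
                | (
                    (support >= config.min_supporting_charges + 1)
                    & (density >= config.min_support_density)
                )
            )
            & (top2_score >= config.min_run_coherence * np.maximum(total, 1e-300))
        )
        if not eligible.any():
            break
        masked = np.where(eligible, total, 0.0)

        def quick_score(m: float, data: np.ndarray) -> float:
            q = (m + z * PROTON_MASS) / z
            ok = (q >= lo_mz) & (q <= hi_mz)
            return float(np.interp(q[ok], mz, data, left=0.0, right=0.0).sum())

        j = -1
        for _attempt in range(20):
            j_try = int(np.argmax(masked))
            if masked[j_try] < threshold:
                break
            m_try = grid[j_try]
            # test against both the residual and the original spectrum: once a
            # weak parent's evidence is eroded by earlier subtractions, only
            # the original still shows that 2M/3M explained more intensity
            alias = max(
                max(quick_score(2 * m_try, w), quick_score(3 * m_try, w))
                / max(quick_score(m_try, w), 1e-300)
                for w in (work, work0)
            )
            if alias > config.alias_score_factor:
                # divisor alias of a larger (possibly sub-threshold) mass
                masked[max(0, j_try - 20) : j_try + 20] = 0.0
                continue
            j = j_try
            break
        if j < 0:
            break
        mass0 = _apex_centroid(grid, total, j)
        # precise mass: each supporting charge's measured apex position gives
        # an independent estimate M = z*c - z*proton; the amplitude-weighted
        # mean is much tighter than the coarse score-grid centroid and immune
        # to shoulders on the score ridge
        fits = _fit_envelope(mz, work, mass0, z, supported[:, j], lo_mz, hi_mz, sigma_factor)
        if fits:
            ests = np.array([zi * c_hat - zi * PROTON_MASS for zi, c_hat, _ in fits])
            mass = float(np.median(ests))  # robust to overlap-contaminated charges
        else:
            mass = mass0
        if any(abs(mass - p.neutral_mass) < 2.0 for p, _ in peaks):
            # residual re-detection of an already extracted mass: hard-zero its
            # envelope windows and move on
            _zero_envelope(work, mz, mass, z, lo_mz, hi_mz, sigma_factor, config.grid_step)
            s = score_matrix()
            total = s.sum(axis=0)
            continue
        # intensity measured on the *original* (preprocessed) spectrum so it
        # does not depend on extraction order when envelopes overlap
        peak = MassPeak(
            neutral_mass=mass,
            intensity=quick_score(mass, work0),
            rt_window=rt_window_label,
            apex_rt=spectrum.rt,
            n_charges_supporting=int(support[j]),
        )
        support_idx = _envelope_support_indices(mass, z, mz, lo_mz, hi_mz)
        peaks.append((peak, support_idx))
        # surgical subtraction: remove the fitted Gaussian (measured apex
        # position and amplitude, width from the configured resolution) at
        # each envelope charge, walking down the tails beyond the supporting
        # run while amplitudes keep decreasing.  Model subtraction (rather
        # than window zeroing) leaves a near-coincident peak of a *different*
        # species standing a few sigma away
        for zi, c_hat, amp in _fit_envelope(
            mz, work, mass, z, supported[:, j], lo_mz, hi_mz, sigma_factor, extend=True
        ):
            sigma = ((mass + zi * PROTON_MASS) / zi) * sigma_factor
            i0, i1 = np.searchsorted(mz, [c_hat - 5 * sigma, c_hat + 5 * sigma])
            x = mz[i0:i1]
            work[i0:i1] = np.maximum(
                work[i0:i1] - amp * np.exp(-0.5 * ((x - c_hat) / sigma) ** 2), 0.0
            )
        s = score_matrix()
        total = s.sum(axis=0)

    kept = _harmonic_filter(peaks, config)
    return sorted(kept, key=lambda p: -p.intensity)


def _support_density(supported: np.ndarray) -> np.ndarray:
    """Per grid mass: supporting-charge count divided by the length of the
    charge span they occupy (0 where nothing supports)."""
    nz, nm = supported.shape
    count = supported.sum(axis=0)
    first = np.argmax(supported, axis=0)
    last = nz - 1 - np.argmax(supported[::-1], axis=0)
    span = last - first + 1
    with np.errstate(invalid="ignore"):
        return np.where(count > 0, count / np.maximum(span, 1), 0.0)


def _top_two_run_scores(supported: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Per grid mass: summed score of the two highest-scoring runs of
    consecutive supporting charge states."""
    n = supported.shape[1]
    run_sum = np.zeros(n)
    best1 = np.zeros(n)
    best2 = np.zeros(n)

    def fold(ending):
        nonlocal best1, best2
        v = np.where(ending, run_sum, 0.0)
        gt1 = v > best1
        best2 = np.where(gt1, best1, np.maximum(best2, np.where(gt1, best2, v)))
        best1 = np.where(gt1, v, best1)

    for row, s_row in zip(supported, s):
        fold(~row & (run_sum > 0))
        run_sum = (run_sum + s_row) * row
    fold(run_sum > 0)
    return best1 + best2


def _apex_centroid(grid: np.ndarray, total: np.ndarray, j: int, max_half_pts: int = 100) -> float:
    """Apex refinement: intensity-weighted centroid of the score peak over its
    upper region (above 70% of the apex; robust on broad, gently noisy score
    peaks where a 3-point parabola jitters and shoulders drag a half-max
    centroid)."""
    half = 0.7 * total[j]
    lo = j
    while lo > 0 and j - lo < max_half_pts and total[lo - 1] > half:
        lo -= 1
    hi = j
    while hi < grid.size - 1 and hi - j < max_half_pts and total[hi + 1] > half:
        hi += 1
    w = total[lo : hi + 1] - half
    if w.sum() <= 0:
        return float(grid[j])
    return float(np.average(grid[lo : hi + 1], weights=w))


def _fit_envelope(
    mz: np.ndarray,
    work: np.ndarray,
    mass: float,
    z: np.ndarray,
    supported_col: np.ndarray,
    lo_mz: float,
    hi_mz: float,
    sigma_factor: float,
    extend: bool = False,
) -> list[tuple[int, float, float]]:
    """Measured apex position and amplitude for each envelope charge.

    Returns ``(z, refined position, amplitude)`` for charges in the main
    supporting run; with ``extend=True`` the run is walked outward down the
    envelope tails while a local peak with positive amplitude persists."""
    idx = np.flatnonzero(supported_col)
    if idx.size == 0:
        return []
    # keep only the longest consecutive stretch (the genuine envelope)
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    main = max(splits, key=len)
    charges = [int(z[i]) for i in main]
    if extend:
        # walk the *full physical charge ladder*, including charges outside
        # the configured scoring range — leaving low-charge peaks of a
        # low-mass species unsubtracted would let later chance alignments
        # assemble phantoms from them
        lo_z, hi_z = charges[0], charges[-1]
        for direction, start, edge in ((-1, lo_z - 1, lo_z), (+1, hi_z + 1, hi_z)):
            c_edge = (mass + edge * PROTON_MASS) / edge
            _, prev_amp = _refine_peak(mz, work, c_edge, c_edge * sigma_factor)
            zq = start
            while 1 <= zq <= 2 * int(z[-1]):
                c = (mass + zq * PROTON_MASS) / zq
                if not (lo_mz <= c <= hi_mz):
                    break
                _, amp = _refine_peak(mz, work, c, c * sigma_factor)
                # envelope tails decay monotonically; an amplitude jump means
                # we ran into a different species' peak — stop walking
                if amp <= 0 or amp > 1.3 * max(prev_amp, 1e-300):
                    break
                charges.append(zq)
                prev_amp = amp
                zq += direction
    out = []
    for zq in sorted(set(charges)):
        c = (mass + zq * PROTON_MASS) / zq
        if not (lo_mz <= c <= hi_mz):
            continue
        c_hat, amp = _refine_peak(mz, work, c, c * sigma_factor)
        if amp > 0:
            out.append((zq, c_hat, amp))
    return out


def _refine_peak(mz: np.ndarray, work: np.ndarray, c: float, sigma: float) -> tuple[float, float]:
    """Measured apex of the profile peak nearest the predicted position ``c``:
    find the strongest sample within +-2.5 sigma, then take the
    intensity-weighted centroid of the samples within +-1.2 sigma of it.
    Centering on the max (not on ``c``) keeps the estimate locked to the
    dominant peak when a weaker peak of another species sits a few sigma away
    in the same gated island."""
    i0, i1 = np.searchsorted(mz, [c - 2.5 * sigma, c + 2.5 * sigma])
    window = work[i0:i1]
    if window.size == 0 or not np.any(window > 0):
        return c, 0.0
    jm = i0 + int(np.argmax(window))
    amp = float(work[jm])
    centroid = float(mz[jm])
    # soft-window centroid iterated to its fixed point: the Gaussian window is
    # symmetric in m/z around the running estimate, so (unlike a hard sample
    # window) it carries no grid-phase truncation bias
    for _ in range(3):
        k0, k1 = np.searchsorted(mz, [centroid - 3 * sigma, centroid + 3 * sigma])
        x = mz[k0:k1]
        wgt = work[k0:k1] * np.exp(-0.5 * ((x - centroid) / (1.2 * sigma)) ** 2)
        if wgt.sum() <= 0:
            break
        centroid = float(np.average(x, weights=wgt))
    return centroid, amp


def _zero_envelope(work, mz, mass, z, lo_mz, hi_mz, sigma_factor, grid_step) -> None:
    for zi in z:
        c = (mass + zi * PROTON_MASS) / zi
        if not (lo_mz <= c <= hi_mz):
            continue
        half = 3.0 * c * sigma_factor + grid_step / z[0]
        i0, i1 = np.searchsorted(mz, [c - half, c + half])
        work[i0:i1] = 0.0


def _envelope_support_indices(mass, z, mz, lo_mz, hi_mz) -> np.ndarray:
    centers = (mass + z * PROTON_MASS) / z
    centers = centers[(centers >= lo_mz) & (centers <= hi_mz)]
    return np.unique(np.searchsorted(mz, centers))


def _harmonic_filter(
    peaks: list[tuple[MassPeak, np.ndarray]], config: DeconvConfig
) -> list[MassPeak]:
    """Drop a peak at M when a >= dominance x stronger peak at ~2M or ~M/2
    shares >= harmonic_share of its supporting m/z positions."""
    kept = []
    for p, support in peaks:
        doomed = False
        for q, q_support in peaks:
            if q is p or q.intensity < config.harmonic_dominance * p.intensity:
                continue
            ratio = q.neutral_mass / p.neutral_mass
            if not (abs(ratio - 2.0) < 0.01 or abs(ratio - 0.5) < 0.0025):
                continue
            shared = np.intersect1d(support, q_support).size
            if support.size and shared / support.size >= config.harmonic_share:
                doomed = True
                break
        if not doomed:
            kept.append(p)
    return kept


def deconvolve_run(
    run: Sequence[Spectrum],
    windows: Sequence[RTWindow],
    deconv_config: DeconvConfig = DeconvConfig(),
    preprocess_config: PreprocessConfig | None = PreprocessConfig(),
) -> list[MassPeak]:
    """Convenience pipeline: per RT window, sum scans, preprocess, deconvolve."""
    peaks: list[MassPeak] = []
    for window in windows:
        composite = sum_window(run, window)
        if preprocess_config is not None and composite.mode == "profile":
            composite = preprocess(composite, preprocess_config)
        peaks.extend(deconvolve(composite, deconv_config, rt_window_label=window.label))
    return peaks


PEAK_COLUMNS = ("neutral_mass", "intensity", "rt_window", "apex_rt", "n_charges_supporting")


def export_peaks(peaks: Sequence[MassPeak], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(PEAK_COLUMNS)
        for p in peaks:
            w.writerow(
                [
                    f"{p.neutral_mass:.4f}",
                    f"{p.intensity:.6g}",
                    p.rt_window,
                    f"{p.apex_rt:.4f}",
                    p.n_charges_supporting,
                ]
            )
    return path


def read_peaks(path: str | Path) -> list[MassPeak]:
    out = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                MassPeak(
                    neutral_mass=float(row["neutral_mass"]),
                    intensity=float(row["intensity"]),
                    rt_window=row["rt_window"],
                    apex_rt=float(row["apex_rt"]),
                    n_charges_supporting=int(row["n_charges_supporting"]),
                )
            )
    return out
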