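"""Synthetic-data generation: structures, sequences, kinetics and spectra.

Everything the pipeline consumes can be generated here with no external data:

* toy linker-payload structures (random trees with optional grafted rings)
  for exhaustive cleavage-enumeration oracles;
* antibody-like chain sequences of realistic length and mass;
* ground-truth biotransformation kinetics: per-payload thiosuccinimide
  hydrolysis and deconjugation-then-cysteinylation are independent
  first-order processes, so a chain with d payloads shows binomial
  hydrolysis-count fractions that drift toward complete hydrolysis over a
  multi-day PK time course;
* raw-style multi-charge electrospray spectra (Gaussian charge envelope of
  Gaussian profile peaks, plus baseline and detector noise) with an mzML
  writer, so the deconvolution module can be tested by round-trip.

All randomness flows through numpy Generators seeded explicitly; the same
seed reproduces identical arrays.
"""

from __future__ import annotations

import base64
import math
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import (
    HYDROLYSIS,
    Biotransformation,
    DeltaMassEntry,
)
from .deconvolution import Spectrum
from .masses import PROTON_MASS, Composition, formula_mass
from .proteoform import (
    CandidateConfig,
    ProteinChain,
    enumerate_candidates,
    format_label,
)

# ---------------------------------------------------------------------------
# toy structures for enumeration oracles
# ---------------------------------------------------------------------------

_TOY_ELEMENTS = (("C", 4), ("N", 3), ("O", 2))


def make_toy_linker_payload(n_heavy_atoms: int, seed: int) -> str:
    """Random valence-respecting tree of C/N/O atoms, optionally with one
    grafted ring, as MOL V2000 text.  Atom 1 (0-based index 0) is the
    attachment atom.  Used as fixture material for the brute-force cleavage
    oracle."""
    if not (3 <= n_heavy_atoms <= 12):
        raise ValueError("n_heavy_atoms must be in [3, 12]")
    rng = np.random.default_rng(seed)
    from rdkit import Chem

    mol = Chem.RWMol()
    valence = []
    degree = []
    # bias toward carbon for realistic trees
    weights = np.array([0.7, 0.15, 0.15])
    for i in range(n_heavy_atoms):
        sym, val = _TOY_ELEMENTS[rng.choice(3, p=weights)]
        mol.AddAtom(Chem.Atom(sym))
        valence.append(val)
        degree.append(0)
        if i > 0:
            open_atoms = [j for j in range(i) if degree[j] < valence[j]]
            if not open_atoms:  # all saturated: fall back to a fresh carbon root
                open_atoms = [0]
                valence[0] += 1  # cannot happen with C present; guard only
            j = int(rng.choice(open_atoms))
            mol.AddBond(i, j, Chem.BondType.SINGLE)
            degree[i] += 1
            degree[j] += 1
    if rng.random() < 0.5:  # graft a ring by closing one extra bond
        candidates = [
            (a, b)
            for a in range(n_heavy_atoms)
            for b in range(a + 1, n_heavy_atoms)
            if degree[a] < valence[a]
            and degree[b] < valence[b]
            and mol.GetBondBetweenAtoms(a, b) is None
        ]
        if candidates:
            a, b = candidates[int(rng.integers(len(candidates)))]
            mol.AddBond(a, b, Chem.BondType.SINGLE)
    m = mol.GetMol()
    Chem.SanitizeMol(m)
    return Chem.MolToMolBlock(m)


# ---------------------------------------------------------------------------
# synthetic antibody chains
# ---------------------------------------------------------------------------

_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
# rough natural amino-acid frequencies (order as _AA_ALPHABET)
_AA_FREQ = np.array(
    [8.3, 1.4, 5.5, 6.8, 3.9, 7.1, 2.3, 6.0, 5.8, 9.7, 2.4, 4.1, 4.7, 3.9, 5.5, 6.6, 5.3, 6.9, 1.1, 3.0]
)
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()


def synthetic_chain(
    chain_id: str,
    length: int,
    seed: int,
    n_intrachain_disulfides: int | None = None,
    n_conjugation_sites: int | None = None,
) -> ProteinChain:
    """Deterministic pseudo-random chain with natural residue frequencies.

    Defaults follow the IgG1/DAR8 convention: LC gets 2 intrachain
    disulfides and 1 conjugation site, HC gets 4 and 3.
    """
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(_AA_ALPHABET), size=length, p=_AA_FREQ))
    defaults = {"LC": (2, 1), "HC": (4, 3)}.get(chain_id.upper(), (0, 0))
    return ProteinChain(
        chain_id=chain_id,
        sequence=seq,
        n_intrachain_disulfides=(
            defaults[0] if n_intrachain_disulfides is None else n_intrachain_disulfides
        ),
        n_conjugation_sites=(
            defaults[1] if n_conjugation_sites is None else n_conjugation_sites
        ),
    )


# ---------------------------------------------------------------------------
# biotransformation kinetics
# ---------------------------------------------------------------------------


def hydrolysis_probability(k_per_hour: float, t_hours: float) -> float:
    """First-order per-site conversion probability, 1 - exp(-k t)."""
    if k_per_hour < 0 or t_hours < 0:
        raise ValueError("rate and time must be non-negative")
    return 1.0 - math.exp(-k_per_hour * t_hours)


def species_state_fractions(
    n_sites: int, p_hydrolysis: float, p_deconjugation: float
) -> dict[tuple[int, int], float]:
    """Fractions of chain states keyed by (payloads lost, payloads hydrolysed).

    Each of the ``n_sites`` payloads independently either deconjugates (and
    the exposed thiol is cysteinylated) with probability ``p_deconjugation``
    or, if retained, is hydrolysed with probability ``p_hydrolysis``.
    Fractions sum to 1.
    """
    out: dict[tuple[int, int], float] = {}
    q = p_deconjugation
    for n_lost in range(n_sites + 1):
        p_lost = math.comb(n_sites, n_lost) * q**n_lost * (1 - q) ** (n_sites - n_lost)
        retained = n_sites - n_lost
        for n_hyd in range(retained + 1):
            p_hyd = (
                math.comb(retained, n_hyd)
                * p_hydrolysis**n_hyd
                * (1 - p_hydrolysis) ** (retained - n_hyd)
            )
            out[(n_lost, n_hyd)] = out.get((n_lost, n_hyd), 0.0) + p_lost * p_hyd
    return out


def hydrolysis_entry(parent_mass_pair: tuple[float, float] = (0.0, 0.0)) -> DeltaMassEntry:
    """Library entry for thiosuccinimide hydrolysis on the intact conjugate."""
    return modification_entry(HYDROLYSIS, parent_mass_pair)


def modification_entry(
    mod: Biotransformation, parent_mass_pair: tuple[float, float] = (0.0, 0.0)
) -> DeltaMassEntry:
    mono, avg = parent_mass_pair
    return DeltaMassEntry(
        name=mod.name,
        source_cleavage=None,
        mods=(mod,),
        neutral_mono_mass=mono + mod.mono_delta,
        neutral_avg_mass=avg + mod.avg_delta,
        delta_formula=Composition(mod.formula_delta),
    )


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpectrumSimConfig:
    mz_range: tuple[float, float] = (1000.0, 5000.0)
    mz_step: float = 0.05
    resolution: float = 10_000.0  # FWHM resolving power
    target_mz: float = 2200.0  # envelope centre; z0 ~ mass / target_mz
    z_sigma_frac: float = 0.15  # charge-envelope width, fraction of z0
    charge_range: tuple[int, int] = (10, 60)
    snr: float = 20.0  # reference signal height / noise sigma
    #: 'min_species' guarantees every simulated species meets ``snr`` (its
    #: tallest peak is snr x noise sigma); 'max_signal' references the tallest
    #: peak in the whole spectrum (stationary detector noise)
    snr_reference: str = "min_species"
    baseline_level: float = 0.5  # absolute flat baseline, a.u.
    abundance_scale: float = 100.0  # peak-height units per unit abundance


def simulate_spectrum(
    species_masses: Sequence[float],
    abundances: Sequence[float],
    config: SpectrumSimConfig = SpectrumSimConfig(),
    seed: int | np.random.Generator = 0,
    rt: float = 0.0,
) -> Spectrum:
    """Profile spectrum of multiply protonated species.

    Each species contributes a Gaussian envelope over charge states centred
    at ``z0 = mass / target_mz`` with width ``z_sigma_frac * z0``, each charge
    state a Gaussian m/z peak of width set by ``resolution``.  A flat baseline
    and additive Gaussian noise (sigma = max signal / snr) are applied;
    intensities are clipped at zero.  Deterministic for a given seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = config.mz_range
    grid = np.arange(lo, hi + config.mz_step, config.mz_step)
    signal = np.zeros_like(grid)
    zmin, zmax = config.charge_range
    species_heights: list[float] = []
    for mass, abundance in zip(species_masses, abundances):
        if abundance <= 0:
            continue
        z0 = mass / config.target_mz
        sigma_z = max(1.5, config.z_sigma_frac * z0)
        z_lo = max(zmin, int(math.floor(z0 - 3 * sigma_z)))
        z_hi = min(zmax, int(math.ceil(z0 + 3 * sigma_z)))
        if z_lo > z_hi:
            continue
        zs = np.arange(z_lo, z_hi + 1)
        w = np.exp(-0.5 * ((zs - z0) / sigma_z) ** 2)
        w /= w.sum()
        species_heights.append(abundance * config.abundance_scale * float(w.max()))
        for z, wz in zip(zs, w):
            c = (mass + z * PROTON_MASS) / z
            if not (lo <= c <= hi):
                continue
            sigma = c / config.resolution / 2.3548
            i0, i1 = np.searchsorted(grid, [c - 5 * sigma, c + 5 * sigma])
            x = grid[i0:i1]
            signal[i0:i1] += (
                abundance * config.abundance_scale * wz
                * np.exp(-0.5 * ((x - c) / sigma) ** 2)
            )
    if config.snr_reference == "min_species":
        ref_height = min(species_heights) if species_heights else 0.0
    elif config.snr_reference == "max_signal":
        ref_height = float(signal.max())
    else:
        raise ValueError(f"unknown snr_reference {config.snr_reference!r}")
    intensity = signal + config.baseline_level
    if ref_height > 0 and config.snr > 0:
        intensity = intensity + rng.normal(0.0, ref_height / config.snr, size=grid.size)
    return Spectrum(rt=rt, mz=grid, intensity=np.maximum(intensity, 0.0), mode="profile")


# ---------------------------------------------------------------------------
# mzML writing (minimal standard subset: 64-bit floats, no compression)
# ---------------------------------------------------------------------------


def _b64_doubles(values: np.ndarray) -> str:
    raw = struct.pack(f"<{values.size}d", *np.asarray(values, dtype=float))
    return base64.b64encode(raw).decode("ascii")


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum"/>
    </fileContent>
  </fileDescription>
  <run id="simulated_run">
    <spectrumList count="{count}">
"""

_MZML_SPECTRUM = """      <spectrum index="{index}" id="scan={scan}" defaultArrayLength="{npts}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="{mode_acc}" name="{mode_name}"/>
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def write_mzml(spectra: Sequence[Spectrum], path: str | Path) -> Path:
    """Write scans as minimal standards-conformant mzML (readable by the
    pyteomics mzML parser)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(_MZML_HEADER.format(count=len(spectra)))
        for i, s in enumerate(sorted(spectra, key=lambda x: x.rt)):
            mz_b64 = _b64_doubles(s.mz)
            int_b64 = _b64_doubles(s.intensity)
            mode_acc, mode_name = (
                ("MS:1000128", "profile spectrum")
                if s.mode == "profile"
                else ("MS:1000127", "centroid spectrum")
            )
            fh.write(
                _MZML_SPECTRUM.format(
                    index=i,
                    scan=i + 1,
                    npts=s.mz.size,
                    rt=f"{s.rt:.6f}",
                    mode_acc=mode_acc,
                    mode_name=mode_name,
                    mz_len=len(mz_b64),
                    mz_b64=mz_b64,
                    int_len=len(int_b64),
                    int_b64=int_b64,
                )
            )
        fh.write(_MZML_FOOTER)
    return path


# ---------------------------------------------------------------------------
# full PK scenarios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimScenario:
    """Study conditions for an end-to-end simulated PK experiment.

    Defaults emulate a DAR8 cysteine-conjugated ADC monitored over a two-week
    PK time course: per-payload hydrolysis rate chosen so hydrolysis is
    essentially complete by ~120 h, a slower deconjugation/cysteinylation
    channel, three biological replicates and 10% multiplicative abundance
    noise.
    """

    chains: tuple[ProteinChain, ...]
    conjugate_mass_pair: tuple[float, float]
    chain_glycans: Mapping[str, str] = field(default_factory=lambda: {"LC": "none", "HC": "G0F"})
    chain_rt: Mapping[str, float] = field(default_factory=lambda: {"LC": 1.9, "HC": 4.5})
    k_hydrolysis: float = 0.03  # per hour; ~97% converted by 120 h
    k_deconjugation: float = 0.001  # per hour
    time_points_h: tuple[float, ...] = (1.0, 24.0, 72.0, 120.0, 168.0, 336.0)
    n_subjects: int = 3
    abundance_cv: float = 0.10
    #: PK samples carry species spanning orders of magnitude in abundance, so
    #: detector noise references the strongest signal (stationary noise);
    #: minor species below the noise floor are genuinely undetectable
    spectrum: SpectrumSimConfig = SpectrumSimConfig(snr_reference="max_signal")


def default_scenario(
    conjugate_mass_pair: tuple[float, float] | None = None, **overrides
) -> SimScenario:
    """Scenario with synthetic LC (~23 kDa) and HC (~50 kDa) chains and the
    bundled synthetic PBD-dimer linker-payload as the conjugate."""
    if conjugate_mass_pair is None:
        from .structures import synthetic_pbd_linker_payload

        parent = synthetic_pbd_linker_payload().formula
        conjugate_mass_pair = (
            formula_mass(parent, "monoisotopic"),
            formula_mass(parent, "average"),
        )
    chains = (
        synthetic_chain("LC", 214, seed=20_240_101),
        synthetic_chain("HC", 447, seed=20_240_102),
    )
    return SimScenario(
        chains=chains, conjugate_mass_pair=conjugate_mass_pair, **overrides
    )


def simulate_species(scenario: SimScenario, t_hours: float) -> pd.DataFrame:
    """Deterministic ground-truth species fractions at one time point.

    Returns one row per chain species: chain, species label (matching the
    proteoform module's canonical labels), fraction, and theoretical masses.
    """
    p_h = hydrolysis_probability(scenario.k_hydrolysis, t_hours)
    p_d = hydrolysis_probability(scenario.k_deconjugation, t_hours)
    rows = []
    for chain in scenario.chains:
        glycan = scenario.chain_glycans.get(chain.chain_id, "none")
        masses = _species_mass_table(chain, scenario.conjugate_mass_pair, glycan)
        for (n_lost, n_hyd), frac in sorted(
            species_state_fractions(chain.n_conjugation_sites, p_h, p_d).items()
        ):
            dar = chain.n_conjugation_sites - n_lost
            label = format_label(
                chain.chain_id, dar, glycan, n_lost, ["hydrolysis"] * n_hyd
            )
            mono, avg = masses[label]
            rows.append(
                {
                    "chain": chain.chain_id,
                    "species": label,
                    "dar": dar,
                    "n_hydrolysis": n_hyd,
                    "n_cys": n_lost,
                    "fraction": frac,
                    "theo_mono_mass": mono,
                    "theo_avg_mass": avg,
                }
            )
    return pd.DataFrame(rows)


def _species_mass_table(
    chain: ProteinChain,
    conjugate_mass_pair: tuple[float, float],
    glycan: str,
) -> dict[str, tuple[float, float]]:
    cands = enumerate_candidates(
        chain,
        conjugate_mass_pair,
        [hydrolysis_entry(conjugate_mass_pair)],
        CandidateConfig(
            dar_range=tuple(range(chain.n_conjugation_sites + 1)),
            glycans=(glycan,),
        ),
    )
    return {c.label: (c.theo_mono_mass, c.theo_avg_mass) for c in cands}


@dataclass
class SimulatedStudy:
    scenario: SimScenario
    runs: dict[str, list[Spectrum]]  # sample_id -> scans
    manifest: pd.DataFrame  # sample_id, subject, time_h
    truth: pd.DataFrame  # per sample x species ground-truth fractions


def simulate_scenario(scenario: SimScenario, seed: int = 0) -> SimulatedStudy:
    """Simulate the full study: per (subject, time point) sample, per-chain
    species abundances with multiplicative replicate noise, and raw-style
    scans around each chain's elution time (apex plus flanking scans)."""
    root = np.random.default_rng(seed)
    runs: dict[str, list[Spectrum]] = {}
    manifest_rows = []
    truth_frames = []
    for subject in range(1, scenario.n_subjects + 1):
        for t in scenario.time_points_h:
            sample_id = f"s{subject}_t{t:g}h"
            rng = np.random.default_rng(root.integers(2**31 - 1))
            species = simulate_species(scenario, t).copy()
            noise = rng.lognormal(
                mean=0.0, sigma=scenario.abundance_cv, size=len(species)
            )
            species["abundance"] = species["fraction"] * noise
            scans: list[Spectrum] = []
            for chain in scenario.chains:
                sub = species[species["chain"] == chain.chain_id]
                rt0 = scenario.chain_rt.get(chain.chain_id, 2.0)
                for drt, weight in ((-0.15, 0.5), (0.0, 1.0), (0.15, 0.5)):
                    scans.append(
                        simulate_spectrum(
                            sub["theo_avg_mass"].to_numpy(),
                            (sub["abundance"] * weight).to_numpy(),
                            scenario.spectrum,
                            seed=rng,
                            rt=rt0 + drt,
                        )
                    )
            runs[sample_id] = sorted(scans, key=lambda s: s.rt)
            manifest_rows.append(
                {"sample_id": sample_id, "subject": f"subj{subject}", "time_h": t}
            )
            species.insert(0, "sample_id", sample_id)
            species.insert(1, "subject", f"subj{subject}")
            species.insert(2, "time_h", t)
            truth_frames.append(species)
    return SimulatedStudy(
        scenario=scenario,
        runs=runs,
        manifest=pd.DataFrame(manifest_rows),
        truth=pd.concat(truth_frames, ignore_index=True),
    )
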