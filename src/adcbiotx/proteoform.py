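"""Theoretical proteoform masses for conjugated antibody chains.

For a DAR8 cysteine-conjugated ADC the interchain disulfides are repurposed as
conjugation sites, so under acid elution the light chain (up to 1 payload) and
heavy chain (up to 3 payloads) are analysed separately.  A proteoform
candidate is a chain plus: fixed terminal modifications (C-terminal lysine
loss, N-terminal pyroglutamate), an N-glycan, a payload count (DAR), optional
cysteinylation caps on unoccupied conjugation sites, and per-payload
linker-payload modifications drawn from the delta-mass library (hydrolysis,
partial cleavages, ...).  Candidate masses are fully additive and are emitted
on both the monoisotopic and average scales; intact deconvolution at
20-80 kDa is isotopically unresolved, so matching normally uses the average
scale.
"""

from __future__ import annotations

import csv
import itertools
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from pyteomics import mass as _pmass

from .chem import DeltaMassEntry
from .masses import Composition, formula_mass

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Net addition for cysteinylation of a free thiol (disulfide-linked cysteine).
CYSTEINYLATION_FORMULA = "C3H5NO2S"

#: Common IgG N-glycans as monosaccharide-residue compositions.
GLYCAN_COMPOSITIONS: dict[str, dict[str, int]] = {
    "none": {},
    "G0": {"HexNAc": 4, "Hex": 3},
    "G0F": {"HexNAc": 4, "Hex": 3, "Fuc": 1},
    "G1F": {"HexNAc": 4, "Hex": 4, "Fuc": 1},
    "G2F": {"HexNAc": 4, "Hex": 5, "Fuc": 1},
    "Man5": {"HexNAc": 2, "Hex": 5},
}

_MONOSACCHARIDE_FORMULAS = {
    "HexNAc": "C8H13NO5",
    "Hex": "C6H10O5",
    "Fuc": "C6H10O4",
}


@dataclass(frozen=True)
class ProteinChain:
    """An antibody chain: sequence plus structural bookkeeping.

    ``n_conjugation_sites`` counts reduced interchain cysteines available for
    payload conjugation or cysteinylation (1 for LC, 3 for HC of a DAR8
    cysteine conjugate); ``n_intrachain_disulfides`` follow IgG1 convention
    (LC 2, HC 4) and subtract two hydrogens each.
    """

    chain_id: str
    sequence: str
    n_intrachain_disulfides: int = 0
    n_conjugation_sites: int = 0

    def __post_init__(self):
        bad = [
            (i, aa) for i, aa in enumerate(self.sequence) if aa not in STANDARD_AA
        ]
        if bad:
            i, aa = bad[0]
            raise ValueError(
                f"invalid residue {aa!r} at position {i + 1} of chain {self.chain_id}"
            )
        if self.n_intrachain_disulfides < 0 or self.n_conjugation_sites < 0:
            raise ValueError("counts must be non-negative")


def chain_mass(chain: ProteinChain, mode: str = "monoisotopic") -> float:
    """Neutral mass of the reduced-terminus chain: residue masses + one water
    minus 2 H per intrachain disulfide."""
    m = _pmass.calculate_mass(sequence=chain.sequence, average=(mode == "average"))
    return m - chain.n_intrachain_disulfides * formula_mass("H2", mode)


def apply_fixed_mods(
    chain: ProteinChain,
    mode: str = "monoisotopic",
    c_term_lysine_loss: bool = True,
    pyroglutamate: bool = True,
) -> float:
    """Mass delta from the common fixed antibody modifications.

    C-terminal lysine clipping removes one lysine residue; an N-terminal
    glutamine cyclises to pyroglutamate with loss of NH3.  Both fire only when
    the sequence permits, and both deltas stack.
    """
    delta = 0.0
    if c_term_lysine_loss and chain.sequence.endswith("K"):
        delta -= _pmass.calculate_mass(
            composition=_pmass.std_aa_comp["K"], average=(mode == "average")
        )
    if pyroglutamate and chain.sequence.startswith("Q"):
        delta -= formula_mass("NH3", mode)
    return delta


def glycan_composition(glycan_name: str) -> Composition:
    if glycan_name not in GLYCAN_COMPOSITIONS:
        raise ValueError(
            f"unknown glycan {glycan_name!r}; known: {sorted(GLYCAN_COMPOSITIONS)}"
        )
    total = Composition()
    for sugar, n in GLYCAN_COMPOSITIONS[glycan_name].items():
        for _ in range(n):
            total += Composition(formula=_MONOSACCHARIDE_FORMULAS[sugar])
    return total


def glycan_mass(glycan_name: str, mode: str = "monoisotopic") -> float:
    """Net mass addition of an N-glycan (residue compositions; the glycosidic
    water is already accounted for, e.g. G0F adds 1444.5339 Da monoisotopic)."""
    return formula_mass(glycan_composition(glycan_name), mode)


# ---------------------------------------------------------------------------
# candidate enumeration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CandidateConfig:
    """Bounds and switches for proteoform candidate enumeration."""

    dar_range: tuple[int, ...] = (0, 1, 2, 3)
    glycans: tuple[str, ...] = ("none",)
    allow_cysteinylation: bool = True
    c_term_lysine_loss: bool = True
    pyroglutamate: bool = True
    #: at most this many payloads per candidate may carry a library entry
    max_modified_payloads: int | None = None
    #: model two adjacent free thiols closing an intrachain bridge (-2H)
    allow_thiol_bridge: bool = False
    max_candidates: int = 200_000


@dataclass(frozen=True)
class ProteoformCandidate:
    chain_id: str
    dar: int
    glycan: str
    caps: int
    conjugate_mods: tuple[str, ...]  # sorted multiset of library-entry names
    theo_mono_mass: float
    theo_avg_mass: float
    label: str
    bridge: bool = False


def format_label(
    chain_id: str,
    dar: int,
    glycan: str,
    caps: int,
    mods: Sequence[str],
    bridge: bool = False,
) -> str:
    """Canonical human-readable proteoform label, e.g.
    ``"HC + 2PL + 1Cys + 1H2O + G0F"``.  Hydrolysis renders as ``kH2O``;
    other library entries as ``k×[entry name]``."""
    parts = [chain_id]
    if dar:
        parts.append(f"{dar}PL")
    if caps:
        parts.append(f"{caps}Cys")
    if bridge:
        parts.append("bridge")
    counted: dict[str, int] = {}
    for m in mods:
        counted[m] = counted.get(m, 0) + 1
    for name in sorted(counted):
        k = counted[name]
        if name == "hydrolysis":
            parts.append(f"{k}H2O")
        else:
            parts.append(f"{k}×[{name}]")
    if glycan != "none":
        parts.append(glycan)
    return " + ".join(parts)


_LABEL_PART = re.compile(
    r"^(?:(?P<dar>\d+)PL|(?P<caps>\d+)Cys|(?P<hyd>\d+)H2O"
    r"|(?P<k>\d+)×\[(?P<name>.+)\]|(?P<bridge>bridge)|(?P<glycan>\w+))$"
)


def parse_label(label: str) -> dict:
    """Invert :func:`format_label` (used to audit label uniqueness)."""
    parts = label.split(" + ")
    out = {
        "chain_id": parts[0],
        "dar": 0,
        "caps": 0,
        "glycan": "none",
        "mods": [],
        "bridge": False,
    }
    for part in parts[1:]:
        m = _LABEL_PART.match(part)
        if not m:
            raise ValueError(f"unparseable label part {part!r} in {label!r}")
        if m.group("dar"):
            out["dar"] = int(m.group("dar"))
        elif m.group("caps"):
            out["caps"] = int(m.group("caps"))
        elif m.group("hyd"):
            out["mods"] += ["hydrolysis"] * int(m.group("hyd"))
        elif m.group("k"):
            out["mods"] += [m.group("name")] * int(m.group("k"))
        elif m.group("bridge"):
            out["bridge"] = True
        else:
            out["glycan"] = m.group("glycan")
    out["mods"] = sorted(out["mods"])
    return out


class CombinatorialBoundError(RuntimeError):
    pass


def enumerate_candidates(
    chain: ProteinChain,
    parent_conjugate_mass_pair: tuple[float, float],
    delta_library: Sequence[DeltaMassEntry] = (),
    config: CandidateConfig = CandidateConfig(),
) -> list[ProteoformCandidate]:
    """Cartesian enumeration of proteoform candidates for one chain.

    Payloads are indistinguishable: per-payload states (intact conjugate or
    one delta-library entry) are enumerated as multisets, so a DAR-3 chain
    with a hydrolysis-only library yields the 0-3 x H2O ladder.  Unoccupied
    conjugation sites may be cysteinylated (0..sites-dar caps).  Candidates
    are deduplicated by label and sorted by theoretical mass.

    Raises :class:`CombinatorialBoundError` when the candidate count would
    exceed ``config.max_candidates`` (restrict ``dar_range`` or the library).
    """
    conj_mono, conj_avg = parent_conjugate_mass_pair
    sites = chain.n_conjugation_sites
    dars = sorted({d for d in config.dar_range if 0 <= d <= sites})
    n_states = 1 + len(delta_library)

    est = 0
    for d in dars:
        caps_opts = (sites - d + 1) if config.allow_cysteinylation else 1
        est += math.comb(n_states + d - 1, d) * caps_opts * len(config.glycans)
    if est > config.max_candidates:
        raise CombinatorialBoundError(
            f"~{est} candidates would exceed the bound of {config.max_candidates}; "
            "restrict dar_range, the glycan set or the delta library"
        )

    base_mono = chain_mass(chain, "monoisotopic") + apply_fixed_mods(
        chain, "monoisotopic", config.c_term_lysine_loss, config.pyroglutamate
    )
    base_avg = chain_mass(chain, "average") + apply_fixed_mods(
        chain, "average", config.c_term_lysine_loss, config.pyroglutamate
    )
    cys_mono = formula_mass(CYSTEINYLATION_FORMULA, "monoisotopic")
    cys_avg = formula_mass(CYSTEINYLATION_FORMULA, "average")

    by_label: dict[str, ProteoformCandidate] = {}
    states: list[DeltaMassEntry | None] = [None, *delta_library]
    for dar in dars:
        for assignment in itertools.combinations_with_replacement(states, dar):
            mods = [e for e in assignment if e is not None]
            if (
                config.max_modified_payloads is not None
                and len(mods) > config.max_modified_payloads
            ):
                continue
            mod_mono = sum(e.mono_delta_vs_parent for e in mods)
            mod_avg = sum(e.avg_delta_vs_parent for e in mods)
            mod_names = sorted(e.name for e in mods)
            caps_options = (
                range(sites - dar + 1) if config.allow_cysteinylation else (0,)
            )
            for caps in caps_options:
                bridge_options = (False, True) if (
                    config.allow_thiol_bridge and sites - dar - caps >= 2
                ) else (False,)
                for bridge in bridge_options:
                    for glycan in config.glycans:
                        gly_mono = glycan_mass(glycan, "monoisotopic")
                        gly_avg = glycan_mass(glycan, "average")
                        bridge_mono = -formula_mass("H2", "monoisotopic") if bridge else 0.0
                        bridge_avg = -formula_mass("H2", "average") if bridge else 0.0
                        label = format_label(
                            chain.chain_id, dar, glycan, caps, mod_names, bridge
                        )
                        cand = ProteoformCandidate(
                            chain_id=chain.chain_id,
                            dar=dar,
                            glycan=glycan,
                            caps=caps,
                            conjugate_mods=tuple(mod_names),
                            theo_mono_mass=base_mono
                            + dar * conj_mono
                            + mod_mono
                            + caps * cys_mono
                            + gly_mono
                            + bridge_mono,
                            theo_avg_mass=base_avg
                            + dar * conj_avg
                            + mod_avg
                            + caps * cys_avg
                            + gly_avg
                            + bridge_avg,
                            label=label,
                            bridge=bridge,
                        )
                        by_label.setdefault(label, cand)
    return sorted(by_label.values(), key=lambda c: (c.theo_avg_mass, c.label))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

CANDIDATE_COLUMNS = (
    "label",
    "chain",
    "dar",
    "glycan",
    "caps",
    "mods",
    "theo_mono_mass",
    "theo_avg_mass",
)

_CHAIN_DEFAULTS = {"LC": (2, 1), "HC": (4, 3)}  # (disulfides, conjugation sites)


def read_chains_fasta(path: str | Path) -> list[ProteinChain]:
    """Read chains from FASTA.  The record id is the chain id; optional
    ``disulfides=N`` / ``sites=N`` tokens in the description override the
    IgG1/DAR8 defaults (LC: 2 disulfides, 1 site; HC: 4 disulfides, 3 sites).
    """
    from Bio import SeqIO

    chains = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ds, sites = _CHAIN_DEFAULTS.get(rec.id.upper(), (0, 0))
        for token in rec.description.split():
            if token.startswith("disulfides="):
                ds = int(token.split("=", 1)[1])
            elif token.startswith("sites="):
                sites = int(token.split("=", 1)[1])
        chains.append(
            ProteinChain(
                chain_id=rec.id,
                sequence=str(rec.seq).upper(),
                n_intrachain_disulfides=ds,
                n_conjugation_sites=sites,
            )
        )
    if not chains:
        raise ValueError(f"no FASTA records in {path}")
    return chains


def export_candidates(
    candidates: Sequence[ProteoformCandidate], path: str | Path
) -> Path:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(CANDIDATE_COLUMNS)
        for c in candidates:
            w.writerow(
                [
                    c.label,
                    c.chain_id,
                    c.dar,
                    c.glycan,
                    c.caps,
                    ";".join(c.conjugate_mods),
                    f"{c.theo_mono_mass:.6f}",
                    f"{c.theo_avg_mass:.6f}",
                ]
            )
    return path


def read_candidates(path: str | Path) -> list[ProteoformCandidate]:
    out = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                ProteoformCandidate(
                    chain_id=row["chain"],
                    dar=int(row["dar"]),
                    glycan=row["glycan"],
                    caps=int(row["caps"]),
                    conjugate_mods=tuple(
                        m for m in row["mods"].split(";") if m
                    ),
                    theo_mono_mass=float(row["theo_mono_mass"]),
                    theo_avg_mass=float(row["theo_avg_mass"]),
                    label=row["label"],
                )
            )
    return out
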