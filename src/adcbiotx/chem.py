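"""Linker-payload biotransformation delta-mass library.

The first half of the pipeline: take the linker-payload structure of an
antibody-drug conjugate (ADC), enumerate the plausible in-vivo cleavage
products under simple constraints (at most ``max_bonds`` simultaneous bond
breaks, never inside a ring, and only fragments still attached to the antibody
through the conjugation site are kept), then combine each cleavage with small
chemical modifications (thiosuccinimide hydrolysis, oxidative deamidation to
the alcohol, and their combination) into a flat library of named delta masses
relative to the parent conjugate.  Downstream, deconvoluted intact-mass peaks
are matched against proteoform candidates built from this library.

Structures are read with RDKit; ring membership is decided by an any-cycle
(bridge) test on the heavy-atom graph, and each broken-bond stub on the
retained fragment is capped with one hydrogen by default.
"""

from __future__ import annotations

import csv
import itertools
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
from rdkit import Chem
from rdkit import RDLogger

from .masses import Composition, format_formula, formula_mass, parse_formula

log = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

#: SMARTS for the maleimide conjugation site; the mapped atom (:1) is one of
#: the alkene carbons that becomes the cysteine attachment point.
MALEIMIDE_SMARTS = "[#6:1]1=[#6]C(=O)[#7]C1=O"


class StructureParseError(ValueError):
    """Raised when a MOL/SDF block cannot be parsed."""


class AttachmentError(ValueError):
    """Raised when the attachment spec matches zero or several atoms."""


@dataclass(frozen=True)
class MolecularGraph:
    """Heavy-atom graph of a linker-payload with one marked conjugation site.

    ``atoms`` holds ``(element symbol, implicit H count, formal charge)``;
    ``bonds`` holds ``(i, j, bond order, is_ring)`` with ``is_ring`` true iff
    the bond lies on at least one cycle.
    """

    atoms: tuple[tuple[str, int, int], ...]
    bonds: tuple[tuple[int, int, float, bool], ...]
    attachment_atom: int

    def __post_init__(self):
        n = len(self.atoms)
        if not (0 <= self.attachment_atom < n):
            raise ValueError("attachment_atom out of range")
        g = self.to_networkx()
        if n > 1 and not nx.is_connected(g):
            raise ValueError("molecular graph must be connected")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.atoms)))
        g.add_edges_from((i, j) for i, j, _, _ in self.bonds)
        return g

    @property
    def formula(self) -> Composition:
        """Elemental formula including implicit hydrogens."""
        return _atoms_formula(self.atoms, range(len(self.atoms)))

    def atom_formula(self, indices: Iterable[int]) -> Composition:
        return _atoms_formula(self.atoms, indices)


def _atoms_formula(atoms, indices) -> Composition:
    comp = Composition()
    for i in indices:
        symbol, n_h, _charge = atoms[i]
        comp[symbol] += 1
        if n_h:
            comp["H"] += n_h
    return Composition({e: n for e, n in comp.items() if n})


def _ring_bond_flags(n_atoms: int, edges: Sequence[tuple[int, int]]) -> list[bool]:
    """A bond is a ring bond iff it is not a bridge of the graph."""
    g = nx.Graph()
    g.add_nodes_from(range(n_atoms))
    g.add_edges_from(edges)
    bridges = {frozenset(e) for e in nx.bridges(g)}
    return [frozenset(e) not in bridges for e in edges]


def graph_from_rdkit(mol: Chem.Mol, attachment_atom: int) -> MolecularGraph:
    """Build a :class:`MolecularGraph` from a sanitized RDKit molecule."""
    atoms = tuple(
        (a.GetSymbol(), a.GetTotalNumHs(), a.GetFormalCharge())
        for a in mol.GetAtoms()
    )
    edges = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    ring = _ring_bond_flags(len(atoms), edges)
    bonds = tuple(
        (i, j, b.GetBondTypeAsDouble(), r)
        for (i, j), b, r in zip(edges, mol.GetBonds(), ring)
    )
    return MolecularGraph(atoms=atoms, bonds=bonds, attachment_atom=attachment_atom)


def _resolve_attachment(mol: Chem.Mol, attachment_spec) -> int:
    if isinstance(attachment_spec, int):
        if not (0 <= attachment_spec < mol.GetNumAtoms()):
            raise AttachmentError(
                f"attachment atom index {attachment_spec} out of range "
                f"(molecule has {mol.GetNumAtoms()} atoms)"
            )
        return attachment_spec
    pattern = Chem.MolFromSmarts(str(attachment_spec))
    if pattern is None:
        raise AttachmentError(f"invalid SMARTS pattern: {attachment_spec!r}")
    mapped = [a.GetIdx() for a in pattern.GetAtoms() if a.GetAtomMapNum()]
    if len(mapped) > 1:
        raise AttachmentError("attachment SMARTS must map at most one atom")
    query_idx = mapped[0] if mapped else 0
    if not mapped and pattern.GetNumAtoms() > 1:
        raise AttachmentError(
            "multi-atom attachment SMARTS must carry exactly one mapped atom"
        )
    hits = {match[query_idx] for match in mol.GetSubstructMatches(pattern)}
    if len(hits) != 1:
        raise AttachmentError(
            f"attachment pattern matched {len(hits)} atoms; need exactly 1"
        )
    return hits.pop()


def parse_structure(molfile_text: str, attachment_spec) -> MolecularGraph:
    """Parse a MOL V2000 / single-record SDF block and mark the conjugation site.

    ``attachment_spec`` is a 0-based atom index or a SMARTS pattern whose
    single mapped atom identifies the site (e.g. :data:`MALEIMIDE_SMARTS`).

    Raises :class:`StructureParseError` for malformed input or a disconnected
    structure and :class:`AttachmentError` for an ambiguous attachment spec.
    """
    lines = molfile_text.splitlines()
    if len(lines) < 4:
        raise StructureParseError(
            f"MOL block too short ({len(lines)} lines; header needs 4)"
        )
    try:
        int(lines[3][0:3]), int(lines[3][3:6])
    except (ValueError, IndexError):
        raise StructureParseError(
            "line 4: malformed counts line (expected V2000 atom/bond counts)"
        ) from None
    mol = Chem.MolFromMolBlock(molfile_text, sanitize=True, removeHs=True)
    if mol is None:
        raise StructureParseError("RDKit could not parse/sanitize the MOL block")
    if len(Chem.GetMolFrags(mol)) > 1:
        raise StructureParseError("structure is disconnected")
    return graph_from_rdkit(mol, _resolve_attachment(mol, attachment_spec))


def parse_smiles(smiles: str, attachment_spec) -> MolecularGraph:
    """Convenience: build the graph from a SMILES string instead of MOL text."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureParseError(f"invalid SMILES: {smiles!r}")
    if len(Chem.GetMolFrags(mol)) > 1:
        raise StructureParseError("structure is disconnected")
    return graph_from_rdkit(mol, _resolve_attachment(mol, attachment_spec))


# ---------------------------------------------------------------------------
# cleavage enumeration
# ---------------------------------------------------------------------------

_CAP_DELTA = {"+H": 1, "-H": -1, "none": 0}


@dataclass(frozen=True)
class CleavageProduct:
    """One attachment-retaining fragment produced by breaking <= max_bonds bonds.

    ``retained_formula`` includes one capping hydrogen per broken-bond stub
    (configurable); ``loss_formula`` is the plain atom complement, so
    ``retained + loss = parent + caps``.
    """

    broken_bonds: frozenset[int]
    retained_atoms: tuple[int, ...]
    retained_formula: Composition
    loss_formula: Composition
    mono_mass: float
    avg_mass: float
    duplicate_formula: bool = False

    @property
    def n_broken(self) -> int:
        return len(self.broken_bonds)


def enumerate_cleavages(
    graph: MolecularGraph,
    max_bonds: int = 2,
    cap: str = "+H",
    bond_orders: Sequence[float] = (1.0,),
) -> list[CleavageProduct]:
    """Enumerate attachment-retaining cleavage products.

    Every subset ``S`` of eligible bonds (acyclic, bond order in
    ``bond_orders``) with ``1 <= |S| <= max_bonds`` is removed simultaneously;
    the product is the connected component containing the attachment atom.
    A subset is valid only when every broken bond touches that component —
    otherwise the same fragment already arises from a smaller cut.  Each stub
    on the retained fragment is capped according to ``cap`` (one H added by
    default).  Formula-identical products from distinct bond sets are all
    kept, flagged ``duplicate_formula=True``.
    """
    if not (1 <= max_bonds <= 3):
        raise ValueError("max_bonds must be between 1 and 3")
    if cap not in _CAP_DELTA:
        raise ValueError(f"cap must be one of {sorted(_CAP_DELTA)}")

    eligible = [
        k
        for k, (_i, _j, order, is_ring) in enumerate(graph.bonds)
        if not is_ring and order in bond_orders
    ]
    adjacency: dict[int, list[tuple[int, int]]] = {
        i: [] for i in range(len(graph.atoms))
    }
    for k, (i, j, _o, _r) in enumerate(graph.bonds):
        adjacency[i].append((j, k))
        adjacency[j].append((i, k))

    parent = graph.formula
    products: list[CleavageProduct] = []
    for size in range(1, max_bonds + 1):
        for subset in itertools.combinations(eligible, size):
            removed = set(subset)
            component = _component_of(graph.attachment_atom, adjacency, removed)
            if any(
                graph.bonds[k][0] not in component
                and graph.bonds[k][1] not in component
                for k in subset
            ):
                continue  # bond not incident to the retained fragment
            if len(component) == len(graph.atoms):
                continue  # nothing lost (cannot happen for bridges)
            retained = graph.atom_formula(sorted(component))
            caps = _CAP_DELTA[cap] * size
            if caps:
                retained = Composition(retained)
                retained["H"] += caps
                if retained["H"] < 0:
                    continue
                retained = Composition({e: n for e, n in retained.items() if n})
            loss = parent - graph.atom_formula(sorted(component))
            products.append(
                CleavageProduct(
                    broken_bonds=frozenset(subset),
                    retained_atoms=tuple(sorted(component)),
                    retained_formula=retained,
                    loss_formula=Composition({e: n for e, n in loss.items() if n}),
                    mono_mass=formula_mass(retained, "monoisotopic"),
                    avg_mass=formula_mass(retained, "average"),
                )
            )

    by_formula: dict[str, int] = {}
    for p in products:
        by_formula[format_formula(p.retained_formula)] = (
            by_formula.get(format_formula(p.retained_formula), 0) + 1
        )
    return [
        replace(p, duplicate_formula=by_formula[format_formula(p.retained_formula)] > 1)
        for p in products
    ]


def _component_of(start: int, adjacency, removed_bonds: set[int]) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v, k in adjacency[u]:
            if k in removed_bonds or v in seen:
                continue
            seen.add(v)
            stack.append(v)
    return seen


# ---------------------------------------------------------------------------
# biotransformations and library expansion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Biotransformation:
    """A named small chemical modification with a signed formula delta."""

    name: str
    formula_delta: Composition
    mono_delta: float = field(default=0.0)
    avg_delta: float = field(default=0.0)

    @classmethod
    def from_formula(cls, name: str, delta: str | Composition) -> "Biotransformation":
        comp = delta if isinstance(delta, Composition) else parse_formula(delta)
        return cls(
            name=name,
            formula_delta=comp,
            mono_delta=formula_mass(comp, "monoisotopic"),
            avg_delta=formula_mass(comp, "average"),
        )


#: Thiosuccinimide ring hydrolysis: +H2O, stabilises the conjugate against
#: retro-Michael deconjugation.
HYDROLYSIS = Biotransformation.from_formula("hydrolysis", "H2O")
#: Oxidative deamidation to the alcohol (R-NH2 -> R-OH): net +O -N -H.
DEAMIDATION = Biotransformation.from_formula("deamidation", "+O-HN")
#: Both modifications on the same fragment.
HYDROLYSIS_DEAMIDATION = Biotransformation.from_formula(
    "hydrolysis+deamidation", Composition(HYDROLYSIS.formula_delta) + DEAMIDATION.formula_delta
)

DEFAULT_BIOTRANSFORMATIONS: tuple[Biotransformation, ...] = (
    HYDROLYSIS,
    DEAMIDATION,
    HYDROLYSIS_DEAMIDATION,
)

BIOTRANSFORMATIONS_BY_NAME = {b.name: b for b in DEFAULT_BIOTRANSFORMATIONS}


@dataclass(frozen=True)
class DeltaMassEntry:
    """One candidate modification of the conjugate, named
    ``"loss of <formula> [+ <mod>]"`` or ``"<mod>"`` for the intact parent."""

    name: str
    source_cleavage: CleavageProduct | None
    mods: tuple[Biotransformation, ...]
    neutral_mono_mass: float
    neutral_avg_mass: float
    delta_formula: Composition  # vs the intact parent conjugate

    @property
    def mono_delta_vs_parent(self) -> float:
        return formula_mass(self.delta_formula, "monoisotopic")

    @property
    def avg_delta_vs_parent(self) -> float:
        return formula_mass(self.delta_formula, "average")


def expand_library(
    parent: MolecularGraph | Composition | str,
    cleavages: Sequence[CleavageProduct],
    biotransformations: Sequence[Biotransformation] = DEFAULT_BIOTRANSFORMATIONS,
) -> list[DeltaMassEntry]:
    """Combine cleavages with biotransformations into the delta-mass library.

    The library is (cleavage x {unmodified}) + (cleavage x each mod) +
    (intact parent x each mod); the unmodified parent is *not* an entry (it is
    the reference conjugate), so ``|library| = (m+1)*c + m`` — 187 entries for
    46 cleavages and 3 modifications.  Entries whose full formula would go
    negative are skipped with a warning.
    """
    if isinstance(parent, MolecularGraph):
        parent_comp = parent.formula
    elif isinstance(parent, Composition):
        parent_comp = parent
    else:
        parent_comp = parse_formula(parent)

    entries: list[DeltaMassEntry] = []

    def try_add(name, cleavage, mods, full_comp, delta_comp):
        if any(n < 0 for n in full_comp.values()):
            log.warning("skipping non-physical library entry %r (%s)", name, dict(full_comp))
            return
        mono = formula_mass(full_comp, "monoisotopic")
        avg = formula_mass(full_comp, "average")
        if mono <= 0:
            log.warning("skipping non-positive-mass entry %r", name)
            return
        entries.append(
            DeltaMassEntry(
                name=name,
                source_cleavage=cleavage,
                mods=tuple(mods),
                neutral_mono_mass=mono,
                neutral_avg_mass=avg,
                delta_formula=Composition({e: n for e, n in delta_comp.items() if n}),
            )
        )

    for c in cleavages:
        base = f"loss of {format_formula(c.loss_formula)}"
        delta0 = c.retained_formula - parent_comp
        try_add(base, c, (), c.retained_formula, delta0)
        for mod in biotransformations:
            try_add(
                f"{base} + {mod.name}",
                c,
                (mod,),
                c.retained_formula + mod.formula_delta,
                delta0 + mod.formula_delta,
            )
    for mod in biotransformations:
        try_add(
            mod.name,
            None,
            (mod,),
            parent_comp + mod.formula_delta,
            mod.formula_delta,
        )
    return _disambiguate_names(entries)


def _disambiguate_names(entries: list[DeltaMassEntry]) -> list[DeltaMassEntry]:
    """Suffix repeated names with (1), (2), ... so names are unique."""
    counts: dict[str, int] = {}
    for e in entries:
        counts[e.name] = counts.get(e.name, 0) + 1
    running: dict[str, int] = {}
    out = []
    for e in entries:
        if counts[e.name] == 1:
            out.append(e)
        else:
            running[e.name] = running.get(e.name, 0) + 1
            out.append(replace(e, name=f"{e.name} ({running[e.name]})"))
    return out


LIBRARY_COLUMNS = (
    "name",
    "formula_delta_vs_parent",
    "neutral_mono_mass",
    "neutral_avg_mass",
    "source",
)


def export_library(entries: Sequence[DeltaMassEntry], path: str | Path) -> Path:
    """Write the delta-mass library to CSV (UTF-8, '.' decimal separator)."""
    if not entries:
        raise ValueError("cannot export an empty library")
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(LIBRARY_COLUMNS)
        for e in entries:
            if e.source_cleavage is not None:
                bonds = "|".join(str(b) for b in sorted(e.source_cleavage.broken_bonds))
                source = f"bonds {bonds}"
            else:
                source = "intact parent"
            if e.mods:
                source += " + " + "+".join(m.name for m in e.mods)
            w.writerow(
                [
                    e.name,
                    format_formula(e.delta_formula),
                    f"{e.neutral_mono_mass:.6f}",
                    f"{e.neutral_avg_mass:.6f}",
                    source,
                ]
            )
    return path


def read_library(path: str | Path) -> list[DeltaMassEntry]:
    """Read a delta-mass library CSV back (inverse of :func:`export_library`)."""
    entries = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(LIBRARY_COLUMNS[:4]) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"library CSV missing columns: {sorted(missing)}")
        for row in reader:
            entries.append(
                DeltaMassEntry(
                    name=row["name"],
                    source_cleavage=None,
                    mods=(),
                    neutral_mono_mass=float(row["neutral_mono_mass"]),
                    neutral_avg_mass=float(row["neutral_avg_mass"]),
                    delta_formula=parse_formula(row["formula_delta_vs_parent"]),
                )
            )
    return entries
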