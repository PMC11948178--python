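import numpy as np
import pytest
from rdkit import Chem

from adcbiotx.chem import MolecularGraph, graph_from_rdkit, parse_smiles


def molblock(smiles: str) -> str:
    return Chem.MolToMolBlock(Chem.MolFromSmiles(smiles))


@pytest.fixture
def ethanol_molblock() -> str:
    return molblock("CCO")


@pytest.fixture
def benzene_molblock() -> str:
    return molblock("c1ccccc1")


@pytest.fixture
def nmethylmaleimide_molblock() -> str:
    return molblock("CN1C(=O)C=CC1=O")


@pytest.fixture
def butane_graph() -> MolecularGraph:
    """Linear 4-heavy-atom chain with the attachment at one end."""
    return parse_smiles("CCCC", 0)


@pytest.fixture
def neopentane_star_graph() -> MolecularGraph:
    """Central atom with three substituents; attachment at the centre."""
    return parse_smiles("C(C)(C)C", 0)


# ---------------------------------------------------------------------------
# independent brute-force cleavage oracle
# ---------------------------------------------------------------------------


def brute_force_cleavage_formulas(graph: MolecularGraph, max_bonds: int = 2):
    """Exhaustive enumeration of attachment-retaining fragments, written
    directly against the graph definition: scan *every* subset of acyclic
    single bonds of size <= max_bonds, remove it, keep the component holding
    the attachment atom iff every removed bond touches it, cap stubs with one
    H.  Returns the multiset (sorted list) of retained formulas as
    element->count dicts serialised to tuples."""
    import itertools

    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(graph.atoms)))
    for k, (i, j, order, _ring) in enumerate(graph.bonds):
        g.add_edge(i, j, key=k, order=order)
    bridges = {frozenset(e) for e in nx.bridges(g)}
    eligible = [
        k
        for k, (i, j, order, _r) in enumerate(graph.bonds)
        if frozenset((i, j)) in bridges and order == 1.0
    ]
    out = []
    for size in range(1, max_bonds + 1):
        for subset in itertools.combinations(eligible, size):
            h = g.copy()
            for k in subset:
                i, j, *_ = graph.bonds[k]
                h.remove_edge(i, j)
            comp = nx.node_connected_component(h, graph.attachment_atom)
            if any(
                graph.bonds[k][0] not in comp and graph.bonds[k][1] not in comp
                for k in subset
            ):
                continue
            formula: dict[str, int] = {}
            for idx in comp:
                sym, n_h, _q = graph.atoms[idx]
                formula[sym] = formula.get(sym, 0) + 1
                if n_h:
                    formula["H"] = formula.get("H", 0) + n_h
            formula["H"] = formula.get("H", 0) + size  # one cap H per stub
            out.append(tuple(sorted((e, n) for e, n in formula.items() if n)))
    return sorted(out)


@pytest.fixture
def bruteforce_oracle():
    return brute_force_cleavage_formulas


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_915)
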