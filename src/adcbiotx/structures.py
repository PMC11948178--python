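"""Bundled example structures.

The real pyrrolobenzodiazepine (PBD) linker-payloads used in published ADC
biotransformation studies are proprietary, so this module ships a *synthetic*
stand-in of the same chemical class for demos and tests: a maleimide
conjugation handle, a short propionyl spacer, a PEG8 stretch, a Val-Ala
dipeptide with a p-aminobenzyl (PAB) carbamate self-immolative unit, and a
PBD dimer joined by a C8/C8' propylenedioxy bridge (one monomer carbamoylated
at N10, the other carrying the N10=C11 imine).  Average mass ~1429 Da,
comparable to real PBD-dimer linker-payloads.  It is *not* a transcription of
any published structure.
"""

from __future__ import annotations

from .chem import MALEIMIDE_SMARTS, MolecularGraph, parse_smiles

#: Synthetic maleimide-PEG8-Val-Ala-PAB-PBD-dimer linker-payload (see module
#: docstring); C71H97N9O22, monoisotopic 1427.67 Da.
SYNTHETIC_PBD_LINKER_PAYLOAD_SMILES = (
    "O=C1C=CC(=O)N1CCC(=O)NCCOCCOCCOCCOCCOCCOCCOCCOCCC(=O)"
    "NC(C(C)C)C(=O)NC(C)C(=O)Nc1ccc(cc1)COC(=O)"
    "N2CC3CCCN3C(=O)c4cc(OC)c(OCCCOc5cc6N=CC7CCCN7C(=O)c6cc5OC)cc24"
)


def synthetic_pbd_linker_payload() -> MolecularGraph:
    """Molecular graph of the bundled synthetic PBD-dimer linker-payload,
    with the conjugation site on the maleimide ring."""
    return parse_smiles(SYNTHETIC_PBD_LINKER_PAYLOAD_SMILES, MALEIMIDE_SMARTS)
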