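"""Enumerate theoretical proteoform masses for conjugated antibody chains.

A DAR8 cysteine conjugate splits under acid elution into light chains (one
conjugation site) and heavy chains (three sites).  Candidates combine DAR,
glycans, cysteinylation caps and per-payload hydrolysis.
"""

from adcbiotx.proteoform import CandidateConfig, enumerate_candidates
from adcbiotx.masses import formula_mass
from adcbiotx.simulate import hydrolysis_entry, synthetic_chain
from adcbiotx.structures import synthetic_pbd_linker_payload

parent = synthetic_pbd_linker_payload().formula
conjugate = (formula_mass(parent, "monoisotopic"), formula_mass(parent, "average"))

hc = synthetic_chain("HC", 447, seed=20_240_102)
candidates = enumerate_candidates(
    hc,
    conjugate,
    [hydrolysis_entry(conjugate)],
    CandidateConfig(dar_range=(0, 1, 2, 3), glycans=("G0F",)),
)
print(f"{len(candidates)} HC proteoform candidates; the DAR-3 hydrolysis ladder:")
for c in candidates:
    if c.dar == 3:
        print(f"  {c.label:30s} avg {c.theo_avg_mass:10.2f} Da")
# Successive ladder members differ by one water (+18.02 Da average): the mass
# signature of thiosuccinimide ring hydrolysis on one more conjugated payload.
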