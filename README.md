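# adcbiotx

Open data-analysis pipeline for **antibody-drug conjugate (ADC)
biotransformation** characterization by intact LC-MS.

ADCs change in circulation: payloads fall off (retro-Michael deconjugation,
with the freed thiol capped by cysteinylation), the thiosuccinimide ring
hydrolyzes (+18 Da, stabilizing the conjugate), and the linker-payload can
cleave partially along its backbone.  Identifying these species from intact
mass spectra of the light and heavy chains is traditionally a slow manual
search.  `adcbiotx` implements the streamlined two-step alternative as an
open, scriptable pipeline for bioanalytical scientists:

1. **Delta-mass library** (`adcbiotx.chem`): from the linker-payload
   structure (MOL/SDF/SMILES), enumerate every cleavage that breaks ≤ 2
   acyclic bonds, never a ring bond, and stays attached to the antibody
   through the conjugation site; combine with hydrolysis (+H₂O),
   deamidation-to-alcohol (+O −N −H) and their combination.  For *c*
   cleavages and *m* modifications the library has (m+1)·c + m entries.
2. **Proteoform matching and quantification** (`adcbiotx.proteoform`,
   `.deconvolution`, `.annotate`, `.quantify`): theoretical chain masses
   (fixed terminal modifications, IgG glycans, DAR, cysteinylation,
   per-payload library entries); charge-envelope deconvolution of intact
   spectra into neutral masses *M* from peaks at (M + z·p)/z; peak matching
   within a 3 Da tolerance with signed ppm accuracy,
   (obs − theo)/theo × 10⁶; fractional abundance Iᵢ/ΣI per chain per sample,
   aggregated to mean ± SD across biological replicates.

A synthetic-data module (`adcbiotx.simulate`) generates everything needed to
exercise the pipeline with no external data: toy structures, antibody-like
chains, first-order hydrolysis/deconjugation kinetics with exact binomial
species fractions, and raw-style multi-charge electrospray spectra with an
mzML writer.

## Worked example

Build the delta-mass library for the bundled synthetic PBD-dimer-class
linker-payload (`examples/01_build_delta_mass_library.py`):

```text
linker-payload: 102 heavy atoms, monoisotopic 1427.6748 Da
154 attachment-retaining cleavages (57 single-bond, 97 two-bond)
619 delta-mass entries written to library.csv ((3+1) x cleavages + 3 parent modifications)
first entries:
  loss of C67H95N8O20                              97.0164 Da
  loss of C67H95N8O20 + hydrolysis                115.0269 Da
```

Each entry names a conjugated-fragment state ("loss of <formula>", plus
optional modification) with its neutral mono/average mass; the matcher uses
the delta versus the intact conjugate.

Recover a heavy-chain hydrolysis ladder (four proteoforms 18 Da apart at
55 kDa) from a simulated noisy spectrum
(`examples/03_deconvolution_round_trip.py`):

```text
      true      found   error intensity charges
   55455.2   55455.15   -0.05      32.7      13
   55473.2   55473.24   +0.04     103.9      14
   55491.3   55491.35   +0.05      93.4      15
   55509.3   55509.32   +0.02      37.1      13
```

Masses come back within ~0.05 Da (far inside the 3 Da matching tolerance)
and intensities track the simulated abundances.

Run the full pipeline on a simulated 6-time-point, n = 3 PK study
(`examples/04_end_to_end_timecourse.py`):

```text
mean fractional abundance of the HC DAR-3 hydrolysis ladder over time:
time_h                 1.0    24.0   72.0   120.0  168.0  336.0
HC + 3PL + 1H2O + G0F    0.0  0.361  0.000  0.000  0.000  0.000
HC + 3PL + 2H2O + G0F    0.0  0.370  0.244  0.000  0.000  0.000
HC + 3PL + 3H2O + G0F    0.0  0.149  0.623  0.742  0.661  0.395
HC + 3PL + G0F           1.0  0.120  0.000  0.000  0.000  0.000

mean absolute error vs simulated ground truth: 0.0249
```

The ladder sweeps from unhydrolyzed to fully hydrolyzed as the
first-order kinetics predict, and the quantified fractions recover the
generator's ground truth within a few percentage points.  (The fully
hydrolyzed species' later decline reflects payload deconjugation moving
intensity to cysteinylated DAR-2 species, not reversal of hydrolysis.)

## Command line

```bash
adcbiotx build-library structure.mol --max-bonds 2 -o library.csv
adcbiotx candidates chains.fasta --library library.csv --conjugate-mono 1427.67 -o candidates.csv
adcbiotx deconvolute run.mzML --window LC=1.7:2.2 --window HC=3.0:5.5 -o peaks.csv
adcbiotx annotate peaks.csv candidates.csv --tol-da 3 -o annotations.csv
adcbiotx quantify annotations.csv manifest.csv -o timecourse.csv
adcbiotx simulate --seed 1 -o runs/
```

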