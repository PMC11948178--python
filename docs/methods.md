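# Methods

`adcbiotx` is an open implementation of a two-step data-analysis workflow for
characterizing in-vivo biotransformation of antibody-drug conjugates (ADCs)
from intact LC-MS data: (1) build a *delta-mass library* of plausible
linker-payload cleavage/modification products from the small-molecule
structure; (2) compute theoretical proteoform masses for the antibody chains,
deconvolute the intact spectra to neutral masses, match peaks against the
candidate space, and quantify fractional abundances over a pharmacokinetic
(PK) time course.  This note records the models, conventions and numerical
choices behind each step, and what the synthetic-data tests do and do not
demonstrate.

## Cleavage enumeration and the delta-mass library

The linker-payload is treated as its heavy-atom molecular graph (RDKit
parsing; implicit hydrogens by standard valence).  A *cleavage product* is
the connected fragment containing the conjugation-site atom after removing a
subset `S` of bonds with `1 <= |S| <= max_bonds` (default 2), under three
constraints:

- **no ring bonds**: a bond is a ring bond iff it lies on some cycle,
  decided by a bridge test on the full graph rather than a smallest-ring
  heuristic;
- **single bonds only** by default (`bond_orders=(1.0,)`): homolytic
  cleavage with hydrogen capping is not meaningful for a double bond.  The
  set of cleavable bond orders is configurable;
- **attachment incidence**: every bond in `S` must touch the retained
  fragment.  Removing a bond that is separated from the attachment by
  another cut produces the same fragment as the smaller cut, so such subsets
  are rejected as duplicates; this makes the product count well defined.

Each broken-bond stub on the retained fragment is capped with one hydrogen
(configurable per cap: `+H`, `-H`, `none`).  The commercial tools this
replaces do not document their capping convention; one-H capping (homolysis
plus hydrogen transfer) is the most common default in small-molecule
metabolite software.  `loss_formula` is defined as the plain atom complement
(parent minus retained atoms), so `retained + loss = parent + |S|·H` exactly;
mass closure is tested to 1e-6 Da.  Formula-identical products from distinct
bond sets are all kept and flagged `duplicate_formula`.

The library combines every cleavage with the standard modification set —
thiosuccinimide ring hydrolysis (+H2O, +18.0106 Da monoisotopic), oxidative
deamidation to the alcohol (R-NH2 → R-OH, +O −N −H, +0.9840 Da), and their
combination — plus each modification applied to the intact conjugate.  The
unmodified parent is *not* a library entry (it is the reference conjugate),
giving `(m+1)·c + m` entries for `c` cleavages and `m` modifications: 187
for a 46-cleavage structure.  Entries whose element counts would go negative
(e.g. deamidation of a nitrogen-free fragment) are skipped with a warning.

Enumeration is verified against an exhaustive brute-force scan (every bond
subset, same validity rule) on randomly generated C/N/O molecules of up to
12 heavy atoms.

The package bundles a *synthetic* PBD-dimer-class linker-payload
(maleimide–PEG8–Val-Ala–PAB-carbamate–pyrrolobenzodiazepine dimer,
C71H97N9O22, average ~1429 Da) as demo and test material; published
structures of this class are proprietary and the bundled molecule is not a
transcription of any of them, so structure-specific cleavage counts are
illustrative, not anchored.

## Proteoform candidate masses

Chain masses are residue-mass sums plus one water (pyteomics `std_aa_comp`),
minus two hydrogens per intrachain disulfide.  Disulfide counts and
conjugation sites follow the IgG1/DAR8-cysteine-conjugate convention (LC: 2
disulfides, 1 site; HC: 4 disulfides, 3 sites) and are per-chain
configurable.  Fixed terminal modifications — C-terminal lysine clipping
(−128.0950) and N-terminal Gln→pyroGlu (−17.0265) — fire only when the
sequence permits.  Glycans are monosaccharide-residue compositions (G0, G0F,
G1F, G2F, Man5), e.g. G0F = HexNAc4Hex3Fuc1 = +1444.5339 monoisotopic.
Cysteinylation of a free thiol adds C3H5NO2S (+119.0041); an optional −2H
"bridge" models two adjacent free thiols closing an intrachain disulfide
(off by default — the usual explanation for the absence of cysteinylated
DAR-1 heavy chains).

Candidates are the Cartesian product DAR × glycan × cysteinylation count ×
per-payload modification multiset (payloads are indistinguishable, so a
DAR-3 chain with a hydrolysis-only library yields the 0–3 × H2O ladder).
Every candidate carries both mass scales; matching defaults to the *average*
scale because 20–80 kDa intact deconvolution is isotopically unresolved.
Labels are canonical and invertible (`"HC + 2PL + 1Cys + 1H2O + G0F"`), and
candidate masses are additive by construction — an independently recomputed
sum agrees to 1e-6 Da in the tests.

## Deconvolution

Electrospray puts a 20–80 kDa proteoform at `(M + z·p)/z` across a block of
consecutive charge states (p = 1.00727646).  The proprietary
maximum-entropy deconvolution of the commercial tools is replaced by a
transparent greedy matched-filter:

1. **Preprocess** (profile mode): rolling-minimum baseline subtraction
   (window 20 m/z); noise gate at `k·MAD` (default k = 5) *above the
   post-subtraction median* — the rolling minimum leaves noise on a positive
   pedestal, so gating against zero would pass most of it; removal of
   surviving nonzero runs narrower than 3 samples (isolated detector spikes;
   genuine profile peaks span many samples).
2. **Score**: for each candidate mass on a 0.5 Da grid (20–80 kDa default),
   sum the interpolated intensity at its predicted charge positions within
   the m/z range (default 1000–5000, charges 10–60).
3. **Eligibility**: a charge *supports* a candidate only above 20% of the
   candidate's strongest charge.  A genuine envelope is a dense block of
   consecutive charges, so a candidate needs: at least 3 supporting charges;
   support filling ≥ 70% of its charge span, with a gapped pattern requiring
   one extra charge of corroboration; and its two longest consecutive runs
   carrying ≥ 65% of its total score.  These reject the classic artifacts: an
   n·M harmonic aligns only with every n-th charge (low density), and chance
   alignments of unrelated peak tails spread their score over scattered
   short runs (low coherence).
4. **Alias arbitration**: before accepting a candidate M, the scores of 2M
   and 3M are compared against M on both the working residual and the
   original spectrum; if a multiple explains ≥ 1.3× the intensity, M is a
   divisor alias (M/2 aligns with every even charge of M) and is skipped.
   The original-spectrum comparison matters because earlier subtractions can
   erode the parent's direct evidence.
5. **Refinement**: the accepted mass is the median of per-charge estimates
   `M_z = z·c_z − z·p`, where each measured apex `c_z` is an iterated
   soft-Gaussian-window centroid of the peak's gated sample island
   (grid-phase-unbiased; the median resists charges contaminated by
   overlapping peaks of other species).  Reported intensity is the envelope
   score measured on the original preprocessed spectrum, so it does not
   depend on extraction order.
6. **Subtraction**: the fitted Gaussian (measured apex and amplitude, width
   from the configured resolving power, default 10 000 FWHM) is subtracted
   at each envelope charge, walking outward along the *full physical charge
   ladder* — including charges outside the configured scoring range — while
   amplitudes keep decaying (an amplitude jump means a different species'
   peak).  Model subtraction rather than window zeroing leaves
   near-coincident peaks of other species standing.
7. Iterate until the best eligible score falls below 10% of the initial
   maximum; a dominance post-filter (drop M when a ≥ 3× stronger peak at 2M
   or M/2 shares ≥ 50% of its supporting positions) remains as a final
   guard.

Isotope structure is not modelled; deconvolved masses are interpreted on the
average-mass scale.  On simulated data (every species at signal-to-noise
≥ 20) the tests show ≥ 95% recovery within 0.5 Da — in practice 100% with a
maximum error below 0.2 Da over 60 replicates — and no reported peak further
than the 3 Da matching tolerance from a true mass.  Species below that
signal-to-noise are outside the validated regime: once an envelope survives
the noise gate only at (say) its even charges, the data genuinely cannot
distinguish M from M/2.

## Annotation and quantification

Peaks are matched to all candidates within a fixed absolute tolerance
(default 3 Da, the practical window for intact QTOF work; a ppm-scaled mode
is available), ranked by |Δ| — equivalent to |ppm| ranking inside one peak's
window — with exact-Da ties broken toward the lower theoretical mass.
Multiple assignments are flagged for manual review rather than
auto-resolved; chemistry plausibility stays with the analyst.  RT windows
restrict the candidate pool per chain (LC elution window → LC candidates).
Mass accuracy is reported as signed ppm, `(obs − theo)/theo × 1e6`, on both
scales.

Consolidation keeps a species iff it appears in at least a configurable
fraction of time points (default 0.5, boundary inclusive) — a refinement
aimed at irreproducible noise peaks — and fills absences with zero.
Fractional abundance divides each species' intensity by its group total
(chain × subject × time point); unidentified peaks are excluded from the
denominator by default.  Replicates aggregate to mean ± sample standard
deviation (n−1; a single subject reports 0).  Percent difference between two
estimates is `(new − old)/mean(new, old) × 100`.

## Synthetic-data generator

The generator provides every input the pipeline needs:

- **toy structures**: random valence-respecting C/N/O trees (3–12 atoms),
  optionally with one grafted ring, for the enumeration oracle;
- **chains**: deterministic pseudo-random sequences at natural amino-acid
  frequencies (defaults: LC 214 aa ≈ 23.4 kDa, HC 447 aa ≈ 49.3 kDa);
- **kinetics**: per-payload first-order processes — hydrolysis at `k_h`
  (default 0.03 h⁻¹, i.e. ~97% converted by 120 h, matching the
  essentially-complete-by-120-h behaviour such conjugates show in vivo) and
  deconjugation-then-cysteinylation at `k_d` (default 0.001 h⁻¹).  A chain
  with `d` payloads therefore shows binomial hydrolysis-count fractions
  drifting toward full hydrolysis; fractions are exact (closed form), not
  sampled;
- **spectra**: per species, a Gaussian charge envelope centred at
  `z0 = M / 2200` with width `max(1.5, 0.15·z0)` charges, each charge a
  Gaussian profile peak at resolving power 10 000 (FWHM), on a 0.05 m/z
  grid over 1000–5000; flat baseline plus Gaussian detector noise.  `snr`
  references the weakest species' tallest peak by default
  (`snr_reference='min_species'`), so "S/N ≥ 20" is a per-species guarantee;
  full PK scenarios instead use stationary noise referenced to the strongest
  signal (`'max_signal'`), since sample species span orders of magnitude;
- **studies**: default 6 time points (1–336 h), 3 subjects, 10%
  multiplicative (log-normal) abundance noise; three scans per chain elution
  (apex ± 0.15 min, weights 0.5/1/0.5; LC at 1.9 min, HC at 4.5 min); runs
  written as minimal standards-conformant mzML (64-bit floats, no
  compression).

What the generator does *not* emulate: realistic chromatographic peak
shapes, adducts (TFA, sodium), detector saturation, isotopic structure,
non-Gaussian charge-state distributions, co-eluting matrix proteins such as
albumin.  Passing tests therefore demonstrate the correctness of the
combinatorics and the self-consistency and robustness of the deconvolution/
quantification chain under idealized-but-noisy signals, not instrument-level
performance on real plasma digests.

## Problem sizes and runtime choices

The deconvolution round-trip suite uses 20 replicates of 2–5 species
(60 used during development); the end-to-end study is 18 samples × 2 RT
windows with the HC window's mass grid restricted to 20–60 kDa, which keeps
the full acceptance run to about half a minute while exercising every module
at the study's actual dimensionality.

## Known limitations

- Cleavage counts depend on the capping and bond-order conventions above;
  other tools with undocumented conventions can count differently on the
  same structure.
- The enumeration treats the molecule as a graph: no ring-opening
  cleavages, stereochemistry, protonation states, or likelihood ranking of
  candidates.
- Deconvolution assumes peaks of the configured resolving power; a badly
  wrong `resolution` setting degrades envelope subtraction and hence
  multi-species separation.
- Species at the same nominal mass within the matching tolerance (e.g.
  deamidation, ~1 Da) are not distinguishable at intact resolution; such
  assignments carry the review flag.
- The kinetic model is first-order and site-independent; cooperative or
  position-dependent hydrolysis would need scenario-level extensions.
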