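"""Full pipeline on a simulated PK study: spectra -> peaks -> annotations ->
fractional-abundance time course, compared against the generator's ground
truth.

Emulates a DAR8 ADC dosed into n=3 subjects, sampled at 6 time points over
two weeks, with per-payload thiosuccinimide hydrolysis (essentially complete
by ~120 h) and slow deconjugation/cysteinylation.  Takes ~30 s.
"""

from adcbiotx.deconvolution import DeconvConfig, RTWindow
from adcbiotx.pipeline import annotate_study, quantify_study
from adcbiotx.proteoform import CandidateConfig, enumerate_candidates
from adcbiotx.simulate import default_scenario, hydrolysis_entry, simulate_scenario

scenario = default_scenario()
study = simulate_scenario(scenario, seed=1)

candidates = []
for chain in scenario.chains:
    candidates += enumerate_candidates(
        chain,
        scenario.conjugate_mass_pair,
        [hydrolysis_entry(scenario.conjugate_mass_pair)],
        CandidateConfig(dar_range=tuple(range(chain.n_conjugation_sites + 1)),
                        glycans=("none", "G0F")),
    )

annotations = annotate_study(
    study.runs,
    candidates,
    windows=[RTWindow("LC", 1.7, 2.2), RTWindow("HC", 4.0, 5.0)],
    window_chain_map={"LC": "LC", "HC": "HC"},
    deconv_config=DeconvConfig(mass_range=(20_000, 60_000)),
)
timecourse = quantify_study(annotations, study.manifest, min_timepoint_fraction=0.0)

est = timecourse.per_subject.rename(columns={"fraction": "fraction_est"})
merged = study.truth.merge(
    est[["species", "subject", "time_h", "fraction_est"]],
    on=["species", "subject", "time_h"], how="left",
)
merged["fraction_est"] = merged["fraction_est"].fillna(0.0)
mae = (merged["fraction_est"] - merged["fraction"]).abs().mean()

print("mean fractional abundance of the HC DAR-3 hydrolysis ladder over time:")
ladder = timecourse.summary[
    timecourse.summary["species"].str.startswith("HC + 3PL")
].pivot(index="species", columns="time_h", values="mean_fraction")
print(ladder.round(3).to_string())
print(f"\nmean absolute error vs simulated ground truth: {mae:.4f}")
# The ladder sweeps from the unhydrolyzed species toward the fully (3x)
# hydrolyzed one; MAE < 0.05 means the pipeline quantifies each species'
# share to within a few percentage points.
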