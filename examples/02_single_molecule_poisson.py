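"""Single-molecule small-pool PCR: titration, QC and allele classification.

Simulates a dilution series for one expansion-prone tissue, picks the
dilution nearest the 1/3-negative-wells target, estimates the mean number of
amplifiable molecules per well from the Poisson zero class, and classifies
every sized allele against the modal repeat.
"""
from repeatmosaic import simcore, smolecule

profile = [p for p in simcore.default_tissue_profiles()
           if p.tissue_name == "occipital_cortex"][0]
dist = simcore.simulate_somatic_distribution(45, profile, n_cells=5000, seed=11)

series = simcore.simulate_dilution_series(
    dist, mean_molecules_per_well=[0.3, 1.1, 3.3], wells_per_dilution=72, seed=12,
    sample_id="patient-1", tissue="occipital_cortex",
)
best = smolecule.select_single_molecule_dilution(series)
plate = [p for p in series.plates if p.dilution_id == best][0]
print(f"selected dilution: {best} (true mean {plate.mean_molecules} molecules/well)")

qc = smolecule.qc_plate(plate)
print(f"plate QC: {'pass' if qc.passed else 'fail ' + str(qc.reasons)}")

est = smolecule.estimate_lambda_from_plate(plate)
print(f"lambda_hat = {est.lambda_hat:.3f} molecules/well "
      f"(95% CI {est.ci_low:.3f}-{est.ci_high:.3f}, "
      f"{est.n_negative}/{est.n_wells} wells negative)")

counts = smolecule.tabulate_alleles(plate)
print(f"modal reference: {counts.modal_reference} repeats")
print(f"contracted/modal/expanded: {counts.n_contracted}/{counts.n_modal}/"
      f"{counts.n_expanded} of {counts.n_total}")
print(f"expansions of >=5 repeats: {counts.expanded_ge5}")
summary = smolecule.summarize_sample(plate)
print(f"sized alleles: {summary.n_alleles}, mean {summary.mean_repeat}, "
      f"range {summary.lowest_repeat}-{summary.highest_repeat}")

# lambda_hat = -ln(fraction of negative wells) estimates input molecules per
# well; near ln 3 ~ 1.1 most positive wells hold a single template molecule,
# so the contracted/modal/expanded counts read out per-cell repeat lengths.
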