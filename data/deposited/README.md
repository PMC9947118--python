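# Deposited data drop-in

The reproduction checks in `tests/test_acceptance.py` (filter counts,
excretion refit, mineralogy refit) run against the compiled reef-fish
carbonate dataset, which is not redistributed here. To enable them, place
two files in this directory:

- `observations.csv` — one row per tank group (192 rows pre-filter), with
  the column schema of `ichthyocarb.data.OBSERVATION_COLUMNS`:
  `obs_id, family, species, region, n_individuals, body_mass_kg, ril, ar,
  temperature_C, salinity, sampling_period_h, titration_method,
  excretion_rate_umol_h, weight` (weight may be left empty; it is
  recomputed from `n_individuals`). Scarine Labridae should already be
  relabelled as their own family level (see
  `ichthyocarb.data.split_families_by_tribe`).
- `profiles.csv` — species-level polymorph fractions with columns
  `species, LMC, HMC, aragonite, MHC, ACMC` (rows summing to 1).

Source: the compiled dataset's Zenodo deposit
(doi:10.5281/zenodo.7530092; intestinal-length data at
doi:10.5281/zenodo.5172790). Column names there differ; map them onto the
schema above and convert units to kg / °C / hours / µmol h⁻¹ per
individual before saving.
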