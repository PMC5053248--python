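# Desk-scale synthetic study: 6 countries plus rest of world, 18 five-year
# age groups, 2 years; ~40% of reports missing per side, 20% sex-only.
#
# The global profiles pin a typical migration age schedule (labour-force peak
# in age groups 5-7, i.e. ages 20-34, with a mild retirement tail) and a
# slight male majority; country effects scatter around them.
dimensions:
  countries: [DE, ES, FR, IT, PL, UK]
  n_ages: 18
  years: [2007, 2008]
  rest_of_world: RW

scenario:
  seed: 7
  base_flow: 100.0
  missing_fraction_send: 0.4
  missing_fraction_recv: 0.4
  sexonly_fraction: 0.2
  report_effect_sd: 0.5
  age_profile: [0.0, -0.2, -0.3, 0.6, 1.8, 2.2, 1.8, 1.2, 0.8, 0.4,
                0.0, -0.3, -0.5, -0.5, -0.4, -0.7, -1.1, -1.5]
  sex_profile: [0.0, 0.1]

mcmc:
  n_iterations: 5000
  burn_in: 2500
  thinning: 10
  seed: 11
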