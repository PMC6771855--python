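# Default run configuration: an eleven-centre stepped-wedge trial of
# revealed PlGF testing for suspected pre-eclampsia, with enrolment,
# subgroup mix and adverse-event rates matching the published trial
# population. Resource-use levels (hurdle probability p, positive-part
# mean mu, dispersion k) are SYNTHETIC calibrations with realistic NHS
# magnitudes; they are not taken from any published supplementary table.
seed: 20177

design:
  n_clusters: 11
  n_steps: 12
  # annual delivery volume per unit (3000-9000), used as enrolment weights
  cluster_weights: [3000, 3500, 4200, 4800, 5200, 5600, 6100, 6800, 7400, 8200, 9000]

enrolment:
  usual: 434
  revealed: 571

subgroups:
  # marginal PlGF band proportions observed in the trial
  plgf_marginals: {gt100: 0.382, "12to100": 0.383, lt12: 0.235}
  # diagnosis mix within band: synthetic, chosen so very-low PlGF is
  # dominated by pre-eclampsia and normal PlGF by uncomplicated outcomes
  diagnosis_given_plgf:
    gt100: {normal: 0.70, GH_CHT_SGA: 0.22, preeclampsia: 0.08}
    "12to100": {normal: 0.40, GH_CHT_SGA: 0.35, preeclampsia: 0.25}
    lt12: {normal: 0.10, GH_CHT_SGA: 0.25, preeclampsia: 0.65}

cluster_effects:
  sigma_c: 0.3    # SD of the shared centre random intercept (link scale)
  beta_t: 0.02    # linear secular trend per 6-week step (link scale)

adverse_events:
  # severe maternal adverse outcomes, events / denominators per arm
  usual: {events: 24, n: 447}
  revealed: {events: 22, n: 573}

# Hurdle parameters per resource category. p/mu/k are the base (PlGF>100,
# normal diagnosis, usual care) values; dx_*, plgf_* and revealed_* are
# multiplicative modifiers (odds ratios for p, ratios for the positive
# mean). Omitted modifiers default to 1.
resource_use:
  outpatient:
    base: {p: 0.92, mu: 6.0, k: 2.0}
    dx_mu: {GH_CHT_SGA: 1.20, preeclampsia: 1.40}
    dx_odds: {GH_CHT_SGA: 1.30, preeclampsia: 1.50}
    plgf_mu: {"12to100": 1.15, lt12: 1.25}
    revealed_mu: {gt100: 0.72, "12to100": 0.85, lt12: 0.93}
    revealed_odds: {gt100: 0.90}
  antenatal_ward:
    base: {p: 0.40, mu: 3.5, k: 1.5}
    dx_mu: {GH_CHT_SGA: 1.20, preeclampsia: 1.60}
    dx_odds: {GH_CHT_SGA: 1.50, preeclampsia: 2.50}
    plgf_mu: {"12to100": 1.10, lt12: 1.20}
    revealed_mu: {gt100: 0.95, "12to100": 1.05, lt12: 1.12}
    revealed_odds: {gt100: 0.85, "12to100": 1.10, lt12: 1.30}
  labour_ward:
    base: {p: 0.95, mu: 1.4, k: 5.0}
    dx_mu: {preeclampsia: 1.15}
    revealed_mu: {gt100: 1.02, lt12: 0.96}
  maternal_postnatal:
    base: {p: 0.90, mu: 2.2, k: 3.0}
    dx_mu: {GH_CHT_SGA: 1.10, preeclampsia: 1.35}
    revealed_mu: {gt100: 0.97, lt12: 1.05}
  maternal_icu_hdu:
    base: {p: 0.04, mu: 2.5, k: 2.0}
    dx_odds: {GH_CHT_SGA: 1.50, preeclampsia: 4.00}
    revealed_odds: {gt100: 0.90, "12to100": 0.80, lt12: 0.85}
  infant_icu_hdu:
    base: {p: 0.06, mu: 8.0, k: 1.2}
    dx_odds: {GH_CHT_SGA: 2.00, preeclampsia: 4.00}
    dx_mu: {preeclampsia: 1.30}
    revealed_odds: {"12to100": 0.85, lt12: 0.90}
  infant_scbu:
    base: {p: 0.09, mu: 9.0, k: 1.2}
    dx_odds: {GH_CHT_SGA: 1.80, preeclampsia: 3.00}
    revealed_odds: {gt100: 0.95, "12to100": 0.90}

delivery:
  # reference-cost delivery modes; probabilities shared across arms
  mode_probs: {spontaneous: 0.40, assisted: 0.12, planned_CS: 0.20, emergency_CS: 0.28}

model:
  candidates: [two_part_truncNB, two_part_truncPoisson, negative_binomial, poisson]
  n_quad: 7

psa:
  iterations: 5000
  test_cost: 70.0
  test_cost_sweep: [50, 100, 150, 200]
  wtp_max: 50000
  wtp_step: 1000
  weights_mode: pooled

scaling:
  annual_births: 646794
  p_suspected: 0.10
  p_preterm_presentation: 0.30
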