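# Example generator configuration for `beehex simulate --config ...`.
# Any omitted key falls back to the built-in default; the seed always
# comes from the --seed flag.

# Shared petal-model parameters (reflectance fractions, nm).
r_spec: 0.06
r_diff: 0.65          # shared long-wavelength plateau
lambda_half: 420.0
gamma: 17.0
dip_center: 550.0
dip_width: 60.0
dip_depths:           # pigment dip depth per spectral morph class
  white: 0.0
  "light pink": 0.3
  "dark pink": 0.6
  violet: 0.85

# Nectar-guide spot model: convex mixture of a dark pigment spectrum and
# the white petal, at the probe-dilution fraction alpha.
spot_mixing_alpha: 0.35
spot_pigment_depth: 0.95
spot_pigment_rdiff_factor: 0.6
white_spotless_prob: 0.0

noise_sd: 0.01        # additive reflectance noise sd
seeds_dispersion: 5.0 # negative-binomial k (variance = mu + mu^2/k)
sown_per_fruit: 30

germination_p:
  native: 0.60
  introduced: 0.45

# Per-region soil means for (water %, pH, C, N, Fe, K, P) and shared sds.
soil_means:
  native: [25.0, 4.5, 6.0, 0.40, 1.5, 0.30, 0.08]
  introduced: [7.0, 6.0, 2.0, 0.15, 1.5, 0.30, 0.08]
soil_sds: [4.0, 0.3, 1.0, 0.05, 0.5, 0.08, 0.02]
violet_p_shift: -0.01

populations:
  - name: B1
    region: introduced
    n_plants: 45
    morph_frequencies: {violet: 0.87, pink: 0.13, white: 0.0}
    visitation_rates: {violet: 0.05, pink: 0.12, white: 0.0}
    census_minutes: 20.0
    census_repeats: 10
    fruits_per_plant_mean: 47.0
    seeds_per_fruit_mean: 1100.0
    robbed_fraction: 0.67
  - name: G1
    region: native
    n_plants: 45
    morph_frequencies: {violet: 0.27, pink: 0.43, white: 0.30}
    visitation_rates: {violet: 0.45, pink: 0.42, white: 0.44}
    fruits_per_plant_mean: 200.0
    seeds_per_fruit_mean: 200.0
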