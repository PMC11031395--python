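# Example experiment configuration for `fairgen run`.
# A two-label planted-bias cohort across three acquisition domains, one held
# out for OOD evaluation; the minority attribute value is capped at 100
# labeled examples; the diffusion model is conditioned on label + attribute.
cohort:
  n_examples: 1200
  image_size: 16
  n_labels: 2
  label_prevalence: [0.5, 0.5]
  attributes:
    - name: sex
      values: [0, 1]
      table: [[0.9, 0.1], [0.5, 0.5]]
  n_domains: 3
  domain_effect:
    - [0.12, -0.06, -0.06]
    - [-0.06, 0.12, -0.06]
    - [-0.06, -0.06, 0.12]
  spurious_strength: 0.9
  noise_sd: 0.15
  seed: 5
property_name: sex
ood_domains: [2]
skew_cap: 100
conditioning: label+property
alpha: 0.5
guidance_weight: 1.5
arms: [baseline, synthetic_augment]
seeds: [0, 1]
diffusion:
  T: 100
  steps: 2000
seed: 9
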