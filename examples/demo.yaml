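# Demo pipeline: 24-run design, 150 synthetic respondents from the
# four-archetype population, MN1 mixed logit, latent-class sweep 2-4,
# compensating-variation table against the CAPI baseline.
out_dir: scratch/demo-out
seed: 1
design:
  n_runs: 24
  n_blocks: 4
  n_iter: 2000
population:
  preset: four_class
  n_respondents: 150
model:
  preset: mn1
  n_draws: 100
lcm:
  class_range: [2, 3, 4]
  n_restarts: 3
  criterion: BIC
  n_convention: respondents
welfare:
  alpha: 0.05
  policies: bundled
  baseline: CAPI
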