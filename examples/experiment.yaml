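# Demo evaluation grid at desk scale: two methods x with/without the
# common full-sib term, five-fold cross-validation.
seed: 7
output_dir: sibstep_out
simulate:
  preset: reduced
  families_per_generation: [20, 18, 10]
  offspring_mean: 15.0
  n_snp: 500
  n_qtl: 100
  genotyped_families: 12
  genotyped_individuals: 120
grid:
  methods: [PBLUP, ssGBLUP]
  c2: [with, without]
  genotypes: [original, imputed]
folds: {k: 5, r: 1}
reml: {tol: 1.0e-4, gtol: 1.0e-2}
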