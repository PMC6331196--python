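# Reference cross under the female-restricted drive, with realistic
# per-meiosis loss and non-disjunction and the chr14 penetrance exception.
parent1: IPO323
parent2: IPO94269
mechanism: female_drive
drive_penetrance:
  chr14: 0.0
loss_rate: 0.037
nondisjunction_rate: 0.015
n_asci: 100
seed: 7
outdir: results/female_drive_run
stages:
  verify: true
  classify: true
  stats: true
  snpspectrum: true
snp:
  n_snps: 5000
  coverage_mean: 11.0
  coverage_dispersion: 2.0
  conversion_rate: 1.0
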