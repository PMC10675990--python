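# Demo simulation: a 2.5 Mb host at 51.4% GC with a dozen planted viral
# elements (GC-poorer than the host), two depth datasets, noiseless marker
# hits, and a tetraploid SNP table. These are also the built-in defaults;
# override any block here.
host:
  n_scaffolds: 40
  min_bp: 40000
  max_bp: 80000
  base_gc: 0.514
plants:
  - {clade: PLVB, length_bp: 23000, gc_offset: -10.0, tir_len: 300, n: 4}
  - {clade: PLVA, length_bp: 25000, gc_offset: -10.0, tir_len: 300, n: 3}
  - {clade: PLV2, length_bp: 15000, gc_offset: -10.0, tir_len: 200, n: 3}
  - {clade: CHeCME, length_bp: 18000, gc_offset: -8.0, n: 2}
min_flank: 6000
depth:
  mean_depth: 50.0
  n_datasets: 2
  drift: 0.0
hits:
  fpr: 0.0
  fnr: 0.0
  jitter_bp: 0
snps:
  ploidy: 4
  n_snps: 2000
  depth: 100
  error_rate: 0.01
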