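# Example pipeline configuration: default synthetic scenario, all stages.
seed: 42
simulate: {}            # generator defaults (600 loci, 4 taxa, 52 progeny)
classify:
  max_missing: 0.05
  alpha: 0.01
tree:
  bootstrap: 200
pca:
  active_groups: [reticulata_like, maxima_like]
ld:
  max_loci: 150
  threshold: 0.2
parentage:
  hybrid: sweet_orange_like_1
  null_aware: true
diversity:
  fstat_groups: [reticulata_like, maxima_like, medica_like]
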