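# Demo configuration for `dgecast run` — a complete synthetic study at
# desk scale (runs in well under a minute on one CPU).
seed: 7

simulate:
  n_genes: 300          # reference genes
  min_len: 120
  max_len: 300
  frac_no_site: 0.02    # genes without a CATG site
  frac_shared_tag: 0.04 # genes sharing a tag (ambiguity filtering at work)
  depth1: 200000        # tags per library
  depth2: 200000
  n_de: 20              # planted differentially expressed genes
  de_log2fc: 2.0
  de_min_expected: 50.0
  frac_empty: 0.02      # contamination fractions for the raw reads
  frac_lowq: 0.02
  frac_singleton_noise: 0.01
  frac_badlen: 0.01

detest:
  fdr_max: 0.001
  lfc_min: 1.0
  pseudocount: 1.0
  sided: two-sided

degtables:
  n_genes: 400
  n_castration_only: 30
  n_crpc_shared: 12
  n_crpc_specific: 15

classify:
  require_direction_match: true

enrich:
  n_sets: 25
  set_size: 20
  enriched_overlap: 12
  top: 10

network:
  n_nodes: 60
  n_edges: 150
  hub_degree: 35
  score_min: 0.15
  hub_min_degree: 30

qpcr:
  reference: GAPDH
  n_replicates: 3
  n_genes: 6
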