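# Packaged end-to-end fixture: the default simulated cytokine-stimulation
# design (control + six reference cytokines, n = 3) plus a chimera
# attenuation grid on STAT3 (alpha = 0 .. 1).
out_dir: statscore_run
seed: 7
sim:
  n_genes: 2000
  program_sizes:
    STAT1: 150
    STAT3: 150
    STAT5: 150
    STAT6: 150
  overlap_fraction: 0.0
  frac_repressed: 0.3
  effect_log2fc: 2.0
  dispersion: 0.1
  baseline_log2_mean_sd:
  - 6.0
  - 2.0
  library_size_range:
  - 0.7
  - 1.3
  n_replicates: 3
  conditions:
  - name: no_ICD
    role: control
  - name: IFNa
    role: reference
    activation:
      STAT1: 1.0
    reference_stat: STAT1
  - name: IL10
    role: reference
    activation:
      STAT3: 1.0
    reference_stat: STAT3
  - name: IL21
    role: reference
    activation:
      STAT3: 1.0
    reference_stat: STAT3
  - name: IL2
    role: reference
    activation:
      STAT5: 1.0
    reference_stat: STAT5
  - name: IL7
    role: reference
    activation:
      STAT5: 1.0
    reference_stat: STAT5
  - name: IL4
    role: reference
    activation:
      STAT6: 1.0
    reference_stat: STAT6
  - name: chimera_STAT3_a000
    role: query
    activation:
      STAT3: 0.0
  - name: chimera_STAT3_a025
    role: query
    activation:
      STAT3: 0.25
  - name: chimera_STAT3_a050
    role: query
    activation:
      STAT3: 0.5
  - name: chimera_STAT3_a075
    role: query
    activation:
      STAT3: 0.75
  - name: chimera_STAT3_a100
    role: query
    activation:
      STAT3: 1.0
  offtarget_fraction: 0.1
  gene_length_range:
  - 500
  - 10000
  seed: 7
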