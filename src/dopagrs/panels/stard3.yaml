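# Three-SNP sub-panel used with imputed dosages (depressed replication cohort);
# scores range 0-6.
name: stard3
variants:
  - variant_id: rs4680
    gene: COMT
    class: snp
    risk_allele: A
    labels: {A: Met, G: Val}
  - variant_id: rs6280
    gene: DRD3
    class: snp
    risk_allele: C
    labels: {C: Gly, T: Ser}
  - variant_id: rs1800497
    gene: DRD2/ANKK1
    class: snp
    risk_allele: G
    labels: {G: Glu, A: Lys}
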