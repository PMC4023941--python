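# Four-SNP sub-panel (healthy replication cohort): three genotyped SNPs plus
# imputed rs1800497; scores range 0-8 (fractional when dosages contribute).
name: gsp4
variants:
  - variant_id: rs4680
    gene: COMT
    class: snp
    risk_allele: A
    labels: {A: Met, G: Val}
  - variant_id: rs4532
    gene: DRD1
    class: snp
    risk_allele: G
    labels: {A: A, G: G}
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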