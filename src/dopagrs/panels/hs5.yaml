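# Five-variant dopamine neurotransmission panel (discovery cohort).
# Risk allele = the allele inferred to increase dopamine neurotransmission;
# one point per copy, so scores range 0-10.
name: hs5
variants:
  - variant_id: rs4680
    gene: COMT
    class: snp
    risk_allele: A
    labels: {A: Met, G: Val}
  - variant_id: rs28363170
    gene: DAT
    class: vntr
    vntr_risk_max_repeat: 9
  - variant_id: rs4532
    gene: DRD1
    class: snp
    risk_allele: G
    labels: {A: A, G: G}
  - variant_id: rs1800497
    gene: DRD2/ANKK1
    class: snp
    risk_allele: G
    labels: {G: Glu, A: Lys}
  - variant_id: rs6280
    gene: DRD3
    class: snp
    risk_allele: C
    labels: {C: Gly, T: Ser}
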