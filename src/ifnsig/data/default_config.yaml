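# Default pipeline configuration.
#
# The ISG, NF-kB and IFN-gamma gene lists below are PLACEHOLDERS assembled
# from the published whole-blood interferon-score literature.  They have the
# right sizes and structure for the assay (30 ISGs, disjoint NF-kB and
# IFN-gamma panels) but are not a clinically validated codeset: supply your
# own panel lists for any real comparison between studies.
schema_version: 1
batch_policy: per_batch
pseudocount: 1.0
log_base: 2
reference_band: [2.5, 97.5]
induction_threshold: 2.0
z_truncation: 10.0
hk_factor_on_raw: false
panels:
  - name: ISG
    code_class: endogenous
    genes:
      - IFI6
      - IFI27
      - IFI44
      - IFI44L
      - IFIH1
      - IFIT1
      - IFIT2
      - IFIT3
      - IFIT5
      - ISG15
      - LY6E
      - MX1
      - MX2
      - OAS1
      - OAS2
      - OAS3
      - RSAD2
      - SIGLEC1
      - USP18
      - EPSTI1
      - HERC5
      - LAMP3
      - LGALS3BP
      - PLSCR1
      - SOCS1
      - SPATS2L
      - STAT1
      - STAT2
      - CMPK2
      - DDX60
  - name: NFKB
    code_class: endogenous
    genes:
      - NFKB1
      - NFKBIA
      - TNFAIP3
      - TNF
      - IL1B
      - IL6
      - CXCL8
      - CCL2
      - ICAM1
      - BIRC3
  - name: IFNG
    code_class: endogenous
    genes:
      - CXCL9
      - CXCL10
      - CXCL11
      - GBP1
      - GBP2
      - GBP5
      - IDO1
      - FCGR1A
      - CIITA
      - HLA-DRA
  - name: housekeeping
    code_class: housekeeping
    genes: [NRDC, OTUD5, TUBB]
  - name: positive_control
    code_class: positive_control
    genes: [POS_A, POS_B, POS_C, POS_D, POS_E, POS_F]
  - name: negative_control
    code_class: negative_control
    genes: [NEG_A, NEG_B, NEG_C, NEG_D, NEG_E, NEG_F, NEG_G, NEG_H]
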