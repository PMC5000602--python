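# Promoter cis-regulatory element consensi (IUPAC DNA codes).
#
# Package-curated consensus patterns for the stress- and hormone-response
# elements surveyed in plant promoters: ABA response (ABRE, CE3), drought
# (MBS), low temperature (LTR), heat (HSE), ethylene (ERE), methyl
# jasmonate (TGACG/CGTCA) and salicylic acid (TCA).  Editable; the
# synthetic promoter generator implants instances drawn from this file.
elements:
  - name: ABRE
    pattern: TACGTGTC
    category: ABA
  - name: CE3
    pattern: GACGCGTGTC
    category: ABA
  - name: MBS
    pattern: CAACTG
    category: drought
  - name: LTR
    pattern: CCGAAA
    category: low_temperature
  - name: HSE
    pattern: AGAANNTTCT
    category: heat
  - name: ERE
    pattern: ATTTCAAA
    category: ethylene
  - name: TGACG_MeJA
    pattern: TGACG
    category: MeJA
  - name: CGTCA_MeJA
    pattern: CGTCA
    category: MeJA
  - name: TCA_SA
    pattern: CCATCTTTTT
    category: SA
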