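# Degenerate amino-acid signature patterns for two-component-system domains.
#
# X matches any residue.  key_residue_offset marks the phospho-accepting /
# catalytic residue inside the match (0-based); its identity is never part
# of the match decision, only of the conserved/substituted call.
#
# The Hpt pattern XHQXKGSSXS is the canonical phosphotransfer signature;
# the remaining patterns are package-curated degenerate consensi standing
# in for the Pfam domain models (HisKA, HATPase, Response_reg, CHASE, GAF,
# PHY, PAS, CCT, Myb, ethylene-binding).  Edit this file to retarget the
# scanner; the synthetic-genome generator builds its proteins from the
# same definitions.
signatures:
  - name: HK_Hbox
    pattern: XHELRTPLNGVL
    key_residue_offset: 1
    key_residue: H
  - name: HK_Nbox
    pattern: LSDNLLSNAVKF
  - name: HK_G1box
    pattern: EKGTGLGLAICK
  - name: HK_Fbox
    pattern: SWFTPFFDQGMS
  - name: HK_G2box
    pattern: GQGLGLYMVKRI
  - name: Hpt
    pattern: XHQXKGSSXS
    key_residue_offset: 1
    key_residue: H
  - name: REC
    pattern: VLVVDDDXVNRT
    key_residue_offset: 6
    key_residue: D
  - name: CHASE
    pattern: GYLGTPXNHPEL
  - name: EthyleneBinding
    pattern: CECCSRPQWPAD
  - name: GAF
    pattern: SGYDRVMVYKFH
  - name: PHY
    pattern: WGLVVCHHTSPR
  - name: PAS
    pattern: NPDGMVIXLSDV
  - name: CCT
    pattern: REARRTRIGEKM
  - name: Myb
    pattern: WTPQEDXLLXQA
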