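# RECONSTRUCTED subpocket definition for an effector-caspase catalytic cleft.
#
# The grouping of interface residues into S1-S4 follows the published
# binding-site description qualitatively, but the exact residue lists were
# never printed alongside the flexibility tables; the numbers below are an
# editable stand-in in mature caspase-3 sequential numbering and MUST be
# adapted to the numbering of the structure actually analyzed.
#
# Schema: subpockets.<name> is a list of {res: <number>, name: <3-letter>}
# entries in protomer-local numbering; protomers.<label> gives the chains of
# each catalytic unit and a residue-number offset relative to the lists.
subpockets:
  S1:
    - {res: 64, name: ARG}
    - {res: 161, name: GLN}
    - {res: 207, name: ARG}
  S2:
    - {res: 204, name: TYR}
    - {res: 206, name: TRP}
    - {res: 256, name: PHE}
  S3:
    - {res: 208, name: ASN}
    - {res: 209, name: SER}
  S4:
    - {res: 214, name: TRP}
    - {res: 250, name: PHE}
protomers:
  "1": {chains: [A], offset: 0}
  "2": {chains: [B], offset: 0}
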