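# Pharmacophore feature typing rules: feature name -> list of SMARTS patterns.
# Every atom matched by any pattern of a feature receives that feature flag.
donor:
  - "[N;!H0]"
  - "[O;!H0]"
acceptor:
  - "[N;!+;!X4]"
  - "[O;!+]"
positive:
  - "[+,++]"
negative:
  - "[-,--]"
hydrophobic:
  - "[C;!$(C~[#7,#8,#9,#15,#16,Cl,Br,I]);!$([C;+,-])]"
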