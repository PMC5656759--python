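# Default replication-protein motif library (consensus-style picorna-like
# patterns for the superfamily III helicase, 3C-like protease and
# superfamily I RdRp loci).
#
# Pattern syntax: '.' matches any of the 20 standard residues; bracketed
# classes are literal alternatives. 'X' and '*' never match anything.
# Patterns are data: replace this file (or pass your own library) to use
# curated motifs without code changes.
motifs:
  - id: Hel-A
    domain: Hel
    pattern: "G..G.GK[ST]"   # Walker A / P-loop
    required: true
  - id: Hel-B
    domain: Hel
    pattern: "[ILVMF][ILVMF][ILVMF]..DE"   # Walker B hydrophobic run + acidic pair
    required: true
  - id: Hel-C
    domain: Hel
    pattern: "[ST]TN..[DE]E"
    required: true
  - id: Pro-H
    domain: Pro
    pattern: "[ILVMF]HY.G[DN]"   # catalytic triad histidine context
    required: false
  - id: Pro-D
    domain: Pro
    pattern: "D[ILVMF][ILVMF]G..P"   # catalytic triad aspartate context
    required: false
  - id: Pro-cat
    domain: Pro
    pattern: "G.[CS]G..[ILVMF][ILVMF]"   # GxCG / GxSG nucleophile site
    required: true
  - id: RdRp-I
    domain: RdRp
    pattern: "KGK.RL[ILVMF]"
    required: false
  - id: RdRp-II
    domain: RdRp
    pattern: "[ST]RF..W"
    required: false
  - id: RdRp-III
    domain: RdRp
    pattern: "DASG.D"
    required: false
  - id: RdRp-IV
    domain: RdRp
    pattern: "DY[ST].FD"   # motif A aspartates
    required: true
  - id: RdRp-V
    domain: RdRp
    pattern: "G.[ILVMF]PSG"   # motif B (GGLPSG-like)
    required: true
  - id: RdRp-VI
    domain: RdRp
    pattern: "[YFM].DD"   # motif C / motif VI: xDD with aromatic context
    required: true
  - id: RdRp-VII
    domain: RdRp
    pattern: "FL[KR]R.F"
    required: false
  - id: RdRp-VIII
    domain: RdRp
    pattern: "[ST]G.P.T"
    required: false
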