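# Calmodulin-binding-protein (CaMBP) inventory for neuroinflammation.
#
# scanned: the 11 neuroinflammation-linked proteins in which putative
#   calcium-dependent CaMBDs were identified by domain scanning (the corpus
#   proteins).
# prior: 13 CaMBPs previously established as neuroinflammation-linked by
#   earlier work, not re-scanned here.
scanned:
  - ABCA7
  - CD33
  - CH3L1
  - CLU
  - CR1
  - EPHA1
  - MS4A4E
  - MS4A6A
  - NLRP3
  - PILRA
  - TREM2
prior:
  - BACE1
  - BIN1
  - CaMKII
  - PP2B
  - PMCA
  - NOS
  - NMDAR
  - AchR
  - Ado A2AR
  - Abeta
  - APOE
  - SNCA
  - TMEM175

# Protein-disease links stated explicitly in the running text of the source
# review (figure-only links are not encoded and are excluded from counts).
# Diseases: AD Alzheimer's, ALS amyotrophic lateral sclerosis,
# FTD frontotemporal dementia, HD Huntington's, LBD Lewy body dementia,
# PD Parkinson's, MS multiple sclerosis, BD/NCL Batten disease / neuronal
# ceroid lipofuscinoses.
disease_links:
  - protein: APOE
    diseases: [AD, ALS, FTD, LBD, PD, BD/NCL]
    source: named a neuroinflammatory risk-factor CaMBP for AD, ALS, FTD, LBD and PD (explicitly not HD or MS), with an additional stated link to BD/NCL
  - protein: CLU
    diseases: [AD, PD, MS]
    source: stated as a CaMBP linked to AD, PD and MS
  - protein: CD33
    diseases: [AD, PD, MS]
    source: stated as a late-onset-AD risk factor also involved in PD and MS
  - protein: TREM2
    diseases: [AD, ALS, FTD, PD]
    source: stated as involved in AD, ALS, FTD and PD
  - protein: ABCA7
    diseases: [AD, FTD]
    source: stated as having a critical function in AD and FTD
  - protein: BACE1
    diseases: [AD, PD]
    source: stated as functioning in AD and PD
  - protein: PP2B
    diseases: [AD, ALS, HD, PD, MS]
    source: stated as associated with AD, ALS, HD, PD and MS
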