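# Literature-reported calmodulin-binding domains (CaMBDs) in human
# neuroinflammation-linked proteins, with the per-class motif counts as
# reported in the source text. Domain strings are in printed-domain
# notation (optional 1-based start/end coordinates flanking the literal
# residues) and are stored byte-identically to how they were reported,
# including known coordinate typographies; the loader flags coordinate
# arithmetic rather than correcting it. printed_counts covers only the
# classes the source text states for that domain.
entries:
  - protein: ABCA7
    label: CaMBD1
    domain_string: "1221LQALLLKRFLLARRSRRGLF1240"
    printed_counts: {"1-10": 3, "1-5-10": 1, "1-14": 1}
    notes: previously reported domain, re-analysed
  - protein: ABCA7
    label: CaMBD2
    domain_string: "1401QGLKTKKWVNEVRYGGFSLG1420"
    printed_counts: {"1-10": 2, "1-5-10": 1}
    notes: ""
  - protein: CD33
    label: CaMBD
    domain_string: null
    printed_counts: {"1-10": 2, "1-12": 2, "1-14": 2}
    notes: sequence-unavailable; only the motif tally was reported
  - protein: CH3L1
    label: CaMBD
    domain_string: "333SVKSKVQYLKDRQLAGAMVW352"
    printed_counts: {"1-10": 1, "1-12": 1, "1-14": 1, "1-16": 1}
    notes: ""
  - protein: CLU
    label: CaMBD
    domain_string: "33VAERLTRKYNELLKSYQWKM352"
    printed_counts: {"1-12": 2, "1-14": 1}
    notes: reported coordinates 33..352 cannot hold a 20-mer; kept as reported
  - protein: CR1
    label: CaMBD
    domain_string: "1090VVTYRCNLGSRGRKVFEL1107"
    printed_counts: {"1-16": 1}
    notes: near-identical repeats at 207, 657 and 1560 were not called domains
  - protein: EPHA1
    label: CaMBD
    domain_string: "167NVERCSLGRLTRRGLYLA184"
    printed_counts: {"1-12": 1, "1-14": 1, "1-16": 1}
    notes: ""
  - protein: MS4A4E
    label: CaMBD1
    domain_string: "28HSYLCKGLQEKFFKRKPKV6"
    printed_counts: {"1-10": 1, "1-12": 1}
    notes: trailing coordinate "6" is a typography in the source; kept as reported
  - protein: MS4A4E
    label: CaMBD2
    domain_string: "107NYLKNLSWRIMGSYLCF123"
    printed_counts: {"1-12": 2, "1-14": 1, "1-5-10": 1}
    notes: ""
  - protein: MS4A6A
    label: CaMBD
    domain_string: "101LSIATEKRLTKLLVH115"
    printed_counts: {"1-10": 2, "1-12": 2, "1-14": 1}
    notes: ""
  - protein: NLRP3
    label: CaMBD1
    domain_string: "564ENYGKFEKGYLIFVVRFLFGLVNQERT589"
    printed_counts: {"1-10": 2, "1-14": 1, "1-16": 1}
    notes: reported span 564..589 is one residue short of the 27-mer; kept as reported
  - protein: NLRP3
    label: CaMBD2
    domain_string: "603QIRLELLKWIEVKAKAKKLQIQ624"
    printed_counts: {"1-10": 2, "1-12": 1, "1-14": 1, "1-16": 1}
    notes: ""
  - protein: PILRA
    label: CaMBD
    domain_string: "208IMILGLICLLRWRRRKGQQRT229"
    printed_counts: {"1-10": 1, "1-5-10": 1}
    notes: reported span 208..229 is one residue longer than the 21-mer; kept as reported
  - protein: TREM2
    label: CaMBD
    domain_string: "62RVVSTHNLWLLSFLRRWNG80"
    printed_counts: {"1-10": 2, "1-12": 1, "1-16": 1}
    notes: extracellular; contains the FTD-like pathogenic site T66M

# The single calcium-independent motif reported across the scanned set:
# an IQ-like occurrence in NLRP3, outside both calcium-dependent domains.
iq_regions:
  - protein: NLRP3
    domain_string: "322WQKAERGDILLSSL335"
    printed_variant: IQ-like
    printed_count: 1
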