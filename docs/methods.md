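# Methods

## Motif model

A calcium-dependent CaM-binding motif class is a tuple of relative anchor
offsets starting at 0: 1-10 ≡ (0, 9), 1-12 ≡ (0, 11), 1-14 ≡ (0, 13),
1-16 ≡ (0, 15), 1-5-10 ≡ (0, 4, 9), 1-5-8-14 ≡ (0, 4, 7, 13). The span of
a class is its last offset + 1. A sequence position `i` (1-based) is an
occurrence iff the residue at `i + o` belongs to the anchor alphabet for
every offset `o`. The scan is exhaustive over all starts, N→C only
(motif nomenclature is defined on the forward chain), overlap-tolerant,
and performs no cross-class deduplication: a 1-5-10 occurrence always
implies a 1-10 occurrence at its outer anchors and both are counted, which
is how tallies are conventionally reported in the CaM literature.
Sequences shorter than a class span yield zero hits rather than an error,
which keeps whole-proteome sweeps simple.

**Anchor alphabet.** The default is the strict bulky-hydrophobic set
{F, I, L, V, W}. It is the single uniform choice that reproduces the
largest share of the literature-reported corpus tallies (24 of 35
compared cells). M, A and Y are offered as named extensions
(`strict+M`, `strict+A`, `strict+Y`, or `custom:<letters>`) because a few
reported tallies are only attainable with them (e.g. the CH3L1 1-10 needs
M; the EPHA1 1-12 needs A). `X` (unknown residue) is accepted in input
but can never anchor. Extended codes (U, B, Z, J, O) are rejected at
parse time: none occur in the corpus, and silent acceptance risks
miscounted anchors.

**IQ motifs.** Canonical IQ is `[FILV]Qxxx[RK]Gxxx[RK]xx[FILVWY]`
(14 residues). "IQ-like" is defined here as the relaxed head
`[FILVWY]Qxxx[RK]G`: incomplete variants keep the IQ head but degenerate
in the tail, and the one IQ-like occurrence in the corpus (NLRP3,
`WQKAERGDILLSSL`) fails the canonical pattern at position 1 (W) and
position 11 (L) while satisfying the head exactly. Positions matching the
canonical pattern are reported as `IQ`; positions matching only the head
as `IQ-like`. Overlaps are all reported.

## Coordinate conventions

All coordinates are 1-based inclusive, matching residue numbering in the
literature. Printed domain-string notation
(`1221LQALLLKRFLLARRSRRGLF1240`) is parsed into sequence plus optional
coordinates; the literal residue letters are always authoritative. When
the coordinate arithmetic fails (`end − start + 1 ≠ length`) the record is
flagged `inconsistent`, never corrected — four corpus entries carry such
typographies (CLU 33..352, MS4A4E CaMBD1 28..6, PILRA 208..229 for a
21-mer, NLRP3 CaMBD1 564..589 for a 27-mer) and all four are preserved
verbatim with the flag set.

## Corpus and concordance

The packaged corpus holds the 13 reported CaMBD sequences across 11
neuroinflammation-linked proteins plus a counts-only CD33 entry (its
sequence was never published), each with the per-class tallies reported
in the source review. `reproduce_counts` re-derives each reported tally
by enumeration under a chosen alphabet and emits a per-cell
(reported, enumerated, match) table. Only classes with a reported count
are compared; the comparison never manufactures implicit zeros for
unmentioned classes. Under the strict alphabet, 11 of 35 cells disagree.
The disagreements are structural, not tunable: some reported counts
require anchors outside any uniform alphabet choice, others are smaller
than the number of strict-anchor occurrences that demonstrably exist
(e.g. TREM2 has the two strict 1-12 pairs (2,13) and (3,14) but one was
reported). The report surfaces all of them; forcing agreement would
require per-cell special-casing with no principled basis.

The inventory unions the 11 scanned proteins with 13 previously
established neuroinflammation CaMBPs (set semantics; an overlap would be
flagged and counted once) giving 24. The protein × disease matrix encodes
only links stated in the source's running text; figure-only links are not
encoded and are excluded from all marginals.

## Domain caller

The profile-HMM predictor historically used for the first stage of CaMBD
identification is an unpublished web service; this package's caller is an
explicitly heuristic stand-in and the corpus reproduction path never uses
it (reported domains are scanned directly). The caller slides windows of
every length in 15–27 (the corpus domains span 15–27 residues) and scores

`composite = 10·motif_density + 0.2·max(net_charge, 0)
+ 0.5·mean_hydropathy + 1.0·hydrophobic_moment − 0.5·proline_count`

with motif density in hits/residue, charge +1 per R/K and −1 per D/E
(acidity floored at zero: basicity is rewarded, acidity merely not),
hydropathy on the Eisenberg consensus scale, and the hydrophobic moment
as the magnitude of the helical-wheel vector sum of **mean-centred**
hydropathies at 100°/residue. Mean-centring makes the moment a pure
amphipathicity measure (a compositionally uniform window scores exactly
zero) rather than conflating it with bulk hydrophobicity. Prolines are
penalised as helix breakers. Windows at or above the threshold (default
2.0) are kept and overlaps resolved greedily by descending composite,
ties by smaller start then shorter window — simple, deterministic and
testable. The weighting emphasises motif density because it is the most
specific of the four signals: a motif-dense 20-mer contributes ~2.5 from
density alone, clearing the threshold, while neutral backgrounds score
near zero. No published score or threshold exists for the original web
predictor and none was inferred from its output; these defaults are this
package's own design and users should treat caller boundaries as
proposals, not reproductions.

## Synthetic data

`synthetic` generates i.i.d. backgrounds from a residue composition —
default uniform over the 20 residues (the simplest null), with an average
human-proteome composition as a named preset — using NumPy's seeded
PCG64 generator, so output is reproducible across runs and platforms.
Planting overwrites residues in place (length and coordinates stay
stable): anchor offsets receive alphabet residues, the rest of the span
receives non-anchor residues, guaranteeing detectability at exactly the
planted start; whole-domain templates can be planted literally. Truth
tables record id, kind, start, end.

For an i.i.d. background with anchor probability `p`, a class with `k`
anchors and span `s` has expected chance hits `p^k · (L − s + 1)` per
length-`L` sequence (per-start indicators are each Bernoulli(`p^k`);
expectations add despite dependence between overlapping starts). This
closed form is the analytic check on the simulator: simulated means agree
within three standard errors.

What the generator does **not** emulate: residue autocorrelation,
secondary-structure and disorder context, compositional bias of real
CaMBD flanks, and homology. Passing planted-recovery and rate tests
therefore validates the scanner's bookkeeping and the null calibration,
not biological discrimination on real proteins.

## Problem sizes and numerical choices

Tests exercise the scanner against an independent lookahead-regex oracle
on 1000 random sequences (length ≤ 40) and measure sensitivity and
background rate on 10⁴ simulated length-50 sequences — sizes at which the
binomial standard error makes the 3σ band a meaningful check while the
whole suite stays interactive (seconds). All statistical tests are
seeded. Floating point enters only the caller (moment/hydropathy);
comparisons there use exact equality on repeated runs (determinism) and
an absolute 1e-9 tolerance on the uniform-window zero-moment identity.

## Known limitations

- Motif presence is necessary, not sufficient, for CaM binding; no
  affinity or calcium-dependence prediction is attempted.
- The caller is untrained and heuristic; its boundaries will not match
  profile-HMM predictors.
- The corpus disease links cover only what the source text states; the
  fuller figure-level association matrix is deliberately not encoded.
- 1-8-14 and other variant classes are not in the default roster (the
  corpus never reports them) but are expressible as custom offset tuples.
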