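# Methods

This note documents the models, parameters and numerical choices behind
phytoms, and what the synthetic benchmarks do and do not demonstrate.

## Mass arithmetic

Monoisotopic masses are sums of most-abundant-isotope masses (C 12
exact, H 1.00782503, N 14.00307400, O 15.99491462, S 31.97207100,
CODATA/NIST values carried at full double precision). Ion m/z values
are electron-corrected: a protonated ion adds a proton
(1.00727646 Da = H − e⁻), a deprotonated ion removes one; the
ammonium, water-loss and formate adduct deltas are derived from the
same isotope table at import time rather than stored as opaque
constants, and a test asserts that derivation. This convention — not
the H-atom convention — reproduces published 4-decimal theoretical
masses of reference flavonoids (e.g. 445.0776 for the deprotonated
C₂₁H₁₈O₁₁ ion), which is how the convention was chosen. Formatting
follows instrument-report practice (4 dp m/z, 2 dp ppm) while all
arithmetic stays at double precision. The supported adduct set is
deliberately closed (`[M+H]+`, `[M+NH4]+`, `[M+H−H2O]+`, `[M−H]−`,
`[M+HCOO]−`, charge ±1): multiply charged species and exotic adducts
are out of scope.

Signed ppm error is `(measured − theoretical)/theoretical × 10⁶`.
Published compound tables occasionally print ppm values that disagree
with recomputation from their own 4-dp masses by up to ~0.5 ppm
(vendor software used unrounded measured masses); tests therefore
assert printed ppm values only where recomputation from printed digits
agrees, and use a 0.00015 Da bound (4-dp rounding half-width plus
slack) for table-wide mass checks.

## Feature extraction

The finder follows the standard open-source LC-MS chain with the
processing parameters the pipeline is validated under: MS¹/MS² noise
floors 1000/100 counts; chromatogram building with ≥ 5 consecutive
scans, tolerance `max(0.005 Da, 10 ppm)` around a running
intensity-weighted mean, ≥ 3000 counts reached at least once; local
minimum resolving with minimum absolute height 7000, 5 scans, peak
duration within (0, 1] min; a ¹³C filter (Δm/z 1.00336 ±
`max(0.001 Da, 5 ppm)`, Δrt ≤ 0.01 min, satellite smaller than parent,
charge 1 only); join alignment at `max(0.001 Da, 5 ppm)` / 0.1 min
with weights 3 (m/z) and 1 (rt).

Two semantics were genuinely open and are package decisions:

* **Chromatographic threshold (90 %).** Implemented as a valley-split
  rule: a local minimum separates two sub-peaks iff its intensity is at
  most `1 − 0.90` of the smaller adjacent apex. A valley at 5 % of the
  apex splits; one at 50 % does not. The rule is monotone in the
  threshold and covered by a golden test.
* **MS² pairing.** A spectrum attaches to a feature when its precursor
  is within the alignment m/z tolerance and its retention time falls
  inside the feature's elution window; the most intense candidate wins.
  Pairing tolerances are not independently specified anywhere, so the
  alignment tolerances are reused.

Tie-breaks everywhere are deterministic (score, then |Δmz|, then input
order); no smoothing and no gap-filling are performed.

## Modified cosine and networking

Intensities are square-root transformed (the molecular-networking
convention; configurable in principle, √ by default). Candidate
fragment pairs match directly (|Δ| ≤ 0.02 Da) or shifted by the
precursor mass difference; each peak participates once; the one-to-one
matching is greedy by descending √-intensity product. Greedy rather
than optimal assignment matches common practice; the benchmark
(`phytoms.benchmark.greedy_vs_optimal`) bounds the gap empirically —
over 1000 randomized ≤ 6-peak pairs the greedy cosine stays ≥ 0.95 of
the exhaustive optimum (in the shipped runs it is numerically equal),
and an independent cross-check against matchms's implementation agrees
to 1e−6 on random spectra. Edges require cosine ≥ 0.70 **and** ≥ 6
matched fragments; clusters are connected components with ≥ 2 nodes.
No top-K edge pruning and no component-size cap are applied by default
(both exist as options but off, so cluster statistics are reproducible
from the two thresholds alone). Library matching reuses the same
scorer with a ≥ 6 matched-peak floor; cluster members inherit a
flagged class *hypothesis* from annotated neighbours, never
overwriting a library or reference-standard annotation, and
conflicting neighbour classes yield an explicit "ambiguous".

## Diagnostic-ion / neutral-loss rule engine

Rules are data (CSV), not code: diagnostic ions (matched against
fragment peaks), neutral losses (matched against all pairwise
precursor/fragment differences > 1 Da) and serial losses (longest
equally-spaced peak ladder, computed by dynamic programming over peaks
sorted by mass). Default tolerance is 0.01 Da against theoretical
values; fixture tests against *printed* worked-example fragments use
0.03 Da because published 4-dp peak lists carry up to ~30 mDa of
calibration and rounding drift.

Scoring is deliberately minimal so that a qualitative practice becomes
reproducible: each fired rule contributes its weight (diagnostic ions
2, losses 1, serial losses 2), a class is assigned only when ≥ 2 rules
fire and the top class beats the runner-up by ≥ 1 weight unit;
otherwise the spectrum is "unclassified" with both candidate scores
reported. The margin prevents oscillating assignments between classes
that share generic losses (H₂O, CO, CH₃). The shipped rulebase covers
the ten class/polarity combinations with well-described fragmentation
chemistry (flavonoids in both modes, iridoid and sesquiterpene/
triterpene terpenoids, phenylpropanoids, indole alkaloids,
anthraquinones in both modes, phenylethanoid glycosides,
oligosaccharides, phenolic acids, xanthones); classes without published
diagnostics (e.g. diarylheptanoids) ship no rules and therefore never
win — a deliberate abstention rather than a guess. Weights and the
class margin were designed jointly with the generator templates so
that every class template outscores all other classes by at least one
weight unit; positive-mode flavonoid aglycones need their A-ring RDA
diagnostics (m/z 169.065, 123.008) for this, because their generic
losses alone are indistinguishable from xanthones.

Annotation validation accepts a proposed class when the engine agrees,
or when it abstains with the proposed class as its top candidate;
everything else is rejected with the conflicting evidence. This is the
mechanism that prunes spectral-library false positives from the
network.

## In-vivo stage

Presence calls: a compound is detected when its selected-adduct XIC
(±5 ppm, optional ±1 min window around the library retention time)
reaches ≥ 7000 counts in the dosed run while the blank apex stays
below 5 % of the dosed apex. The 7000 floor reuses the feature-finder
minimum height; the 5 % blank fraction operationalises "not observed
in blank" and both are configurable and recorded per call.

Metabolite prediction enumerates transformation multisets (order does
not affect the product, so chains are identified by multiset and
rendered in ledger order), deduplicates by resulting formula keeping
the shortest chain, prunes chains that net to the unchanged prototype
or would drive an element count negative. The shipped ledger holds the
twelve common phase-I/II reactions (±CH₂, ±O, ±2H, +SO₃, +C₆H₈O₆,
+C₆H₁₀O₅, −C₆H₈O₆, −C₆H₁₀O₅, −CO₂); chain mass shifts agree with
formula-difference masses to 1e−5 Da at any depth by construction.
Matching requires a dosed-only feature within 5 ppm of a predicted
adduct m/z *of the feature's own polarity* (cross-polarity aliases of
nearby masses are a real failure mode otherwise) and, with evidence
required, ≥ 1 fragment shared with the prototype's spectrum — directly
or shifted by the chain mass — or a rule-engine confirmation of the
prototype's class. Isomeric candidates with identical formulas are all
reported and flagged, never merged: exact mass cannot distinguish
them, and pretending otherwise would be false precision. Pathway
assembly adds glucuronide/glucoside → aglycone hydrolysis edges
between detected prototypes whenever the formula arithmetic links
them.

## Synthetic data: what it emulates, and what it does not

The generator plants, per compound: a symmetric triangular elution
peak 0.3 min wide at 0.05-min scan spacing with apex 1e5 counts (the
simplest shape clearing every finder threshold), m/z jitter of 1 ppm
s.d. (within the 5 ppm error envelope of the study conditions), one
MS² spectrum whose fragments follow the class template at exact
masses, fixed descending rank intensities (base peak 1e5 — only
ordering matters downstream), Poisson noise peaks at 20 % of the
template count below 1000 counts, and uniform MS¹ noise below the 1000
floor. Metabolite spectra shift the precursor and half the fragments
by the chain mass, keeping the conserved core — the signature the
evidence matcher looks for. Decoys sit at metabolite-like masses with
scrambled fragments. Sample structure mirrors a dosing study: extract,
blank/dosed plasma, blank/dosed cerebrum; planted metabolites appear
only in dosed matrices, blanks carry only noise. Identical seeds give
byte-identical outputs; changing the seed changes noise and jitter but
not the planted truth.

Not emulated: chromatographic tailing, matrix effects, in-source
fragmentation, isotope envelopes beyond the single ¹³C satellite,
intensity dependence of fragmentation, and real spectral diversity
within a class. Consequently the planted-truth benchmarks demonstrate
*correctness of the machinery under its stated assumptions* — they do
not estimate real-data annotation accuracy, where class templates vary
far more than the generator's.

## Benchmark sizes and expected outcomes

The end-to-end benchmark uses 9 prototypes spanning seven structure
classes, 5 planted depth-≤ 2 metabolites, 4 decoys, ~420 MS¹ scans per
matrix across 5 matrices — sized so the full suite runs in well under
a minute while exercising every stage. Under these conditions the
pipeline achieves prototype recall 1.0 with zero false calls in
blanks, and formula-level metabolite precision/recall 1.0 (the
acceptance thresholds are ≥ 0.9; "formula-level" means an isomeric
candidate matching a genuinely isomeric planted ion counts as correct).
The classifier corpus (50 noisy spectra per class/polarity) requires
≥ 90 % recall per class and zero cross-class confusions; current
margins give 100 % on most classes.

## Known limitations

* The library-annotation step needs ≥ 6 matched peaks; template
  spectra with fewer than six fragments can never be library-annotated
  under the published default, which is visible in the analysis run
  (positive-mode singleton nodes stay unannotated).
* The rule engine's abstention margin of one weight unit makes some
  correct calls marginal (phenolic acids vs. phenylethanoid glycosides
  share the caffeoyl fragments); rule weights are data, so a user with
  richer spectra should retune them.
* mzML support is read-only and centroid-only; profile data must be
  peak-picked upstream, and vendor formats are out of scope.
* Isomers sharing formula and class (e.g. cis/trans phenylpropanoid
  pairs) are reported side by side, distinguishable only by retention
  time; no retention model is fitted.
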