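# Methods

## The annotation model

An MS1 feature is a chromatographic peak with an *m/z*, a retention time
(seconds, the canonical unit throughout) and a per-sample intensity vector.
`featlink` treats redundancy as a set of typed binary relations between
features — isotope, adduct sibling, neutral loss, in-source fragment, and
shared primary ion — each detected by pure mass/rt arithmetic, and then
derives group structure from the relation graph and from intensity-profile
correlation. Nothing in the annotation path is stochastic; given the same
inputs and parameters, every output is bit-identical.

### Tolerances

All *m/z* comparisons use a paired tolerance (absolute Da, ppm) whose
effective width at an expected *m/z* x is `max(abs_da, ppm * x * 1e-6)`.
The "0.002 Da or 5 ppm" phrasing common in vendor tools is ambiguous about
which term governs; the maximum reading makes the absolute floor active at
low mass and the relative term at high mass, which is the generous and, in
our view, intended behaviour. Retention-time windows are maximal absolute
differences: a window w admits |Δrt| ≤ w.

Defaults, all individually overridable (flags mirror these names):

| step | m/z tolerance | rt window |
|---|---|---|
| target matching | 0.002 Da / 5 ppm | 20 s (only when the target has an rt) |
| adduct search | 0.005 Da / 5 ppm | 2 s around the primary feature |
| precursor alignment | 0.002 Da / 5 ppm | 20 s |
| fragment matching | 0.005 Da / 10 ppm | 3 s co-elution (see below) |
| isotopes | 0.002 Da first order, 0.01 Da higher | 3 s |
| neutral losses | 0.002 Da / 5 ppm | 2 s |
| correlation grouping | — | 2 s per pair |

### Primary ions and adducts

Molecular formulas are parsed (Hill notation, parentheses, multi-letter
elements; charges and isotope labels rejected — target lists carry neutral
formulas) and monoisotopic masses computed from embedded IUPAC element
masses. The primary ion is [M+H]⁺ in positive mode, [M−H]⁻ in negative.
Adduct rules are declarative: ion *m/z* = (k·M + mass_shift)/|z|, with
mass_shift already including charge carriers and electron masses
(proton = 1.007276 Da), so no separate electron correction is applied —
the convention of common ESI adduct calculators. Adduct annotation is
deliberately target-derived: expected *m/z* values come from matched
targets' neutral masses, not from untargeted pairwise shift scanning, which
keeps the false-positive surface small.

### Isotopologue chains and charge states

¹³C isotopologues appear at spacings of 1.0034/z (1.0034, 0.5017, 0.3345
for z = 1, 2, 3), up to order 4. The first-order spacing must match within
0.002 Da; higher orders get 0.01 Da so that peaks dominated by heavier
isotopes of S, Cl or Br are still captured (they keep the generic [M+n]
label). One choice here was genuinely open: a purely pairwise reading of
"differences equal to 1.0034 and multiples" makes z = 1 chains ambiguous,
because 2 × 0.5017 equals 1.0034 exactly, and a higher-charge-wins
tie-break would then misassign every z = 1 first isotope as a z = 2 second
isotope. We therefore require chains to be *contiguous*: order n is only
considered after order n−1 was found at the same charge. That matches how
an isotopologue envelope is physically produced and removes the degeneracy;
conflicts that remain (a feature claimed by several chains) are resolved by
smallest spacing deviation, then higher charge, then lower anchor *m/z*.
Anchors that are themselves satellites are compressed to the chain root.
No intensity-ratio filter is applied — detection is purely m/z/rt-based —
though the satellite must simply exist as a picked feature.

### In-source fragments

ISF detection uses DDA MS2 spectra, ideally from a pool sample: precursor
ions are aligned to the nearest-*m/z* feature within tolerance, then each
aligned spectrum's fragment peaks are matched back to MS1 features. Two
constraints are added beyond the fragment *m/z* tolerance, both
configurable: the fragment feature must co-elute with the precursor feature
(3 s) and must be lighter than it, and fragment peaks below 1% of the base
peak are ignored. Without a co-elution constraint a fragment *m/z* would
match features anywhere in the run, generating spurious ISFs, and real DDA
spectra need a noise floor; both are conservative operational choices, not
claims about source physics. A fragment feature may be the ISF of several
precursors — multimers legitimately share fragments. MGF spectra without
retention times are aligned on *m/z* alone and their edges flagged
`rt-unverified`.

### Grouping

`group` is the connected-component index over all relation edges: any chain
of relations merges features into one group. `corgroup` implements
annotation by perturbation: if a metabolite's abundance changes x-fold
between conditions, every feature it generates changes x-fold, so log₁₀
intensity profiles of same-metabolite features correlate near 1 across a
perturbed sample series. Pairs within 2 s of each other are correlated
(Pearson default; Spearman/Kendall available) over pairwise-complete
samples; zeros and missing values are non-detections and never enter
(log₁₀ 0 is undefined and "not detected" is not "measured zero"). A
correlation is undefined — and never links — when fewer than `min_pairs`
(default 4) complete pairs exist or a vector is constant.

"Every pair in a corgroup exceeds the threshold" is enforced literally:
corgroups are cliques in the correlation graph (strict > 0.8), extracted
greedily — largest maximal clique first, ties by higher mean pairwise
correlation, then earliest-eluting member, then lexicographic ids — with
extracted members removed, so each feature carries at most one corgroup
index. The alternative reading (connected components of the correlation
graph) was rejected because transitive chaining can link features whose
own correlation is weak. The rt constraint applies per pair, so cliques
are also rt-local with no transitive rt chaining.

Both indices are dense and 1-based, ordered by the earliest-eluting member
(ties: lowest *m/z*, then id); singletons stay unassigned. The pairwise
intersection of the two assignments (co-grouped in both) is the
conservative combination; the union (co-grouped in either) the sensitive
one. Intersection can only remove pairs and union only add them, which is
asserted as a property test.

### Evaluation

Grouping quality is the standard pair-counting clustering metric: over all
C(n,2) unordered pairs, predicted-together (same group index) is crossed
with truly-together (same non-background compound). Background features
are never truly together; unassigned features are predicted-apart from
everything, so an ungrouped true satellite costs a false negative.
FDR = FP/(FP+TP) (0 when nothing is co-grouped) and TPR = TP/(TP+FN)
(undefined without true pairs). The implementation uses group-size
contingency sums and is tested against an exhaustive double loop.

## The simulator

The generator emulates a spike-in benchmark: metabolites with sampled CHNO
formulas (C 6–30, H ≈ C..2C+2, N 0–3, O 1–10) elute uniformly over
60–600 s and each emits a primary ion, isotopologue satellites (intensity
ratio approximated as 0.011 × nC per order — crude, but the annotator uses
only spacings), Bernoulli-sampled adducts, and Poisson(1.5) in-source
fragments built as parent minus a bundled neutral-loss mass, so ISF
features are simultaneously NL-annotatable, as real glycoside fragments
are. Fragmenting metabolites get a pseudo-DDA MS2 spectrum whose peaks hit
the ISF *m/z* values, plus low-mass noise peaks below the intensity floor.

Intensities follow the perturbation model: metabolite base abundance
~N(6, 0.5) log₁₀, one shift per condition ~N(0, 0.7) log₁₀ (≈5-fold
changes, an antibiotic-perturbation-like spread) shared by all of the
metabolite's features, a fixed per-feature offset, and i.i.d. replicate
noise (sd 0.05 log₁₀). *m/z* values get N(0, 0.5 mDa) error, retention
times N(0, 0.5 s) jitter, and 2% of intensities drop out. Background
features have independent profiles (per-sample sd 0.4 log₁₀, no condition
structure), so chance correlations above 0.8 across 18 samples are rare.
Defaults — 50 metabolites, 6 conditions × 3 replicates, 100 background
features — are the study conditions under which the acceptance metrics are
computed; `scripts/acceptance.py` pools three simulated datasets per run.

What the simulator does *not* emulate, and hence what passing tests cannot
show: chromatographic peak shape (no peak-shape correlation is available,
by design — grouping here uses perturbation profiles instead), chimeric
MS2 spectra, correlated background structure (real matrix features share
pathways and do correlate), retention-time drift between samples, and
detector saturation. Recovery rates on simulated data are therefore upper
bounds on real-data performance, useful for verifying the algorithm, not
for benchmarking against other tools.

## Numerical and I/O choices

* Feature tables: delimiter sniffed; id/mz/rt columns found by common
  XCMS/MZmine header aliases, every other numeric column is an intensity.
  rt is stored in seconds; the `mzmine` dialect converts from minutes, and
  `auto` assumes minutes (with a warning) when every rt is below 60.
* Absent annotations are written as empty strings, never "NA", which reads
  as a sodium adduct shorthand in this domain.
* mzML is read by a minimal built-in reader (ElementTree, base64, optional
  zlib; 32/64-bit floats) covering centroided single-precursor DDA
  spectra; MGF and mzXML go through pyteomics.
* Tie-breaks are deterministic everywhere (documented per operation above);
  results are invariant to feature-row and spectrum order, asserted as
  property tests.
* Degenerate inputs: empty target list, empty spectra collection and empty
  edge sets are valid and yield empty results; isotope annotation requires
  at least one retention time; correlation requires ≥ 2 samples, and the
  pipeline skips corgroups (all unassigned) on single-sample tables.

## Known limitations

Adduct annotation finds only adducts of *matched targets* — without a
target list the relational grouping rests on isotopes, neutral losses and
ISFs alone. The neutral-loss pass annotates any co-eluting pair whose
Δ*m/z* matches a table entry, which on dense tables can produce chance
links; the corgroup intersection is the intended guard. Isotope detection
trusts the peak picker: split or missing isotopologue peaks break chain
contiguity above the gap. Charge states beyond 3 and isotope orders beyond
4 are out of scope, as are formula inference from mass, spectral-library
identification, and overlapping (soft) group membership.
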