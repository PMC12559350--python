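# Methods

## The decoding problem

A self-encoded library is a combinatorial set: at each of P scaffold
positions one building block (BB) from a per-position set is installed, so
the library is the cross product of the sets.  After an affinity selection,
the retained pool is measured by nanoLC-MS/MS and each hit must be
identified from (a) its intact (MS1) mass and (b) its fragment (MS2)
spectrum.  MS1 alone is insufficient: large combinatorial libraries are
heavily mass-degenerate (BB-permutation isobars and accidental mass
coincidences), so the decoder must test predicted fragments.

## Formula model

Every BB carries a *contribution formula*: the atoms it adds to the
assembled molecule with condensation losses already applied (an amino acid
in an amide scaffold contributes its residue formula).  Scaffold-constant
atoms — terminal H/NH₂ of an amide scaffold, or a heterocyclic core such as
C8H3N2O for a trisubstituted benzimidazole — live in a separate
`scaffold_offset` formula.  A member's formula is then the plain sum of its
P contributions plus the offset, and enumeration reduces to array
arithmetic.  Masses use NIST monoisotopic atomic masses; formula addition
is exact integer arithmetic, so mass additivity holds to < 1e-9 Da.
Signed intermediate formulas are permitted (needed for offsets expressing
losses); a *fragment* whose net formula goes negative is physically
impossible and is skipped with a warning.

Virtual-library BB selection scores members by five drug-likeness bounds
(MW ≤ 500, logP ≤ 5, HBD ≤ 5, HBA ≤ 10, TPSA ≤ 140 Å² — classical
rule-of-five values plus the common TPSA bound; all configurable), one
point per satisfied bound.  Per-BB scores aggregate the *mean* member
points over all members containing the BB, making positions with different
set sizes comparable (a sum would scale with the complementary set sizes);
ranking is descending mean with stable bb_id tie-breaks.  Catalog-scale
virtual libraries (10⁹ members) are scored by streaming flat-index chunks
and accumulating per-BB sums position-wise; full materialisation is only
used for real libraries (≤ 10⁷).

## Fragment grammar

Observed fragmentation of these scaffolds concentrates on bonds between
building blocks, so predicted fragments are described by a small grammar
instead of bond-level combinatorial fragmentation:

* `S[i;j]` — contiguous positions i..j **plus** the scaffold offset
  formula.  Scaffolds with a central core (offset non-empty) thus get
  core-containing fragments; for scaffolds with an empty offset the S-types
  are pure spans.  `S[i:j]` (colon) is accepted as an alias.
* `k` — the BB at position k alone, without the offset.

Each type yields 2H+1 ions for hydrogen shifts −H..+H (H = 1 by default;
±1 hydrogen rearrangements are ubiquitous in small-molecule CID), at
neutral mass + h·1.0078250 Da + adduct mass.  Ionisation defaults to
`[M+H]⁺` (proton 1.0072765 Da, charge 1); Na⁺/K⁺ adducts are available,
charge states > 1 are not modelled.  Whether single-position fragments of a
cored scaffold should also carry part of the core is scaffold chemistry the
grammar leaves to the user: add or omit the core via the type spec.

Fragmentation *frequencies* are estimated from spectra of known compounds:
for each type, the fraction of spectra containing at least one peak within
the MS2 ppm tolerance of any shift variant of that type's ion.  On
simulated data these estimates recover the generator's per-type emission
probabilities within binomial error.

## Scan filter, ranking, replicates

For each MS2 scan the observed neutral mass is
(precursor m/z − adduct mass) × z; candidate compounds are all library
members within the MS1 tolerance, with ppm referenced to the library
(theoretical) mass.  Among the scan's N most intense peaks
(N = `n_considered_peaks`, default 5; intensity ties keep the lower m/z), a
peak matches a predicted ion when within the MS2 tolerance of the predicted
m/z; (peak, ion) pairs are consumed greedily by ascending |Δppm|, each peak
and each ion at most once, and the match count is the number of distinct
matched peaks.  ("Minimum matching peaks" counts distinct *peaks*, not
distinct predicted fragments; the alternative reading is obtainable by
deduplicating ions upstream.)  A scan is retained iff some candidate
reaches `min_matching_peaks` (default 1).  Retention is monotone: raising
`min_matching_peaks` or shrinking either tolerance never adds scans.

Surviving candidates are ranked by a transparent intensity-weighted
coverage score: (Σ intensities of matched considered peaks) / (Σ
intensities of considered peaks), plus 1e-6 × match count as a tie-nudge,
clipped to [0, 1]; exact ties order by compound id so ranking is fully
deterministic.  The published workflow re-ranks candidates with a
molecular-fingerprint scorer; that requires externally trained prediction
models and is deliberately out of scope here — the coverage score keeps the
isobar-resolution step reproducible and testable.  The rank-1 candidate of
a retained scan is the accepted annotation; per-compound hits deduplicate
accepted scans by compound id.  Replicate runs merge by union (any run,
with provenance) or intersection (all runs), with pairwise Jaccard overlap
reported.

## Background subtraction

A sample feature is removed iff some control-run feature matches it within
5 ppm and 10 s (apex RT) *and* the sample/control intensity ratio is below
3; MS2 scans linked to removed features are dropped with them.  With
several controls the rule fires against any of them; control intensity 0
gives an infinite ratio (kept).  Feature intensity is apex by default.  The
source workflow states the GUI parameterisation used here (5 ppm / 10 s /
ratio 3) and, in prose, a stricter variant (2 s / fold < 2); the defaults
follow the GUI values and both are plain configuration.  No RT alignment is
performed — the tolerances absorb drift.

Feature finding itself is a deliberately simple, transparent stand-in for
vendor feature detection: MS1 peaks are clustered by m/z (5 ppm gap rule),
clusters split at RT gaps > 6 s, apex = most intense point; MS2 scans link
to the nearest-in-m/z feature whose padded RT span covers them.  External
feature tables (TSV) can be supplied instead.

## Enrichment statistics

Selection-level: E = (found/after) ÷ (binders/library) with total binders
postulated equal to found binders, i.e. E = library / after × hit fraction;
reported to 2 significant figures (e.g. 74/228 vs 74/499,720 → 2191.75 →
2.2 × 10³).  BB-level: for each BB at each position, the 2×2 table "hits
containing the BB vs not" against "library members containing the BB vs
not" is tested one-sided for enrichment; p = P(X ≥ k) under the
hypergeometric null, computed via the log survival function so deep tails
(≪ 1e-300) do not overflow before the final exponentiation.  Degenerate
margins (BB in all or no members, zero hits with the BB) give p = 1.
Because hundreds of BBs are tested per report, Benjamini–Hochberg q-values
are attached and significance is called at q ≤ α.  Whether the test should
pool positions or be two-sided is not fixed by the source; per-position
one-sided enrichment is the natural reading and the implemented choice.

## Synthetic experiments

The simulator generates the statistical structure the decoder assumes, at
the scale of the published decodability experiments (a few hundred known
compounds per run, dominated by noise):

* defaults: 50 true binders, 500 noise scans, 100 shared background
  features, log-normal intensities (μ = 11.5, σ = 1 in ln counts —
  ~10⁵-count apexes), 1 ppm Gaussian m/z jitter, 1200 s RT window with 2 s
  survey-scan spacing, one MS2 scan per binder feature (data-dependent
  acquisition sparsity), per-fragment-type emission probability 0.8;
* binder features elute over 3 adjacent MS1 spectra; their MS2 peaks are
  the predicted h = 0 ions, each emitted independently with its type's
  probability, with coincident ions merged as one centroid;
* noise-scan precursors are rejection-sampled ≥ 50 ppm from every library
  mass, so the false-positive channel isolates MS2-level failures; the
  `isobaric` decoy mode instead places them on library masses to stress
  fragment-level discrimination;
* background features appear in both runs with sample/control ratio drawn
  uniformly from (0.5, 2.5) — below the subtraction threshold by
  construction — and ≥ 50 ppm from library masses so they never collide
  with binder features.

Everything derives from one integer seed; equal configs produce
byte-identical mzML and truth files.  Not modelled: chromatographic peak
shapes, isotope envelopes, multiple charge states, ionisation bias and
in-source fragmentation.  Synthetic recall therefore validates the
decoding logic (filtering, matching, ranking, subtraction), not
instrument-level detectability; on real data the detectable fraction of
library compounds is governed by chemistry the simulator does not attempt.

Test problem sizes are chosen to make the suite fast while keeping the
statistics meaningful: toy libraries of a few hundred members for
end-to-end runs, n = 500 spectra for frequency-recovery checks (3σ
binomial bounds), full enumeration at published cardinalities only where
the member count itself is the quantity under test.

## Numerical choices and edge cases

* ppm is always |Δm|/m_reference × 10⁶ with the theoretical (library or
  predicted) mass as reference; RT is seconds everywhere (mzML minutes
  converted on read).
* Predicted ion lists are deduplicated within 1e-6 Da for matching;
  centroid merging in the simulator uses the same tolerance.
* The mass-degeneracy histogram uses single-linkage on the sorted mass
  axis (new group when the relative gap exceeds the bin width) — the
  operational notion of "indistinguishable at MS1".
* mzML I/O is a compact lxml-based reader/writer pair (64-bit float
  arrays; reader also accepts 32-bit and zlib-compressed arrays).  Writer
  output is verified against Bioconductor's mzR parser in the test suite.
  Profile-mode input raises with advice to centroid; MS2 scans without a
  precursor are skipped with a warning.
* Annotation is fully deterministic; only the simulator consumes seeds.

## Known limitations

* No reaction-based structure assembly: SMILES handling is limited to
  descriptor computation for supplied structures.
* No spectral-library search, fragmentation trees, isotope-pattern or
  collision-energy modelling.
* The simple feature finder is not a substitute for vendor feature
  detection on real profile data; supply external feature tables for
  production use.
* The per-BB Fisher test treats hits as independent draws; correlated
  hits (e.g. one binder detected in many scans) should be deduplicated to
  compound level first (the pipeline does this).
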