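# Methods

## Environment-code shift prediction

The predictor is a nearest-environment estimator over a reference
collection of assigned spectra.  Every carbon of every reference record is
encoded at spheres 1..4 by a canonical spherical-environment (HOSE) string
and indexed per sphere.  A query carbon's shift is the arithmetic mean of
the reference shifts sharing its deepest matching code; the contributor
count n, the population standard deviation and the sphere used are part of
the result, and n = 1 predictions are marked low-confidence.

**Code grammar.**  The code opens with the center descriptor
(element + charge) and appends one segment per sphere after a `/`
separator, so the sphere-k code is a strict prefix of the sphere-(k+1)
code.  Within a sphere every expanded atom contributes a parenthesized,
comma-separated neighbor list; a descriptor is
`bond symbol + element + charge + ring flag` (`=`, `#`, `%` for
double/triple/aromatic, `@` for ring membership), `&` marks ring closures
onto already-visited atoms, and implicit hydrogens appear as `H`.
Neighbors are ordered by a fixed priority (higher bond order, then element
by table, then ring membership, then charge) with residual ties broken by
the canonical atom ranking, making the code deterministic under atom
relabeling and equal for symmetry-equivalent atoms.  The grammar is our
own — unambiguity and testability were the goals, not byte-parity with
any historical encoder.

**Fallback rule.**  Lookup starts at the deepest sphere (default 4).  If a
sphere gathers at least `min_contributors` (default 3) reference atoms it
is used; otherwise the code is truncated sphere by sphere.  If no sphere
reaches the quorum, the deepest sphere achieving the maximal available
count is used (so a single exact sphere-4 hit beats the same single hit
seen through a coarser code), and a class without any sphere-1 hit is
reported `unpredicted` rather than guessed.

**Leave-in vs leave-one-out.**  When the compound under review is itself
part of the reference collection (the typical manuscript-checking
situation on our fixtures), the exact deepest match is the right
estimator, and the quorum rule would only dilute it with coarser-sphere
pools; the error-injection studies therefore verify with
`min_contributors=1`.  Accuracy studies that ask how well *unseen*
compounds are predicted (leave-one-out error, the worked-example anchors,
wrong-structure recovery) mask the probe record from the index and keep
the default quorum of 3.

## Verification and classification

Experimental signals are matched to carbon symmetry classes, never to
individual atoms: a class of k equivalent carbons consumes one signal
(intensities are ignored by default).  Signals the authors assigned keep
their class; signals tagged exchangeable are permuted exhaustively within
their tag group (groups are small, so the optimum is exact); unassigned
signals are paired with the remaining predicted classes by
minimum-total-|Δδ| bipartite matching (Hungarian algorithm via SciPy).
Deviations classify as green (|Δδ| < 5 ppm), yellow (5 ≤ |Δδ| ≤ 10 ppm —
both boundaries are yellow by convention) and red (> 10 ppm); any
|Δδ| > 20 ppm raises the gross-error flag.  Δδ_C is the mean |Δδ| over
classes that are both predicted and paired; unmatched classes and signals
are surfaced as findings instead of being averaged in, because an
incomplete peak list should be visible, not diluted.

## Similarity and dereplication

Identity search compares canonical identifiers (canonical SMILES over
connectivity, charge and H-count; exact charge match required).  The
identical-pattern scan flags records whose full shift multiset matches the
query pairwise within a tolerance (default 0.1 ppm, config-exposed) at
equal cardinality; a match across two *different* identifiers is the
same-data-twice error class.  Dereplication scores a candidate's predicted
spectrum against the query by the mean |difference| under the optimal
pairing; with unequal cardinality every unpaired position enters the mean
at a 10 ppm penalty, since a candidate with fewer distinct environments
than the query has signals it cannot explain.

## Structure revision

Flagged positions are the atoms of classes at or above the chosen color
level (default red; the recovery studies use yellow) plus, always,
predicted classes left without an experimental counterpart; when
experimental signals stay unexplained, all multi-atom symmetry classes are
added as suspects (the proposal collapses too many positions).  The
generator enumerates, deterministically and within a candidate budget
(default 5000), five formula-preserving move kinds at the flagged
neighborhood: pendant-substituent relocation, pendant swap, double-bond
shift, heteroatom/neighbor exchange, and (opt-in, formula-changing)
substituent addition/removal; paired relocations cover two-step revisions.
Candidates are deduplicated by canonical identifier, must pass the formal
structure check, always include the input proposal, and are ranked by the
same penalized mean-|Δδ| score used for dereplication.  A better-ranked
alternative sets the revision-recommended flag.

## The synthetic reference collection

The fixture generator emulates a curated literature shift collection at
desk scale.  Four families are enumerated deterministically:
n-alkanes C6–C20; benzene plus mono- and meta/para-disubstituted benzenes
over 14 substituents (110 records by default, always including
bromobenzene and four meta-substituted brominated companions); chromones
substituted at ring positions 5–8 in triplets that differ only beyond the
3-sphere of the substituted position (61 records); and fused toy scaffolds
(naphthalenes, benzofuran, coumarins, esculetin and its isomeric chromone)
(30 records) — 202 records in the standard database.

Shifts come from a versioned increment table
(`c13referee/data/increments_v1.yaml`): sp³ carbons use Grant–Paul-style
chain increments (base −2.3; +9.1/+9.4/−2.5 ppm per α/β/γ carbon, plus
heteroatom columns) with the 4-bond term dropped so the sp³ model is a
pure function of the 3-sphere environment; aromatic carbons use the
classic ipso/ortho/meta/para substituent increments on a 128.5 ppm base,
with the bromine ipso increment fixed at −6.0 ppm and the nitrile ipso at
−16.0 ppm (the two substituent-effect anchors the error examples rely
on); simple rules cover carbonyls, olefinic and five-ring aromatic
carbons.  Para increments are harmonized within groups sharing the same
substituent first atom because a 4-sphere code cannot see further from the
para position — without this the generator would put information into the
shifts that no 4-sphere predictor could recover, and uncorrupted entries
would not verify clean.  Gaussian noise of σ = 0.5 ppm is drawn once per
equivalence class (symmetry-equivalent carbons must share one value), with
all randomness keyed to the caller's seed.

The generator does **not** emulate solvent or temperature effects,
conformational averaging, heavy-atom or anisotropy corrections, accidental
degeneracies, or realistic inter-laboratory scatter.  Passing tests on
these fixtures shows that the pipeline's logic is correct under a
well-behaved additive shift world, not that the 2.5 ppm accuracy figure
transfers to real literature data.

**Error injector.**  Five corruption kinds, each invertible with ground
truth retained: digit-drop (a shift in 100–200 ppm loses its leading 1),
assignment swap, sequence shift (rotation of the shift vector), duplicate
data (one record's list copied onto another structure), and
wrong-structure (a pendant substituent relocated to a different position).
A wrong-structure corruption is only emitted when it would change the
noise-free spectrum by ≥ 6 ppm somewhere or alter the signal count — an
isomer indistinguishable within noise is not an error any referee could
flag.

## Study problem sizes and defaults

| quantity | value |
| --- | --- |
| max sphere / min contributors | 4 / 3 (both config-exposed) |
| green / red / gross thresholds | 5 / 10 / 20 ppm |
| pattern tolerance, bin resolution | 0.1 ppm / 0.1 ppm |
| unexplained-position penalty | 10 ppm |
| standard database | 202 records, seed-keyed |
| leave-one-out accuracy | all 202 records, ~1530 classes; MAE ≈ 1.6 ppm |
| matcher optimality | 1000 random instances, n ≤ 7, vs n! enumeration |
| code/prediction determinism | 100 relabelings × 51 molecules (codes), 20 × 21 (predictions) |
| error injections | 100 digit-drops, 100 swaps, 20 duplicate pairs |
| revision recovery | 50 wrong-isomer cases, σ = 1 ppm spectra, budget 2000 |

## Known limitations

* Constitution-only: stereocenters are counted and warned about, never
  used; cis/trans and diastereotopic effects are invisible.
* The canonical identifier satisfies the stated invariants (permutation
  invariance, no collisions on the packaged sets) but is not an InChI
  replacement.
* The generator's move set cannot reach revisions that require ring
  rearrangement or scaffold hopping.
* Dereplication over a handful of reference structures is only meaningful
  at equal-cardinality; the 10 ppm unpaired penalty is a declared design
  constant, not a fitted value.
* V3000 molfiles are rejected; only V2000 is read and written.
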