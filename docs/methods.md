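# Methods

## Problem setting

Ligand-based virtual screening ranks a database of candidate compounds
by similarity to a known active ("query") ligand of a protein target.
Plain structural similarity is agnostic about *which* part of a ligand
matters for binding; `bksim` sharpens it with background knowledge in
the form of binding-relevant substructures, encoded as a binary
occurrence fingerprint and blended into the similarity score.

## The extended similarity

For molecules *a*, *b* and a weight α ∈ [0, 1]:

    sim_ext(a, b) = (1 − α) · sim_base(a, b) + α · sim_bind_fp(a, b)

* `sim_base` is either the Wallis MCS similarity
  `|mcs(a,b)| / (|a| + |b| − |mcs(a,b)|)` — |·| counts heavy atoms and
  mcs(a,b) is the largest *connected* common subgraph — or the Dice
  coefficient on circular-fingerprint identifier sets.
* `sim_bind_fp` is the Tanimoto coefficient of binary occurrence
  fingerprints: bit *i* is set iff the *i*-th binding-relevant pattern
  embeds in the molecule.
* α defaults to 1/3 (kept exact as a rational), weighting the base
  measure twice as heavily as its extension.  The `sweep` command
  re-ranks cached component similarities over an α grid without
  recomputing MCS or fingerprints, exploiting the linearity of the
  blend.

Both coefficients return 0 (not 1) when both fingerprints are empty:
an informationless pair should not look maximally similar.  The event
is logged.

## Where the patterns come from

* **Hand-selected (approach A).**  The user supplies one
  binding-relevant substructure; it is exhaustively fragmented into
  all of its free subtrees (no frequency constraint) and those
  fragments define the fingerprint positions.
* **Mined (approach B).**  Frequent free trees are mined from known
  ligands.  B1 uses all non-query ligands and can calibrate the
  minimum support on a grid (0.50–1.00, step 0.01, largest qualifying
  value) so that every dataset yields approximately a target number of
  features; B2 uses only a random fraction (default 10%, 20% in the
  bundled experiments) of the non-query ligands at a fixed support of
  0.9 — the harder setting where few actives are known.

## Free-tree mining

Patterns are unrooted, connected, acyclic graphs whose nodes carry
(element, aromatic-flag) labels and whose edges carry bond labels with
aromatic distinct from the Kekulé orders.  Charges and hydrogen counts
are deliberately *not* part of pattern labels: the mined fragments are
plain substructures.  Matching is subgraph monomorphism (extra
molecule bonds between matched atoms are allowed), so tree patterns
match inside rings; matching is delegated to RDKit via generated
SMARTS with explicit bond primitives and aromaticity constraints.

The miner grows patterns level-wise: frequent single-node patterns are
extended one leaf at a time using only (label, bond, label) edge
types observed in the data; duplicates are eliminated with a canonical
code (centroid-rooted AHU encoding, with the bicentroidal case handled
by splitting the central edge and combining the two rooted codes
order-independently); branches are pruned by the anti-monotonicity of
transaction support, and support counting for a child is restricted to
the parent's supporting molecules.  Support is transaction-based — the
fraction of molecules containing at least one embedding — the
convention of all standard frequent-substructure miners over molecule
sets.  Single-atom patterns count as patterns.  A size cap
(`max_nodes`, default 10) bounds the otherwise exponential enumeration;
a warning reports frequent patterns sitting at the cap.

## MCS computation

The maximum common substructure is connected, matches atoms on
element + aromatic flag and bonds on exact bond label, and maximises
atom count.  The search is delegated to RDKit's exact FMCS
implementation; when either molecule is aromatic a custom comparator
enforces the aromatic-flag atom criterion (the built-in element
comparator would let an aromatic carbon match an aliphatic one through
an exocyclic single bond).  Two corner cases are handled explicitly:
pairs where one molecule is a single atom, and pairs with no common
*bonded* fragment, where a shared atom label still yields an MCS of
size 1 — this keeps `sim(a, a) = 1` for one-atom molecules.  A
per-pair timeout (default 10 s; never observed to trigger at the
bundled problem sizes) marks the result inexact rather than silently
under-reporting; ranked outputs carry the count of inexact pairs.

## Circular fingerprints

The ECFP-style fingerprint hashes, per atom, the seven
numbering-independent invariants (heavy-neighbour count, valence minus
hydrogens, atomic number, atomic mass, formal charge, attached
hydrogens, ring membership) with a stable 64-bit blake2b hash, then
iterates neighbourhood hashing for `radius` rounds (default 2),
combining each atom's previous identifier with its sorted
(bond-code, neighbour-identifier) pairs.  Identifiers are kept as a
set.  An environment whose bond set duplicates one already captured —
in an earlier round, or by a lower-identifier atom in the same round —
is dropped and the atom stops growing; this mirrors the published
deduplication convention, and the resulting pairwise Dice matrix is
checked in the tests to agree exactly with RDKit's sparse Morgan
implementation on a random molecule panel.  Raw identifier values are
hash-specific and carry no contract; only set intersections matter.

## Screening protocol

Per trial a query is drawn from the ligands; the database is the
decoy set plus the remaining ligands; rankings are descending in
similarity with ties broken by input position (fingerprint ties are
common).  The query is excluded from the mining set as well as the
database — mining from "all" ligands including the query would leak
its own substructures into its trial.  All randomness derives from
one master seed through counter-based per-trial spawn keys, so adding
trials never perturbs earlier ones and reruns are byte-identical.
If mining returns zero patterns the trial falls back to the base
similarity (α forced to 0) with a logged warning.

## Evaluation

Enrichment factors are computed at database fractions (default 1, 5,
10%), with subset size `max(1, floor(fraction/100 · N_all))` — floor,
so the subset never exceeds the stated fraction, with a minimum of one
compound.  `EF_max = (min(N_active, N_(%)) / N_(%)) / (N_active /
N_all)` is the value attained by any all-actives-first ranking, and
the reported score is the shortfall `Δ_EF = EF_max − EF(%)` (smaller
is better, 0 optimal; negative rounding residue is clamped).  Paired
method comparisons count wins/draws/losses on Δ_EF; draws (exact
equality) are excluded from the exact two-sided binomial sign test
`p = min(1, 2 · P(X ≥ max(w, l)))`, `X ~ Binomial(w + l, 1/2)`.

## Synthetic benchmark

The generator plants a binding-relevant scaffold — by default
`OC(=O)CC(O)CC(O)C=C`, a dihydroxy-acid chain of the kind that anchors
statins in their pocket — and emulates the ligand/decoy structure of
curated screening benchmarks:

* **Actives** (default 20) are the scaffold plus 4–8 random acyclic
  decorations from a carbon-biased C/N/O/S alphabet with occasional
  double bonds.  Decorations are acyclic so every planted feature is
  reachable by the free-tree miner.
* **Decoys** (default 600) are *hard* decoys: the scaffold's own atom
  multiset with one or two bonds relocated, then decorated exactly
  like the actives, occasionally closed into a ring.  They therefore
  match the actives in size and elemental composition — a plain
  structural similarity separates the classes only noisily — while
  the precise scaffold topology, which the mined fingerprint captures,
  still distinguishes them.  This mirrors the design intent of
  property-matched decoy collections, where decoys resemble ligands
  physically but differ topologically.
* **Label noise**: a fraction of decoys (default 10%) additionally
  contains the intact scaffold, emulating decoy sets that are only
  presumed inactive; the remainder are verified scaffold-free.  These
  scaffold-bearing decoys put a floor under the achievable Δ_EF of
  *any* scaffold-aware method, for the extended and base measures
  alike.

What the benchmark does **not** emulate: real physico-chemical
property matching (logP/MW), tautomers, stereochemistry, activity
cliffs, or multiple binding modes.  Passing the end-to-end test shows
the pipeline extracts and exploits a genuinely present substructure
signal under class-overlapping base similarity; it does not certify
performance on experimental screening decks.

## Problem sizes and numerical choices

The bundled experiments use 20 actives + 600 decoys, 10 query trials
per benchmark and 10 benchmark seeds — small enough for an exact MCS
per pair while exercising every pipeline stage; results on these sizes
are stable across seeds (the enrichment comparison holds in 10 of 10
seeds in the shipped configuration).  Support-threshold comparisons
use an epsilon of 1e−9 against floating-point counts;
`Δ_EF` consistency is enforced to 1e−9 and α-sweep linearity to
1e−12.  Tie-breaks everywhere are deterministic: canonical-code order
for patterns, input position for rankings, smaller α for best-α
selection.

## Known limitations

* The miner is a generate-and-test pattern grower, adequate for tens
  of molecules and `max_nodes` ≈ 10, not a high-throughput FTM
  replacement for thousands of transactions.
* MCS atom/bond match criteria (element + aromatic flag, exact bond
  label) are one defensible convention; toolkits differ in whether
  ring bonds may match chain bonds, so absolute similarity values are
  not comparable across toolkits.
* ECFP identifiers are implementation-specific; only similarity values
  (not raw identifier sets) are meaningful externally.
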