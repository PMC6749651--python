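# Methods

## Satellite model

A satellite is modelled as a tandem array `u₁u₂…u_n` of n ≥ 4 copies of a
repeat unit of length 10–200 nt, where the copies derive from a common unit
by substitutions and occasional 1-nt indels. Two structural parameters
describe each satellite: **Ni**, the number of copies sharing the modal
(identical) length, and the **repeat score**, the mean per-column majority
frequency over the Ni equal-length copies stacked without gaps. A satellite
is *regular* — and only regular arrays are reported — when Ni / n ≥ 0.6.
Repeat units are treated as circular, strand-symmetric objects: the array
can be read from any phase on either strand, so unit identity is defined
only up to cyclic permutation and reverse complement.

## Detection

Detection is seed-based. All decamers (k = 10) that are not exact
repetitions of a shorter block are indexed; a decamer is a **seed** when it
occurs ≥ `min_copies` (4) times with every `min_copies` consecutive
occurrences spanning ≤ `window` (800) nt. The window constraint is sliding,
not binned, to avoid bin-boundary artifacts. Note that with k = 10 the
window admits 4 copies of units up to ~260 nt, so the 200-nt period ceiling
— not the window — is the binding constraint at default settings.

Each seed cluster yields a period estimate (mode of successive seed
spacings restricted to [min_period, max_period], ties to the smaller
value). The array around the cluster is delimited on the lag-p self-match
profile m(i) = [s(i) = s(i+p)]: the maximal run where every period-length
window of m has density ≥ `extension_identity` (0.7). This is the
period-step extension criterion ("keep extending while the next block
matches the adjacent block at ≥ 0.7 identity") evaluated slidingly; the
sliding form is phase-free, which makes boundaries independent of which
seed rotation anchored the candidate and exactly mirror-symmetric — calling
the reverse complement of a replicon provably yields mirrored coordinates.
A 1-nt indel inside the array shifts the register and blanks up to ~2p of
the smoothed profile, so runs separated by ≤ 2p + 4 nt are bridged; two
genuinely distinct arrays are only ever bridged when separated by ≤ 4 nt of
background. Finally boundaries are trimmed until the terminal window shows
`w = min(6, p)` consecutive lag-p matches: a single chance match in
background (probability ~1/4 per base) would otherwise drag sub-period
flanks into the array, while a clean 6-run in background has probability
~2·10⁻⁴ per position.

The delimited interval is cut into units at occurrences of a cutting
decamer chosen within the interval (the phase with the most occurrences,
ties to the smallest offset). Cutting at seed occurrences means an indel
between copies shifts one unit's length instead of corrupting the register
of all downstream copies. A gap of j ≥ 2 periods (the cutting decamer
destroyed by mutation in j−1 copies) is split into j near-equal sub-units
so copy counts stay meaningful. One windowed seed run can span several
nearby arrays of the same unit; after an array is delimited the cluster is
re-anchored on its remaining occurrences until exhausted. Overlapping
accepted candidates (rotation leftovers, harmonics) are deduplicated
keeping the larger n·p, then the higher score, then the leftmost start.
All tie-breaks are deterministic: repeated runs are bit-identical.

Consequences worth knowing: reported boundaries follow the maximal
self-similar run, which can exceed the planted/true array by a few bases
when background happens to continue the period (and those bases pad the
first or last unit, so Ni is occasionally n−1 even for a perfect array);
conversely a mutation in the terminal w bases shaves the boundary inward.

## Cyclic alignment and consensus

Pairwise unit similarity is a global (Needleman–Wunsch) alignment with
match +1, mismatch 0, linear gap −0.5, maximised over all rotations of the
second sequence and its reverse complement, and normalised by the longer
length; with these parameters score(a, a) = 1 exactly and scores lie in
[0, 1] (mismatch 0 dominates paired gaps, and the rare negative raw score
of very unequal lengths is clamped). The reference implementation whose
behaviour this score family imitates published only "normalised to the
maximum possible value"; the exact mismatch/gap weights and the
normalisation denominator are this package's own choices, exposed in one
place (`cyclal.GAP`, `reverse_mode`). "Reverse" means reverse complement by
default — satellites are double-stranded features — with literal reversal
available behind `reverse_mode="literal"` for fidelity experiments.
Rotation ties prefer forward orientation, then the smaller offset. The DP
is batched over all rotations with a running-maximum formulation of the
in-row gap recurrence, so cost is O(|a|·|b|·min rotations) without Python
inner loops.

Consensus of a unit set: every unit is rotated (and, if its best alignment
is reverse, reverse-complemented) into the register of the first unit; the
consensus is the per-column majority base, ties to the alphabetically
smallest, with columns read cyclically when lengths differ. The output
length equals the first unit's length; for family consensuses the first
unit is the lowest-coordinate member's consensus (determinism).

## Families

Families are built by average-linkage agglomeration over the fixed matrix
of pairwise cyclic scores between satellite consensuses, merging the pair
of clusters with the highest mean inter-cluster score until that mean falls
below the threshold (default 0.6). Average linkage was chosen over
single/complete linkage because the progressive step operates on the score
matrix as a whole and one diverged member should neither chain unrelated
clusters together nor veto a merge. Ties merge the pair containing the
smallest member index (members ordered by replicon, then coordinate).
Families may span replicons and species; `per_replicon=True` restricts
merging. Naming is `Fam_a_b_c` with families ordered by descending member
count, then ascending repeat length, then first member id; `a` is the rank
in that order, so singleton families always trail the list. For equal-size
families the rank order is this package's convention (repeat length, then
first member) — the published lists do not state theirs.

## Summary statistics

Per replicon: size (Mb), %CG computed over A+C+G+T (N excluded from the
denominator), satellite count, satellites/Mb, the percentage of satellites
with repeat unit **strictly** over 30 nt, the count with total length
strictly over 1 500 nt, and the percentage of periods divisible by 3 (a
proxy for arrays embedded in protein-coding sequence). The >30 nt boundary
is ambiguous in the survey literature (a 30-nt family is once listed among
"over 30 nt" families); both behaviours are selectable
(`long_repeat_inclusive`), strict is the default. Presentation rounding (2
decimals for sizes and densities, 1 for percentages) is applied only at
serialisation.

## Synthetic data

The generator emulates the detector's target: i.i.d. background of
configurable GC with tandem arrays inserted at known positions. Insertion
(never overwrite) keeps background composition intact; truth records are
shifted across insertions, and random insertion points are redrawn to avoid
previously planted arrays so that every truth interval remains one intact
array. Copies are mutated independently: per-base substitutions at
`sub_rate`, one 1-nt insertion or deletion per copy with probability
`indel_rate`. All randomness flows through explicit integer seeds; there is
no global generator state.

What the generator does **not** emulate: real genomic composition (codon
structure, GC skew, oligomer bias), insertion sequences and other dispersed
repeats, CRISPR repeat-spacer arrays, nested or higher-order repeat
structure, and multi-nucleotide indels. Passing the synthetic recovery
experiment therefore demonstrates correctness of the detection machinery
under the stated divergence model, not performance on the pathological
repeat structures real genomes can contain.

The standard recovery experiment (`simulate.study_genome`) is 20 seeded
100-kb genomes at GC 0.4, each with 10 planted arrays (unit lengths 10–100
nt, 4–20 copies, substitution rate uniform on [0, 0.02], indel rate uniform
on [0, 0.05]); the acceptance bar is recall ≥ 0.9, precision ≥ 0.9 (at
reciprocal interval overlap ≥ 0.5) and mean period error ≤ 1 nt. The 100-kb
per-replicate size keeps the full 20-replicate experiment at interactive
(sub-minute) scale while holding ~10⁵ background decamers per genome
against false seeding.

## Numerical and degenerate-input conventions

Score comparisons use 1e-9 tolerances; regularity uses an epsilon so
exactly-60% satellites are accepted. Modal choices (unit length, family
repeat length, period spacing) always break ties toward the smaller value.
Empty call lists are valid everywhere (empty catalog, empty family list,
zero-filled summaries); precision over zero calls is reported as 1.0 with
an explicit `precision_defined=False` flag. Sequences shorter than ~2
periods, clusters whose spacings all fall outside the period range, and
candidates whose delimited span is shorter than `min_copies × min_period`
are dropped silently (debug-logged), never errors.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 10 | seed k-mer length (nt) |
| `window` | 800 | region within which a seed must recur (nt) |
| `min_copies` | 4 | minimum seed occurrences / repeat copies |
| `min_period` / `max_period` | 10 / 200 | allowed unit lengths (nt); 260 is the documented alternative ceiling |
| `min_regular_frac` | 0.6 | minimum Ni / copies |
| `seed_merge_overlap` | 0.5 | span overlap merging rotation clusters |
| `extension_identity` | 0.7 | per-period identity to stay inside the array |
| `bridge_slack` | 4 | extra nt when bridging an indel's register gap |
| family `threshold` | 0.6 | mean cyclic score to keep merging families |

`extension_identity = 0.7` keeps diverged flanks out while tolerating the
few-percent divergence typical of real satellite copies; it is far above
the ~0.25 background match density, so the delimitation is insensitive to
its exact value over a broad range.

## Known limitations

- Period estimation assumes the seed spacing mode equals the unit length;
  heavily indel-riddled arrays (> ~10% per copy) can report p ± 1.
- Nested and higher-order repeats are reported at the period the seed
  spacing supports, not decomposed.
- The family threshold acts on consensuses; a family of highly diverged
  satellites whose pairwise consensus scores straddle 0.6 may split.
- CRISPR arrays with constant spacer length satisfy the satellite
  definition and are reported as satellites, as intended; no motif-based
  exclusion is attempted.
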