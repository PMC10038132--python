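# Methods

This note documents the models, parameters and design choices behind
nibbletrim: the packed-word matching algorithm, the scoring and decision
machinery, the overlap consensus, the read simulator, and the accuracy
evaluation. It also states what the simulation does and does not emulate.

## Sequence representation

Bases are 4-bit one-hot codes over the bit set {A=1, C=2, G=4, T=8}; IUPAC
ambiguity codes are bit unions (N=1111, S=0110, …) and gap is 0000. Sixteen
bases pack into one little-endian 64-bit word, base `2n` occupying the
least-significant nibble of the word read at byte position `n`. Buffers are
*bit-safe*: one all-zero word is appended and every bit past the last base is
zero, so any word-sized load inside the padded buffer is legal and decodes
out-of-range positions as gaps. Lowercase input is uppercased; characters
outside the IUPAC-plus-gap alphabet are rejected with the character and
position named (never silently converted to N).

Index convention: all base indices are 0-based; ranges written `i..j` in this
note are inclusive, while code uses half-open Python slices.

## Word-level matching

The matched-base count of two packed 16-mers is `count_ones(a & b)`; the
mismatch count is `K = 16 − count_ones(a & b)`. Ambiguity codes share bits
with several bases, so a popcount can exceed 16 and K is clamped at 0 — the
deliberate consequence is that N-vs-base counts as a match (one shared bit)
and mismatches involving ambiguity codes are under-counted. The scan slides
the query's head 16-mer along every subject offset using only byte-aligned
loads: `a0` (query bases 0..15) is compared at even offsets and
`a⁻ = (a0 ≫ 4) | (a1 ≪ 4)` (query bases 1..16) at odd offsets, so an
odd-offset comparison covers query bases 1..16 — offset −1 is excluded. The
smallest offset achieving the minimum K is reported; a hit requires `K ≤ k`.
Queries shorter than 16 bases are gap-padded and the padding counts as
mismatches, as do subject positions past the end (which lets a query overhang
the subject tail and still match partially). Indels are not handled at this
level; the four-way redundancy and the 1-bp re-positioning compensate. The
scan is one vectorized pass (numpy `bitwise_count` over precomputed
byte-position words): O(n) time, O(1) extra space beyond the packed inputs.

## Scoring

`P = 1 − 10^(−Q/10)` converts a Phred score to the probability the call is
correct (Phred+33 is the only supported encoding). A 16-mer's weight is the
arithmetic mean of P over its window, floored at 0.75: the k-mer scan already
rejects unreliable hits, so the floor stops low-quality windows from
annihilating otherwise confirmed matches. Windows extending past the read
end average only the in-range bases (keeping the score defined at every
candidate insert size); a fully out-of-range window returns the floor. The
match score is `S = count_ones(a & b) · P̄_a · P̄_b ∈ [0, 16]`, with `P̄ = 1`
for user-supplied adapters.

One deliberate reading: the decision-rule low-quality test ("mean 16-mer
accuracy < 0.6") uses the *unfloored* mean — with the 0.75 floor applied it
could never trigger.

## Four-way matching per pair

1. adapter 1 head → read 1, adapter 2 head → read 2 (insert size = hit
   offset);
2. `k_extra = 1` if the best adapter hit matched fewer than `cutoff` bases
   (default 9), else 0;
3. read 1 head → reverse complement of read 2 and vice versa, at tolerance
   `k + k_extra`; a hit at offset p implies insert size `len(mate) − p`.
   The direction — read head into the mate's reverse complement — is the one
   under which a paired-end hit corroborates an adapter position whenever the
   insert is shorter than the read.
4. Rescue: if the best found match exceeds the cutoff, every match that
   failed (or matched fewer than `cutoff` bases) is re-counted,
   tolerance-free, at the single offset its match type implies for the best
   insert size (adapter: offset = s; paired-end: offset = len(mate) − s;
   negative implied offsets are skipped). The old result is replaced when the
   re-count exceeds the cutoff. This realizes the loosened-tolerance re-run
   without a second scan. Rescue eligibility includes failed matches
   regardless of their best-seen count, since the step exists precisely to
   recover them.
5. Scores: adapter `S = n_match · P̄(read at s)`; paired-end
   `S = n_match · P̄(read at s) · P̄(mate head at 0)`.

Defaults `k = 2` and `cutoff = 9`, both CLI-exposed. Note that with 100-bp
reads an adapter remnant shorter than 14 bases cannot pass the strict scan
(tail padding counts as mismatches) and shorter than 10 cannot pass the
rescue; such positions are carried by the paired-end matches alone.

## Decision rules

Within each read, adapter and paired-end candidates are merged — equal insert
sizes sum their scores, otherwise the higher score wins (ties keep the first
operand; absent candidates are identities) — and the two reads' results merge
the same way into `(r12_pos, r12_score)`.

* **Low-quality override.** If the reads' positions differ and one read's
  score exceeds `trim_score` (default 10, strictly greater) while the other
  read either has no base at that position ("too short to check", realized as
  mate length ≤ position — the weakest reading consistent with the phrase)
  or its unfloored mean 16-mer accuracy there is < 0.6, both reads are
  trimmed at the confident read's own position, bypassing the tail filter
  but not the 1-bp re-positioning.
* **Tail false-positive filter.** With tail length 12 bp: E = in some read,
  *both* the adapter and paired-end hits lie in the tail; R = in some read
  the two hits agree exactly; pairs with E and not R are left untrimmed.
  (An alternative reading — adapter in the tail *without* a paired-end hit
  there — is available behind `tail_filter_prose` for experimentation.)
  Absent matches never satisfy tail membership. The filter only ever
  converts trim into no-trim.
* **Adjacent-1-bp re-positioning.** Indels shift the apparent insert size by
  one base, and the two mates' true cut points can differ. Before cutting,
  each read compares the adapter's first 4 bases at s−1, s, s+1
  (out-of-range bases mismatch; negative candidates skipped) and cuts at the
  best-matching candidate, ties preferring s then the smaller position.
  Skipped when s > read length − 3, where too little adapter remains to
  check; applied per read, so the mates may be cut at positions differing
  by one base, as indels require.

Cut positions are clamped to [0, read length]; bases and qualities are cut
together. A minimal single-end mode (adapter match + threshold only) exists
as a convenience, not a benchmarked procedure.

## Consensus calling

Runs after adapter trimming and before quality trimming; disable with
`--no-consensus`. Prediction: trimmed pairs of equal length overlap over
that length; untrimmed pairs overlap at s only if matching the head of each
mate's reverse complement into the other read succeeds in both directions
with the same implied `s = offset + len(other read)` (the scan tolerance k
is reused — no separate value is defined for this step). Trimmed pairs of
unequal length fail prediction. Assessment: the whole overlap is compared
with N converted to gap (N therefore counts as mismatch); the mismatch
fraction, with the overlap length in bases as denominator, must not exceed
0.28. Correction: at each disagreeing position both reads receive the
higher-quality call (complemented for read 2) and the winner's quality is
copied to both; equal qualities keep read 1's call. Lengths never change,
and after correction the overlap is reverse-complement-identical. Reads are
corrected in place, never merged into one fragment.

## Quality trimming and auxiliary filters

A window (default 5 bp) slides from position 0; at the first window whose
mean Phred score falls below the threshold (default 15) the window's first
base and everything after it are removed — inclusive removal, matching
common sliding-window trimmers. Tail windows shorter than the window size
use the truncated mean. Stage order is fixed: adapter trim → consensus →
quality trim → N-trim → hard clip → length filter (which drops both mates
together). All filters are length-monotone. Homopolymer trimming and
complexity filtration are not implemented; their flags are reserved and
rejected.

`--threads` is accepted for interface compatibility; execution is
single-threaded and results are identical at any thread count. Gzip input
is auto-detected by magic bytes; gzip output uses a fixed mtime so repeated
runs are byte-identical.

## Read simulator

A random ACGT insert of the chosen size is drawn once per pair; templates
are `insert + adapter1` and `reverse_complement(insert) + adapter2`. Each
template is copied base by base: per template base, deletion with
probability `del_rate` (base skipped), insertion with `ins_rate` (one
uniform random base emitted before it), substitution with `sub_rate`
(uniform different base). After the template, uniform random filler extends
the read to the target length (the adversarially neutral choice — no second
adapter copy); longer outputs are truncated. The truth position is the
number of bases emitted while copying the insert section, clamped to the
read length — with no indels it equals min(insert size, read length)
regardless of substitutions; an insertion occurring at the insert/adapter
boundary is attributed to the adapter side.

The baseline profile is 0.1% substitutions and 0.001% insertions and
deletions per base (Illumina-like); the benchmark grid crosses 1–5×
multiples of it with adapter lengths 16, 20, 24, 28, 33 (prefixes of the
default adapter pair) and even insert sizes 66–120 at 100-bp reads, fully
crossed, reproducibly from a single seed. Defaults mirror those conditions;
30,000 pairs per condition is the reference scale, and reduced
pairs-per-condition values reproduce the same statistics with wider
sampling error.

Simulated qualities are a constant Phred score (default Q30). This is a
known simplification: the 0.75 score floor, the 0.6 low-quality override
and quality trimming are all inert on simulated data unless the quality is
lowered, so the benchmark exercises position inference, not the quality
machinery. Real-data features *not* emulated: position-dependent quality
decay, correlated/systematic errors, quality-correlated substitutions,
polyG artifacts, and non-uniform insert-size distributions. Passing the
benchmark therefore demonstrates coordinate-exact adapter localization
under indel/substitution noise, not robustness to every real-world artifact.

## Evaluation

Each read is scored independently: a trim is *correct* only at the exact
true position (±1-bp and multi-bp over/under-trims are tallied separately).
Reads with a truth position inside the read are adapter-bearing (TP if
exact, else FN); the rest are adapter-free (TN if fully intact, else FP).
PPV = TP/(TP+FP), sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), and
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FN)(TN+FP)), defined as 0 when a
denominator factor vanishes.

## Benchmark scale and known behaviour

`scripts/acceptance.py` uses 500 pairs per condition (85,000 reads per
profile for the adapter-bearing grid), chosen as the package's reproduction
scale; accuracy estimates at this n carry binomial standard errors of a few
hundredths of a percent.

Two intrinsic behaviours worth knowing:

* **Chance paired-end matches.** In adapter-free random sequence, a
  16-mer paired-end hit with K ≤ 3 (the loosened tolerance active when
  adapter matches are weak) occurs at ≈ 4·10⁻⁴ per scan and scores ≈ 13 >
  10, trimming the pair. The intact fraction of adapter-free reads is
  therefore slightly below 100% (≈ 99.97%) at any scale — a property of
  the score threshold, not a defect; it rounds to 100.0% at one-decimal
  precision.
* **Near-tail indels.** When the insert reaches within two bases of the
  read end, each paired-end match measures the *mate's* insert size; an
  indel then shifts one read's true cut while the re-positioning step is
  skipped (too little adapter to check), costing ~1 bp on a small fraction
  of indel-bearing reads. This bounds 5×-profile exact accuracy near
  99.85–99.9%.
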