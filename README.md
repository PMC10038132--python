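# nibbletrim

Adapter and quality trimming for Illumina paired-end FASTQ data, built on a
byte-based 16-mer matching algorithm, together with a read simulator and a
trimming-accuracy benchmark.

## The problem

In paired-end library preparation, adapters are ligated to both ends of the
DNA fragment of interest (the *insert*). When the insert is shorter than the
read length, the sequencer reads through the insert into the adapter, so the
3′ end of each read carries adapter sequence that must be removed — at the
*exact* position, since over-trimming discards real signal and under-trimming
leaves technical sequence that produces false SNPs and fragmented assemblies.
Adapter remnants are shortest, and base qualities lowest, precisely where
trimming is hardest.

## The algorithm

**Packed matching.** DNA is encoded 4 bits per base with one-hot codes
(A=0001, C=0010, G=0100, T=1000; ambiguity codes are unions, N=1111, gap=0000)
and packed 16 bases per 64-bit word into a *bit-safe* buffer: one extra zero
word past the end so word-sized loads near the tail are always legal and read
as gaps. Two bases match iff their codes share a bit, so for two packed
16-mers `a`, `b` the mismatch count is a single AND plus popcount:

    K = 16 − count_ones(a & b)

Because a byte holds two bases, only even base offsets are byte-aligned; the
scan therefore slides *two* query words — `a0` (bases 0..15) and
`a⁻ = (a0 ≫ 4) | (a1 ≪ 4)` (bases 1..16) — along the byte-aligned words of
the subject, covering every offset in O(n) time and O(1) space. A hit is an
offset with `K ≤ k` (default k = 2), smallest offset winning ties.

**Four-way matching and scoring.** Per pair, four scans are run: each adapter
head against its read, and each read head against the reverse complement of
its mate. All hits convert to insert-size candidates and are weighted by the
mean base-correctness probability `P̄ = mean(1 − 10^(−Q/10))` of the matched
16-mer (floored at 0.75; adapter P̄ = 1):

    S = count_ones(a & b) · P̄_a · P̄_b        (0 ≤ S ≤ 16)

**Decision rules.** Adapter and paired-end candidates are reconciled within
and then across reads (equal positions sum scores, otherwise max wins). The
pair is trimmed when the combined score exceeds 10, subject to a read-tail
false-positive filter (last 12 bp), a low-quality override (mate mean
accuracy < 0.6), and an adjacent-1-bp re-positioning that fixes indel-shifted
cuts by re-matching the adapter's first 4 bases at s−1, s, s+1.

**Consensus and quality trimming.** Overlapping mates are compared base by
base (mismatch fraction ≤ 0.28 required) and disagreeing calls replaced by
the higher-quality call; a sliding window (5 bp, mean Q ≥ 15) then removes
low-quality tails.

## Worked example

Simulate a small benchmark (100 pairs per even insert size 66–120, 100-bp
reads, 33-bp adapters, baseline error profile: 0.1% substitutions, 0.001%
insertions/deletions), trim it, and score the result:

```bash
nibbletrim simulate -o bench --profiles 1 --adapter-lengths 33 \
    --insert-min 66 --insert-max 120 --insert-step 2 \
    --pairs-per-condition 100 --seed 42
# simulated 2800 read pairs
nibbletrim trim -1 bench_R1.fastq -2 bench_R2.fastq -o trimmed \
    --no-consensus --no-quality-trim
# {"pairs_read": 2800, "pairs_trimmed": 1701, ...}
nibbletrim evaluate -1 trimmed/bench_R1.trimmed.fastq \
    -2 trimmed/bench_R2.trimmed.fastq --truth bench_truth.tsv
```

which prints (abridged):

```json
{
  "tp": 3400, "tn": 2198, "fp": 2, "fn": 0,
  "ppv": 0.9994, "sensitivity": 1.0, "specificity": 0.9991, "mcc": 0.9993,
  "n_adapter": 3400, "n_adapter_free": 2200,
  "accurate": 5598, "over_1bp": 0, "under_1bp": 0, "over_multi": 2
}
```

Reading: of the 3,400 adapter-bearing reads (inserts 66–98), every one was
cut at exactly the true adapter start (sensitivity 1.0); of the 2,200
adapter-free reads (inserts 100–120), 2,198 were left untouched. The two
over-trimmed reads come from chance paired-end 16-mer matches in random
sequence — the method's intrinsic, ~10⁻⁴-rate false-positive mode. MCC
summarizes the trim/no-trim confusion table.

The same machinery is available as a library:

```python
from nibbletrim import RunConfig, process_pair, simulate_pair, ErrorProfile
```

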