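# Methods

## Model and procedure

`linforge` maintains a growing collection of genomes in which each genome,
at the moment it is added, is compared precisely against exactly one stored
genome. The procedure per added genome:

1. **Sketching.** All k-mers of every contig are enumerated; windows with
   non-ACGT characters are dropped; each k-mer is canonicalized as the
   lexicographic minimum of itself and its reverse complement, hashed to 64
   bits, and the n smallest distinct hashes form the signature. Defaults:
   k ∈ {21, 51}, n = 2,000. Jaccard between two signatures is estimated as
   |bottom-n of the merged union ∩ both sketches| / |bottom-n of the union|
   (the unbiased bottom-sketch estimator, not the naive sketch-intersection
   ratio).
2. **Two-stage search.** The k=21 signature is compared against one
   representative per 95%-level LINgroup (the first member, by insertion
   order, of every group). The best Jaccard J is bracketed by two empirical
   calibration constants: J > 0.2475 — the query belongs to that group
   (members then ranked at k=51, which resolves close relatives); 0.0025 <
   J ≤ 0.2475 — related at the ≥70%-ANI level only (members ranked at
   k=21); J ≤ 0.0025 — unrelated to everything stored, no alignment is
   performed. The constants are calibrations of Jaccard-vs-ANI at k=21,
   n=2,000 and are configuration, not derived quantities.
3. **One precise ANI.** Fragment-based reciprocal ANI is computed between
   the query and the single best subject: the query is cut into consecutive
   1,020 nt fragments (trailing fragment kept), each fragment is placed at
   its edit-distance-optimal position in the subject on either strand,
   retained iff coverage > 30% and identity > 70% (both strict), one-way
   ANI is the mean retained identity, and the reciprocal value averages the
   two directions.
4. **LIN assignment.** With measured ANI a, the query copies the subject's
   LIN through every position whose threshold ≤ a, takes the smallest
   integer not yet used under that prefix at the first failing position,
   and zero-fills the rest. The first genome receives all zeros; a novel
   genome receives a fresh number at the first position. An ANI at or above
   the scheme's top threshold copies the subject's LIN entirely — duplicate
   LINs are deliberate; identity lives in the genome id.

### Matrix inference

For any two genomes without a direct ANI record, let p be the first LIN
position where they differ. The later-founded branch at p was created by a
recorded divergence event; that event's ANI value is propagated to the
pair. When the later founder has no record (it was novel), the threshold of
the last shared position is used, and 0 when nothing is shared. The
propagated value always lies in [threshold(p−1), threshold(p)) — the
bracket-consistency invariant — and all cross-branch pairs collapse onto
the handful of values recorded at divergence events ("merging"). Direct
records always take precedence. Matrix values are never rounded
internally.

An alternative semantics — returning threshold(p−1) for every inferred
pair — is available implicitly as the inference fallback; propagation of
the recorded value is the primary rule because it preserves the actual
measurement rather than a grid point.

## LIN schemes

Thresholds live on an exact integer grid in units of 10⁻⁶ percent, so
decimal steps (0.1, 0.01, 0.00001) never accumulate floating-point drift
and an ANI exactly equal to a threshold classifies deterministically
(boundary inclusive: the position is shared). Built-ins:

| name | definition | positions |
|------|------------|-----------|
| `lin20` | the primary 20-position scheme (70 … 99.999, positions A–T) | 20 |
| `lin300` | 70 → 99.9 in 0.1 steps | 300 |
| `lin3000` | 70 → 99.99 in 0.01 steps | 3,000 |
| `lin_fine` | 70 → 99.99999 in 0.00001 steps | 3,000,000 |

`lin_fine` is sometimes described as a 300,000-position scheme, but the
stated endpoints and step arithmetically contain 3,000,000 grid points; the
implementation follows the endpoints and step, and neither count is
silently altered. Custom schemes accept any strictly increasing threshold
list; thresholds below 70% ANI are allowed with a warning (ANI stops
reflecting evolutionary relatedness below roughly that level).

The grouping level for the signature layout defaults to 95% ANI: the group
prefix runs through the last position whose threshold ≤ 95. It is
configurable per store (`group_ani`).

## Parameters that matter

| parameter | default | meaning |
|-----------|---------|---------|
| k pair | 21, 51 | k-mer lengths for the coarse / fine search stage |
| n | 2,000 | sketch capacity (hashes per signature) |
| J cutoffs | 0.2475, 0.0025 | k=21 Jaccard ↔ 95% / 70% ANI calibrations |
| fragment length | 1,020 nt | ANI fragment size |
| coverage / identity | >30% / >70% | strict retention filters per fragment |
| min alignment length | 100 nt | fragments shorter than this are never retained |
| group ANI | 95% | LINgroup level used for representatives |

The minimum-alignment-length guard exists because an infix placement of a
few dozen nucleotides can reach 70% identity anywhere in a genome-sized
subject by chance; a BLAST-style aligner discards such hits as
statistically insignificant. Random DNA admits infix matches at roughly
50% identity, but the probability of a ≥100 nt window reaching 70% decays
exponentially, so the guard removes the false positives without touching
genuine homology (a retained trailing fragment of a related genome easily
exceeds 100 nt).

## Numerical and design choices

- **Hashing.** FNV-1a (64-bit) over the 2-bit-encoded canonical k-mer,
  finalized with the splitmix64 mixer for avalanche; fixed constants, fully
  deterministic, vectorized across all windows with numpy. Signatures are
  not hash-compatible with mash/sourmash; only the statistical behaviour
  (bottom-n MinHash) is equivalent.
- **Alignment backend.** edlib in infix ("HW") mode finds the
  edit-distance-optimal placement of the whole fragment in the subject.
  Identity = (columns − edit distance)/columns with gap columns in the
  denominator (the BLAST convention); coverage is the fraction of the
  fragment consumed (100% for an infix placement). A distance cap derived
  from the identity filter (ED < L·(1−t)/t for identity threshold t) lets
  unrelated fragments fail fast. The backend is isolated in one function so
  a different aligner can be substituted. Because the full fragment is
  always consumed, partial homology (e.g. a fragment half-overlapping a
  contig end of the subject) depresses identity rather than coverage; with
  substitution-dominated divergence this is immaterial, and equivalence
  with BLAST-based ANI is statistical, not bit-exact.
- **Tie-breaking.** Everywhere, ties resolve to the lowest insertion order
  (search candidates) or forward strand then lowest subject coordinate
  (alignments). This makes runs reproducible genome-for-genome.
- **Number allocation.** The smallest non-negative integer unused under the
  prefix, reserved transactionally, so interleaved allocations never
  collide and re-runs are deterministic.
- **Mantel test.** Pearson correlation of the upper triangles; the p-value
  permutes rows/columns of the second matrix simultaneously with a seeded
  generator and uses the (1 + hits)/(permutations + 1) convention; default
  999 permutations. Constant matrices yield an explicit NaN outcome.
- **Complete linkage.** SciPy agglomerative clustering on distance
  100 − ANI; dendrograms export as Newick with branch lengths.

## The simulator and what passing tests show

`linforge.simulate` draws an i.i.d. ancestor (length ≥ 10,200 nt so every
genome has at least ten ANI fragments; default GC 0.5) and evolves it down
a user-given tree with per-edge substitution rates (uniform choice among
the three alternative bases) and optional geometric indels. Expected
identity between two leaves is the product of (1 − rate) over the path
connecting them; back mutations are ignored, which at the rates used
(≤ 7%) is accurate to second order. Substitution-only evolution keeps the
true alignment trivial, so the identity oracle is exact; indel tests assert
only monotonicity.

The simulator emulates divergence by point substitution only. Real genomes
additionally differ by rearrangement, horizontal transfer, repeats, mobile
elements, and assembly artifacts — all of which perturb both the
Jaccard-vs-ANI calibration and fragment alignment in ways uniform
substitution does not. Passing tests therefore demonstrate the pipeline's
internal correctness (search, assignment, inference, statistics) and its
parameter recovery under the substitution model, not field accuracy on real
assemblies.

Test and verification problem sizes: sketch checks use 50 kb–1 Mb genomes;
ANI parameter recovery uses 20–40 kb genomes at substitution rates
0.005–0.05 (recovered within ±0.5 percentage points of 100(1 − r)); the
end-to-end check adds a seeded 10-genome, 60 kb two-group clade and
verifies n−1 alignments, a complete symmetric matrix, recovery of the
planted 95% split by complete linkage, and inferred values within one point
of the analytic truth for related pairs.

## Known limitations

- Inferred (non-direct) values are only as good as the founding
  measurement; cross-group cells merge onto few values by construction.
- LIN digits depend on insertion order. Pairwise divergence *brackets* are
  order-stable only when each pair's ANI sits inside one threshold bracket
  regardless of which member pair gets measured; near-boundary ANI values
  genuinely change brackets across orders.
- A Jaccard bracket can disagree with the precise alignment (sketch says
  related, alignment finds nothing retained); the genome is then treated
  as novel, with a warning.
- The infix aligner assumes fragments are collinear units; it does not
  model large-scale rearrangement within a fragment.
- No concurrency beyond single-writer transactions; no re-assignment of
  LINs after the fact.
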