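# linforge

Incremental inference of complete pairwise ANI similarity matrices for
prokaryotic genomes, built on Life Identification Numbers (LINs).

## The problem

Average Nucleotide Identity (ANI) is the standard genomic relatedness
measure for bacteria and archaea: the query genome is cut into consecutive
1,020 nt fragments, each fragment is locally aligned to the subject genome,
alignments with more than 30% fragment coverage and more than 70% identity
are retained, and ANI is the mean identity of the retained alignments
(averaged reciprocally over both directions). Alignment-based ANI is
precise but expensive: a complete similarity matrix for *n* genomes needs
*n(n−1)/2 * pairwise alignments, and every newly sequenced genome added to a
collection re-opens the bill.

`linforge` reduces that cost to **one precise ANI computation per genome**.
Each new genome is located in the collection by a fast MinHash search
(bottom-*n* sketches of canonical k-mers, *k* = 21/51, *n* = 2,000), a single
fragment-based reciprocal ANI is computed against the most similar stored
genome, and the result is encoded as a LIN — a vector of integers, one per
ANI threshold of a scheme such as

| ANI (%) | 70 | 75 | 80 | 85 | 90 | 95 | 96 | 97 | 98 | 98.5 | 99 | 99.25 | 99.5 | 99.75 | 99.9 | 99.925 | 99.95 | 99.975 | 99.99 | 99.999 |
|---------|----|----|----|----|----|----|----|----|----|------|----|-------|------|-------|------|--------|-------|--------|-------|--------|
| position | A | B | C | D | E | F | G | H | I | J | K | L | M | N | O | P | Q | R | S | T |

Two genomes share a LIN prefix exactly as deep as their similarity reaches,
so the stored LINs plus the *n−1* recorded ANI values reconstruct every cell
of the all-against-all matrix. Genomes sharing the prefix through the
95%-threshold position form a 95%-level LINgroup — in practice a species.

The search is two-stage: the query's *k* = 21 sketch is compared against one
representative per 95%-level LINgroup; a best Jaccard *J* > 0.2475 places
the query inside that group (then *k* = 51 ranks the members), 0.0025 < *J*
≤ 0.2475 means some stored genome shares at least 70% ANI (*k* = 21 ranks
the group), and *J* ≤ 0.0025 means the query founds a new top-level branch —
with no alignment at all.

The price of inferring instead of computing is explicit: all pairs across
two groups collapse onto the ANI recorded at the groups' divergence event.
The package exposes this honestly and provides the evaluation statistics
used to quantify it (complete-linkage clustering, Mantel tests with Pearson
correlation).

## Worked example

Simulate a clade with two planted groups (within-group divergence 0.5%,
cross-group ~7%), add the genomes in order, and export the inferred matrix:

```bash
$ linforge simulate clade.yaml --out genomes       # seeded, 40.8 kb genomes
$ linforge init store
$ linforge add store genomes/g1.fasta genomes/g2.fasta genomes/g3.fasta \
                     genomes/g4.fasta genomes/g5.fasta
g1  novel         0.000000  -   -
g2  same_f_group  0.661000  g1  98.9657
g3  same_f_group  0.672500  g2  98.9877
g4  shared_a      0.129500  g2  93.2404
g5  same_f_group  0.675000  g4  99.0075
$ linforge matrix store --out ani.tsv --newick tree.nwk
```

Each `add` line is the audit record: search bracket, best Jaccard, chosen
subject, and the one precise ANI computed for that genome. `g4` fell below
the 0.2475 cutoff (new 95%-level LINgroup, fresh number at the F position);
everyone else joined an existing group. Four ANI computations produced the
complete 5×5 matrix:

```
genome  g1      g2      g3      g4      g5
g1      100.00  98.97   98.99   93.24   93.24
g2      98.97   100.00  98.99   93.24   93.24
g3      98.99   98.99   100.00  93.24   93.24
g4      93.24   93.24   93.24   100.00  99.01
g5      93.24   93.24   93.24   99.01   100.00
```

All six cross-group cells equal 93.24 — the single value recorded when `g4`
founded the second group — while the simulator's analytic truth is 93.15:
direct cells are exact, inferred cells inherit the founding measurement.
`linforge compare ani.tsv other.tsv` runs the seeded Mantel test between two
matrices and prints the Pearson *r* and permutation *p*-value.

## Layout

- `linforge.scheme` — LIN schemes on an exact decimal grid
- `linforge.sketch` — bottom-n MinHash signatures, Jaccard estimation
- `linforge.ani` — fragment-based reciprocal ANI (edlib infix alignment)
- `linforge.store` — SQLite persistence + LINgroup signature layout
- `linforge.assign` — the incremental add-genome algorithm
- `linforge.matrix` — matrix inference, clustering, Mantel test
- `linforge.simulate` — seeded synthetic clades with analytic truth
- `linforge.cli` — `linforge init|add|matrix|compare|simulate|status`

See `docs/methods.md` for the model, parameter defaults, and limitations.
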