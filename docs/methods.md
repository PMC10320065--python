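# Methods

## Model and procedure

`kmersieve` screens sequencing reads against a user-supplied panel of
suspected contaminant genomes. The pipeline has four stages.

**1. Index construction.** All k-mers of all reference sequences are stored
in an exact hash map keyed by canonical k-mer (the lexicographic minimum of
the k-mer and its reverse complement, so both strands index identically; a
flag disables canonicalization for strand-specific work). Each k-mer maps to
one taxonomy node: the labelling node of the only genome containing it, or
the lowest common ancestor (LCA) of all labelling nodes when several genomes
share it. Adding genomes can therefore only move an existing k-mer's
assignment toward the root, never sideways or down. Windows containing any
non-ACGT character are skipped entirely; IUPAC ambiguity codes are not
expanded, matching the masking behaviour of standard k-mer classifiers.

This is an *exact* index — no minimizers, spaced seeds or compact hashing.
It reproduces the assignment semantics of Kraken-family classifiers while
remaining fully auditable (every entry can be checked against a brute-force
scan, and the test suite does exactly that). The cost is memory proportional
to the number of distinct k-mers, which is appropriate for curated
contaminant panels (vectors, a host genome, a set of suspect bacteria), not
for whole-RefSeq databases.

**2. Read scoring.** A read of length *l* has *l* − k + 1 possible windows;
each valid window is looked up and hits are accumulated per node. The
read-node score of node *v* is count(*v*) / (*l* − k + 1); the read is
assigned to the argmax node (ties: deeper node first — more specific — then
smaller node id, making output deterministic). The read-contamination score
is the sum of read-node scores, i.e. the fraction of possible windows
matching the panel at all. Conservation holds exactly: the node scores plus
the unclassified fraction account for every valid window, so the
contamination score always lies in [0, 1] and bounds the assigned score
from above.

**3. Pair combination.** Mates are scored independently; the pair carries
the classification of the higher-scoring mate, so a single contaminated
mate condemns the pair. Which score is compared is configurable
(`contamination-score`, the default, since filtering acts on that score; or
`node-score`); the two agree whenever a mate's k-mers all hit one node, as
in the canonical example (0.2 on species X vs 0.75 on species Y → the pair
is 0.75 on Y). Ties keep the first mate, making combination commutative up
to that documented tie-break and idempotent on identical mates.

**4. Filtering.** Decision rules in priority order: assigned node in the
retained set → retain; in the filtered set → filter; contamination score
strictly below the threshold → retain; otherwise → filter. Unmatched reads
(including reads shorter than k or fully ambiguous, whose scores are
defined as 0) are always clean — nothing in the panel resembles them. The
override sets match the assigned node exactly by default; an optional
subtree mode extends them to descendants via ancestor queries. At exactly
the threshold a read is filtered (retain strictly-below); this choice at
the boundary is a documented convention.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| k | 35 | window length; standard for species-level discrimination. Fully configurable — tests and desk-scale fixtures use k = 3–21, where exactness can be verified by enumeration |
| threshold | 0.5 | contamination score at or above which a read is filtered |
| canonicalize | on | strand-symmetric indexing |
| pair-combine | contamination-score | which mate score decides the pair |
| retain/filter node sets | empty | per-node overrides of the threshold |

## The score matrix and interactive summaries

Classifications are folded once into a 101 × (nodes + 1) matrix: rows are
the score bins 0.00, 0.01, …, 1.00, columns the assigned nodes plus an
"unmatched" pseudo-column, cells the read (or pair) counts. All summaries —
filtered/retained percentages, the per-node table, the threshold
histogram — are pure functions of this matrix and the filter configuration,
so threshold changes and per-node overrides are O(bins × nodes), not
O(reads).

Binning takes the *floor* on the 0.01 grid: score *s* lands in the largest
bin label ≤ *s*. With thresholds selected on the same grid (as a histogram
interface does), "bin ≥ threshold" then coincides exactly with the per-read
rule "score ≥ threshold", so matrix-derived summaries equal a full re-scan
of the classifications — the property the test suite asserts for random
configurations. A round-to-nearest rule would break this at half-bin
margins. Off-grid thresholds are snapped up to the next bin label for
matrix queries. Note that with retained-node overrides active, retained
reads can legitimately sit to the right of the threshold in the histogram.

## Synthetic data

The generator emulates the canonical screening scenario: reads from a
target organism with a planted fraction of contaminant reads.

* Genomes are i.i.d.-uniform ACGT strings, one per leaf of a star (or
  caterpillar) taxonomy. Unrelated random genomes of length *l* share an
  expected ~*l*²/4^k k-mers — effectively zero at k ≥ 21 for desk-scale
  lengths — so classification on them is noiseless by construction.
* Reads or pairs are drawn from a stated mixture of genomes (default 90%
  target / 10% contaminant, 10,000 pairs of 100 bp from 50 kb genomes,
  error-free) at uniform positions and strands; paired mates are the
  fragment ends in forward/reverse orientation. Substitution errors are
  i.i.d. per base; indels are not modelled, since the classifier's math is
  already exercised by substitutions. Qualities are constant dummies and
  never consulted.
* Mirroring real usage, the index is built from contaminant genomes only:
  the target organism is absent, its reads are unmatched, and the pipeline's
  filtered fraction estimates the planted contamination rate.
* The whole generate → classify → filter chain is deterministic under the
  seed.

What passing these tests shows — and does not. On this synthetic model,
separation between target and contaminant is essentially perfect, so the
end-to-end tests verify the *machinery* (scores, thresholds, pairing,
bookkeeping) exactly. They do not measure performance on real data, where
genomes share homologous sequence, reads carry structured errors, and an
exact-k-mer index and a minimizer-based classifier can disagree.

## Numerical choices and degenerate inputs

* Scores are exact small-denominator rationals in double precision;
  conservation identities are asserted to 1e-12.
* Binning guards the float grid with a 1e-6 epsilon so exact rationals like
  29/100 land on their own label.
* Reads with *l* < k or all-ambiguous windows: score functions raise on a
  zero denominator; assignment and filtering define them as unmatched/clean.
* Empty index (k longer than every reference) is a warning, not an error.
* Index files are gzipped sorted text with no timestamp, so identical
  inputs rebuild byte-identical files; a taxonomy fingerprint (SHA-256 of
  the edge list) binds each index to its tree and is verified on load.

## Known limitations

* Exact k-mer storage bounds database size by available memory; no
  low-complexity masking is performed before indexing.
* No quality trimming, adapter removal or reference-free filtering; run
  dedicated preprocessors first if needed.
* Orphaned mates are not re-paired and interleaved FASTQ is not accepted.
* Taxonomy is explicit user input; merged/deleted-node files and rank
  normalization are out of scope.
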