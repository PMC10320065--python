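"""Per-read k-mer profiles and the two scores driving contamination filtering.

A read of length *l* has ``l - k + 1`` possible k-mer windows. Each valid
window (no ambiguous base) is looked up in the index; hits accumulate per
taxonomy node into a :class:`ReadKmerProfile`. Two scores follow:

* **read-node score** — for one node, the count of k-mers assigned to it
  divided by ``l - k + 1``;
* **read-contamination score** — the sum of read-node scores over all nodes,
  i.e. the fraction of the read's possible k-mers that match the contaminant
  database at all.

A read is assigned to the node maximizing its read-node score (ties: the
deeper — more specific — node wins, residual ties to the smaller node id).
Mates of a paired-end read are scored independently and combined by taking
the higher-scoring mate, so one contaminated mate condemns the pair.

Reads shorter than k, or whose windows are all ambiguous, cannot match
anything: they are treated as unmatched with both scores 0, which routes
them to the retained (clean) output downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator

from .errors import ConfigError, PairingError, ParseError, UndefinedScoreError
from .kmer_index import KmerIndex, canonical_form, enumerate_kmers
from .seqio import SeqRecord, pair_stem
from .taxonomy import TaxonomyTree

__all__ = [
    "ReadKmerProfile",
    "ReadClassification",
    "classify_read",
    "read_node_score",
    "contamination_score",
    "assign_read",
    "combine_pair",
    "parse_kraken_style",
    "write_kraken_style",
]


@dataclass
class ReadKmerProfile:
    """Counts of k-mers assigned to each taxonomy node for one read."""

    read_id: str
    read_length: int
    k: int
    node_counts: dict[int, int] = field(default_factory=dict)
    unclassified_count: int = 0

    @property
    def total_possible(self) -> int:
        """Denominator of every score: ``max(l - k + 1, 0)``."""
        return max(self.read_length - self.k + 1, 0)

    @property
    def valid_windows(self) -> int:
        """Windows actually scored (ambiguous windows are excluded)."""
        return sum(self.node_counts.values()) + self.unclassified_count


@dataclass(frozen=True)
class ReadClassification:
    """Assignment and scores for one read (or one combined pair)."""

    read_id: str
    assigned_node: int | None
    assigned_score: float
    contamination_score: float
    mate_of: str | None = None


def classify_read(
    read: SeqRecord, index: KmerIndex, tree: TaxonomyTree | None = None
) -> ReadKmerProfile:
    """Look up every valid k-mer window of *read* in *index*.

    Hits increment the matched node's count; misses increment
    ``unclassified_count``. When *tree* is given, the index/taxonomy
    fingerprints are checked first.
    """
    if tree is not None:
        index.check_tree(tree)
    profile = ReadKmerProfile(read.read_id, len(read.sequence), index.k)
    entries = index.entries
    canon = index.canonicalize
    counts = profile.node_counts
    for kmer in enumerate_kmers(read.sequence, index.k):
        node = entries.get(canonical_form(kmer) if canon else kmer)
        if node is None:
            profile.unclassified_count += 1
        else:
            counts[node] = counts.get(node, 0) + 1
    return profile


def read_node_score(profile: ReadKmerProfile, node: int) -> float:
    """Fraction of the read's possible k-mers assigned to *node*."""
    if profile.total_possible == 0:
        raise UndefinedScoreError(
            f"read {profile.read_id!r}: length {profile.read_length} < k={profile.k}, "
            "scores are undefined"
        )
    return profile.node_counts.get(node, 0) / profile.total_possible


def contamination_score(profile: ReadKmerProfile) -> float:
    """Sum of read-node scores over all nodes: matched windows / (l - k + 1)."""
    if profile.total_possible == 0:
        raise UndefinedScoreError(
            f"read {profile.read_id!r}: length {profile.read_length} < k={profile.k}, "
            "scores are undefined"
        )
    return sum(profile.node_counts.values()) / profile.total_possible


def assign_read(profile: ReadKmerProfile, tree: TaxonomyTree) -> ReadClassification:
    """Assign the read to the node maximizing its read-node score.

    Tie-break: larger count first (trivially), then the deeper node (more
    specific), then the smaller node id — fully deterministic. A profile with
    no matches (including reads shorter than k) is unmatched with both
    scores 0.
    """
    if profile.total_possible == 0 or not profile.node_counts:
        return ReadClassification(profile.read_id, None, 0.0, 0.0)
    best = max(
        profile.node_counts,
        key=lambda n: (profile.node_counts[n], tree.depth(n), -n),
    )
    return ReadClassification(
        read_id=profile.read_id,
        assigned_node=best,
        assigned_score=read_node_score(profile, best),
        contamination_score=contamination_score(profile),
    )


def combine_pair(
    c1: ReadClassification,
    c2: ReadClassification,
    by: str = "contamination-score",
) -> ReadClassification:
    """Combine mate classifications: the higher-scoring mate wins.

    The pair carries the assigned node and both scores of the mate with the
    larger score — e.g. mates scoring 0.2 on species X and 0.75 on species Y
    yield a pair scored 0.75 on species Y. ``by`` selects which score is
    compared: ``"contamination-score"`` (default, the score filtering acts
    on) or ``"node-score"`` (the assigned-node score). On a tie the first
    mate is kept, making the operation deterministic and idempotent on
    identical mates.
    """
    if by == "contamination-score":
        key = lambda c: c.contamination_score  # noqa: E731
    elif by == "node-score":
        key = lambda c: c.assigned_score  # noqa: E731
    else:
        raise ConfigError(f"unknown pair-combine mode {by!r}")
    stem1, stem2 = pair_stem(c1.read_id), pair_stem(c2.read_id)
    if stem1 != stem2:
        raise PairingError(
            f"cannot combine non-mates {c1.read_id!r} and {c2.read_id!r}"
        )
    winner, loser = (c2, c1) if key(c2) > key(c1) else (c1, c2)
    return replace(winner, read_id=stem1, mate_of=loser.read_id)


# -- Kraken-style per-read text format ---------------------------------------
#
# One line per read:  FLAG<TAB>READ_ID<TAB>TAXID<TAB>LENGTH<TAB>TOKENS
# FLAG is C (classified) or U (unclassified); TOKENS are space-separated
# "taxid:count" pairs, with taxid 0 meaning unclassified k-mers and the
# letter A meaning ambiguous windows. This mirrors the per-read output of
# Kraken-family classifiers closely enough to ingest their results directly.


def write_kraken_style(
    profiles: Iterable[ReadKmerProfile],
    tree: TaxonomyTree,
    out: IO[str] | str | Path,
) -> int:
    """Serialize profiles to the per-read text format; returns lines written.

    Node counts are emitted in sorted node order followed by a ``0:n`` token
    for unclassified windows, so the output is deterministic and re-parses to
    an equal profile.
    """
    handle: IO[str]
    own = isinstance(out, (str, Path))
    handle = open(out, "w", encoding="utf-8") if own else out  # type: ignore[arg-type]
    n = 0
    try:
        for profile in profiles:
            cls = assign_read(profile, tree)
            flag = "U" if cls.assigned_node is None else "C"
            taxid = 0 if cls.assigned_node is None else cls.assigned_node
            tokens = [
                f"{node}:{profile.node_counts[node]}"
                for node in sorted(profile.node_counts)
            ]
            if profile.unclassified_count:
                tokens.append(f"0:{profile.unclassified_count}")
            handle.write(
                f"{flag}\t{profile.read_id}\t{taxid}\t{profile.read_length}\t"
                f"{' '.join(tokens)}\n"
            )
            n += 1
    finally:
        if own:
            handle.close()
    return n


def parse_kraken_style(
    lines: Iterable[str] | IO[str] | str | Path,
    tree: TaxonomyTree,
    k: int,
    unknown_taxid: str = "error",
) -> Iterator[ReadKmerProfile]:
    """Parse Kraken-style per-read lines into profiles.

    ``unknown_taxid`` controls what happens when a token's taxid is absent
    from *tree*: ``"error"`` raises, ``"root"`` reassigns the count to the
    root node. Tokens ``0:n`` and ``A:n`` both count as unclassified
    (ambiguous windows are not distinguished from misses here).
    """
    if unknown_taxid not in ("error", "root"):
        raise ConfigError(f"unknown_taxid must be 'error' or 'root', got {unknown_taxid!r}")
    if isinstance(lines, (str, Path)):
        lines = Path(lines).read_text(encoding="utf-8").splitlines()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(f"line {lineno}: expected >=4 tab-separated fields")
        _flag, read_id, _taxid, length_field = fields[:4]
        tokens = fields[4].split() if len(fields) > 4 and fields[4] else []
        try:
            read_length = int(length_field)
        except ValueError:
            raise ParseError(f"line {lineno}: non-integer read length {length_field!r}")
        profile = ReadKmerProfile(read_id, read_length, k)
        for token in tokens:
            taxid_str, sep, count_str = token.partition(":")
            try:
                count = int(count_str)
                if not sep or count < 0:
                    raise ValueError
            except ValueError:
                raise ParseError(f"line {lineno}: malformed token {token!r}")
            if taxid_str in ("0", "A"):
                profile.unclassified_count += count
                continue
            try:
                taxid = int(taxid_str)
            except ValueError:
                raise ParseError(f"line {lineno}: malformed token {token!r}")
            if taxid not in tree:
                if unknown_taxid == "error":
                    raise ParseError(
                        f"line {lineno}: taxid {taxid} absent from taxonomy"
                    )
                taxid = tree.root_id
            profile.node_counts[taxid] = profile.node_counts.get(taxid, 0) + count
        if profile.valid_windows > profile.total_possible:
            raise ParseError(
                f"line {lineno}: {profile.valid_windows} k-mers reported but only "
                f"{profile.total_possible} windows possible at k={k}"
            )
        yield profile
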