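"""Synthetic genomes, taxonomies and reads with planted contamination.

The generator emulates the canonical decontamination scenario: a sequencing
run of a target organism carrying a known fraction of reads from contaminant
organisms. Reference genomes are i.i.d.-uniform ACGT strings — unrelated
organisms share essentially no k-mers at k >= 21 (expected collisions per
genome pair are about l^2 / 4^k) — hung as leaves of a small taxonomy. Reads
(or pairs) are drawn from a stated mixture of genomes at uniform positions
and strands, with i.i.d. per-base substitution errors; indels are not
modelled. Truth labels record each read's source so recovery can be scored.

The default configuration is the 90/10 scenario used throughout the test
harness: two 50 kb genomes, 10,000 error-free pairs of 100 bp at a 90%
target / 10% contaminant mixture. Mirroring real usage, the reference
database is built from the *contaminant* genomes only — the target organism
is absent, so its reads are unmatched and flow to the clean output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .filterer import FilterDecision
from .kmer_index import ReferenceGenome, reverse_complement
from .seqio import SeqRecord, write_records
from .taxonomy import TaxNode, TaxonomyTree

__all__ = [
    "SimConfig",
    "TruthRecord",
    "RecoveryMetrics",
    "generate_genomes",
    "simulate_reads",
    "evaluate_recovery",
]

ROOT_ID = 1
FIRST_LEAF_ID = 101
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic run.

    ``mixture`` maps leaf node ids to sampling fractions (must sum to 1);
    the target node defaults to the largest-fraction entry, every other
    mixture node is a contaminant. Leaf ids start at 101 under root 1.
    """

    n_genomes: int = 2
    genome_length: int = 50_000
    mixture: Mapping[int, float] = field(
        default_factory=lambda: {FIRST_LEAF_ID: 0.9, FIRST_LEAF_ID + 1: 0.1}
    )
    n_reads: int = 10_000
    read_length: int = 100
    error_rate: float = 0.0
    paired: bool = True
    insert_size: int = 300
    topology: str = "star"  # or "caterpillar"
    target_node: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_genomes < 1 or self.genome_length < 1 or self.n_reads < 1:
            raise ConfigError("n_genomes, genome_length and n_reads must be positive")
        if not 0.0 <= self.error_rate < 1.0:
            raise ConfigError(f"error_rate must be in [0, 1), got {self.error_rate}")
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"mixture fractions sum to {total}, expected 1")
        if any(not 0.0 <= f <= 1.0 for f in self.mixture.values()):
            raise ConfigError("mixture fractions must lie in [0, 1]")
        if self.topology not in ("star", "caterpillar"):
            raise ConfigError(f"unknown topology {self.topology!r}")

    @property
    def leaf_ids(self) -> list[int]:
        return [FIRST_LEAF_ID + i for i in range(self.n_genomes)]

    def resolved_target(self) -> int:
        if self.target_node is not None:
            return self.target_node
        return max(self.mixture, key=lambda n: (self.mixture[n], -n))


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated read (or pair)."""

    read_id: str
    source_node: int
    is_contaminant: bool


@dataclass(frozen=True)
class RecoveryMetrics:
    """How well filtering recovered the planted contamination."""

    sensitivity: float  # contaminants filtered / contaminants simulated
    specificity: float  # target reads retained / target reads simulated
    contamination_fraction: float  # filtered / total, the pipeline's estimate
    n_contaminants: int
    n_targets: int


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def generate_genomes(config: SimConfig) -> tuple[list[ReferenceGenome], TaxonomyTree]:
    """Generate one uniform-random genome per taxonomy leaf.

    The taxonomy is either a star (all leaves directly under root 1) or a
    caterpillar (a chain of internal nodes, one leaf hanging off each),
    giving tests a tree with non-trivial LCA structure when needed.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    leaves = config.leaf_ids
    nodes = [TaxNode(ROOT_ID, ROOT_ID, rank="root", name="root")]
    if config.topology == "star":
        nodes += [
            TaxNode(leaf, ROOT_ID, rank="species", name=f"species_{leaf}")
            for leaf in leaves
        ]
    else:  # caterpillar: root - i1 - i2 - ..., leaf j under internal j
        prev = ROOT_ID
        for i, leaf in enumerate(leaves):
            internal = 50 + i
            nodes.append(TaxNode(internal, prev, rank="clade", name=f"clade_{internal}"))
            nodes.append(TaxNode(leaf, internal, rank="species", name=f"species_{leaf}"))
            prev = internal
    tree = TaxonomyTree(nodes)
    references = [
        ReferenceGenome(
            label=f"genome_{leaf}",
            node_id=leaf,
            sequences=(_random_sequence(rng, config.genome_length),),
        )
        for leaf in leaves
    ]
    return references, tree


def _apply_errors(rng: np.random.Generator, sequence: str, error_rate: float) -> str:
    if error_rate == 0.0:
        return sequence
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def simulate_reads(
    references: Sequence[ReferenceGenome],
    config: SimConfig,
    out_dir: str | Path,
    gzip_out: bool = False,
) -> tuple[list[Path], list[TruthRecord]]:
    """Simulate reads from the mixture and write FASTQ file(s) plus truth TSV.

    Fragments are placed uniformly on a uniformly chosen strand of a
    mixture-sampled genome; in paired mode the two mates are the fragment's
    ends in standard forward/reverse orientation. Qualities are constant
    dummies ('I'). Returns the FASTQ paths and the truth records (also
    written to ``truth.tsv``).
    """
    by_node = {ref.node_id: ref for ref in references}
    missing = [n for n in config.mixture if n not in by_node]
    if missing:
        raise ConfigError(f"mixture nodes {missing} have no reference genome")
    frag_len = config.insert_size if config.paired else config.read_length
    if config.paired and config.insert_size < config.read_length:
        raise ConfigError("insert_size must be >= read_length in paired mode")
    for node in config.mixture:
        if frag_len > min(len(s) for s in by_node[node].sequences):
            raise ConfigError(
                f"fragment length {frag_len} exceeds genome length of node {node}"
            )

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    mixture_nodes = sorted(config.mixture)
    probs = np.array([config.mixture[n] for n in mixture_nodes])
    probs = probs / probs.sum()
    target = config.resolved_target()

    sources = rng.choice(mixture_nodes, size=config.n_reads, p=probs)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    reads1: list[SeqRecord] = []
    reads2: list[SeqRecord] = []
    truth: list[TruthRecord] = []
    width = len(str(config.n_reads))
    for i, node in enumerate(sources):
        node = int(node)
        genome = by_node[node].sequences[0]
        pos = int(rng.integers(0, len(genome) - frag_len + 1))
        fragment = genome[pos : pos + frag_len]
        if rng.random() < 0.5:
            fragment = reverse_complement(fragment)
        stem = f"read_{i:0{width}d}"
        qual = "I" * config.read_length
        if config.paired:
            m1 = _apply_errors(rng, fragment[: config.read_length], config.error_rate)
            m2 = _apply_errors(
                rng,
                reverse_complement(fragment[-config.read_length :]),
                config.error_rate,
            )
            reads1.append(SeqRecord(f"{stem}/1", m1, qual))
            reads2.append(SeqRecord(f"{stem}/2", m2, qual))
        else:
            seq = _apply_errors(rng, fragment, config.error_rate)
            reads1.append(SeqRecord(stem, seq, qual))
        truth.append(TruthRecord(stem, node, node != target))

    suffix = ".fastq.gz" if gzip_out else ".fastq"
    if config.paired:
        paths = [out_dir / f"reads_1{suffix}", out_dir / f"reads_2{suffix}"]
        write_records(reads1, paths[0])
        write_records(reads2, paths[1])
    else:
        paths = [out_dir / f"reads{suffix}"]
        write_records(reads1, paths[0])

    truth_path = out_dir / "truth.tsv"
    with open(truth_path, "w", encoding="utf-8") as handle:
        handle.write("#read_id\tsource_node\tis_contaminant\n")
        for t in truth:
            handle.write(f"{t.read_id}\t{t.source_node}\t{int(t.is_contaminant)}\n")

    return paths, truth


def load_truth(path: str | Path) -> list[TruthRecord]:
    """Read a truth TSV written by :func:`simulate_reads`."""
    truth = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        if not raw.strip() or raw.startswith("#"):
            continue
        read_id, node, flag = raw.split("\t")
        truth.append(TruthRecord(read_id, int(node), bool(int(flag))))
    return truth


def evaluate_recovery(
    truth: Sequence[TruthRecord],
    decisions: Mapping[str, FilterDecision] | Sequence[FilterDecision],
) -> RecoveryMetrics:
    """Score filter decisions against the planted truth.

    Sensitivity is the fraction of contaminant reads that were filtered;
    specificity the fraction of target reads retained. Decisions must cover
    exactly the simulated reads (keyed by pair stem).
    """
    if not isinstance(decisions, Mapping):
        decisions = {d.read_id: d for d in decisions}
    missing = [t.read_id for t in truth if t.read_id not in decisions]
    if missing:
        raise ConfigError(
            f"{len(missing)} truth reads lack decisions (first: {missing[0]!r})"
        )
    n_contam = sum(t.is_contaminant for t in truth)
    n_target = len(truth) - n_contam
    tp = sum(
        1
        for t in truth
        if t.is_contaminant and decisions[t.read_id].verdict == "filter"
    )
    tn = sum(
        1
        for t in truth
        if not t.is_contaminant and decisions[t.read_id].verdict == "retain"
    )
    n_filtered = sum(1 for t in truth if decisions[t.read_id].verdict == "filter")
    return RecoveryMetrics(
        sensitivity=tp / n_contam if n_contam else 1.0,
        specificity=tn / n_target if n_target else 1.0,
        contamination_fraction=n_filtered / len(truth) if truth else 0.0,
        n_contaminants=n_contam,
        n_targets=n_target,
    )
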