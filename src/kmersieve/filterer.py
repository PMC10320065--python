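"""Threshold and node-override rules partitioning reads into clean/contaminated.

The decision for one read (or combined pair) applies rules in priority order:

1. assigned node in the retained set (or under one, in subtree mode) -> retain;
2. assigned node in the filtered set -> filter;
3. contamination score strictly below the threshold -> retain;
4. otherwise -> filter.

Unmatched reads — nothing in the database resembles them — are always part of
the clean data. The default threshold is 0.5. At exactly the threshold the
read is filtered (retain strictly-below, filter at-or-above).

Paired reads are a single filtering unit: the decision is made on the
combined pair classification and applied to both mates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from . import seqio
from .classify import ReadClassification
from .errors import ConfigError, PairingError
from .seqio import SeqRecord, pair_stem
from .taxonomy import TaxonomyTree

__all__ = ["FilterConfig", "FilterDecision", "RunStats", "decide", "filter_files"]


@dataclass(frozen=True)
class FilterConfig:
    """Filtering policy: score threshold plus node-level overrides."""

    threshold: float = 0.5
    retained_nodes: frozenset[int] = frozenset()
    filtered_nodes: frozenset[int] = frozenset()
    retain_subtrees: bool = False

    def __post_init__(self):
        if not 0.0 <= self.threshold <= 1.0:
            raise ConfigError(f"threshold must be in [0, 1], got {self.threshold}")
        object.__setattr__(self, "retained_nodes", frozenset(self.retained_nodes))
        object.__setattr__(self, "filtered_nodes", frozenset(self.filtered_nodes))
        overlap = self.retained_nodes & self.filtered_nodes
        if overlap:
            raise ConfigError(
                f"nodes cannot be both retained and filtered: {sorted(overlap)}"
            )


@dataclass(frozen=True)
class FilterDecision:
    read_id: str
    verdict: str  # "retain" | "filter"
    reason: str  # below-threshold | unmatched | retained-node | above-threshold
    #              | filtered-node | mate-filtered


def _in_node_set(
    node: int, node_set: frozenset[int], subtrees: bool, tree: TaxonomyTree | None
) -> bool:
    if node in node_set:
        return True
    if subtrees and tree is not None:
        return any(a in tree and tree.is_ancestor(a, node) for a in node_set)
    return False


def decide(
    c: ReadClassification,
    config: FilterConfig,
    tree: TaxonomyTree | None = None,
) -> FilterDecision:
    """Apply the filtering rules to one classification.

    *tree* is only needed when ``config.retain_subtrees`` is set (override
    sets then cover whole subtrees via ancestor queries).
    """
    if c.assigned_node is None:
        return FilterDecision(c.read_id, "retain", "unmatched")
    if _in_node_set(c.assigned_node, config.retained_nodes, config.retain_subtrees, tree):
        return FilterDecision(c.read_id, "retain", "retained-node")
    if _in_node_set(c.assigned_node, config.filtered_nodes, config.retain_subtrees, tree):
        return FilterDecision(c.read_id, "filter", "filtered-node")
    if c.contamination_score < config.threshold:
        return FilterDecision(c.read_id, "retain", "below-threshold")
    return FilterDecision(c.read_id, "filter", "above-threshold")


@dataclass
class RunStats:
    """Bookkeeping for one filtering pass (counts are reads or pairs)."""

    total: int = 0
    retained: int = 0
    filtered: int = 0
    per_node_filtered: dict[int, int] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "total": self.total,
            "retained": self.retained,
            "filtered": self.filtered,
            "per_node_filtered": {str(k): v for k, v in self.per_node_filtered.items()},
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


def filter_files(
    reads: str | Path,
    classifications: Mapping[str, ReadClassification],
    config: FilterConfig,
    out_clean: str | Path,
    out_contam: str | Path | None = None,
    reads2: str | Path | None = None,
    out_clean2: str | Path | None = None,
    out_contam2: str | Path | None = None,
    tree: TaxonomyTree | None = None,
    decisions_out: list[FilterDecision] | None = None,
) -> RunStats:
    """Partition read file(s) into clean and (optionally) contaminated outputs.

    *classifications* maps each read id — the pair stem, for paired input —
    to its finalized :class:`ReadClassification` (pairs already combined).
    Records are written in input order; with paired input both mates follow
    the pair verdict, and a pair whose mate was condemned is recorded with
    reason ``mate-filtered`` in *decisions_out* for the second mate. Output
    files whose names end in ``.gz`` are gzip-compressed.
    """
    paired = reads2 is not None
    if paired and out_clean2 is None:
        raise ConfigError("paired input requires out_clean2")

    stats = RunStats()

    def verdict_for(stem: str) -> FilterDecision:
        try:
            c = classifications[stem]
        except KeyError:
            raise PairingError(f"no classification for read {stem!r}") from None
        return decide(c, config, tree)

    clean1: list[SeqRecord] = []
    contam1: list[SeqRecord] = []
    clean2: list[SeqRecord] = []
    contam2: list[SeqRecord] = []

    def flush() -> None:
        # Buffered writes keep this simple; desk-scale files fit comfortably.
        seqio.write_records(clean1, out_clean)
        if out_contam is not None:
            seqio.write_records(contam1, out_contam)
        if paired:
            seqio.write_records(clean2, out_clean2)  # type: ignore[arg-type]
            if out_contam2 is not None:
                seqio.write_records(contam2, out_contam2)

    if paired:
        stream = seqio.pair_streams(seqio.read_records(reads), seqio.read_records(reads2))
        for r1, r2 in stream:
            stem = pair_stem(r1.read_id)
            d = verdict_for(stem)
            stats.total += 1
            if d.verdict == "retain":
                stats.retained += 1
                clean1.append(r1)
                clean2.append(r2)
            else:
                stats.filtered += 1
                contam1.append(r1)
                contam2.append(r2)
                node = classifications[stem].assigned_node
                if node is not None:
                    stats.per_node_filtered[node] = (
                        stats.per_node_filtered.get(node, 0) + 1
                    )
            if decisions_out is not None:
                decisions_out.append(d)
                mate_reason = d.reason if d.verdict == "retain" else "mate-filtered"
                decisions_out.append(FilterDecision(r2.read_id, d.verdict, mate_reason))
    else:
        for rec in seqio.read_records(reads):
            d = verdict_for(rec.read_id)
            stats.total += 1
            if d.verdict == "retain":
                stats.retained += 1
                clean1.append(rec)
            else:
                stats.filtered += 1
                contam1.append(rec)
                node = classifications[rec.read_id].assigned_node
                if node is not None:
                    stats.per_node_filtered[node] = (
                        stats.per_node_filtered.get(node, 0) + 1
                    )
            if decisions_out is not None:
                decisions_out.append(d)

    flush()
    return stats
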