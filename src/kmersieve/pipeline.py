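"""End-to-end helpers chaining classification, filtering and reporting.

These are the workflows the CLI wraps: classify every read (or pair) of a
file against an index, then partition the file by the filter configuration
and summarize the outcome.
"""

from __future__ import annotations

from pathlib import Path
from . import seqio
from .classify import (
    ReadClassification,
    assign_read,
    classify_read,
    combine_pair,
)
from .filterer import FilterConfig, FilterDecision, RunStats, filter_files
from .kmer_index import KmerIndex
from .report import Summary, build_matrix, summarize
from .seqio import pair_stem
from .taxonomy import TaxonomyTree

__all__ = ["classify_files", "run_filter"]


def classify_files(
    reads: str | Path,
    index: KmerIndex,
    tree: TaxonomyTree,
    reads2: str | Path | None = None,
    pair_combine: str = "contamination-score",
) -> dict[str, ReadClassification]:
    """Classify a read file (or pair of files) into finalized classifications.

    Returns a mapping keyed by read id (pair stem for paired input); paired
    classifications are already combined by the max-over-mates rule.
    """
    index.check_tree(tree)
    out: dict[str, ReadClassification] = {}
    if reads2 is None:
        for rec in seqio.read_records(reads):
            out[rec.read_id] = assign_read(classify_read(rec, index), tree)
    else:
        pairs = seqio.pair_streams(
            seqio.read_records(reads), seqio.read_records(reads2)
        )
        for r1, r2 in pairs:
            c1 = assign_read(classify_read(r1, index), tree)
            c2 = assign_read(classify_read(r2, index), tree)
            out[pair_stem(r1.read_id)] = combine_pair(c1, c2, by=pair_combine)
    return out


def run_filter(
    reads: str | Path,
    index: KmerIndex,
    tree: TaxonomyTree,
    config: FilterConfig,
    out_clean: str | Path,
    reads2: str | Path | None = None,
    out_clean2: str | Path | None = None,
    out_contam: str | Path | None = None,
    out_contam2: str | Path | None = None,
    pair_combine: str = "contamination-score",
) -> tuple[RunStats, Summary, list[FilterDecision]]:
    """Classify, decide, partition and summarize in one pass.

    Returns the run statistics, the dashboard summary built from the 101-bin
    score matrix, and the per-read decisions.
    """
    classifications = classify_files(
        reads, index, tree, reads2=reads2, pair_combine=pair_combine
    )
    decisions: list[FilterDecision] = []
    stats = filter_files(
        reads,
        classifications,
        config,
        out_clean,
        out_contam=out_contam,
        reads2=reads2,
        out_clean2=out_clean2,
        out_contam2=out_contam2,
        tree=tree,
        decisions_out=decisions,
    )
    summary = summarize(build_matrix(classifications.values()), config, tree)
    return stats, summary, decisions
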