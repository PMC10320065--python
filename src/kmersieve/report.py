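"""The 101-bin score matrix and the summaries derived from it.

Scanning millions of reads per dashboard interaction would be hopeless, so
all summaries are computed from a compact intermediate: a matrix whose rows
are the 101 score bins 0.00, 0.01, ..., 1.00, whose columns are taxonomy
nodes (plus an "unmatched" pseudo-column), and whose cells count the reads —
or combined pairs — falling there. Pie-chart percentages, the per-node table
and the threshold histogram are all exact functions of this matrix and the
current filter configuration, which is what makes real-time interactivity
correct: re-summarizing the matrix gives identical counts to re-deciding
every read.

Binning takes the floor on the 0.01 grid (a score s lands in the largest bin
label <= s). Because thresholds are themselves selected on the same grid (a
histogram bar is clicked), "bin >= threshold" agrees exactly with the
per-read rule "score >= threshold"; a round-to-nearest rule would misplace
scores just below a bin label relative to the threshold comparison.
Off-grid thresholds are snapped up to the next bin label for matrix queries.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .classify import ReadClassification
from .errors import ConfigError
from .filterer import FilterConfig
from .taxonomy import TaxonomyTree

__all__ = [
    "N_BINS",
    "score_bin",
    "ScoreMatrix",
    "Summary",
    "build_matrix",
    "summarize",
    "render_report",
]

N_BINS = 101  # score bins 0.00, 0.01, ..., 1.00


def score_bin(score: float) -> int:
    """Bin index (0..100) of a score: floor on the 0.01 grid.

    A small epsilon absorbs float noise so that exact rationals like 29/100
    land on their own label rather than one below.
    """
    if not 0.0 <= score <= 1.0 + 1e-9:
        raise ConfigError(f"score {score} outside [0, 1]")
    return min(int(math.floor(score * 100 + 1e-6)), 100)


def threshold_bin(threshold: float) -> int:
    """Smallest bin index whose label is >= threshold (snap up off-grid)."""
    return min(int(math.ceil(threshold * 100 - 1e-6)), 101)


@dataclass
class ScoreMatrix:
    """101 x (nodes + 1) read counts; column 0 is the unmatched pseudo-column."""

    node_ids: list[int]
    counts: np.ndarray  # shape (N_BINS, len(node_ids) + 1), non-negative ints

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def column(self, node_id: int) -> int:
        """Matrix column index of a node (column 0 is reserved for unmatched)."""
        return self.node_ids.index(node_id) + 1


def build_matrix(classifications: Iterable[ReadClassification]) -> ScoreMatrix:
    """Accumulate finalized classifications (pairs already combined).

    Each read increments the cell at (binned contamination score, assigned
    node); unmatched reads go to bin 0 of the pseudo-column. Node columns are
    ordered by node id.
    """
    cells: dict[tuple[int, int | None], int] = {}
    nodes: set[int] = set()
    for c in classifications:
        if c.assigned_node is None:
            key = (0, None)
        else:
            nodes.add(c.assigned_node)
            key = (score_bin(c.contamination_score), c.assigned_node)
        cells[key] = cells.get(key, 0) + 1
    node_ids = sorted(nodes)
    col = {node: i + 1 for i, node in enumerate(node_ids)}
    counts = np.zeros((N_BINS, len(node_ids) + 1), dtype=np.int64)
    for (b, node), n in cells.items():
        counts[b, 0 if node is None else col[node]] = n
    return ScoreMatrix(node_ids, counts)


@dataclass
class Summary:
    """Everything a dashboard needs: pie, node table, histogram, threshold."""

    total_reads: int
    pct_contaminated: float
    pct_retained: float
    threshold: float
    node_table: pd.DataFrame  # columns: node_id, name, reads, reads_filtered, filtered
    histogram_retained: list[int]  # per-bin retained counts, length 101
    histogram_filtered: list[int]  # per-bin filtered counts, length 101

    def to_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "pct_contaminated": self.pct_contaminated,
            "pct_retained": self.pct_retained,
            "threshold": self.threshold,
            "node_table": self.node_table.to_dict(orient="records"),
            "histogram_retained": self.histogram_retained,
            "histogram_filtered": self.histogram_filtered,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "Summary":
        table = pd.DataFrame(
            payload["node_table"],
            columns=["node_id", "name", "reads", "reads_filtered", "filtered"],
        )
        return cls(
            total_reads=payload["total_reads"],
            pct_contaminated=payload["pct_contaminated"],
            pct_retained=payload["pct_retained"],
            threshold=payload["threshold"],
            node_table=table,
            histogram_retained=list(payload["histogram_retained"]),
            histogram_filtered=list(payload["histogram_filtered"]),
        )


def summarize(
    matrix: ScoreMatrix,
    config: FilterConfig,
    tree: TaxonomyTree | None = None,
) -> Summary:
    """Derive the dashboard summary from the matrix alone (no read rescan).

    Per node column: a retained-override node contributes nothing to the
    filtered count; a filtered-override node contributes its whole column;
    any other node contributes its cells at bins >= the threshold bin. The
    unmatched pseudo-column is never filtered. With ``retain_subtrees`` set
    and a taxonomy supplied, override sets cover descendant columns too.
    Override nodes matching no column are ignored with a warning.
    """
    tb = threshold_bin(config.threshold)
    known = set(matrix.node_ids)
    for node in (config.retained_nodes | config.filtered_nodes) - known:
        if not (config.retain_subtrees and tree is not None and node in tree):
            warnings.warn(
                f"override node {node} matches no column in the score matrix",
                stacklevel=2,
            )

    def covered(node: int, node_set: frozenset[int]) -> bool:
        if node in node_set:
            return True
        if config.retain_subtrees and tree is not None and node in tree:
            return any(a in tree and tree.is_ancestor(a, node) for a in node_set)
        return False

    hist_filtered = np.zeros(N_BINS, dtype=np.int64)
    rows = []
    for node in matrix.node_ids:
        col = matrix.counts[:, matrix.column(node)]
        if covered(node, config.retained_nodes):
            filt = np.zeros(N_BINS, dtype=np.int64)
        elif covered(node, config.filtered_nodes):
            filt = col.copy()
        else:
            filt = np.zeros(N_BINS, dtype=np.int64)
            filt[tb:] = col[tb:]
        hist_filtered += filt
        n_filt = int(filt.sum())
        rows.append(
            {
                "node_id": node,
                "name": tree.name(node) if tree is not None and node in tree else "",
                "reads": int(col.sum()),
                "reads_filtered": n_filt,
                "filtered": bool(n_filt > 0),
            }
        )
    node_table = pd.DataFrame(
        rows, columns=["node_id", "name", "reads", "reads_filtered", "filtered"]
    )

    hist_total = matrix.counts.sum(axis=1)
    hist_retained = hist_total - hist_filtered
    total = matrix.total
    n_filtered = int(hist_filtered.sum())
    pct_contam = 100.0 * n_filtered / total if total else 0.0
    return Summary(
        total_reads=total,
        pct_contaminated=pct_contam,
        pct_retained=100.0 - pct_contam if total else 100.0,
        threshold=config.threshold,
        node_table=node_table,
        histogram_retained=[int(x) for x in hist_retained],
        histogram_filtered=[int(x) for x in hist_filtered],
    )


def render_report(
    summary: Summary, out_dir: str | Path, plots: bool = False
) -> dict[str, Path]:
    """Write ``report.json`` and ``nodes.tsv`` (plus optional PNG charts).

    Returns a name -> path map of everything written. The JSON is the data
    contract: re-parsing it reproduces the :class:`Summary` exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    report_path = out_dir / "report.json"
    report_path.write_text(
        json.dumps(summary.to_dict(), indent=2) + "\n", encoding="utf-8"
    )
    written["report"] = report_path

    nodes_path = out_dir / "nodes.tsv"
    summary.node_table.to_csv(nodes_path, sep="\t", index=False)
    written["nodes"] = nodes_path

    if plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        ax.pie(
            [summary.pct_contaminated, summary.pct_retained],
            labels=["contaminated", "retained"],
            colors=["tab:orange", "tab:blue"],
            autopct="%.1f%%",
        )
        ax.set_title("Reads filtered vs retained")
        pie_path = out_dir / "pie.png"
        fig.savefig(pie_path, dpi=100)
        plt.close(fig)
        written["pie"] = pie_path

        fig, ax = plt.subplots(figsize=(7, 4))
        bins = np.arange(N_BINS) / 100.0
        ax.bar(bins, summary.histogram_retained, width=0.009, color="tab:blue",
               label="retained")
        ax.bar(bins, summary.histogram_filtered, width=0.009, color="tab:orange",
               bottom=summary.histogram_retained, label="filtered")
        ax.axvline(summary.threshold, color="red", label="threshold")
        ax.set_xlabel("read-contamination score")
        ax.set_ylabel("reads")
        ax.legend()
        hist_path = out_dir / "histogram.png"
        fig.savefig(hist_path, dpi=100)
        plt.close(fig)
        written["histogram"] = hist_path

    return written
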