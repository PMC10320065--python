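"""Rooted taxonomy trees with ancestor and lowest-common-ancestor queries.

The taxonomy is the backbone of k-mer classification: a k-mer present in
several reference genomes is assigned to the most recent common ancestor
(LCA/MRCA) of the genomes' taxonomy nodes, so every downstream score depends
on exact ancestor queries over this tree.

Two on-disk dialects are supported:

* NCBI ``nodes.dmp`` / ``names.dmp`` (fields separated by ``\\t|\\t``), where
  the root is the node whose parent is itself (taxid 1 by convention);
* a plain parent-table TSV with 2-4 columns
  ``node_id<TAB>parent_id[<TAB>rank[<TAB>name]]``, ``#`` comments and an
  optional header. A single top node whose parent id is absent from the table
  is promoted to a self-parenting root.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .errors import TaxonomyError

__all__ = ["TaxNode", "TaxonomyTree", "parse_taxonomy"]


@dataclass(frozen=True)
class TaxNode:
    """One taxonomy node: an integer id, its parent, and optional metadata."""

    node_id: int
    parent_id: int
    rank: str = ""
    name: str = ""


class TaxonomyTree:
    """A validated rooted tree of :class:`TaxNode`.

    Construction checks the structural invariants once (unique ids, exactly
    one self-parenting root, all parent ids resolvable, no cycles) and
    precomputes node depths, so ``lca`` and ``is_ancestor`` are simple
    depth-guided parent walks.
    """

    def __init__(self, nodes: Iterable[TaxNode]):
        self._nodes: dict[int, TaxNode] = {}
        for node in nodes:
            if node.node_id in self._nodes:
                raise TaxonomyError(f"duplicate node_id {node.node_id}")
            self._nodes[node.node_id] = node
        if not self._nodes:
            raise TaxonomyError("taxonomy has no nodes")

        roots = [n.node_id for n in self._nodes.values() if n.parent_id == n.node_id]
        if len(roots) != 1:
            raise TaxonomyError(
                f"expected exactly one self-parenting root, found {sorted(roots)}"
            )
        self.root_id: int = roots[0]

        for node in self._nodes.values():
            if node.parent_id not in self._nodes:
                raise TaxonomyError(
                    f"node {node.node_id} has dangling parent_id {node.parent_id}"
                )

        # Depth computation doubles as cycle detection: a parent chain that
        # does not reach the root within len(nodes) steps must loop.
        self._depth: dict[int, int] = {self.root_id: 0}
        limit = len(self._nodes)
        for node_id in self._nodes:
            chain = []
            cur = node_id
            while cur not in self._depth:
                chain.append(cur)
                cur = self._nodes[cur].parent_id
                if len(chain) > limit:
                    raise TaxonomyError(f"cycle detected involving node {node_id}")
            base = self._depth[cur]
            for offset, nid in enumerate(reversed(chain), start=1):
                self._depth[nid] = base + offset

    # -- basic container protocol ------------------------------------------

    def __contains__(self, node_id: int) -> bool:
        return node_id in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def __iter__(self) -> Iterator[int]:
        return iter(self._nodes)

    def node(self, node_id: int) -> TaxNode:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise TaxonomyError(f"unknown taxonomy node {node_id}") from None

    def name(self, node_id: int) -> str:
        return self.node(node_id).name

    def depth(self, node_id: int) -> int:
        """Number of edges from *node_id* up to the root."""
        if node_id not in self._depth:
            raise TaxonomyError(f"unknown taxonomy node {node_id}")
        return self._depth[node_id]

    def parent(self, node_id: int) -> int:
        return self.node(node_id).parent_id

    def path_to_root(self, node_id: int) -> list[int]:
        """Nodes from *node_id* (inclusive) up to and including the root."""
        path = [node_id]
        cur = self.node(node_id)
        while cur.node_id != self.root_id:
            cur = self.node(cur.parent_id)
            path.append(cur.node_id)
        return path

    # -- queries ------------------------------------------------------------

    def lca(self, node_ids: Iterable[int]) -> int:
        """Lowest common ancestor of a non-empty set of nodes.

        Pairwise LCA is folded over the set; the pairwise step lifts the
        deeper node to equal depth and then walks both chains up in lockstep.
        """
        ids = list(node_ids)
        if not ids:
            raise TaxonomyError("lca of an empty node set is undefined")
        result = ids[0]
        _ = self.depth(result)
        for other in ids[1:]:
            result = self._lca_pair(result, other)
        return result

    def _lca_pair(self, a: int, b: int) -> int:
        da, db = self.depth(a), self.depth(b)
        while da > db:
            a = self._nodes[a].parent_id
            da -= 1
        while db > da:
            b = self._nodes[b].parent_id
            db -= 1
        while a != b:
            a = self._nodes[a].parent_id
            b = self._nodes[b].parent_id
        return a

    def is_ancestor(self, a: int, b: int) -> bool:
        """True iff *a* is *b* itself or lies on *b*'s chain to the root."""
        da, db = self.depth(a), self.depth(b)
        if da > db:
            return False
        while db > da:
            b = self._nodes[b].parent_id
            db -= 1
        return a == b

    # -- persistence ---------------------------------------------------------

    def fingerprint(self) -> str:
        """SHA-256 over the sorted (node_id, parent_id) edge list.

        Binds a k-mer index to the taxonomy it was built against; names and
        ranks are display metadata and deliberately excluded.
        """
        h = hashlib.sha256()
        for node_id in sorted(self._nodes):
            h.update(f"{node_id}\t{self._nodes[node_id].parent_id}\n".encode())
        return h.hexdigest()

    def to_parent_tsv(self, path: str | Path) -> None:
        """Serialize as the 4-column parent-table dialect."""
        with open(path, "w", encoding="utf-8") as handle:
            handle.write("#node_id\tparent_id\trank\tname\n")
            for node_id in sorted(self._nodes):
                n = self._nodes[node_id]
                handle.write(f"{n.node_id}\t{n.parent_id}\t{n.rank}\t{n.name}\n")


def _parse_parent_tsv(lines: Iterable[str]) -> TaxonomyTree:
    rows: list[tuple[int, int, str, str]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise TaxonomyError(f"line {lineno}: expected >=2 tab-separated columns")
        try:
            node_id = int(fields[0])
        except ValueError:
            if not rows:  # optional header row
                continue
            raise TaxonomyError(f"line {lineno}: non-integer node_id {fields[0]!r}")
        try:
            parent_id = int(fields[1])
        except ValueError:
            raise TaxonomyError(f"line {lineno}: non-integer parent_id {fields[1]!r}")
        rank = fields[2].strip() if len(fields) > 2 else ""
        name = fields[3].strip() if len(fields) > 3 else ""
        rows.append((node_id, parent_id, rank, name))
    if not rows:
        raise TaxonomyError("empty taxonomy file")

    ids = {r[0] for r in rows}
    has_root = any(nid == pid for nid, pid, _, _ in rows)
    if not has_root:
        orphans = [nid for nid, pid, _, _ in rows if pid not in ids]
        if len(orphans) == 1:
            rows = [
                (nid, nid if nid == orphans[0] else pid, rank, name)
                for nid, pid, rank, name in rows
            ]
        # otherwise fall through: TaxonomyTree reports the structural problem
    return TaxonomyTree(TaxNode(*row) for row in rows)


def _parse_nodes_dmp(lines: Iterable[str]) -> list[TaxNode]:
    nodes = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n").rstrip()
        if not line:
            continue
        if line.endswith("|"):
            line = line[:-1].rstrip("\t")
        fields = [f.strip() for f in line.split("\t|\t")]
        if len(fields) < 2:
            raise TaxonomyError(f"nodes.dmp line {lineno}: too few fields")
        try:
            node_id, parent_id = int(fields[0]), int(fields[1])
        except ValueError:
            raise TaxonomyError(f"nodes.dmp line {lineno}: non-integer taxid")
        rank = fields[2] if len(fields) > 2 else ""
        nodes.append(TaxNode(node_id, parent_id, rank=rank))
    if not nodes:
        raise TaxonomyError("empty taxonomy file")
    return nodes


def _parse_names_dmp(lines: Iterable[str]) -> dict[int, str]:
    names: dict[int, str] = {}
    for raw in lines:
        line = raw.rstrip("\n").rstrip()
        if not line:
            continue
        if line.endswith("|"):
            line = line[:-1].rstrip("\t")
        fields = [f.strip() for f in line.split("\t|\t")]
        if len(fields) >= 4 and fields[3] == "scientific name":
            names[int(fields[0])] = fields[1]
    return names


def _sniff_dialect(sample: str) -> str:
    return "ncbi-dmp" if "\t|\t" in sample else "parent-tsv"


def parse_taxonomy(
    source: str | Path | io.TextIOBase,
    names: str | Path | None = None,
    dialect: str = "auto",
) -> TaxonomyTree:
    """Parse a taxonomy file into a :class:`TaxonomyTree`.

    Parameters
    ----------
    source:
        Path to ``nodes.dmp`` or a parent-table TSV (or an open text handle).
    names:
        Optional ``names.dmp`` path; only ``scientific name`` rows are used.
        Ignored for the TSV dialect (names live in column 4 there).
    dialect:
        ``"ncbi-dmp"``, ``"parent-tsv"``, or ``"auto"`` (sniffed from the
        first kilobyte: the NCBI dialect uses ``\\t|\\t`` separators).
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    if not text.strip():
        raise TaxonomyError("empty taxonomy file")
    if dialect == "auto":
        dialect = _sniff_dialect(text[:1024])

    if dialect == "parent-tsv":
        return _parse_parent_tsv(text.splitlines())
    if dialect != "ncbi-dmp":
        raise TaxonomyError(f"unknown taxonomy dialect {dialect!r}")

    nodes = _parse_nodes_dmp(text.splitlines())
    name_map: Mapping[int, str] = {}
    if names is not None:
        name_map = _parse_names_dmp(Path(names).read_text(encoding="utf-8").splitlines())
    if name_map:
        nodes = [
            TaxNode(n.node_id, n.parent_id, n.rank, name_map.get(n.node_id, ""))
            for n in nodes
        ]
    return TaxonomyTree(nodes)
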