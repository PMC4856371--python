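"""Serialisation of tree sequences and mutations.

Four formats are supported:

* a tab-delimited text format, one coalescence record per line
  (``left right node child1 child2 time``), with shortest round-trip
  float rendering so that read(write(T)) == T exactly;
* a structured HDF5 container holding the record columns, metadata and
  (optionally) mutations, with optional zlib compression;
* Newick export of individual marginal trees.  Newick stores branch
  lengths rather than node times, so it is the only precision-bounded
  (lossy) path;
* ms-style replicate text (``//`` separators, ``[span]newick`` tree
  lines, ``segsites:`` / ``positions:`` / 0-1 haplotype blocks).
"""

from __future__ import annotations

from typing import Sequence

import h5py
import numpy as np

from .mutations import Mutation, haplotypes, node_times
from .traversal import iterate_trees
from .trees import (
    CoalescenceRecord,
    SparseTree,
    TreeSequence,
    make_tree_sequence,
)

__all__ = [
    "TextParseError",
    "ContainerFormatError",
    "CONTAINER_FORMAT_VERSION",
    "write_text",
    "read_text",
    "write_container",
    "read_container",
    "tree_to_newick",
    "write_ms_style",
]

CONTAINER_FORMAT_VERSION = "1.0"


class TextParseError(ValueError):
    """Malformed record text; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class ContainerFormatError(ValueError):
    """HDF5 container is missing columns or has an unsupported version."""


def _open(sink, mode):
    if hasattr(sink, "read") or hasattr(sink, "write"):
        return sink, False
    return open(sink, mode), True


def write_text(ts: TreeSequence, sink) -> None:
    """Write one tab-separated line per record.

    Times use ``repr`` (shortest round-trip) rendering, so the text
    round-trip is bit-exact.
    """
    f, close = _open(sink, "w")
    try:
        for rec in ts.records():
            children = "\t".join(str(c) for c in rec.children)
            f.write(f"{rec.left}\t{rec.right}\t{rec.node}\t{children}\t{rec.time!r}\n")
    finally:
        if close:
            f.close()


def read_text(source, n: int | None = None, m: int | None = None) -> TreeSequence:
    """Read a tab-delimited record table back into a tree sequence.

    If not given, ``m`` is the largest right coordinate and ``n`` is one
    less than the smallest parent label (exact for simulator output,
    where internal labels start at ``n + 1``).
    """
    f, close = _open(source, "r")
    try:
        records = []
        for lineno, line in enumerate(f, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise TextParseError(
                    f"expected >= 6 tab-separated fields, got {len(fields)}", lineno
                )
            try:
                left, right, node = (int(v) for v in fields[:3])
                children = tuple(int(v) for v in fields[3:-1])
                time = float(fields[-1])
            except ValueError as err:
                raise TextParseError(str(err), lineno) from None
            records.append(CoalescenceRecord(left, right, node, children, time))
    finally:
        if close:
            f.close()
    if not records:
        raise TextParseError("no records found", 0)
    if m is None:
        m = max(rec.right for rec in records)
    if n is None:
        n = min(rec.node for rec in records) - 1
    return make_tree_sequence(records, n, m)


def write_container(
    ts: TreeSequence,
    path,
    mutations: Sequence[Mutation] | None = None,
    *,
    compress: bool = False,
) -> None:
    """Write the tree sequence (and optional mutations) to an HDF5 file.

    Layout: ``/metadata`` attributes ``n``, ``m``, ``format_version``;
    ``/records`` datasets ``left``, ``right`` (uint32), ``node``,
    ``children`` (M x k uint32), ``time`` (float64); optional
    ``/mutations`` datasets ``node`` (uint32), ``position`` (float64).
    """
    kwargs = {"compression": "gzip"} if compress else {}
    arity = max((len(c) for c in ts.children), default=2)
    children = np.zeros((ts.M, arity), dtype=np.uint32)
    for j, c in enumerate(ts.children):
        children[j, : len(c)] = c
    with h5py.File(path, "w") as root:
        meta = root.create_group("metadata")
        meta.attrs["n"] = ts.n
        meta.attrs["m"] = ts.m
        meta.attrs["format_version"] = CONTAINER_FORMAT_VERSION
        rec = root.create_group("records")
        rec.create_dataset("left", data=ts.left.astype(np.uint32), **kwargs)
        rec.create_dataset("right", data=ts.right.astype(np.uint32), **kwargs)
        rec.create_dataset("node", data=ts.node.astype(np.uint32), **kwargs)
        rec.create_dataset("children", data=children, **kwargs)
        rec.create_dataset("time", data=ts.time, **kwargs)
        if mutations is not None:
            grp = root.create_group("mutations")
            grp.create_dataset(
                "node",
                data=np.array([mu.node for mu in mutations], dtype=np.uint32),
                **kwargs,
            )
            grp.create_dataset(
                "position",
                data=np.array([mu.position for mu in mutations], dtype=np.float64),
                **kwargs,
            )


def read_container(path):
    """Read an HDF5 container back; returns ``(tree_sequence, mutations)``
    where ``mutations`` is ``None`` if the file stores none."""
    with h5py.File(path, "r") as root:
        if "metadata" not in root or "records" not in root:
            raise ContainerFormatError("missing /metadata or /records group")
        meta = root["metadata"]
        version = meta.attrs.get("format_version")
        if version != CONTAINER_FORMAT_VERSION:
            raise ContainerFormatError(
                f"unsupported format version {version!r}; "
                f"expected {CONTAINER_FORMAT_VERSION!r}"
            )
        n = int(meta.attrs["n"])
        m = int(meta.attrs["m"])
        rec = root["records"]
        for col in ("left", "right", "node", "children", "time"):
            if col not in rec:
                raise ContainerFormatError(f"missing /records/{col} column")
        left = rec["left"][:].astype(np.int64)
        right = rec["right"][:].astype(np.int64)
        node = rec["node"][:].astype(np.int64)
        children = rec["children"][:].astype(np.int64)
        time = rec["time"][:]
        records = [
            CoalescenceRecord(
                int(left[j]),
                int(right[j]),
                int(node[j]),
                tuple(int(c) for c in children[j] if c != 0),
                float(time[j]),
            )
            for j in range(len(left))
        ]
        mutations = None
        if "mutations" in root:
            grp = root["mutations"]
            mutations = [
                Mutation(int(u), float(p))
                for u, p in zip(grp["node"][:], grp["position"][:])
            ]
    return make_tree_sequence(records, n, m), mutations


def tree_to_newick(
    tree: SparseTree, times=None, precision: int = 6
) -> str:
    """Render a marginal tree in Newick form.

    Leaf labels are the sample labels ``1..n``; branch lengths are
    ``time(parent) - time(child)`` printed with ``precision`` decimal
    digits; children appear in increasing label order.
    """
    if times is None:
        times = tree.node_times
    if times is None:
        raise ValueError("node times are required for Newick export")
    cmap = tree.children_map()
    root = tree.root()

    def render(u: int) -> str:
        kids = cmap.get(u)
        if kids:
            inner = ",".join(
                f"{render(c)}:{times[int(tree.parent[c])] - times[c]:.{precision}f}"
                for c in sorted(kids)
            )
            return f"({inner})"
        return str(u)

    return render(root) + ";"


def write_ms_style(
    replicates, sink, *, trees: bool = False, precision: int = 6
) -> None:
    """Write replicates in ms-style text.

    ``replicates`` is an iterable of ``(tree_sequence, mutations)``
    pairs; pass ``mutations=None`` for genealogy-only output.  Each
    replicate starts with ``//``; with ``trees=True`` every marginal tree
    is written as ``[span]newick``; mutations produce the ``segsites:`` /
    ``positions:`` / haplotype-row block, with positions scaled to
    ``[0, 1)``.
    """
    f, close = _open(sink, "w")
    try:
        for ts, mutations in replicates:
            f.write("//\n")
            if trees:
                times = node_times(ts)
                for (x1, x2), tree in iterate_trees(ts):
                    newick = tree_to_newick(tree, times, precision=precision)
                    f.write(f"[{x2 - x1}]{newick}\n")
            if mutations is not None:
                haps = haplotypes(ts, mutations)
                f.write(f"segsites: {len(haps.mutations)}\n")
                if len(haps.mutations):
                    positions = " ".join(
                        f"{mu.position / ts.m:.6f}" for mu in haps.mutations
                    )
                    f.write(f"positions: {positions}\n")
                    for row in haps.as_strings():
                        f.write(row + "\n")
    finally:
        if close:
            f.close()
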