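"""Alignment and tree I/O plus site-pattern compression.

Alignments are read from FASTA (via Biopython) or NEXUS (via dendropy) into a
plain :class:`Alignment` of IUPAC nucleotide strings, encoded to 4-bit state
masks (A=1, C=2, G=4, T=8; ambiguity codes are unions; gaps and ``?`` are fully
ambiguous), and compressed to unique site patterns with multiplicities.  All
downstream likelihood machinery operates on the compressed patterns: the
likelihood of a pattern is computed once and weighted by its column count.

Trees travel as newick text; parsing goes through dendropy, serialisation is a
direct recursive write of the internal tree structure.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np

from . import tree as _tree

__all__ = [
    "Alignment",
    "CompressedAlignment",
    "AlignmentFormatError",
    "IUPAC_MASKS",
    "read_alignment",
    "parse_alignment_text",
    "write_fasta",
    "write_nexus",
    "encode_states",
    "compress_patterns",
    "read_newick",
    "write_newick",
]


class AlignmentFormatError(ValueError):
    """Raised when an input alignment violates the format contract."""


#: 4-bit state masks. Bit 0=A, 1=C, 2=G, 3=T; ambiguity codes are bit unions,
#: gap characters and '?' are treated as fully ambiguous (mask 15).
IUPAC_MASKS = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15, "X": 15, "-": 15, "?": 15,
}


@dataclass
class Alignment:
    """A rectangular nucleotide alignment over IUPAC codes, gaps and '?'."""

    taxon_labels: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxon_labels) != len(self.rows):
            raise AlignmentFormatError("label/row count mismatch")
        if len(set(self.taxon_labels)) != len(self.taxon_labels):
            dupes = sorted({t for t in self.taxon_labels if self.taxon_labels.count(t) > 1})
            raise AlignmentFormatError(f"duplicate taxon labels: {dupes}")
        if not self.rows:
            raise AlignmentFormatError("empty alignment")
        self.rows = [r.upper() for r in self.rows]
        ncol = len(self.rows[0])
        for label, row in zip(self.taxon_labels, self.rows):
            if len(row) != ncol:
                raise AlignmentFormatError(
                    f"ragged alignment: taxon {label!r} has {len(row)} columns, expected {ncol}"
                )
            for j, ch in enumerate(row):
                if ch not in IUPAC_MASKS:
                    raise AlignmentFormatError(
                        f"illegal character {ch!r} at taxon {label!r}, column {j + 1}"
                    )

    @property
    def n_taxa(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])


@dataclass
class CompressedAlignment:
    """Unique site patterns with column multiplicities.

    ``patterns`` is a (n_taxa, L) uint8 matrix of 4-bit state masks, one column
    per unique site pattern in first-occurrence order; ``weights[z]`` counts how
    many original columns collapse onto pattern z; ``column_pattern`` maps each
    original column back to its pattern index, so compression is invertible.
    """

    taxon_labels: list[str]
    patterns: np.ndarray
    weights: np.ndarray
    column_pattern: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=np.uint8)
        self.weights = np.asarray(self.weights, dtype=np.int64)
        if self.patterns.ndim != 2:
            raise ValueError("patterns must be 2-D (taxa x unique sites)")
        if np.any(self.weights < 1):
            raise ValueError("pattern weights must be >= 1")
        if self.patterns.shape[1] != self.weights.shape[0]:
            raise ValueError("weights length must equal number of patterns")

    @property
    def n_taxa(self) -> int:
        return self.patterns.shape[0]

    @property
    def L(self) -> int:
        """Number of unique site patterns (the computational sequence length)."""
        return self.patterns.shape[1]

    @property
    def n_columns(self) -> int:
        return int(self.weights.sum())

    def decompress(self) -> np.ndarray:
        """Reconstruct the original encoded matrix, column for column."""
        return self.patterns[:, self.column_pattern]


def encode_states(alignment: Alignment) -> np.ndarray:
    """Encode an alignment to a (n_taxa, n_columns) uint8 matrix of 4-bit masks."""
    lut = np.zeros(128, dtype=np.uint8)
    for ch, mask in IUPAC_MASKS.items():
        lut[ord(ch)] = mask
    out = np.empty((alignment.n_taxa, alignment.n_columns), dtype=np.uint8)
    for i, row in enumerate(alignment.rows):
        out[i] = lut[np.frombuffer(row.encode("ascii"), dtype=np.uint8)]
    return out


def compress_patterns(encoded: np.ndarray, taxon_labels: list[str] | None = None) -> CompressedAlignment:
    """Collapse identical columns to unique site patterns with weights.

    Pattern order is first occurrence in the alignment, which keeps sampling
    traces reproducible across runs.
    """
    encoded = np.asarray(encoded, dtype=np.uint8)
    if encoded.ndim != 2 or encoded.size == 0:
        raise ValueError("encoded matrix must be non-empty and 2-D")
    cols = encoded.T
    _, first_idx, inverse, counts = np.unique(
        cols, axis=0, return_index=True, return_inverse=True, return_counts=True
    )
    inverse = inverse.reshape(-1)
    # np.unique sorts lexicographically; reorder to first-occurrence order.
    order = np.argsort(first_idx, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    column_pattern = rank[inverse]
    patterns = encoded[:, first_idx[order]]
    weights = counts[order]
    if taxon_labels is None:
        taxon_labels = [f"t{i}" for i in range(encoded.shape[0])]
    return CompressedAlignment(list(taxon_labels), patterns, weights, column_pattern)


def compress_alignment(alignment: Alignment) -> CompressedAlignment:
    """Encode and pattern-compress in one step."""
    return compress_patterns(encode_states(alignment), alignment.taxon_labels)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_fasta(text: str) -> Alignment:
    from Bio import SeqIO

    labels: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        labels.append(rec.id)
        rows.append(str(rec.seq))
    if not labels:
        raise AlignmentFormatError("no FASTA records found")
    return Alignment(labels, rows)


def _read_nexus(text: str) -> Alignment:
    import dendropy

    try:
        mat = dendropy.DnaCharacterMatrix.get(data=text, schema="nexus")
    except Exception as exc:  # dendropy raises assorted error types
        raise AlignmentFormatError(f"NEXUS parse failure: {exc}") from exc
    labels = [t.label for t in mat.taxon_namespace]
    rows = [str(mat[t]) for t in mat.taxon_namespace]
    return Alignment(labels, rows)


def read_alignment(path: str, format: str | None = None) -> Alignment:
    """Read an alignment file in ``nexus`` or ``fasta`` format.

    If ``format`` is omitted it is sniffed: NEXUS files start with ``#NEXUS``.
    """
    with open(path) as fh:
        text = fh.read()
    return parse_alignment_text(text, format)


def parse_alignment_text(text: str, format: str | None = None) -> Alignment:
    if format is None:
        format = "nexus" if text.lstrip()[:6].upper() == "#NEXUS" else "fasta"
    format = format.lower()
    if format == "fasta":
        return _read_fasta(text)
    if format == "nexus":
        return _read_nexus(text)
    raise AlignmentFormatError(f"unknown alignment format {format!r}")


def write_fasta(alignment: Alignment, path: str) -> None:
    with open(path, "w") as fh:
        for label, row in zip(alignment.taxon_labels, alignment.rows):
            fh.write(f">{label}\n{row}\n")


def write_nexus(alignment: Alignment, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#NEXUS\nbegin data;\n")
        fh.write(f"  dimensions ntax={alignment.n_taxa} nchar={alignment.n_columns};\n")
        fh.write("  format datatype=dna gap=- missing=?;\n  matrix\n")
        width = max(len(t) for t in alignment.taxon_labels) + 2
        for label, row in zip(alignment.taxon_labels, alignment.rows):
            safe = label if " " not in label else f"'{label}'"
            fh.write(f"    {safe:<{width}}{row}\n")
        fh.write("  ;\nend;\n")


# ---------------------------------------------------------------------------
# newick
# ---------------------------------------------------------------------------

def read_newick(source: str, is_path: bool = False) -> "_tree.PhyloTree":
    """Parse newick text (or a file when ``is_path``) into a PhyloTree.

    Rooted (binary root) and unrooted (trifurcating root) shapes are both kept
    as written; branch lengths default to 0.0 where absent.
    """
    import dendropy

    kwargs = {"path": source} if is_path else {"data": source}
    try:
        dtree = dendropy.Tree.get(schema="newick", suppress_internal_node_taxa=True, **kwargs)
    except Exception as exc:
        raise ValueError(f"newick parse failure: {exc}") from exc

    def convert(dnode) -> _tree.Node:
        node = _tree.Node()
        node.length = float(dnode.edge.length) if dnode.edge.length is not None else 0.0
        if dnode.is_leaf():
            if dnode.taxon is None or not dnode.taxon.label:
                raise ValueError("leaf without a label in newick input")
            node.label = dnode.taxon.label
        else:
            for ch in dnode.child_nodes():
                child = convert(ch)
                child.parent = node
                node.children.append(child)
        return node

    root = convert(dtree.seed_node)
    return _tree.PhyloTree.from_root(root)


def _format_length(x: float) -> str:
    return repr(float(x))


def write_newick(tree: "_tree.PhyloTree", include_lengths: bool = True) -> str:
    """Serialise a PhyloTree to newick text (round-trip stable)."""

    def fmt(node: "_tree.Node") -> str:
        if node.is_leaf:
            base = _quote(tree.taxon_labels[node.taxon])
        else:
            base = "(" + ",".join(fmt(c) for c in node.children) + ")"
        if include_lengths and node.parent is not None:
            base += f":{_format_length(node.length)}"
        return base

    return fmt(tree.root) + ";"


def _quote(label: str) -> str:
    if any(ch in label for ch in " ()[]{}:;,'\""):
        return "'" + label.replace("'", "''") + "'"
    return label
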