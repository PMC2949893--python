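"""Readers and writers for the formats the aligner touches.

Formats: multi-FASTA (sequences in, gapped alignments out), newick trees
whose branch lengths are proximities or distances, a TSV of aligned
nucleotide pairs for benchmarking, plain-text background-frequency files and
4x4 transition-rate files.  Nucleotide order is A, C, G, T in all matrix
files.  All writers are deterministic: identical inputs give byte-identical
output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
from Bio import SeqIO

from .evo_model import FunctionalModel, ModelError
from .progressive import GlobalAlignment
from .tree_likelihood import PhyloTree, TreeNode

__all__ = [
    "FormatError",
    "SequenceRecord",
    "read_fasta",
    "write_fasta",
    "write_alignment",
    "read_alignment_fasta",
    "read_pairs_tsv",
    "write_pairs_tsv",
    "read_newick",
    "write_newick",
    "read_background",
    "read_transition_matrix",
]

logger = logging.getLogger("sigma2")

#: default proximity for newick branches with no length (the star value)
DEFAULT_PROXIMITY = 0.33

_IUPAC_TO_N = set("RYSWKMBDHV")


class FormatError(ValueError):
    pass


@dataclass
class SequenceRecord:
    id: str
    description: str
    residues: str


def _normalise(seq: str, origin: str) -> Tuple[str, int]:
    seq = seq.upper().replace("U", "T")
    mapped = 0
    out = []
    for ch in seq:
        if ch in "ACGTN":
            out.append(ch)
        elif ch in _IUPAC_TO_N:
            out.append("N")
            mapped += 1
        else:
            raise FormatError(f"{origin}: invalid residue {ch!r}")
    return "".join(out), mapped


def read_fasta(path) -> List[SequenceRecord]:
    """Read a multi-FASTA of DNA sequences with normalisation.

    Lowercase is uppercased, U becomes T, other IUPAC ambiguity codes become
    N (with a logged count).  Duplicate ids, empty files and
    non-nucleotide-majority content are format errors.
    """
    records = []
    seen = set()
    mapped_total = 0
    for k, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r} "
                              f"(record {k})")
        seen.add(rec.id)
        raw = str(rec.seq)
        if not raw:
            raise FormatError(f"{path}: record {rec.id!r} is empty")
        acgt = sum(raw.upper().count(c) for c in "ACGTNU")
        if acgt * 2 < len(raw):
            raise FormatError(
                f"{path}: record {rec.id!r} does not look like nucleotide "
                f"sequence (record {k})"
            )
        residues, mapped = _normalise(raw, f"{path} record {rec.id!r}")
        mapped_total += mapped
        records.append(SequenceRecord(rec.id, rec.description, residues))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    if mapped_total:
        logger.warning("%s: mapped %d ambiguity codes to N", path, mapped_total)
    return records


def write_fasta(rows: Dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for sid, seq in rows.items():
            fh.write(f">{sid}\n")
            for k in range(0, len(seq), width):
                fh.write(seq[k : k + width] + "\n")


def read_alignment_fasta(path) -> GlobalAlignment:
    """Read a gapped FASTA back into a :class:`GlobalAlignment`."""
    rows = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        rows[rec.id] = str(rec.seq).upper()
    if not rows:
        raise FormatError(f"{path}: no FASTA records found")
    lengths = {len(s) for s in rows.values()}
    if len(lengths) != 1:
        raise FormatError(f"{path}: alignment rows differ in length")
    seq_ids = list(rows)
    columns = []
    pos = {sid: 0 for sid in seq_ids}
    for k in range(lengths.pop()):
        col = {}
        for sid in seq_ids:
            ch = rows[sid][k]
            if ch != "-":
                col[sid] = pos[sid]
                pos[sid] += 1
        columns.append(col)
    return GlobalAlignment(seq_ids, rows, columns)


def write_pairs_tsv(alignment: GlobalAlignment, path) -> None:
    """Aligned nucleotide pairs, one per line, 0-based, lexicographically sorted."""
    pairs = sorted(alignment.aligned_pairs())
    with open(path, "w") as fh:
        fh.write("seq_id1\tpos1\tseq_id2\tpos2\n")
        for a, pa, b, pb in pairs:
            fh.write(f"{a}\t{pa}\t{b}\t{pb}\n")


def read_pairs_tsv(path) -> set:
    pairs = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("seq_id1"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 tab-separated "
                                  f"fields, got {len(parts)}")
            a, pa, b, pb = parts[0], int(parts[1]), parts[2], int(parts[3])
            if (a, pa) > (b, pb):
                a, pa, b, pb = b, pb, a, pa
            pairs.add((a, pa, b, pb))
    return pairs


def write_alignment(alignment: GlobalAlignment, path, format: str = "fasta") -> None:
    if format == "fasta":
        write_fasta(alignment.rows, path)
    elif format == "pairs_tsv":
        write_pairs_tsv(alignment, path)
    else:
        raise ValueError(f"unknown alignment format {format!r}")


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------


def read_newick(path, branch_units: str = "proximity", prior=None) -> PhyloTree:
    """Read a newick tree whose branch lengths are proximities or distances.

    With ``branch_units="proximity"`` lengths are used directly as
    proximities ``q``; with ``"distance"`` they are converted ``q = e**-d``.
    Branches without a length get the star default (0.33) with a warning.
    """
    import dendropy

    if branch_units not in ("proximity", "distance"):
        raise ValueError("branch_units must be 'proximity' or 'distance'")
    dt = dendropy.Tree.get(path=str(path), schema="newick")
    missing = 0

    def convert(node) -> TreeNode:
        nonlocal missing
        length = node.edge.length
        if length is None:
            q = DEFAULT_PROXIMITY
            missing += 1
        elif branch_units == "distance":
            if length < 0:
                raise FormatError(f"{path}: negative branch distance {length}")
            q = float(np.exp(-length))
        else:
            q = float(length)
        if not 0.0 < q <= 1.0:
            raise FormatError(
                f"{path}: branch proximity {q} outside (0, 1] "
                f"(use --branch-units=distance for distance trees)"
            )
        name = node.taxon.label if node.taxon is not None else None
        return TreeNode(name, q, [convert(c) for c in node.child_nodes()])

    root = dt.seed_node
    children = [convert(c) for c in root.child_nodes()]
    if not children:
        raise FormatError(f"{path}: tree has no branches")
    tree = PhyloTree(TreeNode(None, None, children), prior)
    if missing:
        logger.warning(
            "%s: %d branches had no length; using default proximity %.2f",
            path,
            missing,
            DEFAULT_PROXIMITY,
        )
    return tree


def write_newick(tree: PhyloTree, path) -> None:
    """Write a tree with proximities as branch lengths."""

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            body = node.name
        else:
            body = "(" + ",".join(render(c) for c in node.children) + ")"
        if node.q is not None:
            body += f":{node.q:.6g}"
        return body

    with open(path, "w") as fh:
        fh.write(render(tree.root) + ";\n")


# ---------------------------------------------------------------------------
# Model parameter files
# ---------------------------------------------------------------------------


def read_background(path) -> FunctionalModel:
    """Background frequency file.

    Either 16 lines ``XY freq`` of dinucleotide frequencies (X = left
    neighbour, Y = nucleotide) or 4 lines ``X freq`` of mononucleotide
    frequencies.  Frequencies are renormalised on load.
    """
    from .evo_model import NUC_INDEX

    entries = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'KEY freq'")
            key, value = parts[0].upper(), parts[1]
            try:
                freq = float(value)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: bad frequency {value!r}")
            if freq < 0:
                raise FormatError(f"{path}:{lineno}: negative frequency")
            if key in entries:
                raise FormatError(f"{path}:{lineno}: duplicate key {key!r}")
            entries[key] = freq
    keys = set(entries)
    if all(len(k) == 2 for k in keys) and len(keys) == 16:
        joint = np.zeros((4, 4))
        for key, freq in entries.items():
            if key[0] not in NUC_INDEX or key[1] not in NUC_INDEX:
                raise FormatError(f"{path}: bad dinucleotide {key!r}")
            joint[NUC_INDEX[key[0]], NUC_INDEX[key[1]]] = freq
        try:
            return FunctionalModel.from_dinucleotide_freqs(joint)
        except ModelError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if all(len(k) == 1 for k in keys) and len(keys) == 4:
        marginal = np.zeros(4)
        for key, freq in entries.items():
            if key not in NUC_INDEX:
                raise FormatError(f"{path}: bad nucleotide {key!r}")
            marginal[NUC_INDEX[key]] = freq
        if marginal.sum() <= 0:
            raise FormatError(f"{path}: frequencies sum to zero")
        return FunctionalModel(marginal / marginal.sum())
    raise FormatError(
        f"{path}: expected 16 dinucleotide lines or 4 mononucleotide lines, "
        f"got {len(keys)}"
    )


def read_transition_matrix(path) -> np.ndarray:
    """4x4 inverse-mutation/transition-rate file.

    Whitespace-separated, row = descendant, column = ancestor; an optional
    ``#ACGT`` header and comment lines are ignored.  The diagonal is ignored
    and columns are renormalised, so rates, probabilities or counts are all
    acceptable.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 numbers per row")
            try:
                rows.append([float(x) for x in parts])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric entry")
    if len(rows) != 4:
        raise FormatError(f"{path}: expected 4 matrix rows, got {len(rows)}")
    M = np.asarray(rows, dtype=float)
    if np.any(M < 0):
        raise FormatError(f"{path}: negative matrix entries")
    np.fill_diagonal(M, 0.0)
    colsums = M.sum(axis=0)
    if np.any(colsums <= 0):
        raise FormatError(f"{path}: a column has no off-diagonal mass")
    return M / colsums
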