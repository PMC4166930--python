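"""Alignment, partition and tree file I/O plus site-pattern compression.

Supported formats: FASTA and relaxed PHYLIP (sequential or interleaved) for
alignments, a RAxML-style partition file dialect (``DNA, name = 1-500`` with
comma-separated ranges and an optional ``\\3`` codon stride), and Newick for
trees (see :mod:`bayestree.tree`).

Characters are encoded as state bitmasks so IUPAC ambiguity codes and
missing data ('-' and '?', treated identically) flow through the likelihood
and parsimony engines without special cases.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio import AlignIO, SeqIO

from .tree import Tree, parse_newick, write_newick  # noqa: F401  (re-export)

__all__ = [
    "Alignment", "PartitionDef", "PartitionPatterns", "PatternMatrix",
    "read_alignment", "read_partitions", "compress_patterns",
    "write_fasta", "write_phylip", "parse_newick", "write_newick",
]

DNA_STATES = "ACGT"
AA_STATES = "ARNDCQEGHILKMFPSTWYV"

_DNA_AMBIG = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", "?": "ACGT", "X": "ACGT",
}
_AA_AMBIG = {aa: aa for aa in AA_STATES}
_AA_AMBIG.update({
    "B": "ND", "Z": "QE", "J": "IL",
    "X": AA_STATES, "-": AA_STATES, "?": AA_STATES, "*": AA_STATES,
})


def _code_table(data_type: str) -> dict[str, int]:
    states = DNA_STATES if data_type == "DNA" else AA_STATES
    ambig = _DNA_AMBIG if data_type == "DNA" else _AA_AMBIG
    table = {}
    for ch, members in ambig.items():
        mask = 0
        for m in members:
            mask |= 1 << states.index(m)
        table[ch] = mask
    return table


DNA_CODES = _code_table("DNA")
AA_CODES = _code_table("AA")


class AlignmentError(ValueError):
    pass


@dataclass
class Alignment:
    """Taxa-by-sites character matrix with unique, ordered taxon names."""

    taxon_names: list[str]
    matrix: np.ndarray            # (n_taxa, n_sites) of single characters, '<U1'
    data_type: str = "DNA"        # default type; partitions may override

    def __post_init__(self):
        if len(set(self.taxon_names)) != len(self.taxon_names):
            dup = sorted({n for n in self.taxon_names if self.taxon_names.count(n) > 1})
            raise AlignmentError(f"duplicate taxon names: {dup}")
        if any(not n for n in self.taxon_names):
            raise AlignmentError("empty taxon name")
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.taxon_names):
            raise AlignmentError("matrix shape does not match taxon count")
        self._validate_alphabet()

    def _validate_alphabet(self):
        table = DNA_CODES if self.data_type == "DNA" else AA_CODES
        for i, name in enumerate(self.taxon_names):
            row = self.matrix[i]
            bad = [j for j in range(row.size) if row[j] not in table]
            if bad:
                raise AlignmentError(
                    f"illegal character {row[bad[0]]!r} for {self.data_type} data "
                    f"in taxon {name!r} at site {bad[0] + 1}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_names)

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]


@dataclass
class PartitionDef:
    """A named, typed set of alignment sites (1-based inclusive ranges on
    input, half-open 0-based column indices internally)."""

    name: str
    data_type: str
    site_ranges: list[tuple[int, int, int]]   # (start, stop, stride), 1-based inclusive

    def columns(self) -> np.ndarray:
        cols: list[int] = []
        for start, stop, stride in self.site_ranges:
            cols.extend(range(start - 1, stop, stride))
        return np.asarray(sorted(cols), dtype=int)

    @property
    def n_sites(self) -> int:
        return self.columns().size


@dataclass
class PartitionPatterns:
    """Compressed site patterns for one partition."""

    name: str
    data_type: str
    codes: np.ndarray        # (n_taxa, n_patterns) uint32 state bitmasks
    weights: np.ndarray      # (n_patterns,) positive ints, sum = n_sites
    n_sites: int

    @property
    def n_states(self) -> int:
        return 4 if self.data_type == "DNA" else 20

    @property
    def n_patterns(self) -> int:
        return self.codes.shape[1]

    def tip_partials(self, taxon: int) -> np.ndarray:
        """(n_patterns, n_states) 0/1 partial-likelihood rows for one taxon."""
        s = self.n_states
        bits = (self.codes[taxon][:, None] >> np.arange(s)[None, :]) & 1
        return bits.astype(float)

    def tip_all_missing(self, taxon: int) -> np.ndarray:
        """Boolean mask of patterns where this taxon is fully missing."""
        full = (1 << self.n_states) - 1
        return self.codes[taxon] == full


@dataclass
class PatternMatrix:
    """Per-partition compressed patterns for a whole alignment."""

    taxon_names: list[str]
    partitions: list[PartitionPatterns] = field(default_factory=list)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_names)

    @property
    def n_sites(self) -> int:
        return sum(p.n_sites for p in self.partitions)


# ------------------------------------------------------------------- readers

def _infer_data_type(rows: Sequence[str]) -> str:
    chars = set()
    for r in rows:
        chars.update(r)
    return "DNA" if chars <= set(DNA_CODES) else "AA"


def _from_records(names: list[str], rows: list[str], data_type: str | None) -> Alignment:
    if not names:
        raise AlignmentError("no sequences found")
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        ref = len(rows[0])
        bad = next(n for n, r in zip(names, rows) if len(r) != ref)
        raise AlignmentError(f"ragged alignment: taxon {bad!r} has length "
                             f"{len(dict(zip(names, rows))[bad])}, expected {ref}")
    rows = [r.upper() for r in rows]
    if data_type is None:
        data_type = _infer_data_type(rows)
    matrix = np.array([list(r) for r in rows], dtype="<U1")
    if data_type == "DNA":
        matrix[matrix == "U"] = "T"
    return Alignment(list(names), matrix, data_type)


def read_alignment(path: str | os.PathLike | io.TextIOBase,
                   format: str = "fasta",
                   data_type: str | None = None) -> Alignment:
    """Read a FASTA or relaxed PHYLIP alignment.

    ``data_type`` is inferred from the characters when not given (DNA if
    every character is a valid nucleotide code, otherwise AA).
    """
    handle = open(path) if not isinstance(path, io.TextIOBase) else path
    try:
        if format == "fasta":
            records = list(SeqIO.parse(handle, "fasta"))
            names = [r.id for r in records]
            rows = [str(r.seq) for r in records]
        elif format == "phylip":
            try:
                aln = AlignIO.read(handle, "phylip-relaxed")
            except ValueError as exc:
                raise AlignmentError(f"cannot parse PHYLIP file: {exc}") from exc
            names = [r.id for r in aln]
            rows = [str(r.seq) for r in aln]
        else:
            raise AlignmentError(f"unknown alignment format {format!r}")
    finally:
        if handle is not path:
            handle.close()
    return _from_records(names, rows, data_type)


def write_fasta(alignment: Alignment, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for i, name in enumerate(alignment.taxon_names):
            fh.write(f">{name}\n")
            fh.write("".join(alignment.matrix[i]) + "\n")


def write_phylip(alignment: Alignment, path: str | os.PathLike) -> None:
    width = max(len(n) for n in alignment.taxon_names) + 2
    with open(path, "w") as fh:
        fh.write(f" {alignment.n_taxa} {alignment.n_sites}\n")
        for i, name in enumerate(alignment.taxon_names):
            fh.write(name.ljust(width) + "".join(alignment.matrix[i]) + "\n")


def read_partitions(path: str | os.PathLike | None,
                    alignment: Alignment) -> list[PartitionDef]:
    """Parse a RAxML-style partition file; a single default partition covers
    the whole alignment when *path* is None.

    Lines look like ``DNA, gene1 = 1-500, 804-1000`` or
    ``DNA, codon3 = 3-999\\3``.  Partitions must be disjoint and jointly
    cover every site.
    """
    n_sites = alignment.n_sites
    if path is None:
        return [PartitionDef("p0", alignment.data_type, [(1, n_sites, 1)])]
    parts: list[PartitionDef] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                head, ranges_txt = line.split("=", 1)
                dtype_txt, name = (s.strip() for s in head.split(",", 1))
            except ValueError as exc:
                raise AlignmentError(f"malformed partition line {lineno}: {line!r}") from exc
            dtype = dtype_txt.upper()
            if dtype not in ("DNA", "AA"):
                # RAxML spells AA models by name (WAG, LG, ...); treat as AA
                dtype = "AA"
            ranges: list[tuple[int, int, int]] = []
            for chunk in ranges_txt.split(","):
                chunk = chunk.strip()
                stride = 1
                if "\\" in chunk:
                    chunk, stride_txt = chunk.split("\\")
                    stride = int(stride_txt)
                if "-" in chunk:
                    lo, hi = (int(x) for x in chunk.split("-"))
                else:
                    lo = hi = int(chunk)
                if not (1 <= lo <= hi <= n_sites):
                    raise AlignmentError(
                        f"partition {name!r}: range {lo}-{hi} outside 1-{n_sites}")
                ranges.append((lo, hi, stride))
            parts.append(PartitionDef(name, dtype, ranges))
    # coverage / overlap audit
    counts = np.zeros(n_sites, dtype=int)
    for p in parts:
        counts[p.columns()] += 1
    if np.any(counts != 1):
        dup = np.nonzero(counts > 1)[0] + 1
        gap = np.nonzero(counts == 0)[0] + 1
        msg = []
        if dup.size:
            msg.append(f"sites covered more than once: {dup[:10].tolist()}")
        if gap.size:
            msg.append(f"uncovered sites: {gap[:10].tolist()}")
        raise AlignmentError("bad partition scheme: " + "; ".join(msg))
    return parts


# -------------------------------------------------------------- compression

def compress_patterns(alignment: Alignment,
                      partitions: Sequence[PartitionDef] | None = None) -> PatternMatrix:
    """Collapse identical site columns within each partition into weighted
    patterns.  The likelihood of the compressed matrix equals the likelihood
    of the raw sites by construction (weights multiply per-pattern logs)."""
    if partitions is None:
        partitions = read_partitions(None, alignment)
    pm = PatternMatrix(list(alignment.taxon_names))
    for part in partitions:
        table = DNA_CODES if part.data_type == "DNA" else AA_CODES
        cols = part.columns()
        sub = alignment.matrix[:, cols]
        lut = np.zeros(128, dtype=np.uint32)
        for ch, mask in table.items():
            lut[ord(ch)] = mask
        codes = lut[sub.view(np.uint32).reshape(sub.shape)]  # '<U1' -> codepoints
        uniq, weights = np.unique(codes, axis=1, return_counts=True)
        pm.partitions.append(PartitionPatterns(
            name=part.name, data_type=part.data_type,
            codes=uniq.astype(np.uint32), weights=weights.astype(int),
            n_sites=int(cols.size)))
    return pm
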