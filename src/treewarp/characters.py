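"""Alignment input, IUPAC ambiguity coding and site-pattern compression.

Site patterns are stored bit-encoded: each cell is a 4-bit subset of
{A, C, G, T} (A=1, C=2, G=4, T=8).  Gaps, '?' and 'N' all map to the full
set — missing data for both parsimony and likelihood.  Identical columns
are merged with integer weights; ``n_sites`` keeps the *total* alignment
length (constant sites included), which is the N entering the guided
moves' pseudo branch length S/N.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

__all__ = ["AlignmentError", "PatternMatrix", "read_alignment", "read_fasta", "read_nexus", "IUPAC_CODES"]


class AlignmentError(ValueError):
    """Bad alignment input."""


A, C, G, T = 1, 2, 4, 8
FULL = A | C | G | T

IUPAC_CODES = {
    "A": A, "C": C, "G": G, "T": T, "U": T,
    "R": A | G, "Y": C | T, "S": C | G, "W": A | T,
    "K": G | T, "M": A | C,
    "B": C | G | T, "D": A | G | T, "H": A | C | T, "V": A | C | G,
    "N": FULL, "?": FULL, "-": FULL, "X": FULL,
}

_BITS_TO_SET = {code: frozenset(b for b, m in zip("ACGT", (A, C, G, T)) if code & m) for code in range(1, 16)}


@dataclass
class PatternMatrix:
    """Compressed site patterns for a set of taxa.

    Attributes
    ----------
    taxa : tuple of str
        Taxon names in file order.
    codes : np.ndarray, shape (n_taxa, n_patterns), dtype uint8
        Bit-encoded state subsets.
    weights : np.ndarray, shape (n_patterns,), dtype int64
        Multiplicity of each pattern; sums to ``n_sites``.
    n_sites : int
        Total alignment length, constant sites included.
    """

    taxa: tuple
    codes: np.ndarray
    weights: np.ndarray
    n_sites: int = field(default=0)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        self.weights = np.asarray(self.weights, dtype=np.int64)
        if self.n_sites == 0:
            self.n_sites = int(self.weights.sum())
        if int(self.weights.sum()) != self.n_sites:
            raise AlignmentError("pattern weights do not sum to the number of sites")
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.taxa):
            raise AlignmentError("codes must be (n_taxa, n_patterns)")
        if np.any(self.codes == 0) or np.any(self.codes > 15):
            raise AlignmentError("every cell must be a nonempty subset of {A,C,G,T}")

    @property
    def n_patterns(self) -> int:
        return self.codes.shape[1]

    @classmethod
    def from_sequences(cls, seqs: "dict[str, str]", n_sites: int | None = None) -> "PatternMatrix":
        """Build from label->sequence, compressing identical columns.

        ``n_sites`` truncates to the first m columns (used when guide
        weights are computed from a prefix of the alignment).
        """
        if not seqs:
            raise AlignmentError("empty alignment")
        taxa = tuple(seqs)
        if len(set(taxa)) != len(taxa):
            raise AlignmentError("duplicate taxon name")
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: sequence lengths {sorted(lengths)}")
        (length,) = lengths
        if n_sites is not None:
            if not 1 <= n_sites <= length:
                raise AlignmentError(f"site prefix {n_sites} outside 1..{length}")
            length = n_sites
        mat = np.empty((len(taxa), length), dtype=np.uint8)
        for row, name in enumerate(taxa):
            seq = seqs[name].upper()
            for col in range(length):
                sym = seq[col]
                try:
                    mat[row, col] = IUPAC_CODES[sym]
                except KeyError:
                    raise AlignmentError(
                        f"unknown symbol {sym!r} in sequence {name!r} at position {col + 1}"
                    ) from None
        cols, weights = np.unique(mat, axis=1, return_counts=True)
        return cls(taxa=taxa, codes=cols, weights=weights, n_sites=length)

    def expand(self) -> np.ndarray:
        """Uncompressed (n_taxa, n_sites) code matrix; column multiset only
        (the original column order is not retained)."""
        return np.repeat(self.codes, self.weights, axis=1)

    def state_sets(self, taxon: str) -> list:
        row = self.codes[self.taxa.index(taxon)]
        return [_BITS_TO_SET[int(c)] for c in row]

    def empirical_frequencies(self) -> np.ndarray:
        """Observed base proportions over unambiguous cells (A, C, G, T order)."""
        counts = np.zeros(4)
        for i, bit in enumerate((A, C, G, T)):
            mask = self.codes == bit
            counts[i] = (mask * self.weights[None, :]).sum()
        total = counts.sum()
        if total == 0:
            return np.full(4, 0.25)
        return counts / total


def read_fasta(source) -> "dict[str, str]":
    """FASTA file path or handle -> ordered label->sequence dict."""
    if isinstance(source, (str,)) and "\n" in source:
        handle = io.StringIO(source)
    else:
        handle = source
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(handle, "fasta"):
        if rec.id in seqs:
            raise AlignmentError(f"duplicate taxon name {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise AlignmentError("no sequences found (is this FASTA?)")
    return seqs


def read_nexus(source) -> "dict[str, str]":
    """NEXUS DATA/CHARACTERS block (DNA) -> ordered label->sequence dict."""
    import dendropy

    try:
        if isinstance(source, str) and "\n" in source:
            mat = dendropy.DnaCharacterMatrix.get(data=source, schema="nexus")
        else:
            mat = dendropy.DnaCharacterMatrix.get(path=str(source), schema="nexus")
    except Exception as exc:
        raise AlignmentError(f"cannot read NEXUS data: {exc}") from None
    seqs = {}
    for taxon in mat.taxon_namespace:
        seqs[taxon.label] = str(mat[taxon]).replace(" ", "")
    return seqs


def read_alignment(source, fmt: str | None = None, n_sites: int | None = None) -> PatternMatrix:
    """Read a FASTA file or NEXUS data block into a :class:`PatternMatrix`.

    Format is sniffed from the content when not given.  ``n_sites``
    restricts to the first m columns.
    """
    text = None
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and "\n" in source:
        text = source
    else:
        with open(source) as fh:
            text = fh.read()
    if fmt is None:
        fmt = "nexus" if text.lstrip().lower().startswith("#nexus") else "fasta"
    if fmt == "fasta":
        seqs = read_fasta(io.StringIO(text))
    elif fmt == "nexus":
        seqs = read_nexus(text)
    else:
        raise AlignmentError(f"unsupported format {fmt!r}")
    return PatternMatrix.from_sequences(seqs, n_sites=n_sites)
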