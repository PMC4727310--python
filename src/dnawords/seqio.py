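"""Sequence input and normalization.

A strand of a chromosome (or a preprocessed text) is represented by a
:class:`SequenceRecord` carrying its own 1-based coordinate system: position 1
is the first symbol, matching the convention used by every position set in
this package.  Symbols outside the declared alphabet (e.g. ``N`` in a DNA
file) are kept so that they consume coordinates — the full length of the
strand stays the reference frame — but they are marked so that no candidate
word may include or span one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: canonical DNA alphabet, the default for genomic inputs
DNA_ALPHABET: tuple[str, ...] = ("A", "C", "G", "T")

#: 26 lowercase letters, the alphabet used for plain-text inputs
TEXT_ALPHABET: tuple[str, ...] = tuple("abcdefghijklmnopqrstuvwxyz")

#: placeholder strand tag for non-DNA records
STRAND_SENSE = "sense"
STRAND_ANTISENSE = "antisense"
STRAND_NA = "n/a"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SequenceRecord:
    """One strand of one chromosome (or one text) in 1-based coordinates.

    Parameters
    ----------
    id : str
        Record label (FASTA header token, file stem, ...).
    symbols : str
        The sequence.  May contain symbols outside ``alphabet``; those
        positions still count toward ``length`` but are off-limits to words.
    alphabet : tuple of str
        Ordered set of allowed symbols, e.g. ``("A","C","G","T")``.
    strand_tag : str
        ``"sense"``, ``"antisense"`` or ``"n/a"``.
    """

    id: str
    symbols: str
    alphabet: tuple[str, ...] = DNA_ALPHABET
    strand_tag: str = STRAND_SENSE

    @property
    def length(self) -> int:
        return len(self.symbols)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.symbols)

    def is_dna(self) -> bool:
        return tuple(sorted(self.alphabet)) == tuple(sorted(DNA_ALPHABET))

    def out_of_alphabet_positions(self) -> frozenset[int]:
        """1-based positions holding symbols outside the alphabet."""
        allowed = set(self.alphabet)
        return frozenset(
            i for i, s in enumerate(self.symbols, start=1) if s not in allowed
        )


def read_fasta(
    path: str | Path, alphabet: Sequence[str] = DNA_ALPHABET
) -> list[SequenceRecord]:
    """Read a (possibly multi-record, wrapped-line) FASTA file.

    Returns one sense-strand :class:`SequenceRecord` per FASTA record, in
    file order, with symbols uppercased.  Out-of-alphabet symbols are
    retained (they occupy coordinates).  Empty records are skipped with a
    warning; a non-empty file without any header is a format error.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        raise ValueError(f"{path}: not FASTA-formatted (no '>' header)")
    for rec in SeqIO.parse(str(path), "fasta"):
        symbols = str(rec.seq).upper()
        if not symbols:
            logger.warning("skipping empty FASTA record %r in %s", rec.id, path)
            continue
        records.append(
            SequenceRecord(
                id=rec.id,
                symbols=symbols,
                alphabet=tuple(alphabet),
                strand_tag=STRAND_SENSE,
            )
        )
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA with 70-column wrapped lines."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.symbols), 70):
                fh.write(rec.symbols[i : i + 70] + "\n")


def reverse_complement(rec: SequenceRecord) -> SequenceRecord:
    """Antisense strand of a DNA record, in its own coordinate system.

    Position 1 of the result is the complement of the sense record's last
    position.  Each strand is analyzed independently; no attempt is made to
    map antisense coordinates back onto the sense frame.
    """
    if not rec.is_dna():
        raise ValueError("reverse_complement requires the DNA alphabet")
    # Seq.reverse_complement handles IUPAC ambiguity codes (N -> N), keeping
    # out-of-alphabet placeholders in the coordinate frame.
    rc = str(Seq(rec.symbols).reverse_complement()).upper()
    tag = STRAND_SENSE if rec.strand_tag == STRAND_ANTISENSE else STRAND_ANTISENSE
    return replace(rec, symbols=rc, strand_tag=tag)


def preprocess_text(
    raw: str, keep: Sequence[str] = TEXT_ALPHABET, id: str = "text"
) -> SequenceRecord:
    """Reduce a text to a symbol sequence over ``keep``.

    Uppercase letters are lowercased; every character not in ``keep`` after
    lowercasing is deleted.  The result may have length 0.
    """
    keep_set = set(keep)
    symbols = "".join(c for c in raw.lower() if c in keep_set)
    return SequenceRecord(
        id=id, symbols=symbols, alphabet=tuple(keep), strand_tag=STRAND_NA
    )


def iter_strands(rec: SequenceRecord, both: bool = True) -> Iterator[SequenceRecord]:
    """Yield the sense strand and, for DNA records, optionally the antisense."""
    yield rec
    if both and rec.is_dna():
        yield reverse_complement(rec)
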