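"""Vocabulary serialization, comparison and merging.

Vocabularies travel as TSV (one word per row with its statistics) because
per-word statistics must stay attached to the string.  Words are compared as
literal strings: a word and its reverse complement are distinct entries —
sense and antisense strands carry different information and are compared as
different strands.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .extractor import Vocabulary, Word

_COLUMNS = (
    "word",
    "length",
    "raw_count",
    "net_count",
    "dn",
    "p_value",
    "alpha_used",
    "strand_id",
)


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_vocabulary(vocab: Vocabulary, path: str | Path) -> None:
    """Write a vocabulary as TSV.

    A '#'-prefixed header line records the extraction parameters; data rows
    are sorted by descending length then lexicographic word; floats are
    written at 6 significant digits.  Net positions are not serialized.
    """
    path = Path(path)
    with path.open("w") as fh:
        params = " ".join(f"{k}={v}" for k, v in sorted(vocab.params.items()))
        fh.write(f"# strand_id={vocab.strand_id} {params}\n")
        fh.write("\t".join(_COLUMNS) + "\n")
        for w in vocab.sorted_words():
            fh.write(
                "\t".join(
                    [
                        w.word,
                        str(w.length),
                        str(w.raw_count),
                        str(w.net_count),
                        _fmt(w.dn),
                        _fmt(w.p_value),
                        _fmt(w.alpha_used),
                        w.strand_id,
                    ]
                )
                + "\n"
            )


def read_vocabulary(path: str | Path) -> Vocabulary:
    """Read a vocabulary written by :func:`write_vocabulary`.

    String fields round-trip exactly, floats to the 6 significant digits
    they were written at; position sets are not recoverable from TSV.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    strand_id = "unknown"
    params: dict[str, object] = {}
    words: list[Word] = []
    for line in lines:
        if line.startswith("#"):
            for tok in line[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    if k == "strand_id":
                        strand_id = v
                    else:
                        try:
                            params[k] = float(v)
                        except ValueError:
                            params[k] = v
            continue
        if not line.strip() or line.startswith("word\t"):
            continue
        f = line.split("\t")
        words.append(
            Word(
                word=f[0],
                raw_count=int(f[2]),
                net_count=int(f[3]),
                dn=float(f[4]),
                p_value=float(f[5]),
                alpha_used=float(f[6]),
                net_positions=frozenset(),
                strand_id=f[7],
            )
        )
    return Vocabulary(strand_id=strand_id, words=tuple(words), params=params)


@dataclass(frozen=True)
class VocabularyComparison:
    """Shared-word accounting between two strand vocabularies."""

    a_id: str
    b_id: str
    per_length_counts_a: Mapping[int, int]
    per_length_counts_b: Mapping[int, int]
    shared_words: frozenset[str]
    shared_per_length: Mapping[int, int]


def _per_length(words: set[str]) -> dict[int, int]:
    return dict(Counter(len(w) for w in words))


def compare_vocabularies(a: Vocabulary, b: Vocabulary) -> VocabularyComparison:
    """Exact string-set intersection plus per-length histograms."""
    wa, wb = a.word_strings(), b.word_strings()
    shared = wa & wb
    return VocabularyComparison(
        a_id=a.strand_id,
        b_id=b.strand_id,
        per_length_counts_a=_per_length(wa),
        per_length_counts_b=_per_length(wb),
        shared_words=frozenset(shared),
        shared_per_length=_per_length(shared),
    )


def write_comparison(cmp: VocabularyComparison, path: str | Path) -> None:
    """Comparison report as TSV: length, count_a, count_b, count_shared."""
    path = Path(path)
    lengths = sorted(
        set(cmp.per_length_counts_a)
        | set(cmp.per_length_counts_b)
        | set(cmp.shared_per_length)
    )
    with path.open("w") as fh:
        fh.write(f"# a={cmp.a_id} b={cmp.b_id}\n")
        fh.write("length\tcount_a\tcount_b\tcount_shared\n")
        for l in lengths:
            fh.write(
                f"{l}\t{cmp.per_length_counts_a.get(l, 0)}"
                f"\t{cmp.per_length_counts_b.get(l, 0)}"
                f"\t{cmp.shared_per_length.get(l, 0)}\n"
            )


def merge_vocabularies(
    vs: Sequence[Vocabulary], merged_id: str | None = None
) -> Vocabulary:
    """Union of word strings across strands (a species-level vocabulary).

    Every per-strand record of a word is kept, so a word extracted from two
    strands appears once in the word set but carries both records.  Merging
    is associative and idempotent on word sets.
    """
    if merged_id is None:
        merged_id = "+".join(v.strand_id for v in vs) if vs else "empty"
    records: list[Word] = []
    seen: set[tuple[str, str]] = set()
    for v in vs:
        for w in v.words:
            key = (w.word, w.strand_id)
            if key not in seen:
                seen.add(key)
                records.append(w)
    return Vocabulary(strand_id=merged_id, words=tuple(records), params={})
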