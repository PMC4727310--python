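"""Enumeration of repeated symbol sequences with their position sets.

Candidate words are symbol sequences repeated more than ``min_count`` times
(strictly; default 100) on one strand.  Each candidate carries its start
positions and its *occupied* position set — every 1-based coordinate covered
by any occurrence — which is the currency of the downstream integrity filter.

Counting is non-overlapping by default (greedy left-to-right, the semantics
of a Perl/grep-style global match): for a self-overlapping word such as
``TT``, overlapping window counts turn every run of the letter into a burst
of adjacent start positions, and that clumping wrecks the calibration of
the downstream positional uniformity test — uniform random sequences then
sprout spurious short "words".  Greedy counting makes occurrence starts an
anti-clustered renewal process, which if anything is conservative for that
test.  For words that cannot overlap themselves (and all length-1 words)
the two countings coincide.  Overlapping window counting remains available
via ``overlapping=True``.

Enumeration extends length-l survivors to length l+1 (Apriori pruning: a
word can only repeat > min_count times if its length-l prefix does); the
result contract is exact: the table contains exactly the words whose count
under the chosen counting exceeds the threshold, at every length where any
word qualifies.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Iterator, Mapping

from .seqio import SequenceRecord

DEFAULT_MIN_COUNT = 100


@dataclass(frozen=True)
class CandidateRepeat:
    """A symbol sequence with its occurrence start positions on one strand."""

    word: str
    starts: tuple[int, ...]  # sorted, 1-based

    @property
    def length(self) -> int:
        return len(self.word)

    @property
    def raw_count(self) -> int:
        return len(self.starts)

    @cached_property
    def occupied(self) -> frozenset[int]:
        """All 1-based positions covered by any occurrence."""
        k = len(self.word)
        return frozenset(p for s in self.starts for p in range(s, s + k))


@dataclass(frozen=True)
class LengthClassTable:
    """Candidates grouped by length; lengths run 1..max_length."""

    classes: Mapping[int, tuple[CandidateRepeat, ...]]

    @property
    def max_length(self) -> int:
        nonempty = [l for l, c in self.classes.items() if c]
        return max(nonempty) if nonempty else 0

    def lengths_descending(self) -> Iterator[int]:
        for l in sorted(self.classes, reverse=True):
            if self.classes[l]:
                yield l

    def __getitem__(self, length: int) -> tuple[CandidateRepeat, ...]:
        return self.classes.get(length, ())

    def n_candidates(self) -> int:
        return sum(len(c) for c in self.classes.values())


def _greedy_nonoverlapping(starts: list[int], length: int) -> list[int]:
    """Left-to-right maximal set of pairwise non-overlapping starts."""
    out: list[int] = []
    last_end = 0
    for s in starts:
        if s > last_end:
            out.append(s)
            last_end = s + length - 1
    return out


def count_occurrences(
    rec: SequenceRecord, word: str, overlapping: bool = False
) -> CandidateRepeat:
    """Occurrence scan of ``word`` in ``rec``.

    Returns a candidate whose starts list every match position under the
    chosen counting (a word longer than the sequence simply has raw_count
    0).  Matching is literal; a word may not be empty.
    """
    if not word:
        raise ValueError("word must be non-empty")
    starts: list[int] = []
    step = 1 if overlapping else len(word)
    i = rec.symbols.find(word)
    while i != -1:
        starts.append(i + 1)  # 1-based
        i = rec.symbols.find(word, i + step)
    return CandidateRepeat(word=word, starts=tuple(starts))


def enumerate_repeats(
    rec: SequenceRecord,
    min_count: int = DEFAULT_MIN_COUNT,
    overlapping: bool = False,
) -> LengthClassTable:
    """All words whose count exceeds ``min_count``, classified by length.

    Words containing out-of-alphabet symbols are excluded.  Raising
    ``min_count`` never adds a candidate.  The internal extension walk uses
    overlapping start lists (a superset: a word's non-overlapping count
    never exceeds its overlapping count), and the greedy filter is applied
    per emitted candidate, so the table is exact under either counting.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    seq = rec.symbols
    allowed = set(rec.alphabet)

    # length 1: single pass (overlap is vacuous here)
    by_symbol: dict[str, list[int]] = {}
    for i, s in enumerate(seq, start=1):
        if s in allowed:
            by_symbol.setdefault(s, []).append(i)

    classes: dict[int, tuple[CandidateRepeat, ...]] = {}
    survivors = {w: starts for w, starts in by_symbol.items() if len(starts) > min_count}
    length = 1
    while survivors:
        emitted = []
        for w, starts in sorted(survivors.items()):
            if not overlapping:
                starts = _greedy_nonoverlapping(starts, length)
            if len(starts) > min_count:
                emitted.append(CandidateRepeat(word=w, starts=tuple(starts)))
        if emitted:
            classes[length] = tuple(emitted)
        # extend overlapping survivors by one symbol to the right
        extended: dict[str, list[int]] = {}
        limit = len(seq) - length  # last start extensible to length+1
        for w, starts in survivors.items():
            for s in starts:
                if s > limit:
                    continue
                nxt = seq[s + length - 1]
                if nxt not in allowed:
                    continue
                extended.setdefault(w + nxt, []).append(s)
        survivors = {w: st for w, st in extended.items() if len(st) > min_count}
        length += 1
    return LengthClassTable(classes=classes)


def table_to_rows(table: LengthClassTable) -> list[tuple[str, int, int]]:
    """Debug dump: (word, length, raw_count) rows, longest first."""
    rows = []
    for l in table.lengths_descending():
        for cand in table[l]:
            rows.append((cand.word, cand.length, cand.raw_count))
    return rows
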