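"""Word extraction: non-uniformity plus integrity, per strand.

A *word* here is a symbol sequence that (a) repeats more than ``min_count``
times, (b) whose positions — after removing territory claimed by longer
recognized words — deviate from the uniform distribution (KS test, D_n >
``min_dn``, p < per-class alpha), and (c) is a complete unit: the integrity
filter deletes, from a candidate's raw positions, the positions occupied by
any longer recognized word that contains the candidate as a contiguous
substring.  A boundary-broken fragment (think "ioinformatio" inside
"bioinformation") occurs only inside its superword, loses all positions,
and is eliminated; a genuine embedded word ("information") also occurs
standalone and is tested on those *net* positions.

Length classes are processed in strictly descending order; candidates within
a class never filter each other, so the result is independent of the
iteration order inside a class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
from sklearn.base import BaseEstimator

from .repeats import CandidateRepeat, enumerate_repeats
from .seqio import SequenceRecord
from .uniformity import adjusted_alpha, ks_uniform, passes_word_criteria

logger = logging.getLogger(__name__)

IntegrityMode = Literal["occurrence", "set-difference"]


@dataclass(frozen=True)
class Word:
    """An accepted word with the statistics it was accepted on."""

    word: str
    raw_count: int
    net_count: int
    dn: float
    p_value: float
    alpha_used: float
    net_positions: frozenset[int]
    strand_id: str
    raw_starts: tuple[int, ...] = ()

    @property
    def length(self) -> int:
        return len(self.word)

    @property
    def occupied(self) -> frozenset[int]:
        """All positions covered by any raw occurrence (word territory)."""
        k = len(self.word)
        return frozenset(p for s in self.raw_starts for p in range(s, s + k))


@dataclass(frozen=True)
class Vocabulary:
    """The set of accepted words of one strand, with the thresholds used."""

    strand_id: str
    words: tuple[Word, ...]
    params: Mapping[str, float] = field(default_factory=dict)

    def word_strings(self) -> set[str]:
        return {w.word for w in self.words}

    def __len__(self) -> int:
        return len(self.words)

    def __iter__(self):
        return iter(self.words)

    def sorted_words(self) -> list[Word]:
        """Descending length, then lexicographic — the serialization order."""
        return sorted(self.words, key=lambda w: (-w.length, w.word))


def _blocked_mask(
    superwords: Iterable[Word], total_length: int
) -> np.ndarray | None:
    """Boolean mask over 1..L of positions occupied by the given words."""
    mask = None
    for sw in superwords:
        if mask is None:
            mask = np.zeros(total_length + 1, dtype=bool)  # index 0 unused
        k = sw.length
        for s in sw.raw_starts:
            mask[s : s + k] = True
    return mask


def integrity_filter(
    cand: CandidateRepeat,
    vocab: Vocabulary,
    total_length: int,
    mode: IntegrityMode = "occurrence",
) -> tuple[tuple[int, ...], frozenset[int]]:
    """Delete recognized-superword territory from a candidate's positions.

    Let B be the union of occupied positions of every recognized word that is
    strictly longer than the candidate and contains it as a contiguous
    substring.  In ``"occurrence"`` mode (the default) an occurrence survives
    iff its occupied interval is disjoint from B; net positions are the union
    of surviving occurrences' intervals.  In ``"set-difference"`` mode the
    net positions are the plain set difference occupied \\ B, and an
    occurrence survives iff at least one of its positions does.  If no
    recognized word contains the candidate, net equals raw.
    """
    supers = [
        w for w in vocab.words if w.length > cand.length and cand.word in w.word
    ]
    if not supers:
        k = cand.length
        net_pos = frozenset(p for s in cand.starts for p in range(s, s + k))
        return cand.starts, net_pos

    mask = _blocked_mask(supers, total_length)
    assert mask is not None
    k = cand.length
    starts = np.asarray(cand.starts, dtype=np.int64)
    # cumulative count of blocked positions up to and including index i
    csum = np.concatenate(([0], np.cumsum(mask[1:])))
    overlap = csum[starts + k - 1] - csum[starts - 1]
    if mode == "occurrence":
        surviving = starts[overlap == 0]
        if surviving.size == 0:
            return (), frozenset()
        pos = (surviving[:, None] + np.arange(k)).ravel()
        return tuple(int(s) for s in surviving), frozenset(np.unique(pos).tolist())
    elif mode == "set-difference":
        surviving = starts[overlap < k]  # at least one position survives
        pos = (starts[:, None] + np.arange(k)).ravel()
        pos = np.unique(pos)
        pos = pos[~mask[pos]]
        return tuple(int(s) for s in surviving), frozenset(pos.tolist())
    raise ValueError(f"unknown integrity mode {mode!r}")


KSSample = Literal["starts", "occupied"]


def extract_words(
    rec: SequenceRecord,
    min_count: int = 100,
    min_dn: float = 0.1,
    family_conf: float = 0.95,
    integrity: IntegrityMode = "occurrence",
    ks_sample: KSSample = "starts",
    overlapping: bool = False,
    shuffle_within_class_seed: int | None = None,
) -> Vocabulary:
    """Extract the vocabulary of one strand.

    Steps: (1) enumerate repeats (> ``min_count``) into length classes;
    (2) test the longest class on raw positions with the class-adjusted
    alpha = 1 - family_conf^(1/n_class); (3)-(5) for each shorter class, in
    strictly descending length order, apply the integrity filter against the
    vocabulary accumulated from longer classes, drop candidates whose net
    count falls to <= ``min_count``, KS-test the surviving positional sample
    and accept survivors meeting all criteria.  n_class, hence alpha, is the
    candidate count of the class as enumerated, not after elimination.

    ``ks_sample`` selects what is handed to the KS test: ``"starts"`` (the
    default) tests the surviving occurrence start positions, so the sample
    size equals the repetition count that the > ``min_count`` criterion is
    stated on; ``"occupied"`` tests all surviving occupied positions.  The
    occupied sample of a length-k word is k statistically dependent runs per
    occurrence, which inflates the nominal KS sample size k-fold and breaks
    the type-I calibration the per-class alpha relies on — with it, uniform
    random sequences yield spurious words.  The two are identical for
    length-1 words.

    ``shuffle_within_class_seed`` randomizes the processing order inside
    each class; it exists to verify that the result is order-free and has no
    effect on the outcome.
    """
    table = enumerate_repeats(rec, min_count=min_count, overlapping=overlapping)
    total_length = rec.length
    rng = (
        np.random.default_rng(shuffle_within_class_seed)
        if shuffle_within_class_seed is not None
        else None
    )
    accepted: list[Word] = []
    for length in table.lengths_descending():
        cands = list(table[length])
        n_class = len(cands)
        alpha = adjusted_alpha(n_class, family_conf=family_conf)
        if rng is not None:
            rng.shuffle(cands)
        vocab_so_far = Vocabulary(strand_id=rec.id, words=tuple(accepted))
        class_accepted: list[Word] = []
        for cand in cands:
            net_starts, net_positions = integrity_filter(
                cand, vocab_so_far, total_length, mode=integrity
            )
            net_count = len(net_starts)
            if net_count <= min_count:
                logger.debug(
                    "eliminated %r: net_count %d <= %d", cand.word, net_count, min_count
                )
                continue
            sample = net_starts if ks_sample == "starts" else net_positions
            res = ks_uniform(sample, total_length)
            if passes_word_criteria(res, alpha, min_dn=min_dn, min_count=min_count):
                class_accepted.append(
                    Word(
                        word=cand.word,
                        raw_count=cand.raw_count,
                        net_count=net_count,
                        dn=res.dn,
                        p_value=res.p_value,
                        alpha_used=alpha,
                        net_positions=net_positions,
                        strand_id=rec.id,
                        raw_starts=cand.starts,
                    )
                )
            else:
                logger.debug(
                    "eliminated %r: dn=%.4g p=%.4g (alpha=%.4g)",
                    cand.word,
                    res.dn,
                    res.p_value,
                    alpha,
                )
        accepted.extend(class_accepted)
    return Vocabulary(
        strand_id=rec.id,
        words=tuple(sorted(accepted, key=lambda w: (-w.length, w.word))),
        params={
            "min_count": min_count,
            "min_dn": min_dn,
            "family_conf": family_conf,
            "integrity": integrity,
            "ks_sample": ks_sample,
            "overlapping": overlapping,
        },
    )


def audit_vocabulary(rec: SequenceRecord, vocab: Vocabulary) -> bool:
    """Recompute each accepted word's statistics from scratch.

    Returns True iff every word's recorded net positions, KS statistics and
    acceptance criteria are reproduced by an independent pass over the
    strand.  Used as a self-consistency check.
    """
    mode = vocab.params.get("integrity", "occurrence")
    ks_sample = vocab.params.get("ks_sample", "starts")
    min_count = int(vocab.params.get("min_count", 100))
    min_dn = float(vocab.params.get("min_dn", 0.1))
    for w in vocab.words:
        from .repeats import count_occurrences

        cand = count_occurrences(
            rec, w.word, overlapping=bool(vocab.params.get("overlapping", False))
        )
        if cand.starts != w.raw_starts:
            return False
        net_starts, net_positions = integrity_filter(
            cand, vocab, rec.length, mode=mode
        )
        if net_positions != w.net_positions or len(net_starts) != w.net_count:
            return False
        sample = net_starts if ks_sample == "starts" else net_positions
        res = ks_uniform(sample, rec.length)
        if abs(res.dn - w.dn) > 1e-12 or abs(res.p_value - w.p_value) > 1e-9:
            return False
        if not passes_word_criteria(res, w.alpha_used, min_dn=min_dn, min_count=min_count):
            return False
    return True


class WordExtractor(BaseEstimator):
    """Estimator wrapper around :func:`extract_words`.

    Parameters
    ----------
    min_count : int, default=100
        A candidate must repeat strictly more than this, before and after
        the integrity filter.
    min_dn : float, default=0.1
        Minimum KS distance; below it a deviation is treated as sampling
        noise regardless of p-value.
    family_conf : float, default=0.95
        Family-wise confidence per length class; the per-candidate alpha is
        1 - family_conf^(1/n_class).
    integrity : {"occurrence", "set-difference"}, default="occurrence"
        Whether superword territory deletes whole overlapping occurrences or
        bare positions.
    ks_sample : {"starts", "occupied"}, default="starts"
        Positional sample handed to the KS test; see :func:`extract_words`.
    overlapping : bool, default=False
        Count overlapping occurrences instead of greedy non-overlapping
        matches; see :mod:`dnawords.repeats` for why greedy is the default.

    Attributes
    ----------
    vocabulary_ : Vocabulary
        The accepted words of the fitted strand.
    n_words_ : int
        Number of accepted words.

    Examples
    --------
    >>> from dnawords.synthetic import random_sequence
    >>> extractor = WordExtractor().fit(random_sequence(50_000, seed=0))
    >>> vocab = extractor.vocabulary_
    """

    def __init__(
        self,
        min_count: int = 100,
        min_dn: float = 0.1,
        family_conf: float = 0.95,
        integrity: IntegrityMode = "occurrence",
        ks_sample: KSSample = "starts",
        overlapping: bool = False,
    ):
        self.min_count = min_count
        self.min_dn = min_dn
        self.family_conf = family_conf
        self.integrity = integrity
        self.ks_sample = ks_sample
        self.overlapping = overlapping

    def fit(self, X: SequenceRecord | str, y=None) -> "WordExtractor":
        """Extract the vocabulary of one strand (or text record)."""
        if isinstance(X, str):
            X = SequenceRecord(id="sequence", symbols=X.upper())
        self.vocabulary_ = extract_words(
            X,
            min_count=self.min_count,
            min_dn=self.min_dn,
            family_conf=self.family_conf,
            integrity=self.integrity,
            ks_sample=self.ks_sample,
            overlapping=self.overlapping,
        )
        self.n_words_ = len(self.vocabulary_)
        return self
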