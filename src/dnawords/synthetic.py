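"""Generators for controls and toy datasets.

Three families of inputs, all deterministic given a seed:

* uniform random symbol sequences — the negative control: i.i.d. equiprobable
  bases carry no positional information, so extraction must return nothing;
* planted-word sequences — a fixed word overwritten into a confined region
  of a uniform background, giving a known clustered signal with a provable
  lower bound on its KS distance;
* toy gene/annotation tables whose exclusive-vs-control membership follows
  an exactly logistic law in the planted word counts, for parameter-recovery
  and calibration tests of the association stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import GeneFunctionDataset, word_frequency_matrix
from .seqio import DNA_ALPHABET, STRAND_NA, SequenceRecord


def random_sequence(
    length: int,
    alphabet: tuple[str, ...] = DNA_ALPHABET,
    seed: int = 0,
    id: str | None = None,
) -> SequenceRecord:
    """Uniform i.i.d. symbols over ``alphabet`` (the pseudo-chromosome)."""
    if length < 0:
        raise ValueError("length must be >= 0")
    rng = np.random.default_rng(seed)
    symbols = "".join(np.array(alphabet)[rng.integers(0, len(alphabet), size=length)])
    return SequenceRecord(
        id=id or f"rand-{seed}",
        symbols=symbols,
        alphabet=tuple(alphabet),
        strand_tag=STRAND_NA,
    )


@dataclass(frozen=True)
class PlantSpec:
    """Where and how often to overwrite a word into a background.

    ``region`` is a 1-based inclusive interval; planted copies never overlap
    each other and must pack into the region: copies * len(word) <=
    hi - lo + 1.
    """

    word: str
    copies: int
    region: tuple[int, int]
    seed: int = 0
    #: scrub chance occurrences of the word outside the planted set, so the
    #: word's positions are exactly the planted ones (makes positional bounds
    #: like "all occurrences below quantile 0.2" hold by construction)
    exclusive: bool = False


def _place_nonoverlapping(
    rng: np.random.Generator, copies: int, word_len: int, lo: int, hi: int
) -> list[int]:
    """Uniformly chosen non-overlapping 1-based starts within [lo, hi].

    Stars-and-bars: choose ``copies`` distinct offsets in the compacted
    range, then re-expand so consecutive picks sit at least ``word_len``
    apart.
    """
    if copies == 0:
        return []
    # compacted slots: each occurrence consumes word_len, gaps are free
    slots = (hi - lo + 2 - word_len) - (copies - 1) * (word_len - 1)
    if slots < copies:
        raise ValueError("cannot pack copies into region without overlap")
    picks = np.sort(rng.choice(slots, size=copies, replace=False))
    starts = [int(lo + p + i * (word_len - 1)) for i, p in enumerate(picks)]
    return starts


def plant_words(
    background: SequenceRecord, spec: PlantSpec
) -> tuple[SequenceRecord, tuple[int, ...]]:
    """Overwrite non-overlapping copies of a word into the background.

    Returns the modified record plus the true planted starts (ground truth
    for recovery tests).  Total length and coordinates are preserved:
    planting overwrites, it does not insert.
    """
    lo, hi = spec.region
    k = len(spec.word)
    if not (1 <= lo <= hi <= background.length):
        raise ValueError("region outside the background")
    if spec.copies * k > hi - lo + 1:
        raise ValueError("copies * word length exceeds region size")
    rng = np.random.default_rng(spec.seed)
    starts = _place_nonoverlapping(rng, spec.copies, k, lo, hi)
    symbols = list(background.symbols)
    for s in starts:
        symbols[s - 1 : s - 1 + k] = spec.word
    if spec.exclusive:
        planted = set(starts)
        occupied = {p for s in starts for p in range(s, s + k)}  # 1-based
        alphabet = list(background.alphabet)
        while True:
            text = "".join(symbols)
            i = text.find(spec.word)
            dirty = False
            while i != -1:
                if i + 1 not in planted:
                    # chance hit: mutate one of its bases, never touching a
                    # planted copy's territory
                    free = [j for j in range(i, i + k) if j + 1 not in occupied]
                    if not free:  # wholly inside planted territory: harmless
                        i = text.find(spec.word, i + 1)
                        continue
                    j = free[len(free) // 2]
                    choices = [a for a in alphabet if a != symbols[j]]
                    symbols[j] = choices[int(rng.integers(0, len(choices)))]
                    dirty = True
                i = text.find(spec.word, i + 1)
            if not dirty:
                break
    return (
        SequenceRecord(
            id=background.id,
            symbols="".join(symbols),
            alphabet=background.alphabet,
            strand_tag=background.strand_tag,
        ),
        tuple(starts),
    )


def toy_association_dataset(
    n_exclusive: int,
    n_control: int,
    signal_words: tuple[str, ...] | list[str] | set[str],
    effect: float,
    seed: int = 0,
    baseline_rate: float = 0.4,
    gene_length: int = 600,
    n_share: int = 0,
) -> GeneFunctionDataset:
    """Toy gene set with an exactly logistic group/frequency relationship.

    Each gene is a uniform random sequence into which each signal word is
    overwritten a Poisson number of times: rate ``baseline_rate`` in the
    control group and ``baseline_rate * exp(effect)`` in the exclusive
    group.  Because the class-conditional counts are Poisson, the true
    posterior log-odds of exclusive membership are linear in the counts
    with slope exactly ``effect`` per word (and intercept
    log(n_exclusive/n_control) + n_words * (rate_ctrl - rate_excl)), so
    ``effect`` is the log-odds change per unit word frequency.  With
    ``effect`` = 0 the dataset is an exact null.  Share-group genes, if
    requested, are generated at the exclusive rate.

    Returns a :class:`GeneFunctionDataset` whose ``freq`` is computed by
    :func:`dnawords.association.word_frequency_matrix` on the generated
    sequences and whose ``true_params`` holds the generating intercept and
    per-word slopes.
    """
    if n_exclusive < 1 or n_control < 1:
        raise ValueError("group sizes must be >= 1")
    words = sorted(signal_words)
    rng = np.random.default_rng(seed)
    rate_excl = baseline_rate * float(np.exp(effect))
    genes: dict[str, tuple[str, ...]] = {}
    groups: dict[str, str] = {}

    def make_gene(gid: str, rate: float) -> None:
        seq = list(
            np.array(DNA_ALPHABET)[rng.integers(0, 4, size=gene_length)]
        )
        for w in words:
            k = len(w)
            c = int(rng.poisson(rate))
            c = min(c, (gene_length // (2 * k)))  # keep packing feasible
            if c:
                starts = _place_nonoverlapping(rng, c, k, 1, gene_length)
                for s in starts:
                    seq[s - 1 : s - 1 + k] = w
        genes[gid] = ("".join(seq),)

    for i in range(n_exclusive):
        gid = f"exc{i:04d}"
        make_gene(gid, rate_excl)
        groups[gid] = "exclusive"
    for i in range(n_control):
        gid = f"ctl{i:04d}"
        make_gene(gid, baseline_rate)
        groups[gid] = "control"
    for i in range(n_share):
        gid = f"shr{i:04d}"
        make_gene(gid, rate_excl)
        groups[gid] = "share"

    freq = word_frequency_matrix(genes, words)
    labels = pd.Series(
        {g: 1 if grp == "exclusive" else 0 for g, grp in groups.items()}
    ).loc[freq.index]
    true_params = {"const": float(np.log(n_exclusive / n_control)
                                  + len(words) * (baseline_rate - rate_excl))}
    true_params.update({w: effect for w in words})
    return GeneFunctionDataset(
        freq=freq,
        labels=labels,
        exclusive=frozenset(g for g, grp in groups.items() if grp == "exclusive"),
        share=frozenset(g for g, grp in groups.items() if grp == "share"),
        control=frozenset(g for g, grp in groups.items() if grp == "control"),
        genes=genes,
        true_params=true_params,
    )
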