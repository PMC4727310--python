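"""Associating word frequencies with gene-function categories.

Pipeline: grade function terms by level in the term hierarchy (a DAG with
one root per category); for each term, split the annotated-gene universe
into *exclusive* (annotated only by this term among same-level terms),
*share* (also annotated by another same-level term) and *control* (not
annotated by the term); build a per-gene adjusted word-frequency matrix
(occurrences inside a longer vocabulary word are not double-counted under
its subwords); select words in two stages (frequency contrast, then
per-coefficient p-value) and fit a logistic model — optionally with all
first-order interaction products — of exclusive-vs-control membership;
evaluate by bootstrap resampling, reporting the median and MAD of
sensitivity, specificity, agreement rate and share-group accuracy.

The hierarchy is consumed as a plain child->parent edge list; levels use
min-depth (a term with several parents sits at 1 + the minimum parent
level).  Annotation entries are expected pre-filtered (IEA-evidence entries
and conflict genes removed upstream).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

logger = logging.getLogger(__name__)

MIN_GROUP_SIZE = 150  # a term qualifies if exclusive and control both exceed this


# ---------------------------------------------------------------------------
# term hierarchy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TermHierarchy:
    """Leveled view of a term DAG.

    ``levels`` maps each term to its level: direct children of a root are
    level 1, their children level 2, and so on, taking the minimum over
    multiple parents.  ``descendants`` is transitively closed (direct and
    indirect children).
    """

    terms: frozenset[str]
    roots: tuple[str, ...]
    levels: Mapping[str, int]
    descendants: Mapping[str, frozenset[str]]

    def same_level_terms(self, term: str) -> set[str]:
        lv = self.levels[term]
        return {t for t, l in self.levels.items() if l == lv}


def grade_terms(
    edges: Iterable[tuple[str, str]],
    roots: Sequence[str],
    category_root: str | None = None,
) -> TermHierarchy:
    """Assign levels and descendant sets from a child->parent edge list.

    ``roots`` are the category roots (level 0).  If ``category_root`` is
    given, only terms reachable from that root are retained (e.g. keeping
    the molecular-function category only).  A cycle is an error.
    """
    g = nx.DiGraph()  # parent -> child
    g.add_nodes_from(roots)
    for child, parent in edges:
        g.add_edge(parent, child)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("term hierarchy contains a cycle")
    sources = [category_root] if category_root is not None else list(roots)
    for r in sources:
        if r not in g:
            raise ValueError(f"root {r!r} absent from hierarchy")
    levels: dict[str, int] = {}
    for r in sources:
        for term, dist in nx.single_source_shortest_path_length(g, r).items():
            if dist == 0:
                continue  # roots themselves are not leveled terms
            levels[term] = min(levels.get(term, dist), dist)
    descendants = {
        t: frozenset(nx.descendants(g, t)) for t in levels
    }
    return TermHierarchy(
        terms=frozenset(levels),
        roots=tuple(roots),
        levels=levels,
        descendants=descendants,
    )


# ---------------------------------------------------------------------------
# gene grouping
# ---------------------------------------------------------------------------


def _annotated_by(
    term: str, hierarchy: TermHierarchy, ann_by_gene: Mapping[str, set[str]]
) -> set[str]:
    scope = {term} | set(hierarchy.descendants.get(term, ()))
    return {g for g, ts in ann_by_gene.items() if ts & scope}


def group_genes(
    term: str,
    hierarchy: TermHierarchy,
    annotations: Iterable[tuple[str, str]] | Mapping[str, set[str]],
) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
    """(exclusive, share, control) gene sets for one term.

    A gene counts as annotated by a term if annotated by the term or any of
    its descendants.  Exclusive: annotated by this term only, among terms of
    the same level.  Share: annotated by this term and at least one other
    same-level term.  Control: the annotated-gene universe minus genes
    annotated by the term.
    """
    if term not in hierarchy.levels:
        raise ValueError(f"unknown term {term!r}")
    if isinstance(annotations, Mapping):
        ann_by_gene = {g: set(ts) for g, ts in annotations.items()}
    else:
        ann_by_gene = {}
        for g, t in annotations:
            ann_by_gene.setdefault(g, set()).add(t)
    universe = set(ann_by_gene)
    mine = _annotated_by(term, hierarchy, ann_by_gene)
    others: set[str] = set()
    for other in hierarchy.same_level_terms(term) - {term}:
        others |= _annotated_by(other, hierarchy, ann_by_gene)
    exclusive = mine - others
    share = mine & others
    control = universe - mine
    return frozenset(exclusive), frozenset(share), frozenset(control)


def term_qualifies(
    exclusive: frozenset[str],
    control: frozenset[str],
    min_size: int = MIN_GROUP_SIZE,
) -> bool:
    """Retain a term for modelling only if both groups exceed ``min_size``."""
    return len(exclusive) > min_size and len(control) > min_size


# ---------------------------------------------------------------------------
# word-frequency features
# ---------------------------------------------------------------------------


def _count_overlapping(seq: str, word: str) -> int:
    n, i = 0, seq.find(word)
    while i != -1:
        n += 1
        i = seq.find(word, i + 1)
    return n


def word_frequency_matrix(
    genes: Mapping[str, str | Sequence[str]],
    vocabulary: Iterable[str],
) -> pd.DataFrame:
    """Adjusted word frequency f_{m,i} of each vocabulary word per gene.

    Raw counts are overlapping-occurrence counts per sequence.  For every
    (subword, superword) pair within the vocabulary, subword occurrences
    that are accounted for by the superword — superword count times the
    number of times the subword occurs inside the superword string — are
    subtracted from the subword's count, flooring at 0.  A gene with several
    sequence variants gets the average over its sequences; an empty
    sequence contributes zeros (logged).
    """
    words = sorted(set(vocabulary), key=lambda w: (-len(w), w))
    # how many times each shorter word occurs inside each longer word
    nested: dict[str, list[tuple[str, int]]] = {w: [] for w in words}
    for short in words:
        for sup in words:
            if len(sup) > len(short) and short in sup:
                nested[short].append((sup, _count_overlapping(sup, short)))

    rows: dict[str, np.ndarray] = {}
    for gene_id, seqs in genes.items():
        if isinstance(seqs, str):
            seqs = [seqs]
        per_seq = np.zeros((max(len(seqs), 1), len(words)))
        for si, seq in enumerate(seqs):
            if not seq:
                logger.warning("gene %s has an empty sequence; frequency 0", gene_id)
                continue
            raw = {w: _count_overlapping(seq, w) for w in words}
            for wi, w in enumerate(words):
                adj = raw[w]
                for sup, times in nested[w]:
                    adj -= raw[sup] * times
                per_seq[si, wi] = max(adj, 0)
        rows[gene_id] = per_seq.mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=words)


# ---------------------------------------------------------------------------
# staged selection and logistic fits
# ---------------------------------------------------------------------------


def select_words_stage1(
    freq: pd.DataFrame,
    labels: pd.Series,
    min_fe: float = 0.6,
    min_fd: float = 0.1,
    cap: int | None = None,
) -> list[str]:
    """Frequency-contrast selection.

    fe is the mean adjusted frequency over exclusive-group genes (label 1),
    fc over control-group genes (label 0), fd = fe - fc.  Words pass with
    fe > min_fe and fd > min_fd (strict).  If ``cap`` is given and the
    selection is not smaller than it, the fd threshold rises in steps of
    0.01 until it is.
    """
    labels = labels.loc[freq.index]
    fe = freq.loc[labels == 1].mean(axis=0)
    fc = freq.loc[labels == 0].mean(axis=0)
    fd = fe - fc
    thr = min_fd
    selected = list(freq.columns[(fe > min_fe) & (fd > thr)])
    if cap is not None:
        while len(selected) >= cap:
            thr += 0.01
            selected = list(freq.columns[(fe > min_fe) & (fd > thr)])
    return selected


@dataclass(frozen=True)
class BootstrapEvaluation:
    """Median and MAD over bootstrap replicates of the four rates."""

    sensitivity: float
    sensitivity_mad: float
    specificity: float
    specificity_mad: float
    agreement: float
    agreement_mad: float
    share_accuracy: float | None
    share_accuracy_mad: float | None
    n_boot: int


@dataclass(frozen=True)
class FitResult:
    """A fitted (possibly interaction-augmented) logistic model.

    ``terms`` are column labels: a bare word for a main effect, ``"a*b"``
    for an interaction product.  ``coefficients`` holds the intercept under
    ``"const"`` plus one log-odds coefficient per term.
    """

    model_kind: str
    terms: tuple[str, ...]
    coefficients: Mapping[str, float]
    p_values: Mapping[str, float]
    converged: bool
    evaluation: BootstrapEvaluation | None = None

    def design(self, freq: pd.DataFrame) -> pd.DataFrame:
        cols = {}
        for t in self.terms:
            if "*" in t:
                a, b = t.split("*")
                cols[t] = freq[a] * freq[b]
            else:
                cols[t] = freq[t]
        X = pd.DataFrame(cols, index=freq.index)
        X.insert(0, "const", 1.0)
        return X

    def predict_proba(self, freq: pd.DataFrame) -> pd.Series:
        X = self.design(freq)
        beta = np.array([self.coefficients[c] for c in X.columns])
        eta = X.to_numpy() @ beta
        return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=freq.index)


def _design_matrix(freq: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    cols = {}
    for t in terms:
        if "*" in t:
            a, b = t.split("*")
            cols[t] = freq[a] * freq[b]
        else:
            cols[t] = freq[t]
    X = pd.DataFrame(cols, index=freq.index) if cols else pd.DataFrame(index=freq.index)
    X.insert(0, "const", 1.0)
    return X


def _logit_fit(freq, labels, terms):
    X = _design_matrix(freq, terms)
    y = labels.loc[X.index].astype(float)
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = model.fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", True))
        except (np.linalg.LinAlgError, PerfectSeparationError):
            # Newton's Hessian goes singular under (quasi-)separation; BFGS
            # still yields finite parameters, flagged as non-converged
            res = model.fit(disp=0, maxiter=500, method="bfgs")
            converged = False
    return res, converged


def fit_term_model(
    freq: pd.DataFrame,
    labels: pd.Series,
    words: Sequence[str],
    model_kind: str = "main_effects",
    p_keep: float = 0.2,
) -> FitResult:
    """Staged maximum-likelihood logistic fit.

    Main-effects path: fit on the given words, keep coefficients with
    p < ``p_keep``, refit on the keepers.  Interaction path: after the
    main-effect keep step, add every pairwise product of the kept words,
    fit, keep terms with p < ``p_keep`` again, and refit.  Complete
    separation or non-convergence flags the result instead of raising; a
    flagged model is excluded from evaluation by the caller.
    """
    if model_kind not in ("main_effects", "with_interaction"):
        raise ValueError(f"unknown model_kind {model_kind!r}")
    terms: list[str] = list(words)
    try:
        if terms:
            res, conv = _logit_fit(freq, labels, terms)
            kept = [t for t in terms if res.pvalues[t] < p_keep]
        else:
            kept, conv = [], True
        if model_kind == "with_interaction" and kept:
            inter = [
                f"{a}*{b}"
                for i, a in enumerate(kept)
                for b in kept[i + 1 :]
            ]
            res, c2 = _logit_fit(freq, labels, kept + inter)
            conv = conv and c2
            kept = [t for t in kept + inter if res.pvalues[t] < p_keep]
        final, c3 = _logit_fit(freq, labels, kept)
        conv = conv and c3
    except (np.linalg.LinAlgError, PerfectSeparationError) as e:
        logger.warning("logistic fit failed (%s); flagging model", e)
        return FitResult(
            model_kind=model_kind,
            terms=tuple(terms),
            coefficients={},
            p_values={},
            converged=False,
        )
    return FitResult(
        model_kind=model_kind,
        terms=tuple(kept),
        coefficients=dict(final.params),
        p_values=dict(final.pvalues),
        converged=conv,
    )


def _mad(x: np.ndarray) -> float:
    m = np.median(x)
    return float(np.median(np.abs(x - m)))


def bootstrap_evaluate(
    fit: FitResult,
    freq: pd.DataFrame,
    labels: pd.Series,
    share_freq: pd.DataFrame | None = None,
    n_boot: int = 100,
    seed: int | None = None,
    max_retries: int = 100,
) -> BootstrapEvaluation:
    """Bootstrap the fitted model's terms and score on the original groups.

    Per replicate: resample the exclusive-plus-control genes with
    replacement at the original size, refit the final model's terms, and
    predict on the full original data.  Sensitivity is the fraction of
    exclusive genes with P > 0.5, specificity the fraction of control genes
    with P < 0.5, agreement the overall correct fraction, share accuracy the
    fraction of share genes with P > 0.5 (missing when the share group is
    empty).  Each rate is summarized by its median and MAD across
    replicates.  A degenerate replicate (a single class in the resample) is
    redrawn, up to ``max_retries`` extra draws; a replicate whose refit
    fails outright (separation) is dropped.
    """
    rng = np.random.default_rng(seed)
    y = labels.loc[freq.index]
    has_share = share_freq is not None and len(share_freq) > 0
    sens, spec, agree, share_acc = [], [], [], []
    n = len(freq)
    for _ in range(n_boot):
        for _retry in range(max_retries + 1):
            take = rng.integers(0, n, size=n)
            yb = y.iloc[take].reset_index(drop=True)
            if yb.nunique() == 2:
                break
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap sample")
        fb = freq.iloc[take].reset_index(drop=True)
        try:
            res, _ = _logit_fit(fb, yb, list(fit.terms))
        except (np.linalg.LinAlgError, PerfectSeparationError):
            continue  # replicate dropped; rare at qualifying group sizes
        rep = replace(fit, coefficients=dict(res.params))
        p = rep.predict_proba(freq)
        sens.append(float((p[y == 1] > 0.5).mean()))
        spec.append(float((p[y == 0] < 0.5).mean()))
        agree.append(float(((p > 0.5) == (y == 1)).mean()))
        if has_share:
            share_acc.append(float((rep.predict_proba(share_freq) > 0.5).mean()))
    return BootstrapEvaluation(
        sensitivity=float(np.median(sens)),
        sensitivity_mad=_mad(np.array(sens)),
        specificity=float(np.median(spec)),
        specificity_mad=_mad(np.array(spec)),
        agreement=float(np.median(agree)),
        agreement_mad=_mad(np.array(agree)),
        share_accuracy=float(np.median(share_acc)) if share_acc else None,
        share_accuracy_mad=_mad(np.array(share_acc)) if share_acc else None,
        n_boot=n_boot,
    )


# ---------------------------------------------------------------------------
# datasets and estimators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneFunctionDataset:
    """Genes, group labels and the adjusted word-frequency matrix for a term.

    ``labels`` is 1 for exclusive-group genes and 0 for control-group genes;
    share-group genes are carried separately (they never enter the fit, only
    the evaluation).  ``true_params`` holds the generating logistic
    parameters when the dataset is synthetic.
    """

    freq: pd.DataFrame
    labels: pd.Series
    exclusive: frozenset[str]
    share: frozenset[str]
    control: frozenset[str]
    genes: Mapping[str, tuple[str, ...]] | None = None
    true_params: Mapping[str, float] | None = None

    @property
    def share_freq(self) -> pd.DataFrame:
        return self.freq.loc[[g for g in self.freq.index if g in self.share]]

    @property
    def model_freq(self) -> pd.DataFrame:
        keep = [g for g in self.freq.index if g not in self.share]
        return self.freq.loc[keep]


def evaluate_dataset(
    fit: FitResult,
    dataset: GeneFunctionDataset,
    n_boot: int = 100,
    seed: int | None = None,
) -> BootstrapEvaluation:
    """Bootstrap evaluation of a fitted term model on its dataset."""
    freq = dataset.model_freq
    return bootstrap_evaluate(
        fit,
        freq,
        dataset.labels.loc[freq.index],
        share_freq=dataset.share_freq,
        n_boot=n_boot,
        seed=seed,
    )


class WordFrequencyTransformer(BaseEstimator, TransformerMixin):
    """Turn gene sequences into the adjusted word-frequency matrix.

    Parameters
    ----------
    vocabulary : sequence of str
        The word strings to count.  Subword counts are corrected for
        occurrences inside longer vocabulary words.
    """

    def __init__(self, vocabulary: Sequence[str] = ()):
        self.vocabulary = vocabulary

    def fit(self, X=None, y=None):
        self.words_ = sorted(set(self.vocabulary), key=lambda w: (-len(w), w))
        return self

    def transform(self, X: Mapping[str, str | Sequence[str]]) -> pd.DataFrame:
        if not hasattr(self, "words_"):
            self.fit()
        return word_frequency_matrix(X, self.words_)


class TermAssociationModel(BaseEstimator, ClassifierMixin):
    """Staged logistic model of term membership from word frequencies.

    Parameters
    ----------
    min_fe, min_fd : float
        Stage-1 thresholds on the exclusive-group mean frequency and on the
        exclusive-minus-control contrast (both strict).
    interaction : bool
        Add all pairwise products of the stage-2 keepers before the final
        p-value screen.
    cap : int or None
        On the interaction path, escalate the fd threshold (steps of 0.01)
        until fewer than ``cap`` words pass stage 1.
    p_keep : float
        Per-coefficient p-value screen used at each refit stage.

    Attributes
    ----------
    selected_words_ : list of str
        Stage-1 survivors.
    fit_result_ : FitResult
        Final model terms and coefficients.
    """

    def __init__(
        self,
        min_fe: float = 0.6,
        min_fd: float = 0.1,
        interaction: bool = False,
        cap: int | None = None,
        p_keep: float = 0.2,
    ):
        self.min_fe = min_fe
        self.min_fd = min_fd
        self.interaction = interaction
        self.cap = cap
        self.p_keep = p_keep

    def fit(self, X: pd.DataFrame, y) -> "TermAssociationModel":
        y = pd.Series(np.asarray(y), index=X.index)
        cap = self.cap if self.cap is not None else (50 if self.interaction else None)
        self.selected_words_ = select_words_stage1(
            X, y, min_fe=self.min_fe, min_fd=self.min_fd, cap=cap
        )
        kind = "with_interaction" if self.interaction else "main_effects"
        self.fit_result_ = fit_term_model(
            X, y, self.selected_words_, model_kind=kind, p_keep=self.p_keep
        )
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        p1 = self.fit_result_.predict_proba(X).to_numpy()
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)
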