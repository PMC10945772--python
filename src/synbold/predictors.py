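"""Assembly of the word-level predictor table.

One row per spoken word, carrying timings, node-count metrics under each
strategy, lexical covariates (syllable count, log frequency, surprisal) and
the sentence-boundary indicator columns.  Word-by-word predictors are
mean-centered per recall before HRF convolution, except the word-rate impulse
and the two boundary indicators, which stay on their 0/1 scale.
"""

from __future__ import annotations

import logging
import re
import warnings
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus_io import DependencyParse, ParseTree, TokenTiming
from .node_metrics import all_metrics

logger = logging.getLogger(__name__)

#: columns never mean-centered: impulse/indicator regressors keep their scale
UNCENTERED = ("word_rate", "sentence_onset", "sentence_offset")

_VOWELS = set("aeiouy")


@lru_cache(maxsize=8192)
def _syllable_heuristic(letters: str) -> int:
    groups = re.findall(r"[aeiouy]+", letters)
    n = len(groups)
    # silent final e ("make"); "-le", "-ee", "-ye" endings keep theirs
    if letters.endswith("e") and not letters.endswith(("le", "ee", "ye")) and n > 1:
        n -= 1
    return max(1, n)


def syllable_count(
    token: str, dictionary: Mapping[str, int] | None = None
) -> int:
    """Heuristic syllable count: maximal vowel-letter groups, with a
    silent-e correction; ≥ 1 always.

    An optional pronunciation dictionary (word → syllables) overrides the
    heuristic.  Non-alphabetic tokens count 1 with a warning.
    """
    word = token.strip().lower()
    if dictionary and word in dictionary:
        return max(1, int(dictionary[word]))
    letters = re.sub(r"[^a-z]", "", word)
    if not letters:
        warnings.warn(f"non-alphabetic token {token!r}; counted as 1 syllable")
        return 1
    return _syllable_heuristic(letters)


def boundary_regressors(sentence_id: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """0/1 indicators for the first and last word of each sentence."""
    sid = np.asarray(sentence_id)
    n = len(sid)
    onset = np.zeros(n, dtype=int)
    offset = np.zeros(n, dtype=int)
    if n == 0:
        return onset, offset
    onset[0] = 1
    offset[-1] = 1
    change = np.flatnonzero(sid[1:] != sid[:-1]) + 1
    onset[change] = 1
    offset[change - 1] = 1
    return onset, offset


def surprisal_column(
    probabilities: Sequence[float], base: str = "e"
) -> np.ndarray:
    """Surprisal = −log p(word | context); natural log by default."""
    p = np.asarray(probabilities, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        bad = np.flatnonzero((p <= 0) | (p > 1)).tolist()
        raise ValueError(f"probabilities outside (0, 1] at rows {bad}")
    s = -np.log(p)
    if base == "2":
        s /= np.log(2.0)
    elif base != "e":
        raise ValueError("base must be 'e' or '2'")
    return s


def mean_center(
    table: pd.DataFrame,
    exclude: Iterable[str] = UNCENTERED,
    group: str | None = "recall_id",
) -> pd.DataFrame:
    """Mean-center the numeric predictor columns, per centering group.

    ``exclude`` columns are left untouched; a zero-variance column centers to
    all zeros with a warning.  Centering is per recall by default since
    convolution is per run.
    """
    out = table.copy()
    exclude = set(exclude) | {"onset", "offset", "sentence_id"}
    cols = [
        c
        for c in out.columns
        if c not in exclude and np.issubdtype(out[c].dtype, np.number)
    ]
    grouper = out[group] if group is not None and group in out.columns else None
    for c in cols:
        vals = out[c].astype(float)
        if float(vals.std()) == 0.0:
            warnings.warn(f"column {c!r} has zero variance; centered to zeros")
        if grouper is not None:
            out[c] = vals - vals.groupby(grouper).transform("mean")
        else:
            out[c] = vals - vals.mean()
    return out


def build_word_table(
    timings: Sequence[TokenTiming],
    trees: Sequence[ParseTree],
    deps: Sequence[DependencyParse] | None = None,
    covariates: pd.DataFrame | None = None,
    count_preterminals: bool = False,
    modality: str = "production",
) -> pd.DataFrame:
    """Join timings, per-sentence node metrics and covariates into one table.

    Sentences are matched positionally: tree ``k`` parses the words of
    ``sentence_id == k`` (per the order sentences appear).  Words missing
    from a tree (length mismatch) are dropped from the node-count columns and
    reported through the module logger.
    """
    df = pd.DataFrame(
        {
            "token": [t.token for t in timings],
            "onset": [t.onset for t in timings],
            "offset": [t.offset for t in timings],
            "sentence_id": [t.sentence_id for t in timings],
            "recall_id": [t.recall_id for t in timings],
        }
    )
    df["word_rate"] = 1
    df["n_syllables"] = [syllable_count(t) for t in df["token"]]
    onset_col, offset_col = boundary_regressors(df["sentence_id"].to_numpy())
    df["sentence_onset"] = onset_col
    df["sentence_offset"] = offset_col
    df["modality"] = modality

    sent_order = df["sentence_id"].drop_duplicates().tolist()
    if len(sent_order) != len(trees):
        raise ValueError(
            f"{len(sent_order)} sentences in timings but {len(trees)} trees"
        )
    strategies = [
        "top_down", "bottom_up", "left_corner", "open_nodes", "early_top_down",
    ] + (["chunked"] if deps is not None else [])
    cols = {s: np.zeros(len(df), dtype=int) for s in strategies}
    positions = {
        sid: np.flatnonzero(df["sentence_id"].to_numpy() == sid)
        for sid in sent_order
    }
    n_dropped = 0
    for k, sid in enumerate(sent_order):
        idx = positions[sid]
        tree = trees[k]
        dep = deps[k] if deps is not None else None
        metrics = all_metrics(tree, dep, count_preterminals)
        n_words = len(idx)
        n_tree = tree.n_terminals
        take = min(n_words, n_tree)
        if n_words != n_tree:
            n_dropped += abs(n_words - n_tree)
        for s in strategies:
            cols[s][idx[:take]] = metrics[s][:take]
    for s in strategies:
        df[s] = cols[s]
    if n_dropped:
        logger.warning(
            "alignment: %d word/terminal mismatches across sentences; "
            "node counts zero-filled for unmatched words", n_dropped,
        )

    if covariates is not None:
        for c in covariates.columns:
            if c not in df.columns:
                if len(covariates) != len(df):
                    raise ValueError(
                        "covariate table length does not match word count"
                    )
                df[c] = np.asarray(covariates[c])
    return df
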