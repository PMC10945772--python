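"""Synthetic corpora, speech timings and ROI BOLD with known ground truth.

Stands in for publicly shared spoken-recall fMRI datasets so every pipeline
stage is testable offline: a small English-like PCFG samples sentence trees
(mean length calibrated to the ~9.4 words of the spoken recalls), a
deterministic head-percolation pass derives dependency parses, a timing model
produces word onsets/offsets whose pauses grow with top-down node counts, and
a forward model generates ROI BOLD as a known linear combination of the
HRF-convolved predictors plus by-participant random slopes and AR(1) noise.

The forward model reuses :mod:`synbold.hrf_design` for the convolution — the
simulator and the analysis share one design-matrix code path — so recovery
tests probe estimation, not reimplementation drift.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import hrf_design, predictors
from .corpus_io import (
    DependencyParse,
    ParseTree,
    ROITimeseries,
    TokenTiming,
    _assign_spans,
    tag_preterminals,
    write_bracketed_trees,
    write_dependency,
    write_roi_timeseries,
    write_word_timings,
)
from .node_metrics import top_down_counts

# ---------------------------------------------------------------------------
# Grammar
# ---------------------------------------------------------------------------

#: rule: (right-hand side, probability, index of the head child)
DEFAULT_GRAMMAR: dict[str, list[tuple[tuple[str, ...], float, int]]] = {
    "S": [(("NP", "VP"), 1.0, 1)],
    "VP": [
        (("V",), 0.12, 0),
        (("V", "NP"), 0.35, 0),
        (("V", "NP", "PP"), 0.12, 0),
        (("V", "SBAR"), 0.26, 0),
        (("V", "PP"), 0.15, 0),
    ],
    "NP": [
        (("Det", "N"), 0.43, 1),
        (("Det", "Adj", "N"), 0.15, 2),
        (("NP", "PP"), 0.22, 0),
        (("Pro",), 0.20, 0),
    ],
    "PP": [(("P", "NP"), 1.0, 0)],
    "SBAR": [(("C", "S"), 1.0, 1)],
}

LEXICON: dict[str, list[str]] = {
    "Det": ["the", "a", "this", "that"],
    "N": ["detective", "viewer", "story", "movie", "string", "situation",
          "friend", "morning", "victim", "suicide", "apple", "police"],
    "Adj": ["suspicious", "mundane", "successive", "strange", "quiet"],
    "Pro": ["he", "she", "they", "we", "it", "I"],
    "V": ["eats", "sees", "believes", "says", "shows", "finds", "thinks",
          "follows", "recalls", "watches"],
    "P": ["in", "of", "with", "at", "from"],
    "C": ["that", "because", "while"],
}

PRETERMINALS = frozenset(LEXICON)

#: Zipf-like frequency-per-million by within-category rank; log_frequency is
#: its natural log
_ZIPF_TOP = 30_000.0


def word_frequency(category: str, rank: int) -> float:
    return _ZIPF_TOP / (rank + 1) / (10.0 if category in ("N", "Adj", "V") else 1.0)


def _lexical_probs(n: int) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1)
    return w / w.sum()


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _default_betas() -> dict[str, float]:
    # magnitudes on the scale of the fitted encoding-model estimates
    return {
        "word_rate": 1.0,
        "n_syllables": 0.3,
        "log_frequency": 0.3,
        "surprisal": 0.5,
        "open_nodes": 0.3,
        "top_down": 0.9,
        "bottom_up": -0.35,
        "sentence_onset": -1.4,
        "sentence_offset": 1.4,
    }


def _default_slope_sd() -> dict[str, float]:
    return {"top_down": 0.3, "bottom_up": 0.3}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generative model; the defaults are the study
    conditions the pipeline is validated under.

    ``timing_model`` selects which structure-building column carries the
    ``top_down`` beta in the BOLD truth: ``standard_td`` (counts at the
    word), ``early_td`` (counts shifted one word earlier) or ``chunked``
    (head-driven chunks).
    """

    seed: int = 0
    n_participants: int = 20
    n_sentences: int = 60
    rois: tuple[str, ...] = ("BA44", "BA45", "LpMTG")
    grammar: dict = field(default_factory=lambda: DEFAULT_GRAMMAR)
    mean_length_target: float = 9.4
    min_length: int = 2
    max_length: int = 40
    max_depth: int = 60
    # timing (seconds)
    syllable_rate: float = 0.2
    pause_base: float = 0.08
    pause_td_coef: float = 0.1
    timing_noise_sd: float = 0.3
    sentence_pause_threshold: float = 1.0
    # BOLD
    tr: float = 1.5
    n_scans: int = 300
    betas: dict = field(default_factory=_default_betas)
    slope_sd: dict = field(default_factory=_default_slope_sd)
    noise_sd: float = 1.0
    ar1_rho: float = 0.3
    timing_model: str = "standard_td"

    def __post_init__(self) -> None:
        for lhs, rules in self.grammar.items():
            total = sum(p for _, p, _ in rules)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"probabilities of {lhs} rules sum to {total}")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.timing_model not in {"standard_td", "early_td", "chunked"}:
            raise ValueError(f"unknown timing_model {self.timing_model!r}")


TIMING_MODEL_COLUMN = {
    "standard_td": "top_down",
    "early_td": "early_top_down",
    "chunked": "chunked",
}


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class GrammarError(ValueError):
    """Raised when derivations fail to terminate within the depth cap."""


_LEX_CUM = {cat: np.cumsum(_lexical_probs(len(ws))) for cat, ws in LEXICON.items()}


def _sample_tree_once(
    config: SimulationConfig, rng: np.random.Generator
) -> ParseTree | None:
    grammar = config.grammar
    rule_cum = {
        lhs: np.cumsum([p for _, p, _ in rules])
        for lhs, rules in grammar.items()
    }

    def expand(symbol: str, depth: int) -> ParseTree | None:
        if depth > config.max_depth:
            return None
        if symbol in PRETERMINALS:
            words = LEXICON[symbol]
            j = int(np.searchsorted(_LEX_CUM[symbol], rng.random()))
            return ParseTree(symbol, [words[min(j, len(words) - 1)]])
        rules = grammar[symbol]
        k = int(np.searchsorted(rule_cum[symbol], rng.random()))
        rhs = rules[min(k, len(rules) - 1)][0]
        kids = []
        for sym in rhs:
            sub = expand(sym, depth + 1)
            if sub is None:
                return None
            kids.append(sub)
        return ParseTree(symbol, kids)

    return expand("S", 0)


def _percolate_heads(tree: ParseTree, config: SimulationConfig) -> DependencyParse:
    """Dependency heads by deterministic head percolation over the grammar.

    Each rule designates a head child; every other child's lexical head
    becomes a dependent of the head child's lexical head.  The sentence root
    is the main verb (head of S percolates through VP to V).
    """
    n = tree.n_terminals
    head = [0] * n

    def lexical_head(node: ParseTree) -> int:
        if node.label in PRETERMINALS:
            return node.span[0]
        rules = config.grammar[node.label]
        labels = tuple(
            c.label if isinstance(c, ParseTree) else c for c in node.children
        )
        head_idx = next(h for rhs, _, h in rules if rhs == labels)
        children = [c for c in node.children if isinstance(c, ParseTree)]
        h_word = lexical_head(children[head_idx])
        for i, c in enumerate(children):
            if i != head_idx:
                dep_word = lexical_head(c)
                head[dep_word] = h_word + 1  # CoNLL heads are 1-based
        return h_word

    root_word = lexical_head(tree)
    head[root_word] = 0
    return DependencyParse(head=head)


def sample_trees(
    config: SimulationConfig,
    n: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[tuple[ParseTree, DependencyParse]]:
    """Sample i.i.d. PCFG derivations with their dependency parses.

    Derivations exceeding the depth cap or outside the configured length
    range are resampled; persistent failure (improper grammar) raises
    :class:`GrammarError`.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = n if n is not None else config.n_sentences
    out = []
    failures = 0
    while len(out) < n:
        tree = _sample_tree_once(config, rng)
        if tree is not None:
            _assign_spans(tree, 0)
            if config.min_length <= tree.n_terminals <= config.max_length:
                tag_preterminals(tree)
                out.append((tree, _percolate_heads(tree, config)))
                continue
        failures += 1
        if failures > 50 * (n + 10):
            raise GrammarError(
                "grammar appears non-terminating or incompatible with the "
                "configured length range"
            )
    return out


# ---------------------------------------------------------------------------
# Timings
# ---------------------------------------------------------------------------

def simulate_timings(
    sentences: list[tuple[ParseTree, DependencyParse]],
    config: SimulationConfig,
    rng: np.random.Generator,
    recall_id: str = "r0",
) -> list[TokenTiming]:
    """Word onsets/offsets for one recall.

    Word duration is ``syllable_rate * n_syllables`` times mean-one lognormal
    noise; the silent pause before a word inside a sentence is
    ``pause_base * exp(pause_td_coef * top_down)`` times the same noise,
    clipped below the segmentation threshold so that pause-based segmentation
    recovers the true sentence boundaries exactly.  Inter-sentence pauses
    always exceed the threshold.
    """
    sd = config.timing_noise_sd
    mu = -0.5 * sd * sd  # mean-one lognormal

    def noise() -> float:
        return float(rng.lognormal(mu, sd))

    out: list[TokenTiming] = []
    t = 2.0  # lead-in before speech starts
    for sid, (tree, _dep) in enumerate(sentences):
        words = tree.terminals()
        td = top_down_counts(tree).values
        for w, (word, td_w) in enumerate(zip(words, td)):
            if w == 0:
                if sid > 0:
                    t += config.sentence_pause_threshold + 0.3 + float(
                        rng.exponential(0.5)
                    )
            else:
                pause = config.pause_base * np.exp(
                    config.pause_td_coef * td_w
                ) * noise()
                t += min(pause, 0.8 * config.sentence_pause_threshold)
            dur = config.syllable_rate * predictors.syllable_count(word) * noise()
            out.append(
                TokenTiming(token=word, onset=round(t, 4),
                            offset=round(t + dur, 4), sentence_id=sid,
                            recall_id=recall_id)
            )
            t += dur
    return out


# ---------------------------------------------------------------------------
# Covariates and word table
# ---------------------------------------------------------------------------

_WORD_CATEGORY: dict[str, tuple[str, int]] = {}
for _cat, _words in LEXICON.items():
    for _r, _w in enumerate(_words):
        _WORD_CATEGORY.setdefault(_w, (_cat, _r))


def covariate_table(tokens: list[str], rng: np.random.Generator) -> pd.DataFrame:
    """Per-word log frequency and toy unigram surprisal.

    Frequencies follow the fixed Zipf assignment of the lexicon; surprisal is
    the negative log of the empirical unigram probability of the token in the
    corpus at hand (a stand-in for the transformer surprisal column ingested
    with real data), plus a small lognormal context jitter.
    """
    counts: dict[str, int] = {}
    for tok in tokens:
        counts[tok] = counts.get(tok, 0) + 1
    total = float(len(tokens))
    log_freq = []
    surprisal = []
    jitter = rng.lognormal(0, 0.1, size=len(tokens))
    for tok, jit in zip(tokens, jitter):
        cat, rank = _WORD_CATEGORY.get(tok, ("N", 5))
        log_freq.append(float(np.log(word_frequency(cat, rank))))
        surprisal.append(float(-np.log(counts[tok] / total) * jit))
    return pd.DataFrame({"log_frequency": log_freq, "surprisal": surprisal})


def participant_word_table(
    config: SimulationConfig,
    rng: np.random.Generator,
    recall_id: str,
) -> tuple[pd.DataFrame, list[tuple[ParseTree, DependencyParse]]]:
    """Sample one participant's recall and assemble its word table."""
    sentences = sample_trees(config, rng=rng)
    timings = simulate_timings(sentences, config, rng, recall_id=recall_id)
    trees = [t for t, _ in sentences]
    deps = [d for _, d in sentences]
    cov = covariate_table([t.token for t in timings], rng)
    table = predictors.build_word_table(
        timings, trees, deps, covariates=cov, modality="production"
    )
    table["recall_id"] = recall_id
    return table, sentences


# ---------------------------------------------------------------------------
# BOLD forward model
# ---------------------------------------------------------------------------

def _ar1_noise(
    n: int, rho: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    eta_sd = sd * np.sqrt(max(1.0 - rho * rho, 1e-12))
    eps = np.empty(n)
    eps[0] = rng.normal(0, sd)
    innov = rng.normal(0, eta_sd, size=n - 1)
    for t in range(1, n):
        eps[t] = rho * eps[t - 1] + innov[t - 1]
    return eps


def truth_design(
    table: pd.DataFrame, config: SimulationConfig,
    spec: hrf_design.HRFSpec = hrf_design.HRFSpec(),
) -> pd.DataFrame:
    """Scan-resolution design carrying the generative predictor set.

    The structure-building column named by ``timing_model`` carries the
    ``top_down`` beta; the word-level predictors are mean-centered per recall
    before convolution, exactly as in the analysis path.
    """
    focal = TIMING_MODEL_COLUMN[config.timing_model]
    columns = tuple(
        focal if c == "top_down" else c for c in hrf_design.DEFAULT_COLUMNS
    )
    centered = predictors.mean_center(table)
    return hrf_design.build_design_matrix(
        centered, spec=spec, tr=config.tr, n_scans=config.n_scans,
        columns=columns,
    )


def simulate_bold(
    design: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    participant: str,
    slopes: dict[str, float] | None = None,
) -> tuple[list[ROITimeseries], dict[str, float]]:
    """ROI BOLD = Σ_j (β_j + b_j)·x_j + AR(1) noise, per ROI.

    ``b_j ~ N(0, slope_sd_j²)`` are the participant's random slopes (shared
    across that participant's ROIs, drawn here unless supplied); noise is
    independent across ROIs with lag-1 autocorrelation ``ar1_rho`` and
    stationary sd ``noise_sd``.
    """
    focal = TIMING_MODEL_COLUMN[config.timing_model]
    if slopes is None:
        slopes = {
            TIMING_MODEL_COLUMN[config.timing_model] if k == "top_down" else k:
                float(rng.normal(0, sd))
            for k, sd in config.slope_sd.items()
        }
    signal = np.zeros(config.n_scans)
    for col in design.columns:
        beta_key = "top_down" if col == focal else col
        beta = config.betas.get(beta_key, 0.0) + slopes.get(col, 0.0)
        signal = signal + beta * design[col].to_numpy()
    series = []
    for roi in config.rois:
        eps = _ar1_noise(config.n_scans, config.ar1_rho, config.noise_sd, rng)
        series.append(
            ROITimeseries(participant, roi, signal + eps, tr=config.tr)
        )
    return series, slopes


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------

def simulate_study(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate the whole study: per-participant recalls, designs and BOLD.

    Returns ``(long, word_tables, truth)`` where ``long`` stacks
    (participant, roi, scan) rows with the BOLD response and the participant's
    analysis design columns, ``word_tables`` stacks the word-level predictor
    tables, and ``truth`` records the generative parameters and per-
    participant random slopes.
    """
    rng = np.random.default_rng(config.seed)
    long_rows = []
    word_rows = []
    truth: dict = {
        "betas": dict(config.betas),
        "timing_model": config.timing_model,
        "slope_sd": dict(config.slope_sd),
        "noise_sd": config.noise_sd,
        "ar1_rho": config.ar1_rho,
        "participants": {},
    }
    for p in range(config.n_participants):
        pid = f"p{p:02d}"
        table, _sentences = participant_word_table(config, rng, recall_id=pid)
        table["participant"] = pid
        word_rows.append(table)
        design = truth_design(table, config)
        series, slopes = simulate_bold(design, config, rng, pid)
        truth["participants"][pid] = slopes
        for s in series:
            block = design.copy()
            block["bold"] = s.values
            block["participant"] = pid
            block["roi"] = s.roi
            block["scan"] = np.arange(config.n_scans)
            long_rows.append(block)
    long = pd.concat(long_rows, ignore_index=True)
    words = pd.concat(word_rows, ignore_index=True)
    return long, words, truth


def make_fixture_corpus(seed: int, out_dir: str | Path,
                        config: SimulationConfig | None = None) -> dict:
    """Write a small deterministic bundle in the pipeline's external formats.

    Emits ``trees.txt``, ``deps.conllu``, ``timings.tsv``, ``covariates.tsv``,
    ``bold.tsv`` and ``truth.json`` under ``out_dir``; every file loads
    through the corresponding reader.  Returns the truth record.
    """
    if config is None:
        config = SimulationConfig(seed=seed, n_participants=3, n_sentences=25,
                                  n_scans=120)
    else:
        config = replace(config, seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    all_trees, all_deps, all_tokens = [], [], []
    all_timings: list[TokenTiming] = []
    bold_series: list[ROITimeseries] = []
    cov_frames = []
    truth: dict = {
        "betas": dict(config.betas),
        "timing_model": config.timing_model,
        "slope_sd": dict(config.slope_sd),
        "noise_sd": config.noise_sd,
        "ar1_rho": config.ar1_rho,
        "seed": config.seed,
        "participants": {},
    }
    for p in range(config.n_participants):
        pid = f"p{p:02d}"
        sentences = sample_trees(config, rng=rng)
        timings = simulate_timings(sentences, config, rng, recall_id=pid)
        trees = [t for t, _ in sentences]
        deps = [d for _, d in sentences]
        cov = covariate_table([t.token for t in timings], rng)
        table = predictors.build_word_table(timings, trees, deps,
                                            covariates=cov)
        table["recall_id"] = pid
        design = truth_design(table, config)
        series, slopes = simulate_bold(design, config, rng, pid)
        truth["participants"][pid] = slopes
        all_trees.extend(trees)
        all_deps.extend(deps)
        all_tokens.extend(t.terminals() for t in trees)
        all_timings.extend(timings)
        cov["recall_id"] = pid
        cov_frames.append(cov)
        bold_series.extend(series)

    write_bracketed_trees(all_trees, out / "trees.txt")
    write_dependency(all_deps, all_tokens, out / "deps.conllu")
    write_word_timings(all_timings, out / "timings.tsv")
    pd.concat(cov_frames, ignore_index=True).to_csv(
        out / "covariates.tsv", sep="\t", index=False
    )
    write_roi_timeseries(bold_series, out / "bold.tsv")
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return truth
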