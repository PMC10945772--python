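"""Validation studies for the whole pipeline, with known generative truth.

Each function runs one self-contained study — node-count conservation and
oracle equivalence over random trees, encoding-model parameter recovery and
type-I calibration, AIC model recovery for the production-specific parsing
strategies, pause-model slope recovery, and segmentation round-trips — and
returns plain numbers.  The test suite, the numbered analysis drivers and the
results-reproduction script all call these functions, so every reported
number comes from one code path.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import hrf_design as hd
from . import predictors
from . import synthetic_data as sd
from .behavior import build_behavioral_table, fit_pause_model
from .corpus_io import segment_sentences
from .encoding_models import (
    FitResult,
    ModelSpec,
    compare_models,
    fit_mixed_model,
    prewhiten_long,
)
from .node_metrics import (
    bottom_up_counts,
    chunked_counts,
    countable_nodes,
    early_top_down_counts,
    left_corner_counts,
    open_node_counts,
    span_oracle,
    top_down_counts,
)


def _child_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Tree metric studies
# ---------------------------------------------------------------------------

def random_tree_suite(n_trees: int = 1000, seed: int = 0):
    """Random PCFG trees (2–40 words) with dependency parses."""
    cfg = sd.SimulationConfig(seed=seed, min_length=2, max_length=40)
    return sd.sample_trees(cfg, n=n_trees)


def conservation_study(trees=None, n_trees: int = 1000, seed: int = 0) -> dict:
    """Fraction of trees on which every strategy's counts sum to the
    countable-node total (all strategies distribute one fixed node count)."""
    trees = trees if trees is not None else random_tree_suite(n_trees, seed)
    ok = 0
    for tree, dep in trees:
        total = len(countable_nodes(tree))
        sums = [
            int(top_down_counts(tree).values.sum()),
            int(bottom_up_counts(tree).values.sum()),
            int(left_corner_counts(tree).values.sum()),
            int(early_top_down_counts(tree).values.sum()),
            int(chunked_counts(tree, dep).values.sum()),
        ]
        ok += all(s == total for s in sums)
    return {"n_trees": len(trees), "fraction_conserved": ok / len(trees)}


def oracle_equivalence_study(trees=None, n_trees: int = 1000, seed: int = 0) -> dict:
    """Fraction of trees where the incremental traversals exactly match the
    brute-force span-attribution oracle for all three parsing strategies."""
    trees = trees if trees is not None else random_tree_suite(n_trees, seed)
    impl = {
        "top_down": top_down_counts,
        "bottom_up": bottom_up_counts,
        "left_corner": left_corner_counts,
    }
    ok = 0
    for tree, _dep in trees:
        ok += all(
            np.array_equal(f(tree).values, span_oracle(tree, s).values)
            for s, f in impl.items()
        )
    return {"n_trees": len(trees), "fraction_matching_oracle": ok / len(trees)}


def open_nodes_study(trees=None, n_trees: int = 1000, seed: int = 0) -> dict:
    """Check the open-nodes identity cumTD − cumBU, non-negativity, and a
    zero final value, over random trees."""
    trees = trees if trees is not None else random_tree_suite(n_trees, seed)
    ok = 0
    for tree, _dep in trees:
        td = top_down_counts(tree).values
        bu = bottom_up_counts(tree).values
        op = open_node_counts(tree).values
        ok += (
            np.array_equal(op, np.cumsum(td) - np.cumsum(bu))
            and op[-1] == 0
            and (op >= 0).all()
        )
    return {"n_trees": len(trees), "fraction_valid": ok / len(trees)}


# ---------------------------------------------------------------------------
# Encoding-model studies
# ---------------------------------------------------------------------------

def _simulate_long(
    config: sd.SimulationConfig,
    analysis_columns: tuple[str, ...],
    add_null: bool = False,
) -> pd.DataFrame:
    """Per-participant: sample recall, simulate BOLD from the truth design,
    then assemble the stacked analysis table (possibly with extra candidate
    columns the truth does not contain)."""
    rng = np.random.default_rng(config.seed)
    rows = []
    for p in range(config.n_participants):
        pid = f"p{p:02d}"
        table, _ = sd.participant_word_table(config, rng, pid)
        if add_null:
            table["null_reg"] = rng.normal(size=len(table))
        centered = predictors.mean_center(table)
        truth_dm = hd.build_design_matrix(
            centered, tr=config.tr, n_scans=config.n_scans,
            columns=tuple(
                sd.TIMING_MODEL_COLUMN[config.timing_model]
                if c == "top_down" else c
                for c in hd.DEFAULT_COLUMNS
            ),
        )
        series, _slopes = sd.simulate_bold(truth_dm, config, rng, pid)
        analysis_dm = hd.build_design_matrix(
            centered, tr=config.tr, n_scans=config.n_scans,
            columns=analysis_columns,
        )
        for s in series:
            block = analysis_dm.copy()
            block["bold"] = s.values
            block["participant"] = pid
            block["roi"] = s.roi
            rows.append(block)
    return pd.concat(rows, ignore_index=True)


def fit_encoding_model(
    long: pd.DataFrame,
    fixed: tuple[str, ...],
    random: tuple[str, ...],
    focal: tuple[str, ...] = (),
    prewhiten: bool = True,
    name: str = "",
) -> FitResult:
    """Prewhiten a stacked BOLD table and fit the mixed encoding model."""
    if prewhiten:
        long = prewhiten_long(long, fixed, "bold")
    spec = ModelSpec(
        response="bold", fixed=fixed, random=random, focal=focal or random
    )
    return fit_mixed_model(long, spec, name=name)


def recovery_study(
    n_seeds: int = 100,
    seed: int = 0,
    n_participants: int = 20,
    n_scans: int = 300,
) -> dict:
    """Parameter recovery for the structure-building betas.

    Simulates the default study (β_TD = 0.9, β_BU = −0.35, random-slope sd
    0.3, AR(1) ρ = 0.3) and reports the fraction of seeds whose fitted
    estimate lies within ±3 SE of truth, plus mean estimates and bias.
    """
    hits_td = hits_bu = 0
    est_td, est_bu = [], []
    for k in range(n_seeds):
        cfg = sd.SimulationConfig(
            seed=_child_seed(seed, k),
            n_participants=n_participants,
            n_scans=n_scans,
        )
        long = _simulate_long(cfg, hd.DEFAULT_COLUMNS)
        fit = fit_encoding_model(
            long, hd.DEFAULT_COLUMNS, random=("top_down", "bottom_up")
        )
        b_td = cfg.betas["top_down"]
        b_bu = cfg.betas["bottom_up"]
        hits_td += abs(fit.params["top_down"] - b_td) <= 3 * fit.bse["top_down"]
        hits_bu += abs(fit.params["bottom_up"] - b_bu) <= 3 * fit.bse["bottom_up"]
        est_td.append(float(fit.params["top_down"]))
        est_bu.append(float(fit.params["bottom_up"]))
    return {
        "n_seeds": n_seeds,
        "coverage_top_down": hits_td / n_seeds,
        "coverage_bottom_up": hits_bu / n_seeds,
        "mean_estimate_top_down": float(np.mean(est_td)),
        "mean_estimate_bottom_up": float(np.mean(est_bu)),
        "bias_top_down": float(np.mean(est_td) - 0.9),
        "bias_bottom_up": float(np.mean(est_bu) + 0.35),
    }


def type1_study(
    n_seeds: int = 500,
    seed: int = 0,
    n_participants: int = 8,
    n_scans: int = 200,
    n_sentences: int = 40,
) -> dict:
    """Type-I calibration: rejection rate of a generatively null regressor.

    A white-noise word-level column (true beta 0) is convolved alongside the
    real predictors; the study reports how often its Wald |t| exceeds 1.96.
    Run at reduced size so many seeds fit in a desk-scale budget.
    """
    cols = hd.DEFAULT_COLUMNS + ("null_reg",)
    rejections = 0
    for k in range(n_seeds):
        cfg = sd.SimulationConfig(
            seed=_child_seed(seed, k),
            n_participants=n_participants,
            n_scans=n_scans,
            n_sentences=n_sentences,
            rois=("BA44",),
        )
        long = _simulate_long(cfg, cols, add_null=True)
        fit = fit_encoding_model(
            long, cols, random=("top_down", "bottom_up"), focal=()
        )
        rejections += abs(float(fit.tvalues["null_reg"])) >= 1.96
    return {"n_seeds": n_seeds, "type1_rate": rejections / n_seeds}


# ---------------------------------------------------------------------------
# Production-parser model selection
# ---------------------------------------------------------------------------

#: candidate structure-building regressors of the production analysis
CANDIDATES = ("top_down", "early_top_down", "chunked")

#: baseline regressors of the production models: lexical/rate covariates plus
#: the integratory bottom-up counts; the structure-building slot stays open
MODEL_SELECTION_BASE = (
    "word_rate", "n_syllables", "log_frequency", "surprisal", "bottom_up",
)


def model_selection_study(
    generating: str,
    n_seeds: int = 100,
    seed: int = 0,
    n_participants: int = 16,
    n_scans: int = 600,
    rois: tuple[str, ...] = ("BA44", "BA45", "LpMTG"),
) -> dict:
    """AIC model recovery for the production-specific parsing strategies.

    BOLD is generated with the structure-building beta on the regressor of
    ``generating`` (``standard_td``, ``early_td`` or ``chunked``) on top of
    the baseline covariates — the truth lies inside the candidate space, as a
    model-recovery design requires.  Three candidate models — each the
    baseline (word rate, syllable rate, frequency, surprisal, bottom-up) plus
    one candidate regressor and its random slope — are fit by ML and ranked
    by AIC.  Reports how often each candidate wins.
    """
    analysis_columns = tuple(dict.fromkeys(MODEL_SELECTION_BASE + CANDIDATES))
    betas = {
        c: v for c, v in sd.SimulationConfig().betas.items()
        if c in MODEL_SELECTION_BASE + ("top_down",)
    }
    wins = {c: 0 for c in CANDIDATES}
    for k in range(n_seeds):
        cfg = sd.SimulationConfig(
            seed=_child_seed(seed, k),
            n_participants=n_participants,
            n_scans=n_scans,
            rois=rois,
            timing_model=generating,
            betas=betas,
            slope_sd={"top_down": 0.3},
        )
        long = _simulate_long(cfg, analysis_columns)
        long_w = prewhiten_long(long, analysis_columns, "bold")
        fits = [
            fit_mixed_model(
                long_w,
                ModelSpec(
                    response="bold",
                    fixed=MODEL_SELECTION_BASE + (cand,),
                    random=(cand,),
                    focal=(cand,),
                    estimation="ML",
                ),
                name=cand,
            )
            for cand in CANDIDATES
        ]
        table = compare_models(fits)
        wins[str(table.iloc[0]["model"])] += 1
    out = {"n_seeds": n_seeds, "generating": generating}
    matched = sd.TIMING_MODEL_COLUMN[generating]
    for c in CANDIDATES:
        out[f"win_rate_{c}"] = wins[c] / n_seeds
    out["win_rate_matched"] = wins[matched] / n_seeds
    return out


# ---------------------------------------------------------------------------
# Behavioral studies
# ---------------------------------------------------------------------------

def behavior_recovery_study(
    gamma: float = 0.1,
    n_seeds: int = 100,
    seed: int = 0,
    n_participants: int = 10,
    n_sentences: int = 60,
) -> dict:
    """Pause-model slope recovery.

    Pauses are simulated as ``pause_base · exp(γ · top_down) · noise``; the
    log-scale mixed pause model should recover γ on the top-down coefficient.
    Reports ±3 SE coverage of γ and the detection rate (|t| ≥ 1.96), which is
    the type-I rate when γ = 0.
    """
    hits = detections = 0
    ests = []
    for k in range(n_seeds):
        cfg = sd.SimulationConfig(
            seed=_child_seed(seed, k),
            n_participants=n_participants,
            n_sentences=n_sentences,
            pause_td_coef=gamma,
        )
        rng = np.random.default_rng(cfg.seed)
        tables = []
        for p in range(cfg.n_participants):
            pid = f"p{p:02d}"
            table, _ = sd.participant_word_table(cfg, rng, pid)
            table["participant"] = pid
            tables.append(table)
        words = pd.concat(tables, ignore_index=True)
        fit = fit_pause_model(build_behavioral_table(words))
        est = float(fit.params["top_down"])
        se = float(fit.bse["top_down"])
        hits += abs(est - gamma) <= 3 * se
        detections += abs(est / se) >= 1.96
        ests.append(est)
    return {
        "n_seeds": n_seeds,
        "gamma": gamma,
        "coverage": hits / n_seeds,
        "detection_rate": detections / n_seeds,
        "mean_estimate": float(np.mean(ests)),
    }


# ---------------------------------------------------------------------------
# Segmentation round-trip
# ---------------------------------------------------------------------------

def segmentation_roundtrip_study(
    n_recalls: int = 20, seed: int = 0, n_sentences: int = 40
) -> dict:
    """Does pause-based segmentation recover the simulated boundaries?

    The timing model keeps within-sentence pauses below the threshold and
    inter-sentence pauses above it, so segmentation at the default threshold
    must reproduce the generative sentence ids exactly.
    """
    cfg = sd.SimulationConfig(seed=seed, n_sentences=n_sentences)
    rng = np.random.default_rng(cfg.seed)
    exact = 0
    for r in range(n_recalls):
        sentences = sd.sample_trees(cfg, rng=rng)
        timings = sd.simulate_timings(sentences, cfg, rng, recall_id=f"r{r}")
        stripped = [replace(t, sentence_id=0) for t in timings]
        seg = segment_sentences(stripped, cfg.sentence_pause_threshold)
        truth_ids = [t.sentence_id for t in timings]
        seg_ids = [t.sentence_id for t in seg]
        exact += seg_ids == truth_ids
    return {"n_recalls": n_recalls, "fraction_exact": exact / n_recalls}
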