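"""Speech-timing models: pause length before each word, and word duration.

Pauses are attributed to the *following* word — if structure for a word is
planned before its articulation, the planning load should surface as a longer
silence immediately before that word.  Both responses are modelled with the
same mixed-model machinery as the BOLD encoding models: six word-level
predictors (syllable count, log frequency, surprisal, top-down, bottom-up and
open node counts) with uncorrelated by-participant random slopes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .encoding_models import FitResult, ModelSpec, fit_mixed_model

logger = logging.getLogger(__name__)

PREDICTORS = (
    "n_syllables",
    "log_frequency",
    "surprisal",
    "top_down",
    "bottom_up",
    "open_nodes",
)

#: offset added before the log transform of second-scale responses (1 ms)
LOG_EPS = 1e-3


def build_behavioral_table(words: pd.DataFrame) -> pd.DataFrame:
    """Per-word pause and duration columns from a word predictor table.

    ``pause_before = onset − previous offset`` within a recall; the first word
    of each recall gets NA (it has no preceding silence) and is excluded from
    the pause model.  Overlapping words (negative gap) are clamped to a zero
    pause; the clamp count is logged.  ``duration = offset − onset``.
    """
    required = {"onset", "offset", "participant"} | set(PREDICTORS)
    missing = required - set(words.columns)
    if missing:
        raise KeyError(f"behavioral table missing columns: {sorted(missing)}")
    out = words.copy()
    group = "recall_id" if "recall_id" in out.columns else "participant"
    prev_offset = out.groupby(group)["offset"].shift(1)
    pause = out["onset"] - prev_offset
    n_clamped = int((pause < 0).sum())
    if n_clamped:
        logger.warning("%d overlapping words; pauses clamped to 0", n_clamped)
    out["pause_before"] = pause.clip(lower=0.0)
    out["duration"] = out["offset"] - out["onset"]
    if (out["duration"] <= 0).any():
        raise ValueError("non-positive word duration")
    return out


def _drop_boundary_pauses(df: pd.DataFrame) -> pd.DataFrame:
    """Remove sentence-initial words from the pause model's rows.

    The silence before a sentence-initial word is (part of) the boundary the
    pause-based segmentation was built from, not a planning pause within
    fluent speech, so it carries no information about word-level structure
    building."""
    if "sentence_onset" in df.columns:
        return df[df["sentence_onset"] == 0]
    return df


def _timing_spec(response: str, focal: str = "top_down") -> ModelSpec:
    return ModelSpec(
        response=response,
        fixed=PREDICTORS,
        random=(focal,),
        focal=(focal,),
        estimation="ML",
    )


def fit_pause_model(
    table: pd.DataFrame,
    scale: str = "log",
    focal: str = "top_down",
    include_sentence_initial: bool = False,
) -> FitResult:
    """Mixed model for the silent pause before each word.

    The response is ``log(pause + 1 ms)`` by default (``scale='raw'`` for
    seconds).  First words of a recall are always excluded (no preceding
    silence exists); sentence-initial words are excluded by default because
    their pauses are the segmentation boundaries themselves.  ``focal`` names
    the predictor whose random slope is never dropped by the convergence
    fallback.
    """
    df = table.dropna(subset=["pause_before"]).copy()
    if not include_sentence_initial:
        df = _drop_boundary_pauses(df).copy()
    if scale == "log":
        df["pause_response"] = np.log(df["pause_before"] + LOG_EPS)
    elif scale == "raw":
        df["pause_response"] = df["pause_before"]
    else:
        raise ValueError("scale must be 'log' or 'raw'")
    return fit_mixed_model(df, _timing_spec("pause_response", focal),
                           name=f"pause[{scale}]")


def fit_duration_model(
    table: pd.DataFrame, scale: str = "log", focal: str = "n_syllables"
) -> FitResult:
    """Mixed model for word duration; same fixed design as the pause model,
    only the response differs."""
    df = table.copy()
    if scale == "log":
        df["duration_response"] = np.log(df["duration"] + LOG_EPS)
    elif scale == "raw":
        df["duration_response"] = df["duration"]
    else:
        raise ValueError("scale must be 'log' or 'raw'")
    return fit_mixed_model(df, _timing_spec("duration_response", focal),
                           name=f"duration[{scale}]")
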