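"""HRF convolution and scan-resolution design-matrix assembly.

Word-level predictors become BOLD regressors by placing an impulse of the
predictor's (centered) amplitude at each word onset on a finely oversampled
grid, convolving with the canonical double-gamma hemodynamic response
function, and sampling the result at the scan times ``t_k = k * TR``
(TR = 1.5 s in the source datasets).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist


@dataclass(frozen=True)
class HRFSpec:
    """Double-gamma HRF parameters (SPM convention, seconds).

    ``h(t) = g(t; peak_delay/peak_dispersion, peak_dispersion)
           - g(t; undershoot_delay/undershoot_dispersion,
                  undershoot_dispersion) / peak_undershoot_ratio``

    with ``g`` the gamma probability density.  Defaults give a peak near 5 s
    and an undershoot around 15 s, truncated at ``kernel_length``.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_undershoot_ratio: float = 6.0
    kernel_length: float = 32.0
    oversampling_dt: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "peak_delay", "undershoot_delay", "peak_dispersion",
            "undershoot_dispersion", "peak_undershoot_ratio",
            "kernel_length", "oversampling_dt",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.kernel_length < self.undershoot_delay:
            raise ValueError("kernel_length must cover the undershoot delay")


def hrf_kernel(spec: HRFSpec = HRFSpec()) -> np.ndarray:
    """Sample the double-gamma kernel on the oversampled grid.

    Returns ``h`` at times ``np.arange(n) * spec.oversampling_dt`` covering
    ``[0, kernel_length]``; ``h(0) = 0`` and the single positive peak falls
    near ``peak_delay`` (shifted slightly earlier by the dispersion shape).
    """
    t = np.arange(0.0, spec.kernel_length + spec.oversampling_dt / 2,
                  spec.oversampling_dt)
    peak = gamma_dist.pdf(
        t, spec.peak_delay / spec.peak_dispersion, scale=spec.peak_dispersion
    )
    under = gamma_dist.pdf(
        t,
        spec.undershoot_delay / spec.undershoot_dispersion,
        scale=spec.undershoot_dispersion,
    )
    h = peak - under / spec.peak_undershoot_ratio
    return h


def hrf_kernel_derivative(spec: HRFSpec = HRFSpec()) -> np.ndarray:
    """Time derivative of the kernel on the oversampled grid."""
    h = hrf_kernel(spec)
    return np.gradient(h, spec.oversampling_dt)


def _oversampled_impulses(
    onsets: np.ndarray,
    amplitudes: np.ndarray,
    spec: HRFSpec,
    tr: float,
    n_scans: int,
) -> np.ndarray:
    run_end = n_scans * tr + spec.kernel_length
    keep = onsets < run_end
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} onsets beyond run end dropped"
        )
        onsets, amplitudes = onsets[keep], amplitudes[keep]
    if np.any(onsets < 0):
        raise ValueError("negative onsets")
    n_grid = int(np.ceil(n_scans * tr / spec.oversampling_dt)) + 1
    x = np.zeros(n_grid)
    idx = np.round(onsets / spec.oversampling_dt).astype(int)
    inside = idx < n_grid
    np.add.at(x, idx[inside], amplitudes[inside])
    return x


def _sample_at_scans(
    dense: np.ndarray, spec: HRFSpec, tr: float, n_scans: int
) -> np.ndarray:
    step = tr / spec.oversampling_dt
    idx = np.round(np.arange(n_scans) * step).astype(int)
    idx = np.clip(idx, 0, len(dense) - 1)
    return dense[idx]


def convolve_events(
    onsets,
    amplitudes,
    spec: HRFSpec = HRFSpec(),
    tr: float = 1.5,
    n_scans: int = 0,
    kernel: np.ndarray | None = None,
) -> np.ndarray:
    """Impulses at word onsets, convolved with the HRF, sampled at scan times.

    Linear in the amplitudes.  ``kernel`` overrides the double-gamma (used
    for temporal-derivative columns).
    """
    onsets = np.asarray(onsets, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if onsets.shape != amplitudes.shape:
        raise ValueError("onsets and amplitudes must have equal length")
    if n_scans <= 0:
        raise ValueError("n_scans must be positive")
    x = _oversampled_impulses(onsets, amplitudes, spec, tr, n_scans)
    h = hrf_kernel(spec) if kernel is None else kernel
    dense = np.convolve(x, h)[: len(x)]
    return _sample_at_scans(dense, spec, tr, n_scans)


def orthogonalize(column: np.ndarray, against: np.ndarray) -> np.ndarray:
    """Residualize ``column`` on ``against`` (least squares)."""
    denom = float(against @ against)
    if denom == 0.0:
        return column.copy()
    return column - (column @ against) / denom * against


def temporal_derivative(
    onsets,
    amplitudes,
    parent: np.ndarray,
    spec: HRFSpec = HRFSpec(),
    tr: float = 1.5,
    n_scans: int = 0,
) -> np.ndarray:
    """Derivative regressor for a parent column, orthogonalized against it.

    Convolves the same impulses with the kernel's time derivative, then
    removes the component collinear with the parent so the parent's beta
    keeps its interpretation; captures small latency shifts of the response.
    """
    deriv = convolve_events(
        onsets, amplitudes, spec, tr, n_scans,
        kernel=hrf_kernel_derivative(spec),
    )
    return orthogonalize(deriv, parent)


#: design columns required from the word table, in output order
DEFAULT_COLUMNS = (
    "word_rate",
    "n_syllables",
    "log_frequency",
    "surprisal",
    "open_nodes",
    "top_down",
    "bottom_up",
    "sentence_onset",
    "sentence_offset",
)



def build_design_matrix(
    table: pd.DataFrame,
    spec: HRFSpec = HRFSpec(),
    tr: float = 1.5,
    n_scans: int = 0,
    columns: tuple[str, ...] = DEFAULT_COLUMNS,
    derivatives: bool = False,
) -> pd.DataFrame:
    """Scan-resolution design matrix from a (centered) word predictor table.

    Each regressor places the word's predictor value (1 for the word-rate and
    boundary indicators) as an impulse at the word onset and convolves with
    the HRF.  ``derivatives`` appends an orthogonalized temporal-derivative
    column per regressor.  Deterministic: identical inputs give identical
    output.
    """
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise KeyError(f"word table missing design columns: {missing}")
    onsets = table["onset"].to_numpy(dtype=float)
    out: dict[str, np.ndarray] = {}
    for c in columns:
        # impulse/indicator columns (word_rate, boundaries) are uncentered
        # 0/1 values, so the column itself is the impulse amplitude
        amp = table[c].to_numpy(dtype=float)
        out[c] = convolve_events(onsets, amp, spec, tr, n_scans)
        if derivatives:
            out[c + "_derivative"] = temporal_derivative(
                onsets, amp, out[c], spec, tr, n_scans
            )
    dm = pd.DataFrame(out)
    dm.attrs["tr"] = tr
    dm.attrs["hrf"] = spec
    return dm


def collinearity_report(
    dm: pd.DataFrame, threshold: float = 0.7
) -> pd.DataFrame:
    """Pairwise Pearson correlations between design columns.

    Flags pairs with ``|r|`` above ``threshold``; a zero-variance column
    yields NA correlations.  Used as the diagnostic behind fitting the highly
    correlated structure-building regressors in separate models.
    """
    cols = list(dm.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 columns")
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            x, y = dm[a].to_numpy(), dm[b].to_numpy()
            if x.std() == 0 or y.std() == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            rows.append(
                {
                    "col_a": a,
                    "col_b": b,
                    "r": r,
                    "flagged": bool(abs(r) > threshold) if np.isfinite(r) else False,
                }
            )
    return pd.DataFrame(rows)
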