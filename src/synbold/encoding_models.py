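"""Linear mixed-effects encoding models for ROI BOLD.

Scan-resolution design-matrix columns predict ROI-averaged BOLD in a long
table stacked over participants, ROIs and scans.  Categorical factors are
contrast-coded (deviation coding for modality, Helmert coding for ROI), fixed
terms may interact with them, and by-participant random slopes are modelled
as *uncorrelated* variance components (no random correlations), mirroring the
lme4 structure ``(0 + slope || participant)``.  Models are compared with AIC
and, when nested, likelihood-ratio tests; per-term Wald chi-square tests and
pairwise cell contrasts complete the inference toolkit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

# -- factor coding -----------------------------------------------------------

#: deviation coding: the interaction coefficient with a +/- 1/2 coded factor
#: equals the between-level slope difference
MODALITY_CODES = {"production": 0.5, "comprehension": -0.5}

#: Helmert coding for ROI: (BA44+BA45) vs LpMTG, then BA44 vs BA45
ROI_CODES = {
    "BA44": {"roi_h1": 0.5, "roi_h2": 0.5},
    "BA45": {"roi_h1": 0.5, "roi_h2": -0.5},
    "LpMTG": {"roi_h1": -1.0, "roi_h2": 0.0},
}

FACTOR_COLUMNS = {"modality": ["modality_dev"], "roi": ["roi_h1", "roi_h2"]}


class CodingError(ValueError):
    """Unknown factor level."""


def code_factors(
    modality: pd.Series | None = None, roi: pd.Series | None = None
) -> pd.DataFrame:
    """Numeric contrast codes for the modality and ROI factors.

    Modality is deviation-coded ±1/2 (production positive); ROI gets two
    orthogonal zero-sum Helmert columns contrasting LIFG (BA44+BA45) with
    LpMTG, and the two LIFG parcels with each other.
    """
    out = {}
    if modality is not None:
        bad = set(modality.unique()) - set(MODALITY_CODES)
        if bad:
            raise CodingError(f"unknown modality levels: {sorted(bad)}")
        out["modality_dev"] = modality.map(MODALITY_CODES).astype(float)
    if roi is not None:
        bad = set(roi.unique()) - set(ROI_CODES)
        if bad:
            raise CodingError(f"unknown ROI levels: {sorted(bad)}")
        for col in ("roi_h1", "roi_h2"):
            out[col] = roi.map(lambda lv: ROI_CODES[lv][col]).astype(float)
    return pd.DataFrame(out, index=(modality if modality is not None else roi).index)


# -- model specification -----------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Specification of one mixed encoding model.

    ``fixed`` lists terms: a plain column name, a factor name ("modality",
    "roi"), or an interaction joined with ":" (e.g. "top_down:modality:roi").
    ``random`` lists continuous columns receiving by-participant uncorrelated
    random slopes.  ``focal`` random slopes are never dropped by the
    convergence fallback.  ``estimation`` is "ML" (required for AIC/LRT
    comparison) or "REML".
    """

    response: str = "bold"
    fixed: tuple[str, ...] = ()
    random: tuple[str, ...] = ()
    focal: tuple[str, ...] = ()
    estimation: str = "ML"
    groups: str = "participant"

    def __post_init__(self) -> None:
        if self.estimation not in {"ML", "REML"}:
            raise ValueError("estimation must be 'ML' or 'REML'")


@dataclass
class FitResult:
    """Fitted mixed-model summary.

    ``terms`` maps each fixed term to the design-column names of its
    coefficient block; ``vcomp`` holds the random-slope variances.  ``aic``
    is ``2k − 2·logLik`` with ``k`` counting fixed effects, variance
    components and the residual variance.  t statistics use a normal
    approximation (n per participant is large).
    """

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    cov: pd.DataFrame
    terms: dict[str, list[str]]
    vcomp: dict[str, float]
    resid_var: float
    llf: float
    aic: float
    n_obs: int
    k_params: int
    converged: bool
    estimation: str
    spec: ModelSpec
    dropped_slopes: list[str] = field(default_factory=list)
    name: str = ""

    def pvalue(self, col: str) -> float:
        return float(2 * stats.norm.sf(abs(self.tvalues[col])))


def _expand_base(name: str) -> list[str]:
    return FACTOR_COLUMNS.get(name, [name])


def _term_columns(term: str) -> list[str]:
    """Design columns for a (possibly interaction) term."""
    parts = term.split(":")
    expanded = [_expand_base(p) for p in parts]
    return [":".join(combo) for combo in product(*expanded)]


def build_fixed_design(data: pd.DataFrame, fixed: tuple[str, ...]):
    """Expand fixed terms into a numeric design with an intercept.

    Factors must already be coded (``modality_dev``, ``roi_h1``, ``roi_h2``
    present); interaction columns are elementwise products of their parts.
    Returns (X DataFrame, term → columns mapping).
    """
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(data))}
    terms: dict[str, list[str]] = {"Intercept": ["Intercept"]}
    for term in fixed:
        names = _term_columns(term)
        terms[term] = names
        for name in names:
            parts = name.split(":")
            x = np.ones(len(data))
            for p in parts:
                if p not in data.columns:
                    raise KeyError(f"design column {p!r} not in data")
                x = x * data[p].to_numpy(dtype=float)
            cols[name] = x
    X = pd.DataFrame(cols, index=data.index)
    # rank check: name the aliased columns
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X.to_numpy())
        aliased = [
            X.columns[i] for i in range(X.shape[1])
            if abs(r[min(i, r.shape[0] - 1), i]) < 1e-8
        ]
        raise ValueError(f"rank-deficient fixed design; aliased: {aliased}")
    return X, terms


def _prepare(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    df = data.copy()
    needs_modality = any("modality" in t.split(":") for t in spec.fixed)
    needs_roi = any("roi" in t.split(":") for t in spec.fixed)
    if needs_modality or needs_roi:
        coded = code_factors(
            df["modality"] if needs_modality else None,
            df["roi"] if needs_roi else None,
        )
        for c in coded.columns:
            df[c] = coded[c]
    return df


def estimate_ar1(resid: np.ndarray) -> float:
    """Lag-1 autocorrelation of a residual series."""
    r = resid - resid.mean()
    denom = float(r @ r)
    if denom == 0.0:
        return 0.0
    return float(r[1:] @ r[:-1] / denom)


def _ar1_whiten(Z: np.ndarray, rho: float) -> np.ndarray:
    W = Z.copy().astype(float)
    W[1:] = Z[1:] - rho * Z[:-1]
    W[0] = Z[0] * np.sqrt(1.0 - rho * rho)
    return W


def reml_ar1(
    X: np.ndarray, y: np.ndarray, grid: np.ndarray | None = None
) -> float:
    """REML estimate of the lag-1 autoregressive residual parameter.

    Profiles the restricted likelihood of ``y ~ N(Xβ, σ²·AR1(ρ))`` over a ρ
    grid.  REML matters here: HRF-convolved regressors are smooth, so plug-in
    residual autocorrelation is biased low (the fit absorbs part of the
    autocorrelated noise), while the REML profile corrects for estimating β.
    """
    if grid is None:
        grid = np.linspace(-0.2, 0.9, 23)
    n, p = X.shape

    def crit(rho: float) -> float:
        Xw = _ar1_whiten(X, rho)
        yw = _ar1_whiten(y, rho)
        q, r = np.linalg.qr(Xw)
        resid = yw - q @ (q.T @ yw)
        rss = float(resid @ resid)
        if rss <= 0:
            return np.inf
        return (
            (n - p) * np.log(rss)
            - np.log(1.0 - rho * rho)
            + 2.0 * float(np.sum(np.log(np.abs(np.diag(r)))))
        )

    values = np.array([crit(r) for r in grid])
    j = int(np.argmin(values))
    best = float(grid[j])
    # parabolic refinement between the best grid point's neighbours
    if 0 < j < len(grid) - 1 and np.isfinite(values[j - 1 : j + 2]).all():
        c_l, c_m, c_r = values[j - 1 : j + 2]
        denom = c_l - 2 * c_m + c_r
        if denom > 0:
            step = float(grid[1] - grid[0])
            best += 0.5 * step * (c_l - c_r) / denom
    return float(np.clip(best, grid[0], grid[-1]))


def prewhiten_long(
    data: pd.DataFrame,
    columns: tuple[str, ...],
    response: str,
    series_keys: tuple[str, ...] = ("participant", "roi"),
) -> pd.DataFrame:
    """AR(1) prewhitening of a stacked (participant, roi, scan) table.

    Within each BOLD series, ρ is estimated by REML (see :func:`reml_ar1`)
    and response plus design columns are transformed as ``z_t − ρ̂ z_{t−1}``
    (first scan scaled by ``sqrt(1 − ρ̂²)``).  Standard fMRI practice:
    without it, smooth HRF-convolved regressors against autocorrelated noise
    understate the fixed-effect standard errors.
    """
    keys = [k for k in series_keys if k in data.columns]
    out = data.copy()
    cols = [c for c in columns if c in out.columns] + [response]
    for _, idx in out.groupby(keys, sort=False).groups.items():
        block = out.loc[idx, cols].to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(block)), block[:, :-1]])
        y = block[:, -1]
        rho = reml_ar1(X, y)
        out.loc[idx, cols] = _ar1_whiten(block, rho)
    return out


def fit_mixed_model(
    data: pd.DataFrame, spec: ModelSpec, name: str = ""
) -> FitResult:
    """Fit one mixed encoding model.

    On non-convergence (or singular random-effect covariance) the weakest
    non-focal random slope — smallest estimated variance — is dropped and the
    model refit; drops are recorded in ``dropped_slopes``.  A model that
    still fails returns with ``converged=False`` rather than raising.
    """
    df = _prepare(data, spec)
    if df[spec.response].isna().any():
        raise ValueError("missing values in response")
    X, terms = build_fixed_design(df, spec.fixed)
    y = df[spec.response].to_numpy(dtype=float)
    groups = df[spec.groups]
    reml = spec.estimation == "REML"

    def _fit_once(random_now: list[str]):
        """Fit with the given random-slope set; empty set reduces to OLS."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if not random_now:
                return _OLSAdapter(sm.OLS(y, X).fit())
            vc_mats = {
                c: df[[c]].rename(columns={c: f"vc_{c}"}) for c in random_now
            }
            m = sm.MixedLM(y, X, groups=groups,
                           exog_vc=_vcspec(vc_mats, groups))
            best = None
            # quasi-Newton can stall near the variance boundary and reports
            # non-convergence; fall back to the slower simplex-style search
            # and keep the better likelihood
            for method in ("bfgs", "powell"):
                try:
                    cand = m.fit(reml=reml, method=method, maxiter=500)
                except Exception:
                    continue
                if best is None or (
                    np.isfinite(cand.llf) and cand.llf > best.llf + 1e-6
                ):
                    best = cand
                if best is not None and best.converged:
                    break
            return best

    random = list(spec.random)
    dropped: list[str] = []
    while True:
        result = _fit_once(random)
        if (result is not None and bool(result.converged)) or not random:
            break
        droppable = [c for c in random if c not in spec.focal]
        if not droppable:
            break
        if result is not None and len(result.vcomp):
            order = np.argsort(np.asarray(result.vcomp))
            by_weakness = [random[i] for i in order]
            victim = next(c for c in by_weakness if c in droppable)
        else:
            victim = droppable[-1]
        random.remove(victim)
        dropped.append(victim)

    if result is None:
        raise RuntimeError("mixed model could not be evaluated")

    # Singular-fit handling: a variance component estimated at (or pinned
    # just off) the zero boundary still inflates fixed-effect SEs, making
    # Wald tests conservative.  When a component is negligible relative to
    # the residual variance, compare by AIC against the model without it and
    # keep the better model — the same random-structure simplification
    # applied in practice when lme4 reports a singular fit.
    changed = True
    while changed and random:
        changed = False
        vcomp_now = dict(zip(random, np.asarray(result.vcomp, dtype=float)))
        tiny = [c for c, v in vcomp_now.items()
                if v < 1e-2 * float(result.scale)]
        for victim in tiny:
            reduced = [c for c in random if c != victim]
            cand = _fit_once(reduced)
            # dropping one variance parameter: keep the smaller model unless
            # the likelihood loss exceeds the AIC break-even of 1
            if cand is not None and (result.llf - cand.llf) < 1.0:
                random = reduced
                dropped.append(victim)
                result = cand
                changed = True
                break

    vcomp = dict(zip(random, np.asarray(result.vcomp, dtype=float)))
    k = X.shape[1] + len(result.vcomp) + result.k_re * (result.k_re + 1) // 2 + 1
    llf = float(result.llf)
    fe = result.fe_params
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cov_full = np.asarray(result.cov_params())
    cov = pd.DataFrame(
        cov_full[: len(fe), : len(fe)], index=fe.index, columns=fe.index
    )
    bse = np.sqrt(np.clip(np.diag(cov.to_numpy()), 1e-300, None))
    return FitResult(
        params=pd.Series(fe, index=fe.index, dtype=float),
        bse=pd.Series(bse, index=fe.index, dtype=float),
        tvalues=pd.Series(np.asarray(fe) / bse, index=fe.index),
        cov=cov,
        terms=terms,
        vcomp=vcomp,
        resid_var=float(result.scale),
        llf=llf,
        aic=2 * k - 2 * llf,
        n_obs=len(y),
        k_params=k,
        converged=bool(result.converged),
        estimation=spec.estimation,
        spec=spec,
        dropped_slopes=dropped,
        name=name or spec.response,
    )


class _OLSAdapter:
    """Presents an OLS fit through the slice of the MixedLM results API that
    :func:`fit_mixed_model` consumes (the zero-random-effects limit)."""

    def __init__(self, res):
        self._res = res
        self.fe_params = res.params
        self.vcomp = np.empty(0)
        self.k_re = 0
        self.converged = True
        n = int(res.nobs)
        # ML residual variance and the matching Gaussian log-likelihood
        self.scale = float(res.ssr / n)
        self.llf = float(res.llf)

    def cov_params(self):
        # OLS cov uses the unbiased variance; rescale to the ML variance for
        # comparability with the MixedLM path
        factor = self.scale / float(self._res.mse_resid)
        return np.asarray(self._res.cov_params()) * factor


def _vcspec(vc_mats: dict[str, pd.DataFrame], groups: pd.Series):
    """Assemble a statsmodels VCSpec: one iid variance component per slope."""
    from statsmodels.regression.mixed_linear_model import VCSpec

    names = list(vc_mats)
    # statsmodels orders groups by sorted label; the component matrices must
    # follow the same order
    labels = sorted(set(groups))
    colnames, mats = [], []
    for nm in names:
        colnames.append([[nm] for _ in labels])
        mats.append(
            [vc_mats[nm].loc[groups == g].to_numpy() for g in labels]
        )
    return VCSpec(names, colnames, mats)


# -- inference ---------------------------------------------------------------

def wald_tests(fit: FitResult, include_intercept: bool = False) -> pd.DataFrame:
    """Wald chi-square test per fixed term (coefficient blocks jointly).

    For a single-coefficient term the statistic equals t².  Singular
    covariance blocks yield NA with a warning.
    """
    rows = []
    for term, cols in fit.terms.items():
        if term == "Intercept" and not include_intercept:
            continue
        b = fit.params[cols].to_numpy()
        V = fit.cov.loc[cols, cols].to_numpy()
        try:
            stat = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError:
            warnings.warn(f"singular covariance block for term {term!r}")
            rows.append({"term": term, "chi2": np.nan, "df": len(cols),
                         "p": np.nan})
            continue
        df = len(cols)
        rows.append(
            {
                "term": term,
                "chi2": stat,
                "df": df,
                "p": float(stats.chi2.sf(stat, df)),
            }
        )
    return pd.DataFrame(rows)


def _cell_vector(fit: FitResult, term: str, cell: dict[str, str]) -> np.ndarray:
    """Contrast vector giving the slope of ``term`` in a factor cell."""
    idx = {c: i for i, c in enumerate(fit.params.index)}
    vec = np.zeros(len(idx))
    codes = {}
    if "modality" in cell:
        codes["modality_dev"] = MODALITY_CODES[cell["modality"]]
    if "roi" in cell:
        codes.update(ROI_CODES[cell["roi"]])
    for name, i in idx.items():
        parts = name.split(":")
        if term not in parts:
            continue
        others = [p for p in parts if p != term]
        if any(p not in codes for p in others):
            continue  # involves a factor not in this family
        w = 1.0
        for p in others:
            w *= codes[p]
        vec[i] = w
    return vec


def pairwise_contrasts(
    fit: FitResult,
    term: str,
    by: str,
    adjust: str = "tukey",
) -> pd.DataFrame:
    """Per-cell slopes of ``term`` across levels of factor ``by``, and all
    pairwise cell differences with multiplicity-adjusted p values.

    With ±1/2 deviation coding the production−comprehension difference equals
    the ``term:modality`` interaction coefficient.  Adjustment: Tukey via the
    studentized range over the family of cells (default), or "none".
    """
    levels = {"modality": list(MODALITY_CODES), "roi": list(ROI_CODES)}[by]
    vecs = {lv: _cell_vector(fit, term, {by: lv}) for lv in levels}
    params = fit.params.to_numpy()
    V = fit.cov.to_numpy()
    rows = []
    for lv in levels:
        c = vecs[lv]
        est = float(c @ params)
        se = float(np.sqrt(c @ V @ c))
        rows.append({"kind": "cell", "contrast": lv, "estimate": est,
                     "se": se, "p": float(2 * stats.norm.sf(abs(est / se)))})
    k = len(levels)
    for a, b in combinations(levels, 2):
        c = vecs[a] - vecs[b]
        est = float(c @ params)
        se = float(np.sqrt(c @ V @ c))
        z = est / se
        if adjust == "tukey" and k > 2:
            p = float(stats.studentized_range.sf(abs(z) * np.sqrt(2), k, np.inf))
        elif adjust in {"tukey", "none"}:
            p = float(2 * stats.norm.sf(abs(z)))
        else:
            raise ValueError("adjust must be 'tukey' or 'none'")
        rows.append({"kind": "difference", "contrast": f"{a} - {b}",
                     "estimate": est, "se": se, "p": p})
    return pd.DataFrame(rows)


# -- model comparison --------------------------------------------------------

def _is_nested(small: FitResult, big: FitResult) -> bool:
    cols_small = set(small.params.index)
    cols_big = set(big.params.index)
    vc_small = set(small.vcomp)
    vc_big = set(big.vcomp)
    return cols_small <= cols_big and vc_small <= vc_big and (
        small.k_params < big.k_params
    )


def likelihood_ratio_test(small: FitResult, big: FitResult) -> dict:
    """LRT between nested ML fits on the same observations."""
    for f in (small, big):
        if f.estimation != "ML":
            raise ValueError("likelihood-ratio tests require ML fits")
    if small.n_obs != big.n_obs:
        raise ValueError("fits are on different observation sets")
    if not _is_nested(small, big):
        raise ValueError("models are not nested")
    chi2 = max(0.0, 2 * (big.llf - small.llf))
    df = big.k_params - small.k_params
    return {
        "chi2": chi2,
        "df": df,
        "p": float(stats.chi2.sf(chi2, df)) if df > 0 else np.nan,
    }


def compare_models(fits: list[FitResult]) -> pd.DataFrame:
    """AIC ranking of candidate fits, with LRTs against the best where nested.

    All fits must share the response and observation count; REML fits with
    different fixed structures are refused.
    """
    n0 = fits[0].n_obs
    if any(f.n_obs != n0 for f in fits):
        raise ValueError("fits have differing n_obs; comparison refused")
    if any(f.estimation == "REML" for f in fits):
        structs = {tuple(f.params.index) for f in fits}
        if len(structs) > 1:
            raise ValueError(
                "REML fits with different fixed effects cannot be compared"
            )
    rows = []
    best = min(fits, key=lambda f: f.aic)
    for f in fits:
        row = {
            "model": f.name,
            "aic": f.aic,
            "delta_aic": f.aic - best.aic,
            "llf": f.llf,
            "k": f.k_params,
            "converged": f.converged,
        }
        row["lrt_chi2"] = row["lrt_df"] = row["lrt_p"] = np.nan
        if f is not best and f.estimation == "ML" and best.estimation == "ML":
            try:
                lrt = likelihood_ratio_test(f, best)
                row.update(
                    lrt_chi2=lrt["chi2"], lrt_df=lrt["df"], lrt_p=lrt["p"]
                )
            except ValueError:
                pass
        rows.append(row)
    return pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
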