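"""Statistical workflow for freezing and photometry summaries.

Freezing percentages are positive, right-skewed measurements, so the
multivariable model is a gamma GLM with a log link (multiplicative
group/epoch effects on a strictly positive mean), with planned
comparisons as Wald contrasts on the linear predictor and
Benjamini–Hochberg FDR correction across the contrast family.
Univariate comparisons use Kruskal–Wallis and Mann–Whitney; normality
and homoscedasticity checks use Kolmogorov–Smirnov (against a normal
with estimated moments; optionally the Lilliefors small-sample
correction) and Levene's test (median-centred).

Implementation notes: the GLM is fit by IRLS via statsmodels with
t-based Wald inference (dispersion estimated by Pearson chi-square);
KW/MW/KS/Levene come from scipy.stats; FDR from statsmodels
``multipletests``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateFitError, InvalidParameterError

logger = logging.getLogger(__name__)

GAMMA_LOG = sm.families.Gamma(sm.families.links.Log())


@dataclass(frozen=True)
class TestResult:
    """One hypothesis test: statistic, raw p, optional FDR-adjusted p."""

    name: str
    statistic: float
    p_value: float
    adjusted_p: float | None = None
    df: float | None = None

    @property
    def significant(self) -> bool:
        """p (adjusted when available) below the conventional 0.05."""
        p = self.adjusted_p if self.adjusted_p is not None else self.p_value
        return p < 0.05


@dataclass(frozen=True)
class GroupedMeasurements:
    """Tidy positive measurements with factor labels and an animal id.

    ``data`` must contain a strictly positive ``value`` column when used
    with the gamma GLM; factor columns (e.g. group, epoch) and
    ``animal_id`` identify the design.
    """

    data: pd.DataFrame
    value_col: str = "value"

    def __post_init__(self) -> None:
        if self.value_col not in self.data.columns:
            raise InvalidParameterError(f"missing value column {self.value_col!r}")

    def require_positive(self, zero_offset: float | None = None) -> pd.DataFrame:
        """Return data with strictly positive values, applying an offset to zeros.

        A configurable small offset replaces exact zeros (logged); zeros
        with no offset are a domain error for the gamma likelihood.
        """
        df = self.data.copy()
        v = df[self.value_col].to_numpy(float)
        if np.any(v < 0):
            raise InvalidParameterError("negative values are outside the gamma domain")
        zeros = v == 0
        if zeros.any():
            if zero_offset is None:
                raise InvalidParameterError(
                    f"{zeros.sum()} zero value(s); pass zero_offset to shift them"
                )
            logger.info("offsetting %d zero value(s) by %g", zeros.sum(), zero_offset)
            v = v + zeros * zero_offset
            df[self.value_col] = v
        return df


def check_assumptions(
    groups: dict[str, np.ndarray], method: str = "ks"
) -> dict:
    """Normality (KS) and homoscedasticity (Levene) checks per the workflow.

    ``method='ks'`` runs a one-sample KS test per group against a normal
    with that group's estimated mean and sd — the common practice, but
    anti-conservative because the parameters are estimated from the same
    sample; ``method='lilliefors'`` applies the Lilliefors correction.
    Levene's test is median-centred (Brown–Forsythe).
    """
    if method not in ("ks", "lilliefors"):
        raise InvalidParameterError(f"method must be 'ks' or 'lilliefors', got {method!r}")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if len(arr) < 3:
            raise InvalidParameterError(f"group {name!r} has fewer than 3 values")
        if np.std(arr) == 0:
            raise DegenerateFitError(f"group {name!r} has zero variance")
    normality = {}
    if method == "ks":
        logger.info(
            "KS normality test uses estimated moments; p-values are anti-conservative"
        )
        for name, arr in arrays.items():
            res = sps.kstest(arr, "norm", args=(arr.mean(), arr.std(ddof=1)))
            normality[name] = float(res.pvalue)
    else:
        from statsmodels.stats.diagnostic import lilliefors

        for name, arr in arrays.items():
            normality[name] = float(lilliefors(arr, dist="norm")[1])
    lev_stat, lev_p = sps.levene(*arrays.values(), center="median")
    return {
        "normality_p": normality,
        "homoscedasticity_p": float(lev_p),
        "levene_statistic": float(lev_stat),
        "method": method,
    }


def select_glm_family(
    values: np.ndarray,
    candidates: tuple[str, ...] = ("gamma", "gaussian", "inverse_gaussian"),
) -> dict:
    """Goodness-of-fit family selection for an intercept-only GLM.

    Fits each candidate family (log link for the positive families) and
    picks the lowest AIC.  Returns the choice and all scores.
    """
    if not candidates:
        raise InvalidParameterError("need at least one candidate family")
    fams = {
        "gamma": sm.families.Gamma(sm.families.links.Log()),
        "gaussian": sm.families.Gaussian(),
        "inverse_gaussian": sm.families.InverseGaussian(sm.families.links.Log()),
    }
    v = np.asarray(values, dtype=float)
    scores: dict[str, float] = {}
    for name in candidates:
        if name not in fams:
            raise InvalidParameterError(f"unknown family {name!r}")
        try:
            res = sm.GLM(v, np.ones((len(v), 1)), family=fams[name]).fit()
            scores[name] = float(res.aic)
        except Exception as exc:  # a family can fail on its domain
            logger.warning("family %s failed to fit: %s", name, exc)
            scores[name] = np.inf
    best = min(scores, key=scores.get)
    return {"family": best, "aic": scores}


def gamma_glm_contrasts(
    data: "pd.DataFrame | GroupedMeasurements",
    contrasts: "list[tuple[str, str]] | list[str]",
    formula: str = "value ~ C(group) * C(epoch)",
    zero_offset: float | None = None,
) -> list[TestResult]:
    """Gamma(log) GLM with planned Wald contrasts, BH-corrected jointly.

    ``contrasts`` is a list of constraint strings in statsmodels/patsy
    syntax (e.g. ``"C(epoch)[T.ON] = 0"``), optionally as (name,
    constraint) pairs.  Each contrast is a Wald t-test on the linear
    predictor; the family of contrast p-values is adjusted together by
    Benjamini–Hochberg.
    """
    gm = data if isinstance(data, GroupedMeasurements) else GroupedMeasurements(data)
    df = gm.require_positive(zero_offset)
    model = smf.glm(formula, df, family=GAMMA_LOG)
    res = model.fit(use_t=True)
    if not res.converged:
        raise DegenerateFitError(
            f"gamma GLM did not converge (deviance {res.deviance:.3g})"
        )
    named = [c if isinstance(c, tuple) else (c, c) for c in contrasts]
    raw: list[tuple[str, float, float]] = []
    for name, constraint in named:
        tt = res.t_test(constraint)
        raw.append((name, float(np.squeeze(tt.statistic)), float(np.squeeze(tt.pvalue))))
    adjusted = bh_fdr([p for _, _, p in raw])
    return [
        TestResult(name, stat, p, adj, df=float(res.df_resid))
        for (name, stat, p), adj in zip(raw, adjusted)
    ]


def _fit_on_off(values_off: np.ndarray, values_on: np.ndarray) -> float:
    """Wald p-value of the ON effect in a gamma(log) GLM, array fast path.

    Builds the two-column design (intercept, ON indicator) directly,
    bypassing the formula layer; equivalent to ``gamma_glm_contrasts``
    with ``value ~ C(epoch)`` and the ``C(epoch)[T.ON]`` contrast (a
    unit test asserts the equivalence).
    """
    y = np.concatenate([values_off, values_on])
    x = np.column_stack(
        [np.ones(len(y)), np.r_[np.zeros(len(values_off)), np.ones(len(values_on))]]
    )
    res = sm.GLM(y, x, family=GAMMA_LOG).fit(use_t=True)
    return float(res.pvalues[1])


def on_off_rejection_rate(
    n_per_group: int,
    effect: float,
    n_sims: int,
    seed: int,
    off_mean: float = 15.0,
    shape: float = 3.0,
    alpha: float = 0.05,
) -> float:
    """Monte-Carlo rejection rate of the ON–OFF gamma-GLM contrast.

    Draws independent gamma freezing percentages for OFF (mean
    ``off_mean``) and ON (mean ``effect * off_mean``) epochs,
    ``n_per_group`` animals per epoch, and reports the fraction of
    replicates whose Wald contrast p-value falls below ``alpha``.  With
    ``effect=1`` this measures the type-I error; with ``effect>1`` the
    power.
    """
    if n_per_group < 2 or n_sims < 1:
        raise InvalidParameterError("need n_per_group >= 2 and n_sims >= 1")
    if shape <= 0 or off_mean <= 0 or effect <= 0:
        raise InvalidParameterError("shape, off_mean and effect must be > 0")
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        off = rng.gamma(shape, off_mean / shape, n_per_group)
        on = rng.gamma(shape, effect * off_mean / shape, n_per_group)
        if _fit_on_off(off, on) < alpha:
            rejections += 1
    return rejections / n_sims


def kruskal_wallis(groups: "list[np.ndarray] | dict[str, np.ndarray]") -> TestResult:
    """Kruskal–Wallis H test (tie-corrected, chi-square approximation)."""
    arrays = list(groups.values()) if isinstance(groups, dict) else list(groups)
    if len(arrays) < 2 or any(len(a) == 0 for a in arrays):
        raise InvalidParameterError("need >= 2 nonempty groups")
    flat = np.concatenate([np.asarray(a, dtype=float) for a in arrays])
    if np.ptp(flat) == 0:
        raise DegenerateFitError("all values identical; ranks are degenerate")
    stat, p = sps.kruskal(*arrays)
    return TestResult("kruskal_wallis", float(stat), float(p), df=float(len(arrays) - 1))


def mann_whitney(
    a: np.ndarray, b: np.ndarray, alternative: str = "two-sided"
) -> TestResult:
    """Mann–Whitney U test; exact p for small tie-free samples, else normal approx.

    The reported statistic is U for the first sample; swapping the
    samples maps U to ``n_a * n_b - U``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise InvalidParameterError("both samples must be nonempty")
    res = sps.mannwhitneyu(a, b, alternative=alternative, method="auto")
    return TestResult(f"mann_whitney_{alternative}", float(res.statistic), float(res.pvalue))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def results_to_frame(results: list[TestResult]) -> pd.DataFrame:
    """Flat results table: contrast, statistic, p, adjusted_p, significance."""
    return pd.DataFrame(
        {
            "contrast": [r.name for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
            "adjusted_p": [r.adjusted_p for r in results],
            "significant": [r.significant for r in results],
        }
    )
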