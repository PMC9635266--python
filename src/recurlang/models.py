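"""Linear models relating recurrence metrics to language measures.

The cohort is assembled into a long table with four rows per child — one per
(type, level) cell — joining that cell's RR and %DET to the child's MLU,
total utterance count, and autism severity score.  Type and analysis level
are effect-coded (+0.5 / -0.5) so that in a balanced table they are
orthogonal to every covariate and "main effects" are interpreted at the
grand mean.

The model for each response is ordinary least squares on a 16-term design:
intercept, the five main effects (Type, Level, MLU, Utterances, Severity),
the Type x Level interaction, the six two-way factor-by-covariate
interactions, and the three three-way interactions.  Rows with missing %DET
(series with no recurrent points) are dropped listwise from the %DET model
only.  Rows are treated as independent observations; a per-child
random-intercept variant is available behind a flag for sensitivity checks
but is not the default.

Post-hoc comparisons of the four (type, level) cell means use Tukey's HSD
over the six pairwise contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .codebooks import LEVELS, TYPES
from .rqa import RQAResult

__all__ = [
    "ModelFit",
    "PairwiseContrast",
    "TYPE_CODES",
    "LEVEL_CODES",
    "build_long_table",
    "fit_metric_model",
    "posthoc_cell_contrasts",
    "predictor_correlations",
]

# effect coding: noun/grammar carry +0.5
TYPE_CODES = {"noun": 0.5, "verb": -0.5}
LEVEL_CODES = {"grammar": 0.5, "lexical": -0.5}

FORMULA = "{response} ~ type_code * level_code * (mlu + total_utterances + ados_severity)"
N_TERMS = 16

METADATA_COLS = ("mlu", "total_utterances", "ados_severity")


@dataclass(frozen=True)
class ModelFit:
    """OLS fit summary: per-term B, SE, t, 95% CI, plus F and R^2."""

    response: str
    coefficients: pd.DataFrame  # index: term; columns: B, SE, t, ci_low, ci_high
    f_statistic: float
    df_model: int
    df_resid: int
    r_squared: float
    n_obs: int


@dataclass(frozen=True)
class PairwiseContrast:
    pair: tuple[str, str]       # cell labels like "noun:grammar"
    estimate: float             # mean(second) - mean(first)
    t: float
    df: int
    p_adjusted: float           # Tukey family-wise


def _cell_label(type: str, level: str) -> str:
    return f"{type}:{level}"


def build_long_table(profiles: dict[str, dict[tuple[str, str], RQAResult]],
                     metadata: pd.DataFrame) -> pd.DataFrame:
    """Join per-child RQA profiles to metadata, four rows per child.

    `metadata` must be indexed (or indexable) by child_id with columns
    mlu, total_utterances, ados_severity.  Missing %DET stays as NaN.
    """
    meta = metadata.copy()
    if "child_id" in meta.columns:
        meta = meta.set_index("child_id")
    rows = []
    for child_id, profile in profiles.items():
        if child_id not in meta.index:
            raise KeyError(f"metadata missing for child {child_id!r}")
        m = meta.loc[child_id]
        for col in METADATA_COLS:
            if col not in m or pd.isna(m[col]):
                raise KeyError(
                    f"metadata column {col!r} missing for child {child_id!r}")
        for ty in TYPES:
            for lv in LEVELS:
                r = profile[(ty, lv)]
                rows.append({
                    "child_id": child_id,
                    "type": ty,
                    "level": lv,
                    "cell": _cell_label(ty, lv),
                    "type_code": TYPE_CODES[ty],
                    "level_code": LEVEL_CODES[lv],
                    "rr": r.rr,
                    "det": np.nan if r.det is None else r.det,
                    "mlu": float(m["mlu"]),
                    "total_utterances": int(m["total_utterances"]),
                    "ados_severity": float(m["ados_severity"]),
                })
    return pd.DataFrame(rows)


def fit_metric_model(rows: pd.DataFrame, response: str,
                     center_covariates: bool = False,
                     random_intercept: bool = False) -> ModelFit:
    """OLS of `response` (rr or det) on the 16-term factorial design.

    `center_covariates` mean-centers MLU, utterances and severity before
    fitting (a sensitivity option; the default enters them raw).
    `random_intercept` fits a per-child random-intercept mixed model instead
    of OLS — a sensitivity variant, not the default reporting model.
    """
    if response not in ("rr", "det"):
        raise ValueError("response must be 'rr' or 'det'")
    data = rows.dropna(subset=[response]).copy()
    if center_covariates:
        for col in METADATA_COLS:
            data[col] = data[col] - data[col].mean()
    n = len(data)
    if n < N_TERMS + 1:
        raise ValueError(
            f"need at least {N_TERMS + 1} complete rows, have {n}")
    formula = FORMULA.format(response=response)
    if random_intercept:
        fit = smf.mixedlm(formula, data, groups=data["child_id"]).fit(reml=True)
        params = fit.params.drop("Group Var")
        conf = fit.conf_int().drop(index="Group Var")
        coefs = pd.DataFrame({
            "B": params, "SE": fit.bse[params.index],
            "t": fit.tvalues[params.index],
            "ci_low": conf[0], "ci_high": conf[1]})
        return ModelFit(response=response, coefficients=coefs,
                        f_statistic=np.nan, df_model=N_TERMS - 1,
                        df_resid=n - N_TERMS, r_squared=np.nan, n_obs=n)
    fit = smf.ols(formula, data).fit()
    if len(fit.params) != N_TERMS:
        raise ValueError(
            f"design is rank deficient: {len(fit.params)} estimable terms")
    conf = fit.conf_int(alpha=0.05)
    coefs = pd.DataFrame({
        "B": fit.params, "SE": fit.bse, "t": fit.tvalues,
        "ci_low": conf[0], "ci_high": conf[1]})
    return ModelFit(
        response=response,
        coefficients=coefs,
        f_statistic=float(fit.fvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        r_squared=float(fit.rsquared) if np.isfinite(fit.rsquared) else 0.0,
        n_obs=n,
    )


def posthoc_cell_contrasts(rows: pd.DataFrame, response: str
                           ) -> list[PairwiseContrast]:
    """All six pairwise (type, level) cell-mean contrasts, Tukey-adjusted."""
    data = rows.dropna(subset=[response])
    cells = sorted(data["cell"].unique())
    if len(cells) != 4:
        raise ValueError(f"expected 4 populated cells, found {len(cells)}")
    tukey = pairwise_tukeyhsd(endog=data[response].to_numpy(),
                              groups=data["cell"].to_numpy(), alpha=0.05)
    df_resid = int(len(data) - len(cells))
    mse = _pooled_mse(data, response)
    out = []
    frame = pd.DataFrame(tukey.summary().data[1:],
                         columns=tukey.summary().data[0])
    counts = data.groupby("cell")[response].count()
    for _, row in frame.iterrows():
        g1, g2 = str(row["group1"]), str(row["group2"])
        est = float(row["meandiff"])
        se = np.sqrt(mse * (1.0 / counts[g1] + 1.0 / counts[g2]))
        out.append(PairwiseContrast(
            pair=(g1, g2), estimate=est,
            t=est / se if se > 0 else np.nan,
            df=df_resid, p_adjusted=float(row["p-adj"])))
    return out


def _pooled_mse(data: pd.DataFrame, response: str) -> float:
    resid = data[response] - data.groupby("cell")[response].transform("mean")
    return float((resid ** 2).sum() / (len(data) - data["cell"].nunique()))


def predictor_correlations(rows: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations among the five predictors."""
    cols = ["type_code", "level_code", "mlu", "total_utterances",
            "ados_severity"]
    return rows[cols].corr()
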