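"""All-subsets AIC model selection with Akaike weights.

Every combination of the candidate predictors (including the
intercept-only model) is fitted by PGLS under a common covariance and
ranked by AIC.  Differences Delta_i = AIC_i - min AIC give relative
likelihoods l_i = exp(-Delta_i / 2), normalized to Akaike weights
w_i = l_i / sum_j l_j — the probability that model i is the best in the
set.  Categorical predictors enter as whole treatment-coded blocks: a
subset either contains the entire factor or none of it.

A pre-screen flags predictor pairs that are too strongly associated to
co-occur (|score| > 0.7 by default): Pearson r for numeric pairs,
Cramer's V for categorical pairs, the correlation ratio eta for mixed
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .inference import GlsFit, fit_gls, treatment_design

__all__ = [
    "ModelTable",
    "FlaggedPair",
    "all_subsets",
    "rank_models",
    "collinearity_screen",
    "fit_all_subsets",
]


def all_subsets(predictors: list[str]) -> list[tuple[str, ...]]:
    """All 2^m predictor subsets, ordered by size then lexicographically.

    Includes the empty (intercept-only) model first.
    """
    preds = list(predictors)
    if len(set(preds)) != len(preds):
        dupes = sorted({p for p in preds if preds.count(p) > 1})
        raise ValueError(f"duplicate predictor names: {dupes}")
    if len(preds) > 16:
        raise ValueError("more than 16 predictors: model space too large")
    out: list[tuple[str, ...]] = []
    for size in range(len(preds) + 1):
        for combo in sorted(combinations(sorted(preds), size)):
            out.append(combo)
    return out


@dataclass
class ModelTable:
    """Ranked model set: AIC, Delta_i, relative likelihoods, Akaike weights."""

    table: pd.DataFrame  # sorted ascending by aic

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self) -> list[dict]:
        return self.table.to_dict(orient="records")

    @property
    def best(self) -> pd.Series:
        return self.table.iloc[0]


def rank_models(fits: list[tuple[tuple[str, ...], "GlsFit"]]) -> ModelTable:
    """Rank fitted models by AIC and attach Akaike weights.

    ``fits`` is a list of (predictor_subset, GlsFit) pairs fitted on the
    same response, taxa and covariance.
    """
    if not fits:
        raise ValueError("empty model list")
    rows = []
    for subset, fit in fits:
        rows.append(
            {
                "predictors": " + ".join(subset) if subset else "(intercept only)",
                "n_predictors": len(subset),
                "k": len(fit.beta) + 1,
                "loglik": fit.loglik,
                "aic": fit.aic,
            }
        )
    df = pd.DataFrame(rows)
    df["delta"] = df["aic"] - df["aic"].min()
    df["rel_likelihood"] = np.exp(-0.5 * df["delta"])
    df["weight"] = df["rel_likelihood"] / df["rel_likelihood"].sum()
    df = df.sort_values(["aic", "predictors"], kind="mergesort").reset_index(drop=True)
    return ModelTable(table=df)


@dataclass
class FlaggedPair:
    a: str
    b: str
    measure: str  # "pearson_r" | "cramers_v" | "corr_ratio_eta" | "undefined"
    score: float | None


def _cramers_v(x: pd.Series, y: pd.Series) -> float:
    tab = pd.crosstab(x, y).to_numpy(dtype=float)
    n = tab.sum()
    row = tab.sum(axis=1, keepdims=True)
    col = tab.sum(axis=0, keepdims=True)
    expected = row @ col / n
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.nansum(np.where(expected > 0, (tab - expected) ** 2 / expected, 0.0))
    r, c = tab.shape
    denom = n * (min(r, c) - 1)
    return float(np.sqrt(chi2 / denom)) if denom > 0 else np.nan


def _corr_ratio(num: pd.Series, cat: pd.Series) -> float:
    """Correlation ratio eta: sqrt(between-group SS / total SS)."""
    v = num.to_numpy(dtype=float)
    total = np.sum((v - v.mean()) ** 2)
    if total == 0:
        return np.nan
    between = 0.0
    for _, grp in num.groupby(cat.to_numpy()):
        g = grp.to_numpy(dtype=float)
        between += len(g) * (g.mean() - v.mean()) ** 2
    return float(np.sqrt(between / total))


def collinearity_screen(table: pd.DataFrame, threshold: float = 0.7) -> list[FlaggedPair]:
    """Flag predictor pairs more strongly associated than ``threshold``.

    Strict inequality.  Constant columns make the association undefined;
    their pairs are flagged with score None rather than a number.
    """
    cols = list(table.columns)
    if len(cols) < 2:
        raise ValueError("collinearity screen needs >= 2 predictors")
    numeric = {c: pd.api.types.is_numeric_dtype(table[c]) for c in cols}
    flagged: list[FlaggedPair] = []
    for a, b in combinations(cols, 2):
        sa, sb = table[a], table[b]
        if sa.nunique() < 2 or sb.nunique() < 2:
            flagged.append(FlaggedPair(a, b, "undefined", None))
            continue
        if numeric[a] and numeric[b]:
            score = float(np.corrcoef(sa.astype(float), sb.astype(float))[0, 1])
            measure = "pearson_r"
        elif not numeric[a] and not numeric[b]:
            score = _cramers_v(sa.astype(str), sb.astype(str))
            measure = "cramers_v"
        else:
            num, cat = (sa, sb) if numeric[a] else (sb, sa)
            score = _corr_ratio(num.astype(float), cat.astype(str))
            measure = "corr_ratio_eta"
        if score is not None and np.isfinite(score) and abs(score) > threshold:
            flagged.append(FlaggedPair(a, b, measure, score))
    return flagged


def fit_all_subsets(
    data: pd.DataFrame,
    response: str,
    numeric: list[str],
    categorical: list[str],
    C=None,
    force_absent: list[str] | None = None,
) -> ModelTable:
    """Fit the all-subsets PGLS model space over the named predictors.

    Categorical predictors enter as whole treatment-coded blocks.
    ``force_absent`` removes predictors from the candidate set (used for
    the ecological-variables-only model space).
    """
    drop = set(force_absent or [])
    candidates = [p for p in numeric + categorical if p not in drop]
    y = data[response].to_numpy(dtype=float)
    n = len(y)
    fits = []
    for subset in all_subsets(candidates):
        cols = [np.ones(n)]
        names = ["(Intercept)"]
        for pred in subset:
            if pred in numeric:
                cols.append(data[pred].to_numpy(dtype=float))
                names.append(pred)
            else:
                D, dnames, _ = treatment_design(data[pred])
                for j, nm in enumerate(dnames):
                    cols.append(D[:, j])
                    names.append(f"{pred}{nm}")
        X = np.column_stack(cols)
        fits.append((subset, fit_gls(X, y, C, names=names)))
    return rank_models(fits)
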