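"""Downstream statistics: PCA over pieces, mixed ANOVA on logit TPs, and
stepwise chronological regression.

PCA orientation
---------------
The entities of interest are the pieces: the decomposition is of the
correlation matrix *among pieces* computed across the aligned pattern
vocabulary, so each piece receives a loading on each component.  Components
with eigenvalue > 1 (Kaiser criterion on the correlation matrix) are
retained and the first two are flagged for interpretation.  Because the
matrix is a correlation matrix, eigenvalues sum to the number of pieces and
percentage variance sums to 100.

Mixed ANOVA
-----------
Musician is the between-subject factor, transition pattern the
within-subject factor, and pieces are the subjects.  The dependent variable
is the logit-transformed TP (zeros clamped at eps so structural zeros stay
finite).  Sphericity of the within factor is assessed with Mauchly's test;
when violated (p < 0.05) the within main effect is reported with
Greenhouse-Geisser-corrected degrees of freedom and p-value.  Post-hoc
pairwise comparisons are Bonferroni-corrected.  The heavy lifting is
delegated to pingouin.

Stepwise regression
-------------------
Chronological index (1..K within a musician) is regressed on candidate
predictors (per-piece TPs of top-ranked patterns, or per-piece entropies)
by bidirectional stepwise selection: at each step the best admissible
candidate enters if its selection-adjusted p-value (Bonferroni over the
candidates screened at that step) is at most ``entry_alpha``; included
predictors with p above ``removal_alpha`` are dropped.  A candidate whose
entry would push any variance inflation factor to >= 2 or the model
condition index to >= 20 is refused.  An empty final model ("no significant
regression equation") is a valid result.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import pingouin as pg
import scipy.stats
import statsmodels.api as sm
from sklearn.metrics import silhouette_score
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .markov import (
    DEFAULT_LOGIT_EPS,
    MeanTPTable,
    PatternRank,
    TPMatrix,
    TPTable,
    logit_tp,
    serialize_pattern,
)

KAISER_EIGENVALUE = 1.0
DEFAULT_ENTRY_ALPHA = 0.05
DEFAULT_REMOVAL_ALPHA = 0.10
DEFAULT_VIF_MAX = 2.0
DEFAULT_CI_MAX = 20.0


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Correlation PCA of pieces over the pattern vocabulary."""

    eigenvalues: np.ndarray           # non-increasing
    pct_variance: np.ndarray          # eigenvalue / n_pieces * 100
    cumulative_pct: np.ndarray
    loadings: pd.DataFrame            # pieces x components (PC1, PC2, ...)
    retained: np.ndarray              # eigenvalue > 1

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    def first_two(self) -> pd.DataFrame:
        return self.loadings[["PC1", "PC2"]]


def run_pca(matrix: Union[TPMatrix, pd.DataFrame]) -> PCAResult:
    """Eigendecompose the correlation matrix among pieces.

    Requires at least 3 pieces and at least 2 patterns; a piece whose TP
    vector is constant has no defined correlation and is reported by id.
    """
    frame = matrix.values if isinstance(matrix, TPMatrix) else matrix
    if frame.shape[0] < 3:
        raise ValueError(f"PCA needs at least 3 pieces, got {frame.shape[0]}")
    if frame.shape[1] < 2:
        raise ValueError(f"PCA needs at least 2 patterns, got {frame.shape[1]}")

    X = frame.to_numpy(dtype=float)
    stds = X.std(axis=1)
    constant = [str(pid) for pid, sd in zip(frame.index, stds) if sd == 0.0]
    if constant:
        raise ValueError(
            "degenerate PCA input: constant TP vectors for pieces "
            + ", ".join(constant)
        )

    corr = np.corrcoef(X)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]

    loadings = eigvec * np.sqrt(eigval)
    for j in range(loadings.shape[1]):  # deterministic sign: dominant loading positive
        column = loadings[:, j]
        anchor = np.argmax(np.abs(column))
        if column[anchor] < 0:
            loadings[:, j] = -column

    pct = eigval / eigval.sum() * 100.0
    return PCAResult(
        eigenvalues=eigval,
        pct_variance=pct,
        cumulative_pct=np.cumsum(pct),
        loadings=pd.DataFrame(
            loadings,
            index=frame.index,
            columns=[f"PC{j + 1}" for j in range(loadings.shape[1])],
        ),
        retained=eigval > KAISER_EIGENVALUE,
    )


def loading_silhouette(result: PCAResult, labels: Dict[str, str]) -> float:
    """Silhouette of musician labels on the first two component loadings."""
    coords = result.first_two()
    y = [labels[str(pid)] for pid in coords.index]
    return float(silhouette_score(coords.to_numpy(), y))


# ---------------------------------------------------------------------------
# mixed ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """Mixed-ANOVA effects, sphericity diagnostics and Bonferroni post-hocs."""

    effects: pd.DataFrame     # Source, SS, df1, df2, F, p, np2
    posthoc: pd.DataFrame
    mauchly_w: float
    mauchly_p: float
    gg_epsilon: float
    gg_applied: bool


def build_anova_table(
    tables: Sequence[TPTable],
    ranks: Sequence[PatternRank],
    eps: float = DEFAULT_LOGIT_EPS,
) -> pd.DataFrame:
    """Long-format logit-TP table for the mixed ANOVA.

    The within-factor levels are the union of the musicians' top-ranked
    patterns (deduplicated), evaluated on every piece; a pattern a piece
    never produced contributes tp = 0, i.e. logit(eps) — this keeps the
    design balanced.
    """
    patterns: List = []
    seen = set()
    for rank in ranks:
        for pattern, _tp in rank.patterns:
            key = serialize_pattern(pattern, rank.sequence_type)
            if key not in seen:
                seen.add(key)
                patterns.append((key, pattern))
    rows = []
    for table in tables:
        tps = table.pattern_tps()
        for key, pattern in patterns:
            rows.append({
                "piece_id": table.piece_id,
                "musician_id": table.musician_id,
                "pattern": key,
                "logit_tp": logit_tp(tps.get(pattern, 0.0), eps),
            })
    return pd.DataFrame(rows)


def run_anova(
    data: pd.DataFrame,
    dv: str = "logit_tp",
    within: str = "pattern",
    between: str = "musician_id",
    subject: str = "piece_id",
    sphericity_alpha: float = 0.05,
) -> AnovaResult:
    """Mixed ANOVA (between = musician, within = pattern, subjects = pieces)."""
    cells = data.groupby([subject, within], observed=True).size()
    if (cells != 1).any() or cells.shape[0] != data[subject].nunique() * data[within].nunique():
        expected = set(itertools.product(data[subject].unique(), data[within].unique()))
        missing = sorted(expected - set(cells[cells > 0].index))
        raise ValueError(f"unbalanced design; missing or duplicated cells: {missing[:10]}")

    if np.ptp(data[dv].to_numpy(dtype=float)) == 0.0:
        # constant response: no variance to partition anywhere
        effects = pd.DataFrame({
            "effect": ["musician", "sequence", "musician x sequence"],
            "SS": 0.0, "df1": np.nan, "df2": np.nan,
            "F": 0.0, "p": 1.0, "np2": 0.0,
        })
        return AnovaResult(
            effects=effects, posthoc=pd.DataFrame(),
            mauchly_w=float("nan"), mauchly_p=float("nan"),
            gg_epsilon=float("nan"), gg_applied=False,
        )

    aov = pg.mixed_anova(
        data=data, dv=dv, within=within, subject=subject, between=between,
        correction=True, effsize="np2",
    )
    try:
        spher = pg.sphericity(data=data, dv=dv, within=within, subject=subject)
    except Exception:  # singular covariance (e.g. more levels than subjects)
        spher = None
    eps_col = aov.loc[aov["Source"] == within, "eps"]
    eps_hat_avail = len(eps_col) > 0 and not math.isnan(float(eps_col.iloc[0]))
    gg_applied = (
        spher is not None and bool(spher.pval < sphericity_alpha) and eps_hat_avail
    )

    effects = []
    for _, row in aov.iterrows():
        source = row["Source"]
        df1, df2, p = float(row["DF1"]), float(row["DF2"]), float(row["p_unc"])
        if source == within and gg_applied:
            eps_hat = float(row["eps"])
            df1, df2 = df1 * eps_hat, df2 * eps_hat
            # recomputed from the corrected dfs (not taken from pingouin,
            # whose reported GG p is unreliable for strongly non-spherical data)
            p = float(scipy.stats.f.sf(float(row["F"]), df1, df2))
        name = {between: "musician", within: "sequence", "Interaction": "musician x sequence"}.get(
            source, source
        )
        effects.append({
            "effect": name, "SS": float(row["SS"]), "df1": df1, "df2": df2,
            "F": float(row["F"]), "p": p, "np2": float(row["np2"]),
        })

    posthoc = pg.pairwise_tests(
        data=data, dv=dv, within=within, subject=subject, between=between,
        padjust="bonf",
    )
    return AnovaResult(
        effects=pd.DataFrame(effects),
        posthoc=posthoc,
        mauchly_w=float(spher.W) if spher is not None else float("nan"),
        mauchly_p=float(spher.pval) if spher is not None else float("nan"),
        gg_epsilon=float(eps_col.iloc[0]) if eps_hat_avail else float("nan"),
        gg_applied=gg_applied,
    )


# ---------------------------------------------------------------------------
# stepwise regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    """Final stepwise model; empty ``predictors`` means no significant equation."""

    predictors: pd.DataFrame  # name, B, SE, beta, p, VIF
    intercept: float = float("nan")
    condition_index: float = float("nan")
    r2_adj: float = float("nan")
    f_stat: float = float("nan")
    p_model: float = float("nan")
    response: str = "chronological_index"

    @property
    def selected(self) -> List[str]:
        return list(self.predictors["name"]) if len(self.predictors) else []

    @property
    def is_empty(self) -> bool:
        return len(self.predictors) == 0


def condition_index(X: np.ndarray) -> float:
    """Largest/smallest singular-value ratio of the column-scaled design matrix
    (intercept included) — the standard collinearity condition index."""
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0] = 1.0
    s = np.linalg.svd(X / norms, compute_uv=False)
    smin = s[s > 0].min() if (s > 0).any() else 0.0
    return float(s.max() / smin) if smin > 0 else float("inf")


def _vifs(X_with_const: np.ndarray) -> List[float]:
    if X_with_const.shape[1] <= 2:
        return [1.0] * (X_with_const.shape[1] - 1)
    return [
        float(variance_inflation_factor(X_with_const, i))
        for i in range(1, X_with_const.shape[1])
    ]


def _fit(y: np.ndarray, X: pd.DataFrame):
    exog = sm.add_constant(X, has_constant="add")
    return sm.OLS(y, exog).fit(), exog


def stepwise_regression(
    response: Sequence[float],
    predictors: pd.DataFrame,
    entry_alpha: float = DEFAULT_ENTRY_ALPHA,
    removal_alpha: float = DEFAULT_REMOVAL_ALPHA,
    vif_max: float = DEFAULT_VIF_MAX,
    ci_max: float = DEFAULT_CI_MAX,
    response_name: str = "chronological_index",
) -> RegressionResult:
    """Bidirectional stepwise OLS of chronological order on candidate predictors.

    ``response`` must be the chronological indices 1..K (in any order) of the
    K observations.  Entry applies a Bonferroni adjustment over the
    candidates screened at that step, so selection among many noise
    candidates does not inflate the false-entry rate; removal uses the raw
    within-model p-value.
    """
    y = np.asarray(response, dtype=float)
    if sorted(y.tolist()) != list(range(1, len(y) + 1)):
        raise ValueError(
            f"response must be a permutation of 1..{len(y)}, got {list(response)}"
        )
    if len(y) < 3:
        raise ValueError("need at least 3 observations")
    X_all = predictors.astype(float)
    if not np.isfinite(X_all.to_numpy()).all():
        raise ValueError("predictors must be finite")

    candidates = [c for c in X_all.columns if X_all[c].std() > 0]
    model: List[str] = []

    while True:
        # removal pass
        removed = False
        while model:
            fit, _ = _fit(y, X_all[model])
            pvals = fit.pvalues.drop("const")
            worst = pvals.idxmax()
            if pvals[worst] > removal_alpha:
                model.remove(worst)
                removed = True
            else:
                break

        # entry pass
        screening = [c for c in candidates if c not in model]
        best_name, best_p = None, np.inf
        for name in screening:
            trial = model + [name]
            fit, exog = _fit(y, X_all[trial])
            p_entry = float(fit.pvalues[name])
            if not math.isfinite(p_entry):
                p_entry = 0.0 if fit.ssr <= 1e-12 else 1.0  # perfect fit -> enters
            X_mat = exog.to_numpy()
            if max(_vifs(X_mat), default=1.0) >= vif_max:
                continue
            if condition_index(X_mat) >= ci_max:
                continue
            if p_entry < best_p:
                best_name, best_p = name, p_entry
        if best_name is not None and best_p * len(screening) <= entry_alpha:
            model.append(best_name)
            continue
        if not removed:
            break

    if not model:
        return RegressionResult(
            predictors=pd.DataFrame(columns=["name", "B", "SE", "beta", "p", "VIF"]),
            response=response_name,
        )

    fit, exog = _fit(y, X_all[model])
    X_mat = exog.to_numpy()
    vifs = _vifs(X_mat)
    sd_y = y.std(ddof=1)
    rows = []
    for name, vif in zip(model, vifs):
        rows.append({
            "name": name,
            "B": float(fit.params[name]),
            "SE": float(fit.bse[name]),
            "beta": float(fit.params[name]) * X_all[name].std(ddof=1) / sd_y,
            "p": float(fit.pvalues[name]),
            "VIF": vif,
        })
    return RegressionResult(
        predictors=pd.DataFrame(rows),
        intercept=float(fit.params["const"]),
        condition_index=condition_index(X_mat),
        r2_adj=float(fit.rsquared_adj),
        f_stat=float(fit.fvalue),
        p_model=float(fit.f_pvalue),
        response=response_name,
    )


def chronology_predictors(
    tables: Sequence[TPTable],
    rank: PatternRank,
    chronological_index: Dict[str, int],
) -> Tuple[List[int], pd.DataFrame]:
    """Per-piece TPs of a musician's top-ranked patterns, chronologically indexed.

    Returns (response, predictors) ready for :func:`stepwise_regression`.
    """
    ordered = sorted(tables, key=lambda t: chronological_index[t.piece_id])
    response = [chronological_index[t.piece_id] for t in ordered]
    columns = {}
    for pattern, _mean in rank.patterns:
        key = serialize_pattern(pattern, rank.sequence_type)
        columns[key] = [t.pattern_tps().get(pattern, 0.0) for t in ordered]
    return response, pd.DataFrame(columns, index=[t.piece_id for t in ordered])
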