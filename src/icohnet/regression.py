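"""Feature tables, quadratic-scope stepwise selection, and LOO prediction.

Candidate features are task-related graph metrics (DC, LE, CC) and ERD per
motor-area channel; the outcome is the clinical UL-FMA score (0-66).  The
stepwise search starts from the intercept-only model and iterates forward
addition / backward removal over a quadratic scope (linear, squared, and
pairwise-product terms) using partial-F p-values.  Hierarchy is not enforced:
a squared term may enter without its linear parent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: Bilateral motor-area channels used as the regression feature set
#: (premotor FC*, primary motor C*, sensorimotor CP* rows of both hemispheres).
MOTOR_CHANNELS: tuple[str, ...] = (
    "FC1", "FC3", "FC5", "C1", "C3", "C5", "CP1", "CP3", "CP5",
    "FC2", "FC4", "FC6", "C2", "C4", "C6", "CP2", "CP4", "CP6",
)

GRAPH_METRIC_NAMES: tuple[str, ...] = ("DC", "LE", "CC")


# ---------------------------------------------------------------------------
# model terms


@dataclass(frozen=True)
class Term:
    """A regression term over feature-table columns: linear, square or product."""

    kind: str  # 'lin' | 'sq' | 'prod'
    cols: tuple[str, ...]

    def __str__(self) -> str:
        if self.kind == "lin":
            return self.cols[0]
        if self.kind == "sq":
            return f"{self.cols[0]}^2"
        return f"{self.cols[0]}*{self.cols[1]}"

    def evaluate(self, table: pd.DataFrame) -> np.ndarray:
        if self.kind == "lin":
            return table[self.cols[0]].to_numpy(float)
        if self.kind == "sq":
            v = table[self.cols[0]].to_numpy(float)
            return v * v
        return table[self.cols[0]].to_numpy(float) * table[self.cols[1]].to_numpy(float)


def quadratic_scope(columns: list[str]) -> list[Term]:
    """Intercept-implied scope: all linear, squared and pairwise-product terms."""
    terms = [Term("lin", (c,)) for c in columns]
    terms += [Term("sq", (c,)) for c in columns]
    terms += [
        Term("prod", (a, b))
        for i, a in enumerate(columns)
        for b in columns[i + 1 :]
    ]
    return terms


def design_matrix(table: pd.DataFrame, terms: list[Term]) -> np.ndarray:
    """Intercept column followed by one column per term."""
    cols = [np.ones(len(table))] + [t.evaluate(table) for t in terms]
    return np.column_stack(cols)


def model_formula(terms: list[Term], outcome: str = "y") -> str:
    rhs = " + ".join(["1"] + [str(t) for t in terms])
    return f"{outcome} ~ {rhs}"


# ---------------------------------------------------------------------------
# feature table


def build_features(
    graph_metrics: pd.DataFrame,
    erd_map: pd.DataFrame,
    outcomes: pd.DataFrame,
    channels: tuple[str, ...] = MOTOR_CHANNELS,
) -> pd.DataFrame:
    """Assemble the subjects x features table with the UL-FMA outcome.

    ``graph_metrics``: long table (subject, metric, window, channel, value)
    with windows 'pre' and 'post'; each metric becomes a task-related-percent
    column ``METRIC(CH)``.  ``erd_map``: (subject, channel, value) in percent,
    becoming ``ERD(CH)``.  ``outcomes``: (subject, ul_fma).  Missing values or
    pre == 0 contrasts are hard errors listing every gap.
    """
    subjects = list(outcomes["subject"])
    wide = graph_metrics.pivot_table(
        index="subject", columns=["metric", "window", "channel"], values="value"
    )
    erd_wide = erd_map.pivot_table(index="subject", columns="channel", values="value")

    gaps: list[str] = []
    data: dict[str, list[float]] = {}
    for metric in GRAPH_METRIC_NAMES:
        for ch in channels:
            col = f"{metric}({ch})"
            vals = []
            for sid in subjects:
                try:
                    pre = wide.loc[sid, (metric, "pre", ch)]
                    post = wide.loc[sid, (metric, "post", ch)]
                except KeyError:
                    gaps.append(f"{sid}:{col}")
                    vals.append(np.nan)
                    continue
                if pd.isna(pre) or pd.isna(post):
                    gaps.append(f"{sid}:{col}")
                    vals.append(np.nan)
                elif pre == 0:
                    gaps.append(f"{sid}:{col} (pre == 0)")
                    vals.append(np.nan)
                else:
                    vals.append((post - pre) / pre * 100.0)
            data[col] = vals
    for ch in channels:
        col = f"ERD({ch})"
        vals = []
        for sid in subjects:
            try:
                v = erd_wide.loc[sid, ch]
            except KeyError:
                v = np.nan
            if pd.isna(v):
                gaps.append(f"{sid}:{col}")
            vals.append(v)
        data[col] = vals
    if gaps:
        raise ValueError("missing or undefined feature values: " + ", ".join(gaps))
    table = pd.DataFrame(data, index=pd.Index(subjects, name="subject"))
    table["ul_fma"] = outcomes.set_index("subject").loc[subjects, "ul_fma"].to_numpy(float)
    if table["ul_fma"].isna().any():
        raise ValueError("missing outcome for some subjects")
    return table


# ---------------------------------------------------------------------------
# OLS helpers (plain linear algebra; n is tiny and stepwise refits thousands
# of candidate models, so lstsq beats a full statsmodels fit per candidate)


def _ols_sse(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid), rank


@dataclass
class RegressionFit:
    """A fitted stepwise model with per-term statistics."""

    terms: list[Term]
    params: pd.DataFrame  # index: term (incl. intercept); coef, se, std_coef, t, p
    r2: float
    adj_r2: float
    f_stat: float
    f_p: float
    outcome: str
    formula: str


def _fit_stats(table: pd.DataFrame, terms: list[Term], outcome: str) -> RegressionFit:
    y = table[outcome].to_numpy(float)
    X = design_matrix(table, terms)
    n, p = X.shape
    beta, sse, rank = _ols_sse(X, y)
    if rank < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    df_resid = n - p
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df_resid if df_resid > 0 else np.nan
    mse = sse / df_resid if df_resid > 0 else np.nan
    cov = mse * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    pvals = 2 * sps.t.sf(np.abs(tvals), df_resid)
    sy = y.std(ddof=1)
    std_coef = np.empty(p)
    std_coef[0] = np.nan
    for j, t in enumerate(terms, start=1):
        std_coef[j] = beta[j] * np.std(t.evaluate(table), ddof=1) / sy
    if p > 1 and df_resid > 0:
        f_stat = ((sst - sse) / (p - 1)) / mse
        f_p = float(sps.f.sf(f_stat, p - 1, df_resid))
    else:
        f_stat, f_p = np.nan, np.nan
    params = pd.DataFrame(
        {"coef": beta, "se": se, "std_coef": std_coef, "t": tvals, "p": pvals},
        index=["Intercept"] + [str(t) for t in terms],
    )
    return RegressionFit(
        terms=list(terms),
        params=params,
        r2=r2,
        adj_r2=adj_r2,
        f_stat=float(f_stat),
        f_p=f_p,
        outcome=outcome,
        formula=model_formula(terms, outcome),
    )


def stepwise_select(
    table: pd.DataFrame,
    outcome: str = "ul_fma",
    candidates: list[str] | None = None,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.05,
    max_iter: int = 200,
) -> RegressionFit:
    """Forward/backward stepwise selection by partial-F p-value.

    Scope = quadratic over ``candidates`` (default: every column except the
    outcome).  Zero-variance candidates are excluded with a warning.  The
    search stops when no add/remove changes the model or a visited term set
    repeats (cycle guard).
    """
    if len(table) < 3:
        raise ValueError("need at least 3 subjects")
    if candidates is None:
        candidates = [c for c in table.columns if c != outcome]
    usable = []
    for c in candidates:
        if np.isclose(table[c].to_numpy(float).var(), 0.0):
            warnings.warn(f"excluding zero-variance candidate {c!r} from scope")
        else:
            usable.append(c)
    scope = quadratic_scope(usable)
    y = table[outcome].to_numpy(float)
    n = len(y)

    selected: list[Term] = []
    visited = {frozenset()}
    for _ in range(max_iter):
        changed = False
        # forward step
        X0 = design_matrix(table, selected)
        _, sse0, _ = _ols_sse(X0, y)
        best_p, best_term, best_sse = None, None, None
        for t in scope:
            if t in selected:
                continue
            X1 = np.column_stack([X0, t.evaluate(table)])
            df1 = n - X1.shape[1]
            if df1 < 1 or np.linalg.matrix_rank(X1) < X1.shape[1]:
                continue
            _, sse1, _ = _ols_sse(X1, y)
            if sse1 <= 0:
                pval = 0.0
            else:
                f = (sse0 - sse1) / (sse1 / df1)
                pval = float(sps.f.sf(f, 1, df1))
            if best_p is None or pval < best_p:
                best_p, best_term, best_sse = pval, t, sse1
        if best_p is not None and best_p < alpha_enter:
            selected = selected + [best_term]
            changed = True
        # backward step
        if selected:
            X1 = design_matrix(table, selected)
            df1 = n - X1.shape[1]
            _, sse1, _ = _ols_sse(X1, y)
            worst_p, worst_idx = None, None
            for idx in range(len(selected)):
                rest = selected[:idx] + selected[idx + 1 :]
                _, sse0_, _ = _ols_sse(design_matrix(table, rest), y)
                if df1 < 1:
                    pval = 1.0
                elif sse1 <= 0:
                    pval = 0.0
                else:
                    f = (sse0_ - sse1) / (sse1 / df1)
                    pval = float(sps.f.sf(f, 1, df1))
                if worst_p is None or pval > worst_p:
                    worst_p, worst_idx = pval, idx
            if worst_p is not None and worst_p > alpha_remove:
                selected = selected[:worst_idx] + selected[worst_idx + 1 :]
                changed = True
        state = frozenset(selected)
        if not changed:
            break
        if state in visited:
            warnings.warn("stepwise add/remove cycle detected; returning current model")
            break
        visited.add(state)
    return _fit_stats(table, selected, outcome)


# ---------------------------------------------------------------------------
# prediction


def prediction_metrics(actual, predicted, n_predictors: int = 1) -> dict[str, float]:
    """RMSE (both /n and /(n-1) denominators), R^2, adjusted R^2, Pearson r."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape:
        raise ValueError("actual and predicted must have equal length")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.isclose(p.std(), 0):
        raise ValueError("correlation undefined for constant predictions")
    err = p - a
    sse = float(err @ err)
    sst = float(((a - a.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst
    df = n - n_predictors - 1
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df if df > 0 else np.nan
    return {
        "rmse_n": float(np.sqrt(sse / n)),
        "rmse_n1": float(np.sqrt(sse / (n - 1))),
        "r2": r2,
        "adj_r2": adj_r2,
        "pearson_r": float(np.corrcoef(a, p)[0, 1]),
    }


@dataclass
class PredictionResult:
    """Per-subject leave-one-out predictions plus summary metrics."""

    predictions: pd.DataFrame  # index subject; actual, predicted
    metrics: dict[str, float]
    terms: list[Term]
    formula: str


def loo_predict(table: pd.DataFrame, terms: list[Term], outcome: str = "ul_fma") -> PredictionResult:
    """Refit the fixed term set on n-1 subjects and predict the held-out one.

    The term set is fixed before the loop (selected on the full sample);
    only the coefficients are re-estimated per fold.
    """
    y = table[outcome].to_numpy(float)
    X = design_matrix(table, terms)
    n = len(y)
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xi, yi = X[mask], y[mask]
        if np.linalg.matrix_rank(Xi) < Xi.shape[1]:
            raise np.linalg.LinAlgError(f"singular refit leaving out subject {table.index[i]!r}")
        beta, _, _ = _ols_sse(Xi, yi)
        preds[i] = X[i] @ beta
    metrics = prediction_metrics(y, preds, n_predictors=len(terms))
    predictions = pd.DataFrame({"actual": y, "predicted": preds}, index=table.index)
    return PredictionResult(
        predictions=predictions,
        metrics=metrics,
        terms=list(terms),
        formula=model_formula(terms, outcome),
    )


def bootstrap_stability(
    table: pd.DataFrame,
    runs: int = 1000,
    seed: int = 0,
    outcome: str = "ul_fma",
    candidates: list[str] | None = None,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.05,
    unit: str = "feature",
) -> pd.Series:
    """Hold-one-out + bootstrap-resample stepwise reruns; selection rates.

    Each run cycles the held-out subject, resamples the remaining n-1 rows
    with replacement, reruns the stepwise search, and records what was
    selected.  With ``unit='feature'`` (default) a feature counts as selected
    in a run when any chosen term involves it — linear, squared or product —
    which is the stable notion when a feature's term forms are collinear
    (e.g. x and x^2 for a one-signed x).  ``unit='term'`` counts exact terms.
    Degenerate resamples (constant outcome) are skipped and logged.
    """
    if unit not in {"feature", "term"}:
        raise ValueError("unit must be 'feature' or 'term'")
    if len(table) < 5:
        raise ValueError("need at least 5 subjects for bootstrap stability")
    rng = np.random.default_rng(seed)
    counts: dict[str, int] = {}
    effective = 0
    n = len(table)
    for run in range(runs):
        hold = run % n
        rest = table.drop(index=table.index[hold])
        idx = rng.integers(0, len(rest), size=len(rest))
        sample = rest.iloc[idx]
        if np.isclose(sample[outcome].to_numpy(float).var(), 0.0):
            logger.info("run %d: constant outcome in resample; skipped", run)
            continue
        sample = sample.reset_index(drop=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = stepwise_select(
                    sample,
                    outcome=outcome,
                    candidates=candidates,
                    alpha_enter=alpha_enter,
                    alpha_remove=alpha_remove,
                )
            except np.linalg.LinAlgError:
                logger.info("run %d: singular design; skipped", run)
                continue
        effective += 1
        if unit == "feature":
            selected = {c for t in fit.terms for c in t.cols}
        else:
            selected = {str(t) for t in fit.terms}
        for name in selected:
            counts[name] = counts.get(name, 0) + 1
    if effective == 0:
        raise RuntimeError("all bootstrap runs degenerate")
    freq = pd.Series(counts, dtype=float) / effective
    return freq.sort_values(ascending=False)
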