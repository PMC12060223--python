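"""Task-related contrasts, ERD/S, group tests, and the threshold scan.

Task-related activity normalizes every metric to its pre-task value,
``(post - pre) / pre * 100``, which removes subject- and session-level scale
so groups can be compared on task-induced change alone.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.signal import welch

from .network import global_efficiency, threshold_top_fraction
from .preprocess import EpochSet, extract_windows

logger = logging.getLogger(__name__)


def task_related_activity(pre, post):
    """Percent change from pre- to post-task: (post - pre) / pre * 100.

    Scale-invariant: multiplying pre and post by any c != 0 leaves it
    unchanged.  Raises when pre is 0 (contrast undefined).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if np.any(pre == 0):
        raise ZeroDivisionError("task-related activity undefined where pre == 0")
    out = (post - pre) / pre * 100.0
    return float(out) if out.ndim == 0 else out


def band_power(window_trials: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Trial-averaged band power per channel from Hann-windowed short-time spectra.

    Welch segments of 0.5 s with 50% overlap; power integrated over the
    half-open band [low, high).
    """
    x = np.asarray(window_trials, dtype=float)
    nperseg = min(int(round(fs / 2)), x.shape[-1])
    freqs, psd = welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2, axis=-1)
    mask = (freqs >= band[0]) & (freqs < band[1])
    if not mask.any():
        raise ValueError(f"no spectral bins in band {band}")
    return psd[..., mask].sum(axis=-1).mean(axis=0)


def erd(e: EpochSet, band: tuple[float, float]) -> pd.Series:
    """ERD/S map: percent change of band power, post window vs pre baseline.

    Negative values are desynchronization (ERD), positive synchronization
    (ERS).  Raises when a channel's baseline band power is zero.
    """
    pre, post = extract_windows(e)
    p_pre = band_power(pre, e.fs, band)
    p_post = band_power(post, e.fs, band)
    if np.any(p_pre == 0):
        bad = [e.ch_names[i] for i in np.flatnonzero(p_pre == 0)]
        raise ZeroDivisionError(f"zero baseline band power at channels {bad}")
    return pd.Series(task_related_activity(p_pre, p_post), index=e.ch_names, name="erd")


def rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Exact null enumeration (via the equivalent Mann-Whitney U) when both
    samples have n <= 10 and no ties; tie-corrected normal approximation
    otherwise.  Returns (rank-sum statistic of x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        warnings.warn("all values identical across both samples; p = 1")
        ranks = sps.rankdata(combined)
        return float(ranks[: x.size].sum()), 1.0
    has_ties = np.unique(combined).size < combined.size
    if x.size <= 10 and y.size <= 10 and not has_ties:
        u = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        p = float(u.pvalue)
    else:
        # normal approximation with tie and continuity corrections
        # (the U-test z is the rank-sum z)
        u = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(u.pvalue)
    stat = float(sps.rankdata(combined)[: x.size].sum())
    return stat, p


def _spearman_exact_p(rho: float, n: int) -> float:
    """Two-sided exact p by full enumeration of the n! rank permutations."""
    base = np.arange(1, n + 1, dtype=float)
    perms = np.array(list(itertools.permutations(range(n))), dtype=int)
    # rho for each permutation of ranks against the identity ranking
    d2 = ((perms + 1.0) - base) ** 2
    rhos = 1.0 - 6.0 * d2.sum(axis=1) / (n * (n * n - 1.0))
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation; exact p for n <= 9 (tie-free), t-approx otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for constant input")
    rho, p_approx = sps.spearmanr(x, y)
    rho = float(rho)
    n = x.size
    tie_free = np.unique(x).size == n and np.unique(y).size == n
    if n <= 9 and tie_free:
        return rho, _spearman_exact_p(rho, n)
    return rho, float(p_approx)


def ancova_group_effect(post, groups, pre) -> tuple[float, float]:
    """F-test of the group factor in ``post ~ group + pre`` (Type II SS).

    Controls for the pre-task level of the metric, so a group difference that
    is entirely carried by baseline differences yields F near 0.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = pd.DataFrame(
        {"post": np.asarray(post, float), "group": list(groups), "pre": np.asarray(pre, float)}
    )
    if df["group"].nunique() < 2:
        raise ValueError("need at least 2 groups")
    if np.isclose(df["pre"].var(), 0):
        raise ValueError("covariate has no variance (degenerate design)")
    model = ols("post ~ C(group) + pre", data=df).fit()
    if model.df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    table = sm.stats.anova_lm(model, typ=2)
    return float(table.loc["C(group)", "F"]), float(table.loc["C(group)", "PR(>F)"])


@dataclass
class ThresholdScanResult:
    """Per-fraction group contrast of task-related global efficiency."""

    table: pd.DataFrame  # columns: fraction, p, median_diff, n_per_group
    selected_fraction: float | None
    selected_p: float | None
    samples: dict[float, dict[str, np.ndarray]] = field(default_factory=dict)


def threshold_scan(
    icoh_by_subject: dict[str, dict[str, np.ndarray]],
    groups: dict[str, str],
    fractions: np.ndarray | None = None,
) -> ThresholdScanResult:
    """Scan proportional thresholds for a group difference in task-related E_glob.

    ``icoh_by_subject`` maps subject id -> {'pre': matrix, 'post': matrix}
    (one band).  For each fraction the per-subject task-related global
    efficiency is contrasted between the two groups with the rank-sum test;
    the selected threshold is the minimum-p fraction among those with
    p < 0.05, or None when no fraction is significant.  No multiple-testing
    correction is applied across fractions.
    """
    if fractions is None:
        fractions = np.arange(1, 91) / 100.0
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    by_group = {g: [s for s in icoh_by_subject if groups[s] == g] for g in labels}
    if min(len(v) for v in by_group.values()) < 2:
        raise ValueError("need at least 2 subjects per group")

    rows = []
    samples: dict[float, dict[str, np.ndarray]] = {}
    for frac in fractions:
        acts: dict[str, np.ndarray] = {}
        for g, sids in by_group.items():
            vals = []
            for sid in sids:
                e_pre = global_efficiency(threshold_top_fraction(icoh_by_subject[sid]["pre"], frac))
                e_post = global_efficiency(threshold_top_fraction(icoh_by_subject[sid]["post"], frac))
                vals.append(task_related_activity(e_pre, e_post))
            acts[g] = np.asarray(vals)
        _, p = rank_sum(acts[labels[0]], acts[labels[1]])
        rows.append(
            {
                "fraction": float(frac),
                "p": p,
                "median_diff": float(np.median(acts[labels[0]]) - np.median(acts[labels[1]])),
                "n_per_group": min(len(v) for v in acts.values()),
            }
        )
        samples[float(frac)] = acts
    table = pd.DataFrame(rows)
    sig = table[table["p"] < 0.05]
    if sig.empty:
        return ThresholdScanResult(table=table, selected_fraction=None, selected_p=None, samples=samples)
    best = sig.loc[sig["p"].idxmin()]
    return ThresholdScanResult(
        table=table,
        selected_fraction=float(best["fraction"]),
        selected_p=float(best["p"]),
        samples=samples,
    )
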