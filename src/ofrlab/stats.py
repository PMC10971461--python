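"""OFR summaries, direction tests, and the interocular-correlation comparison.

The ocular-following response (OFR) of one condition is the difference between
the mean vertical eye-in-head displacements in the movement epoch for upward-
and downward-drifting stimuli:

    OFR = mean(dy_up) - mean(dy_down)          [deg]
    SD  = sqrt(sd_up^2 + sd_down^2)
    SEM = sqrt(sd_up^2/n_up + sd_down^2/n_down)

Up-vs-down significance uses the unpaired (pooled-variance) t-test and the
Mann-Whitney U test.  Whether a subject is sensitive to interocular
correlation is decided by a bootstrap comparison of the correlated and
anticorrelated OFRs: each of the four condition x direction trial cells is
resampled with replacement at its own size, Delta* = OFR_c* - OFR_ac* is
recomputed, and the two-sided p-value is the (add-one corrected) fraction of
the bootstrap distribution on the far side of zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ConditionSummary",
    "ComparisonResult",
    "summarize_condition",
    "direction_test",
    "bootstrap_condition_comparison",
    "classify_cohort",
    "summarize_session",
]


@dataclass(frozen=True)
class ConditionSummary:
    """Per-direction moments and the derived OFR of one stimulus condition."""

    condition: str
    mean_up: float
    sd_up: float
    n_up: int
    mean_dw: float
    sd_dw: float
    n_dw: int
    p_t: float | None = None
    p_np: float | None = None

    @property
    def ofr(self) -> float:
        return self.mean_up - self.mean_dw

    @property
    def ofr_sd(self) -> float:
        return float(np.hypot(self.sd_up, self.sd_dw))

    @property
    def ofr_sem(self) -> float:
        return float(np.sqrt(self.sd_up**2 / self.n_up + self.sd_dw**2 / self.n_dw))


@dataclass(frozen=True)
class ComparisonResult:
    """Bootstrap comparison of correlated vs anticorrelated OFRs."""

    ofr_correlated: ConditionSummary
    ofr_anticorrelated: ConditionSummary
    p_bootstrap: float
    n_bootstrap: int
    seed: int | None
    alpha: float = 0.05

    @property
    def delta(self) -> float:
        return self.ofr_correlated.ofr - self.ofr_anticorrelated.ofr

    @property
    def sensitive_flag(self) -> bool:
        return self.p_bootstrap < self.alpha


def summarize_condition(
    up: np.ndarray, dw: np.ndarray, condition: str = "", run_tests: bool = True
) -> ConditionSummary:
    """Summarize one condition from its up- and down-drift trial values.

    Sample SDs use the n-1 denominator.  Raises if either direction has
    fewer than two trials (the SDs would be undefined).
    """
    up = np.asarray(up, dtype=float)
    dw = np.asarray(dw, dtype=float)
    for name, v in (("up", up), ("down", dw)):
        if v.size < 2:
            raise ValueError(f"condition {condition or '?'}: direction '{name}' has "
                             f"{v.size} trial(s); need at least 2")
    p_t = p_np = None
    if run_tests:
        p_t, p_np = direction_test(up, dw)
    return ConditionSummary(
        condition=condition,
        mean_up=float(up.mean()), sd_up=float(up.std(ddof=1)), n_up=int(up.size),
        mean_dw=float(dw.mean()), sd_dw=float(dw.std(ddof=1)), n_dw=int(dw.size),
        p_t=p_t, p_np=p_np,
    )


def _exact_mwu_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p by enumeration of group labelings.

    Enumerates all C(n+m, n) assignments of the pooled sample to the two
    groups and counts those with a U statistic at least as extreme (in
    distance from the null mean nm/2) as observed.  Handles ties, since U is
    computed with the midrank convention on the pooled values.
    """
    pooled = np.concatenate([x, y])
    n, m = x.size, y.size
    ranks = sps.rankdata(pooled)
    u_null = n * m / 2.0

    def u_of(idx: tuple[int, ...]) -> float:
        r = ranks[list(idx)].sum()
        return r - n * (n + 1) / 2.0

    observed = abs(u_of(tuple(range(n))) - u_null)
    total = extreme = 0
    for idx in itertools.combinations(range(n + m), n):
        total += 1
        if abs(u_of(idx) - u_null) >= observed - 1e-12:
            extreme += 1
    return extreme / total


def direction_test(up: np.ndarray, dw: np.ndarray, exact_threshold: int = 8) -> tuple[float, float]:
    """Up-vs-down significance: (pooled-variance t p, Mann-Whitney U p).

    The U test uses exact enumeration when the smaller group has
    ``exact_threshold`` or fewer trials, otherwise the normal approximation
    with continuity and tie correction.  Two groups with zero variance and
    equal means return p = 1 by convention.
    """
    up = np.asarray(up, dtype=float)
    dw = np.asarray(dw, dtype=float)
    if up.size < 2 or dw.size < 2:
        raise ValueError("need at least 2 values per direction")
    if up.std(ddof=1) == 0 and dw.std(ddof=1) == 0:
        p_t = 1.0 if up.mean() == dw.mean() else 0.0
    else:
        p_t = float(sps.ttest_ind(up, dw, equal_var=True).pvalue)
    if np.array_equal(np.sort(up), np.sort(dw)) and up.size == dw.size:
        p_np = 1.0
    elif min(up.size, dw.size) <= exact_threshold:
        p_np = _exact_mwu_p(up, dw)
    else:
        p_np = float(
            sps.mannwhitneyu(up, dw, alternative="two-sided",
                             method="asymptotic", use_continuity=True).pvalue
        )
    return p_t, min(p_np, 1.0)


def bootstrap_condition_comparison(
    up_c: np.ndarray,
    dw_c: np.ndarray,
    up_ac: np.ndarray,
    dw_ac: np.ndarray,
    n_bootstrap: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Bootstrap test of OFR_correlated vs OFR_anticorrelated.

    Each of the four trial cells is resampled with replacement at its own
    size; Delta* = (mean up_c* - mean dw_c*) - (mean up_ac* - mean dw_ac*).
    Two-sided p = 2 * min(#(Delta* <= 0) + 1, #(Delta* >= 0) + 1) /
    (n_bootstrap + 1), capped at 1 — the add-one correction keeps p off zero.
    Reproducible bit-for-bit for a given (seed, n_bootstrap); cells are
    sorted before resampling so the result is invariant to trial order.
    """
    cells = [np.sort(np.asarray(c, dtype=float)) for c in (up_c, dw_c, up_ac, dw_ac)]
    for name, cell in zip(("up_c", "dw_c", "up_ac", "dw_ac"), cells):
        if cell.size < 2:
            raise ValueError(f"cell {name} has {cell.size} trial(s); need at least 2")
    if n_bootstrap < 100:
        import warnings

        warnings.warn(f"n_bootstrap={n_bootstrap} is too small for stable p-values",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    means = []
    for cell in cells:
        idx = rng.integers(0, cell.size, size=(n_bootstrap, cell.size))
        means.append(cell[idx].mean(axis=1))
    delta_star = (means[0] - means[1]) - (means[2] - means[3])
    n_le = int(np.sum(delta_star <= 0.0))
    n_ge = int(np.sum(delta_star >= 0.0))
    p = 2.0 * min(n_le + 1, n_ge + 1) / (n_bootstrap + 1)
    p = min(p, 1.0)
    summary_c = summarize_condition(cells[0], cells[1], "correlated")
    summary_ac = summarize_condition(cells[2], cells[3], "anticorrelated")
    return ComparisonResult(summary_c, summary_ac, p_bootstrap=p,
                            n_bootstrap=n_bootstrap, seed=seed, alpha=alpha)


def classify_cohort(p_values, alpha: float = 0.05) -> dict:
    """Count correlation-sensitive subjects (p < alpha) in a cohort.

    Accepts ComparisonResult objects or raw comparison p-values.  Returns
    per-subject flags and the sensitive / insensitive counts.  No
    multiple-testing correction is applied: the experimental design reports
    per-subject tests at the nominal level.
    """
    ps = [r.p_bootstrap if isinstance(r, ComparisonResult) else float(r) for r in p_values]
    if not ps:
        raise ValueError("need at least one result")
    flags = [p < alpha for p in ps]
    return {
        "n_subjects": len(ps),
        "n_sensitive": int(sum(flags)),
        "n_insensitive": int(len(ps) - sum(flags)),
        "flags": flags,
        "alpha": alpha,
    }


def summarize_session(
    kept: pd.DataFrame,
    n_bootstrap: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
    value_col: str = "eye_dy_mov",
) -> tuple[pd.DataFrame, ComparisonResult]:
    """Full per-session statistics from a kept eye-in-head trial table.

    Returns a table with one row per condition (means, SDs, Ns, direction
    p-values, OFR, SD, SEM) and the correlated-vs-anticorrelated
    ComparisonResult.
    """
    cells = {}
    for condition in ("correlated", "anticorrelated"):
        for direction in ("up", "down"):
            sel = (kept["condition"] == condition) & (kept["direction"] == direction)
            cells[(condition, direction)] = kept.loc[sel, value_col].to_numpy(dtype=float)
    rows = []
    for condition in ("correlated", "anticorrelated"):
        s = summarize_condition(cells[(condition, "up")], cells[(condition, "down")], condition)
        rows.append({
            "condition": condition,
            "mean_up": s.mean_up, "sd_up": s.sd_up, "n_up": s.n_up,
            "mean_dw": s.mean_dw, "sd_dw": s.sd_dw, "n_dw": s.n_dw,
            "p_t": s.p_t, "p_np": s.p_np,
            "ofr": s.ofr, "ofr_sd": s.ofr_sd, "ofr_sem": s.ofr_sem,
        })
    comparison = bootstrap_condition_comparison(
        cells[("correlated", "up")], cells[("correlated", "down")],
        cells[("anticorrelated", "up")], cells[("anticorrelated", "down")],
        n_bootstrap=n_bootstrap, seed=seed, alpha=alpha,
    )
    return pd.DataFrame(rows), comparison
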