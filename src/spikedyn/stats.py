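"""Repeated-measures condition comparison across neurons pooled over cultures.

Values of every measure span orders of magnitude, so they are
log-transformed (natural log) before testing; nonpositive and missing
values are excluded, and only complete cases -- units with a value in all
three conditions after exclusion -- enter the tests, the reported means,
and the cumulative-distribution plots. The omnibus test is Friedman's
chi-squared over the three matched conditions; post hoc contrasts are
paired t-tests per condition pair with paired Cohen's d (mean difference /
SD of differences; the pooled-SD variant is also reported), Bonferroni-
corrected across the three pairs (uncorrected p also reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import CONDITIONS

__all__ = [
    "PairResult",
    "ConditionComparison",
    "log_transform",
    "friedman_test",
    "posthoc_pairs",
    "complete_case_matrix",
    "condition_summary",
    "plot_condition_cdfs",
]


@dataclass
class PairResult:
    pair: tuple
    t: float
    p: float
    p_bonferroni: float
    cohen_d_paired: float
    cohen_d_pooled: float


@dataclass
class ConditionComparison:
    measure: str
    n: int  # complete cases
    means: dict  # condition -> mean of log values
    sds: dict
    friedman_q: float
    friedman_p: float
    pairs: list = field(default_factory=list)  # PairResult
    n_excluded_nonpositive: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pr in self.pairs:
            a, b = pr.pair
            rows.append(
                {
                    "measure": self.measure,
                    "n": self.n,
                    "friedman_q": self.friedman_q,
                    "friedman_p": self.friedman_p,
                    "pair": f"{a}_vs_{b}",
                    "mean_a": self.means[a],
                    "sd_a": self.sds[a],
                    "mean_b": self.means[b],
                    "sd_b": self.sds[b],
                    "t": pr.t,
                    "p": pr.p,
                    "p_bonferroni": pr.p_bonferroni,
                    "cohen_d_paired": pr.cohen_d_paired,
                    "cohen_d_pooled": pr.cohen_d_pooled,
                    "n_excluded_nonpositive": self.n_excluded_nonpositive,
                }
            )
        return pd.DataFrame(rows)


def log_transform(values) -> tuple[np.ndarray, int]:
    """Natural-log transform; returns (log values, #excluded nonpositive/NaN).

    Excluded entries come back as NaN so positional alignment survives.
    Raises if nothing positive remains.
    """
    out, n_excluded = _safe_log(np.asarray(values, dtype=float))
    if np.isnan(out).all():
        raise ValueError("no positive values to log-transform")
    return out, n_excluded


def friedman_test(matrix: np.ndarray) -> tuple[float, float]:
    """Friedman's rank test over an (n subjects x k conditions) matrix.

    Average-rank tie handling; p from chi-squared with k - 1 df. Missing
    cells are a hard error -- complete-case filtering is the caller's job.
    Identical columns (all ranks tied) give Q = 0, p = 1.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 3:
        raise ValueError("need an n x k matrix with k >= 3")
    if np.isnan(m).any():
        raise ValueError("missing cells; filter to complete cases first")
    if np.all(m == m[:, :1]):
        return 0.0, 1.0
    q, p = sps.friedmanchisquare(*m.T)
    return float(q), float(p)


def posthoc_pairs(matrix: np.ndarray, conditions=CONDITIONS) -> list[PairResult]:
    """Paired t-tests with Cohen's d for every condition pair.

    d (paired) = mean(diff) / SD(diff); d (pooled) = mean(diff) / pooled SD
    of the two columns. Zero-variance differences leave t undefined (nan).
    """
    m = np.asarray(matrix, dtype=float)
    if np.isnan(m).any():
        raise ValueError("missing cells; filter to complete cases first")
    out = []
    pairs = [(i, j) for i in range(len(conditions)) for j in range(i + 1, len(conditions))]
    for i, j in pairs:
        a, b = m[:, i], m[:, j]
        diff = a - b
        sd = diff.std(ddof=1)
        if sd == 0:
            # Zero-variance differences: t undefined unless identical columns.
            if diff.mean() == 0:
                t, p, d_z = 0.0, 1.0, 0.0
            else:
                t, p, d_z = np.nan, np.nan, np.nan
        else:
            t, p = sps.ttest_rel(a, b)
            d_z = diff.mean() / sd
        pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        d_pool = diff.mean() / pooled if pooled > 0 else np.nan
        out.append(
            PairResult(
                (conditions[i], conditions[j]),
                float(t),
                float(p),
                float(min(1.0, p * len(pairs))) if np.isfinite(p) else np.nan,
                float(d_z),
                float(d_pool),
            )
        )
    return out


def complete_case_matrix(
    tidy: pd.DataFrame,
    value_col: str,
    unit_cols=("culture", "neuron"),
    conditions=CONDITIONS,
) -> pd.DataFrame:
    """Pivot a tidy (unit, condition, value) table to complete-case wide form."""
    wide = tidy.pivot_table(
        index=list(unit_cols), columns="condition", values=value_col, aggfunc="first"
    )
    missing = [c for c in conditions if c not in wide.columns]
    for c in missing:
        wide[c] = np.nan
    wide = wide[list(conditions)]
    return wide.dropna()


def condition_summary(
    tidy: pd.DataFrame,
    measures: list,
    unit_cols=("culture", "neuron"),
    conditions=CONDITIONS,
    log: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """One ConditionComparison per measure from a tidy results table.

    Returns (stacked summary table, {measure: ConditionComparison}). Units
    with nonpositive values are dropped before the complete-case pivot when
    ``log`` is set, so reported means/tests all describe the same sample.
    """
    frames, comps = [], {}
    for measure in measures:
        sub = tidy[["condition", *unit_cols, measure]].copy()
        n_excl = 0
        if log:
            vals, _ = _safe_log(sub[measure].to_numpy())
            n_excl = int(np.isnan(vals).sum() - sub[measure].isna().sum())
            sub[measure] = vals
        wide = complete_case_matrix(sub, measure, unit_cols, conditions)
        if len(wide) < 2:
            continue
        m = wide.to_numpy()
        q, p = friedman_test(m)
        pairs = posthoc_pairs(m, conditions)
        comp = ConditionComparison(
            measure=measure,
            n=len(wide),
            means={c: float(m[:, k].mean()) for k, c in enumerate(conditions)},
            sds={c: float(m[:, k].std(ddof=1)) for k, c in enumerate(conditions)},
            friedman_q=q,
            friedman_p=p,
            pairs=pairs,
            n_excluded_nonpositive=max(0, n_excl),
        )
        comps[measure] = comp
        frames.append(comp.to_frame())
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return table, comps


def _safe_log(v: np.ndarray) -> tuple[np.ndarray, int]:
    v = np.asarray(v, dtype=float)
    ok = np.isfinite(v) & (v > 0)
    out = np.full(v.shape, np.nan)
    out[ok] = np.log(v[ok])
    return out, int((~ok).sum())


def plot_condition_cdfs(
    tidy: pd.DataFrame,
    measure: str,
    path,
    unit_cols=("culture", "neuron"),
    conditions=CONDITIONS,
    log: bool = True,
):
    """Empirical CDF of a measure per condition (complete cases), saved to file."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    sub = tidy[["condition", *unit_cols, measure]].copy()
    if log:
        sub[measure], _ = _safe_log(sub[measure].to_numpy())
    wide = complete_case_matrix(sub, measure, unit_cols, conditions)
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    for cond in conditions:
        x = np.sort(wide[cond].to_numpy())
        ax.step(x, np.arange(1, len(x) + 1) / len(x), where="post", label=cond)
    ax.set_xlabel(f"log {measure}" if log else measure)
    ax.set_ylabel("cumulative fraction of neurons")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
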