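"""Statistical pipeline for pre/post two-group designs.

Two analyses cover the study design the toolkit supports:

* **Baseline comparison** — independent-samples Student t-test (pooled
  variance; Welch as an option) per parameter between two groups.
* **2 x 2 mixed repeated-measures ANOVA** — group (between) x time
  (within, pre/post) per parameter, computed from first principles via
  the difference/mean-score decomposition. For one within factor at two
  levels the design collapses exactly: with per-subject difference
  ``d_i = post_i - pre_i`` and mean ``s_i = (pre_i + post_i)/2``,

  - interaction F  = squared pooled two-sample t on the ``d_i``
  - time F        = squared t of the unweighted mean of the group
                    ``d`` means against zero (type-III cell means)
  - group F       = squared pooled two-sample t on the ``s_i``

  all on (1, N-2) degrees of freedom. The first identity is exposed as a
  built-in oracle for testing. Sphericity is moot with two within
  levels.

Per-parameter tests are reported at raw p against alpha = 0.05 by
default (no multiplicity correction); Holm adjustment is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import DEFAULT_CONFIG, RunConfig
from .errors import ContractError, ParameterError
from .metrics import TABLE_COLUMNS

logger = logging.getLogger(__name__)


class EffectResult(NamedTuple):
    F: float
    df1: int
    df2: int
    p: float
    significant: bool


@dataclass(frozen=True)
class StatResult:
    """Result of one test on one parameter."""

    parameter: str
    test: str                      # "independent-t" | "mixed-anova"
    statistic: float               # t for t-tests; interaction F for ANOVA
    df: float
    p: float
    significant: bool
    alpha: float = 0.05
    effects: Mapping[str, EffectResult] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Baseline between-group comparison
# ---------------------------------------------------------------------------

def _two_sample_t(
    a: np.ndarray, b: np.ndarray, variant: str = "student"
) -> tuple[float, float, float]:
    """(t, df, p); zero variance in both samples with equal means maps to
    the t = 0, p = 1 convention."""
    if len(a) < 2 or len(b) < 2:
        raise ContractError("each group needs at least 2 subjects")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            df = len(a) + len(b) - 2 if variant == "student" else float("nan")
            return 0.0, float(df), 1.0
        # distinct constants: infinitely strong evidence
        return float("inf"), float(len(a) + len(b) - 2), 0.0
    if variant == "student":
        t, p = sps.ttest_ind(a, b, equal_var=True)
        df = len(a) + len(b) - 2
    elif variant == "welch":
        res = sps.ttest_ind(a, b, equal_var=False)
        t, p = res.statistic, res.pvalue
        df = res.df
    else:
        raise ParameterError(f"unknown t variant {variant!r}")
    return float(t), float(df), float(p)


def baseline_compare(
    metrics: pd.DataFrame,
    groups: Sequence[str] | None = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> dict[str, StatResult]:
    """Per-parameter two-sample t-test between two groups.

    ``metrics`` is long format with columns subject_id, group, parameter,
    value (a single phase). Returns one :class:`StatResult` per
    parameter, ordered as encountered.
    """
    _require_columns(metrics, ["subject_id", "group", "parameter", "value"])
    groups = list(groups) if groups else sorted(metrics.group.unique())
    if len(groups) != 2:
        raise ContractError(f"baseline comparison needs exactly 2 groups, got {groups}")
    alpha = config.stats.alpha
    out: dict[str, StatResult] = {}
    for param in metrics.parameter.unique():
        sel = metrics[metrics.parameter == param]
        a = sel[sel.group == groups[0]].value.to_numpy(dtype=float)
        b = sel[sel.group == groups[1]].value.to_numpy(dtype=float)
        t, df, p = _two_sample_t(a, b, config.stats.t_variant)
        out[param] = StatResult(
            parameter=param,
            test="independent-t",
            statistic=t,
            df=df,
            p=p,
            significant=p < alpha,
            alpha=alpha,
        )
    if config.stats.holm:
        out = _holm_adjust(out)
    return out


# ---------------------------------------------------------------------------
# 2 x 2 mixed repeated-measures ANOVA
# ---------------------------------------------------------------------------

def mixed_anova_from_scores(
    pre_a: np.ndarray,
    post_a: np.ndarray,
    pre_b: np.ndarray,
    post_b: np.ndarray,
    alpha: float = 0.05,
    parameter: str = "",
) -> StatResult:
    """Mixed ANOVA for two groups (a, b) measured pre and post.

    Arrays are per-subject, matched within each group. See the module
    docstring for the difference/mean-score decomposition used.
    """
    n1, n2 = len(pre_a), len(pre_b)
    if n1 < 2 or n2 < 2:
        raise ContractError("each group needs at least 2 complete subjects")
    if len(post_a) != n1 or len(post_b) != n2:
        raise ContractError("pre and post must be matched per subject")
    N = n1 + n2
    inv = 1.0 / n1 + 1.0 / n2

    d1, d2 = post_a - pre_a, post_b - pre_b
    s1, s2 = (post_a + pre_a) / 2.0, (post_b + pre_b) / 2.0

    ss_werr = 0.5 * (np.sum((d1 - d1.mean()) ** 2) + np.sum((d2 - d2.mean()) ** 2))
    ms_werr = ss_werr / (N - 2)
    ss_int = (d1.mean() - d2.mean()) ** 2 / (2.0 * inv)
    m_time = (d1.mean() + d2.mean()) / 2.0
    ss_time = 2.0 * m_time**2 / inv

    ss_berr = 2.0 * (np.sum((s1 - s1.mean()) ** 2) + np.sum((s2 - s2.mean()) ** 2))
    ms_berr = ss_berr / (N - 2)
    ss_group = 2.0 * (s1.mean() - s2.mean()) ** 2 / inv

    effects = {
        "group": _f_effect(ss_group, ms_berr, N - 2, alpha),
        "time": _f_effect(ss_time, ms_werr, N - 2, alpha),
        "interaction": _f_effect(ss_int, ms_werr, N - 2, alpha),
    }
    inter = effects["interaction"]
    return StatResult(
        parameter=parameter,
        test="mixed-anova",
        statistic=inter.F,
        df=float(inter.df2),
        p=inter.p,
        significant=inter.significant,
        alpha=alpha,
        effects=effects,
    )


def _f_effect(ss: float, ms_err: float, df2: int, alpha: float) -> EffectResult:
    if ms_err == 0.0:
        f = 0.0 if ss == 0.0 else float("inf")
    else:
        f = ss / ms_err
    p = 1.0 if f == 0.0 else float(sps.f.sf(f, 1, df2))
    return EffectResult(F=float(f), df1=1, df2=df2, p=p, significant=p < alpha)


def mixed_anova(
    metrics: pd.DataFrame,
    groups: Sequence[str] | None = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> dict[str, StatResult]:
    """Per-parameter mixed ANOVA on a long pre/post table.

    ``metrics`` has columns subject_id, group, phase (pre/post),
    parameter, value. Subjects missing either phase are excluded listwise
    with a logged warning.
    """
    _require_columns(metrics, ["subject_id", "group", "phase", "parameter", "value"])
    groups = list(groups) if groups else sorted(metrics.group.unique())
    if len(groups) != 2:
        raise ContractError(f"mixed ANOVA needs exactly 2 groups, got {groups}")
    alpha = config.stats.alpha
    out: dict[str, StatResult] = {}
    for param in metrics.parameter.unique():
        sel = metrics[metrics.parameter == param]
        wide = sel.pivot_table(
            index=["subject_id", "group"], columns="phase", values="value"
        )
        if not {"pre", "post"} <= set(wide.columns):
            raise ContractError(f"{param}: need both 'pre' and 'post' phases")
        incomplete = wide[wide[["pre", "post"]].isna().any(axis=1)]
        if len(incomplete):
            logger.warning(
                "%s: excluding %d subject(s) missing a phase: %s",
                param,
                len(incomplete),
                [i[0] for i in incomplete.index],
            )
            wide = wide.dropna(subset=["pre", "post"])
        wide = wide.reset_index()
        ga = wide[wide.group == groups[0]]
        gb = wide[wide.group == groups[1]]
        out[param] = mixed_anova_from_scores(
            ga.pre.to_numpy(dtype=float),
            ga.post.to_numpy(dtype=float),
            gb.pre.to_numpy(dtype=float),
            gb.post.to_numpy(dtype=float),
            alpha=alpha,
            parameter=param,
        )
    if config.stats.holm:
        out = _holm_adjust(out)
    return out


def _holm_adjust(results: dict[str, StatResult]) -> dict[str, StatResult]:
    """Holm step-down adjustment of the primary p-values."""
    items = sorted(results.items(), key=lambda kv: kv[1].p)
    m = len(items)
    adjusted: dict[str, StatResult] = {}
    running_max = 0.0
    for rank, (name, res) in enumerate(items):
        p_adj = min(1.0, (m - rank) * res.p)
        running_max = max(running_max, p_adj)
        adjusted[name] = dataclass_replace(res, p=running_max, significant=running_max < res.alpha)
    return {k: adjusted[k] for k in results}


def dataclass_replace(res: StatResult, **changes) -> StatResult:
    import dataclasses

    return dataclasses.replace(res, **changes)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def _fmt_cell(values: np.ndarray) -> str:
    return f"{np.mean(values):.2f} ± {np.std(values, ddof=1):.2f}"


def _fmt_p(res: StatResult) -> str:
    star = " *" if res.significant else ""
    return f"{res.p:.4f}{star}"


def _row_label(param: str) -> str:
    return TABLE_COLUMNS.get(param, param)


def build_report(
    results: Mapping[str, StatResult],
    metrics: pd.DataFrame,
    groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean ± SD summary table with significance stars at p < alpha.

    For pre/post data (phase column with both levels) the layout is
    group x phase with the per-group p of the test; for single-phase data
    it is one column per group plus the between-group p. Regenerating the
    report from the same inputs is deterministic.
    """
    if not results:
        return pd.DataFrame()
    _require_columns(metrics, ["group", "parameter", "value"])
    groups = list(groups) if groups else sorted(metrics.group.unique())
    prepost = "phase" in metrics.columns and {"pre", "post"} <= set(
        metrics.phase.unique()
    )
    rows = []
    for param, res in results.items():
        sel = metrics[metrics.parameter == param]
        row: dict[str, str] = {"Parameter": _row_label(param)}
        if prepost:
            for g in groups:
                for phase in ("pre", "post"):
                    vals = sel[(sel.group == g) & (sel.phase == phase)].value
                    row[f"{g} {phase}"] = _fmt_cell(vals.to_numpy(dtype=float))
            row["p (interaction)"] = _fmt_p(res)
            if res.effects:
                row["p (time)"] = f"{res.effects['time'].p:.4f}"
                row["p (group)"] = f"{res.effects['group'].p:.4f}"
        else:
            for g in groups:
                vals = sel[sel.group == g].value
                row[g] = _fmt_cell(vals.to_numpy(dtype=float))
            row["p"] = _fmt_p(res)
        rows.append(row)
    return pd.DataFrame(rows).set_index("Parameter")


def _require_columns(df: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ContractError(f"table missing required columns: {missing}")
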