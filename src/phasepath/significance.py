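"""Statistical screen: group summaries, worked mean differences, one-way ANOVA.

The screen mirrors the workflow of the reference study: per-group mean and
sample standard deviation of each phase parameter (per tissue, state and
magnification), an informal comparison of the healthy-tumoral mean difference
against both group SDs, and a one-way ANOVA (Snedecor F) per cell with a
p < 0.005 significance rule.  No multiple-testing correction is applied; the
table reports the number of tests performed so readers can apply their own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reference import PARAMETERS, REPORTING_DECIMALS

ALPHA_DEFAULT = 0.005


@dataclass(frozen=True)
class GroupSummary:
    tissue: str
    state: str
    magnification: str
    parameter: str
    n: int
    mean: float
    sd: float  # sample SD (divisor n-1); NaN when n < 2


@dataclass(frozen=True)
class MeanDifferenceReport:
    """Worked comparison of one healthy/tumoral pair of group means."""

    tissue: str
    magnification: str
    parameter: str
    abs_difference: float  # |mean_T - mean_H|, rounded to reporting precision
    sd_healthy: float
    sd_tumoral: float
    exceeds: str  # 'both' | 'one' | 'neither'


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p_value: float
    df_between: int
    df_within: int
    significant: bool
    alpha: float = ALPHA_DEFAULT


def group_summary(
    cohort: pd.DataFrame,
    parameters: tuple[str, ...] = PARAMETERS,
) -> list[GroupSummary]:
    """Mean and sample SD per (tissue, magnification, state, parameter).

    Output ordering is deterministic: tissue, magnification, state (all
    alphabetical), then parameter order.  Groups with a single observation
    get ``sd = NaN``.
    """
    out: list[GroupSummary] = []
    keys = ["tissue", "magnification", "state"]
    for (tissue, mag, state), grp in sorted(
        cohort.groupby(keys), key=lambda kv: kv[0]
    ):
        for p in parameters:
            vals = grp[p].to_numpy(dtype=float)
            n = len(vals)
            sd = float(np.std(vals, ddof=1)) if n >= 2 else float("nan")
            out.append(
                GroupSummary(
                    tissue=tissue,
                    state=state,
                    magnification=mag,
                    parameter=p,
                    n=n,
                    mean=float(np.mean(vals)),
                    sd=sd,
                )
            )
    return out


def summary_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def mean_difference(
    summary_h: GroupSummary, summary_t: GroupSummary
) -> MeanDifferenceReport:
    """|mean_T - mean_H| for one parameter cell, compared against both SDs.

    The difference is rounded to the parameter's reporting precision (e.g. 4
    decimals for the refractive-index variance, 2 for the scattering
    coefficient), matching how the group means themselves are reported.
    """
    same_cell = (
        summary_h.tissue == summary_t.tissue
        and summary_h.magnification == summary_t.magnification
        and summary_h.parameter == summary_t.parameter
    )
    if not same_cell:
        raise ValueError("mean_difference needs summaries of the same tissue/magnification/parameter")
    if summary_h.state == summary_t.state:
        raise ValueError("mean_difference needs one healthy and one tumoral summary")

    decimals = REPORTING_DECIMALS.get(summary_h.parameter, 4)
    diff = round(abs(summary_t.mean - summary_h.mean), decimals)
    n_exceeded = int(diff > summary_h.sd) + int(diff > summary_t.sd)
    exceeds = {2: "both", 1: "one", 0: "neither"}[n_exceeded]
    return MeanDifferenceReport(
        tissue=summary_h.tissue,
        magnification=summary_h.magnification,
        parameter=summary_h.parameter,
        abs_difference=diff,
        sd_healthy=summary_h.sd if summary_h.state == "healthy" else summary_t.sd,
        sd_tumoral=summary_t.sd if summary_h.state == "healthy" else summary_h.sd,
        exceeds=exceeds,
    )


def reference_summaries(
    tissue: str, magnification: str, parameter: str, n: int = 100
) -> tuple[GroupSummary, GroupSummary]:
    """(healthy, tumoral) summaries of one cell of the published reference table."""
    from .reference import reference_group

    out = []
    for state in ("healthy", "tumoral"):
        mean, sd = reference_group(tissue, magnification, state)[parameter]
        out.append(
            GroupSummary(
                tissue=tissue,
                state=state,
                magnification=magnification,
                parameter=parameter,
                n=n,
                mean=mean,
                sd=sd,
            )
        )
    return tuple(out)


def one_way_anova(groups: list[np.ndarray], alpha: float = ALPHA_DEFAULT) -> AnovaResult:
    """One-way fixed-effects ANOVA: ``F = MS_between / MS_within``.

    The decomposition is computed explicitly from sums of squares (and
    cross-checked against the library routine in the test suite).  Degenerate
    cases follow the limiting behavior: all observations identical gives
    ``F = 0, p = 1``; zero within-group variance with unequal means gives
    ``F = inf, p = 0``.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least two observations")

    n_total = sum(len(a) for a in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = len(arrays) - 1
    df_within = n_total - len(arrays)

    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        if ms_between == 0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = float("inf"), 0.0
    else:
        f_stat = ms_between / ms_within
        p = float(stats.f.sf(f_stat, df_between, df_within))
    return AnovaResult(
        F=float(f_stat),
        p_value=p,
        df_between=df_between,
        df_within=df_within,
        significant=p < alpha,
        alpha=alpha,
    )


def significance_table(
    cohort: pd.DataFrame,
    alpha: float = ALPHA_DEFAULT,
    parameters: tuple[str, ...] = PARAMETERS,
) -> pd.DataFrame:
    """Healthy-vs-tumoral ANOVA p-value per (parameter, magnification, tissue).

    Returns a long-format frame with columns ``parameter, magnification,
    tissue, F, p_value, significant`` plus attrs ``n_tests`` and ``alpha``.
    Cells missing one of the two states are emitted with NaN and a warning
    column entry.
    """
    rows = []
    for (tissue, mag), grp in sorted(cohort.groupby(["tissue", "magnification"]), key=lambda kv: kv[0]):
        healthy = grp[grp.state == "healthy"]
        tumoral = grp[grp.state == "tumoral"]
        for p in parameters:
            row: dict = {"parameter": p, "magnification": mag, "tissue": tissue}
            hv = healthy[p].dropna().to_numpy(dtype=float)
            tv = tumoral[p].dropna().to_numpy(dtype=float)
            if len(hv) < 2 or len(tv) < 2:
                row.update(F=math.nan, p_value=math.nan, significant=False,
                           warning="missing state or too few observations")
            else:
                res = one_way_anova([hv, tv], alpha=alpha)
                row.update(F=res.F, p_value=res.p_value, significant=res.significant, warning="")
            rows.append(row)
    table = pd.DataFrame(rows)
    table.attrs["alpha"] = alpha
    table.attrs["n_tests"] = int(table.p_value.notna().sum())
    return table


def worked_difference_report(cohort_or_summaries, parameters=PARAMETERS) -> pd.DataFrame:
    """All healthy-vs-tumoral worked mean differences of a cohort or summary list."""
    if isinstance(cohort_or_summaries, pd.DataFrame):
        summaries = group_summary(cohort_or_summaries, parameters=parameters)
    else:
        summaries = list(cohort_or_summaries)
    by_cell: dict[tuple[str, str, str], dict[str, GroupSummary]] = {}
    for s in summaries:
        by_cell.setdefault((s.tissue, s.magnification, s.parameter), {})[s.state] = s
    rows = []
    for (tissue, mag, param), states in sorted(by_cell.items()):
        if {"healthy", "tumoral"} <= states.keys():
            rep = mean_difference(states["healthy"], states["tumoral"])
            rows.append(rep.__dict__)
    return pd.DataFrame(rows)


__all__ = [
    "ALPHA_DEFAULT",
    "GroupSummary",
    "MeanDifferenceReport",
    "AnovaResult",
    "group_summary",
    "summary_frame",
    "mean_difference",
    "one_way_anova",
    "significance_table",
    "worked_difference_report",
]
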