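"""Cohort-level statistics on the site x sample editing-level matrix.

Two analyses mirror the study design the package targets: per-site
Spearman correlation between editing level and age at death, computed
within each group and BH-corrected across sites, and per-site
Mann-Whitney U comparison of case versus control editing levels. The
case-control screen follows the convention of calling raw p < 0.05
significant while also reporting BH-adjusted q-values alongside, because
the two conventions coexist in this literature; users can filter on
either column. An optional age cutoff (strictly younger than) restricts
the analysis to a paediatric subgroup before any statistic is computed.

Ties are handled with midranks everywhere. Exact null distributions are
enumerated when feasible (all group labelings for Mann-Whitney, all age
permutations for Spearman at n <= 8) and replaced by the usual
approximations beyond.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import CohortError, InputError, ParameterError

_EXACT_PERM_N = 8  # Spearman: enumerate permutations up to this n
_EXACT_ENUM_COMB = 50_000  # Mann-Whitney: enumerate labelings up to this many
_EXACT_PRODUCT = 400  # Mann-Whitney: scipy exact distribution up to n1*n2


@dataclass
class CorrelationResult:
    site: str
    rho: float  # nan when undefined (zero variance)
    p_value: float
    q_value: float
    significant: bool
    n: int


@dataclass
class ComparisonResult:
    site: str
    u_statistic: float  # U of the case group
    p_value: float
    q_value: float
    direction: str | None  # "hyper" | "hypo" | None on tied medians
    significant: bool  # raw p < 0.05 convention
    n_case: int
    n_control: int


def _rank(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def spearman_age(
    levels: Sequence[float], ages: Sequence[float]
) -> tuple[float, float]:
    """Midrank Spearman correlation of editing level against age.

    Exact permutation p-value for n <= 8 (two-sided, enumerating all age
    orderings), t-approximation beyond. A zero-variance vector yields
    (nan, nan) — an undefined-correlation signal, not an exception.
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(ages, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("levels and ages must be aligned")
    n = len(x)
    if n < 3:
        raise ParameterError("Spearman correlation needs at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")

    rx = _rank(x) - (n + 1) / 2.0
    ry = _rank(y) - (n + 1) / 2.0
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    rho = float(rx @ ry) / denom

    if n <= _EXACT_PERM_N:
        perms = np.array(list(itertools.permutations(ry)))
        rho_null = (perms @ rx) / denom
        p = float(np.mean(np.abs(rho_null) >= abs(rho) - 1e-12))
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


def _mannwhitney_u(case: np.ndarray, control: np.ndarray) -> float:
    n1 = len(case)
    ranks = _rank(np.concatenate([case, control]))
    r1 = float(ranks[:n1].sum())
    return r1 - n1 * (n1 + 1) / 2.0


def mannwhitney_site(
    case_levels: Sequence[float], control_levels: Sequence[float]
) -> ComparisonResult:
    """Mann-Whitney U test of case versus control editing levels.

    U is computed from midranks. The two-sided p-value is
    P(|U - n1 n2 / 2| >= |u - n1 n2 / 2|) under random group labeling:
    enumerated exactly for small groups, from scipy's exact distribution
    when the groups are untied and moderately sized, and otherwise from
    the normal approximation with tie correction and continuity
    correction. Direction compares group medians (hyper = case above
    control); tied medians leave it None.
    """
    case = np.asarray(case_levels, dtype=float)
    control = np.asarray(control_levels, dtype=float)
    n1, n2 = len(case), len(control)
    if n1 == 0 or n2 == 0:
        raise ParameterError("both groups must be non-empty")

    u = _mannwhitney_u(case, control)
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([case, control])

    if np.ptp(pooled) == 0:
        p = 1.0
    elif math.comb(n1 + n2, n1) <= _EXACT_ENUM_COMB:
        ranks = _rank(pooled)
        offset = n1 * (n1 + 1) / 2.0
        combos = np.array(list(itertools.combinations(range(n1 + n2), n1)))
        u_null = ranks[combos].sum(axis=1) - offset
        p = float(np.mean(np.abs(u_null - mu) >= abs(u - mu) - 1e-12))
    elif n1 * n2 <= _EXACT_PRODUCT and len(np.unique(pooled)) == n1 + n2:
        p = float(
            stats.mannwhitneyu(case, control, alternative="two-sided", method="exact").pvalue
        )
    else:
        _, counts = np.unique(pooled, return_counts=True)
        n = n1 + n2
        tie_term = float(((counts**3 - counts).sum())) / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:
            p = 1.0
        else:
            z = (abs(u - mu) - 0.5) / math.sqrt(sigma2)
            p = float(2.0 * stats.norm.sf(max(z, 0.0)))
    p = min(p, 1.0)

    med_case, med_control = float(np.median(case)), float(np.median(control))
    if med_case > med_control:
        direction = "hyper"
    elif med_case < med_control:
        direction = "hypo"
    else:
        direction = None
    return ComparisonResult(
        site="",
        u_statistic=u,
        p_value=p,
        q_value=1.0,
        direction=direction,
        significant=p < 0.05,
        n_case=n1,
        n_control=n2,
    )


def bh_correct(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _normalize_design(design: pd.DataFrame) -> pd.DataFrame:
    d = design.copy()
    if "sample" in d.columns:
        d = d.set_index("sample")
    d.index = d.index.astype(str)
    required = {"group", "age"}
    missing = required - set(d.columns)
    if missing:
        raise CohortError(f"design is missing columns: {sorted(missing)}")
    if d.index.duplicated().any():
        raise CohortError("duplicate sample ids in design")
    bad = set(d["group"]) - {"case", "control"}
    if bad:
        raise CohortError(f"unknown group labels: {sorted(bad)}")
    if (d["age"].astype(float) < 0).any():
        raise CohortError("ages must be non-negative")
    return d


def run_cohort_analysis(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    subgroup_max_age: float | None = None,
) -> tuple[dict[str, list[CorrelationResult]], list[ComparisonResult]]:
    """Per-site age correlations per group and case-control comparisons.

    ``matrix`` holds editing levels with sites as rows and samples as
    columns; ``design`` maps each sample to a group ("case"/"control")
    and an age in years (a "sample" column or the index). When
    ``subgroup_max_age`` is given, only samples strictly younger are
    analysed. Correlation q-values are BH-corrected across sites within
    each group; comparison q-values across sites. Sites with undefined
    correlation (zero variance) are reported with nan and excluded from
    the BH family.
    """
    d = _normalize_design(design)
    cols = [str(c) for c in matrix.columns]
    unknown = set(cols) - set(d.index)
    if unknown:
        raise CohortError(f"samples without design rows: {sorted(unknown)}")
    d = d.loc[cols]

    if subgroup_max_age is not None:
        keep = d["age"].astype(float) < subgroup_max_age
        d = d[keep]
        matrix = matrix.loc[:, keep.values]
    for g in ("case", "control"):
        if (d["group"] == g).sum() == 0:
            raise CohortError(f"no {g} samples left after filtering")

    correlations: dict[str, list[CorrelationResult]] = {}
    for g in ("case", "control"):
        samples = d.index[d["group"] == g]
        ages = d.loc[samples, "age"].astype(float).to_numpy()
        results = []
        for site in matrix.index:
            levels = matrix.loc[site, samples].astype(float).to_numpy()
            if len(levels) < 3:
                rho, p = float("nan"), float("nan")
            else:
                rho, p = spearman_age(levels, ages)
            results.append(
                CorrelationResult(
                    site=str(site), rho=rho, p_value=p, q_value=float("nan"),
                    significant=False, n=len(levels),
                )
            )
        defined = [r for r in results if not math.isnan(r.p_value)]
        if defined:
            qvals = bh_correct([r.p_value for r in defined])
            for r, q in zip(defined, qvals):
                r.q_value = float(q)
                r.significant = r.q_value < 0.05
        correlations[g] = results

    case_samples = d.index[d["group"] == "case"]
    control_samples = d.index[d["group"] == "control"]
    comparisons: list[ComparisonResult] = []
    for site in matrix.index:
        res = mannwhitney_site(
            matrix.loc[site, case_samples].astype(float).to_numpy(),
            matrix.loc[site, control_samples].astype(float).to_numpy(),
        )
        res.site = str(site)
        comparisons.append(res)
    if comparisons:
        qvals = bh_correct([r.p_value for r in comparisons])
        for r, q in zip(comparisons, qvals):
            r.q_value = float(q)
    return correlations, comparisons


def category_summary(categories: Mapping[str, str] | Sequence[str]) -> pd.DataFrame:
    """Counts and percentages of sites per category.

    Accepts a site->category mapping or a plain category sequence; rows
    cover the full nine-category vocabulary so absent categories show as
    zero.
    """
    from .classify import CATEGORIES

    values = list(categories.values()) if isinstance(categories, Mapping) else list(categories)
    counts = pd.Series(values, dtype="object").value_counts()
    out = pd.DataFrame(index=pd.Index(CATEGORIES, name="category"))
    out["count"] = [int(counts.get(c, 0)) for c in CATEGORIES]
    total = out["count"].sum()
    out["percent"] = 100.0 * out["count"] / total if total else 0.0
    return out
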