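"""Nested case-control pipeline: cohort filters, 1:1 matching, 2x2 tests.

Subjects are filtered on the registry inclusion rules (complete data, no
heart failure of NYHA class II-IV, age 20-80), exposed subjects are matched
1:1 to unexposed controls exactly on sex and atrial fibrillation and by
nearest neighbor on age and BMI within calipers, and the exposure-outcome
association is summarized with prevalences, a Pearson chi-square, and the
Mantel-Haenszel stratified test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_FIELDS = ("age", "sex", "bmi", "af", "digoxin", "fatty_liver")


@dataclass
class CohortFilterReport:
    """Bookkeeping for the inclusion/exclusion stage.

    Exclusion reasons are counted under the precedence
    missing -> heart failure -> age, so the reason counts partition the
    exclusions; the total is precedence-independent.
    """

    n_input: int
    n_excluded_missing: int
    n_excluded_hf: int
    n_excluded_age: int
    n_remaining: int
    n_exposed_remaining: int

    @property
    def n_excluded_total(self) -> int:
        return self.n_excluded_missing + self.n_excluded_hf + self.n_excluded_age

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_excluded_total": self.n_excluded_total,
            "n_excluded_missing": self.n_excluded_missing,
            "n_excluded_hf": self.n_excluded_hf,
            "n_excluded_age": self.n_excluded_age,
            "n_remaining": self.n_remaining,
            "n_exposed_remaining": self.n_exposed_remaining,
        }


@dataclass
class MatchingCriteria:
    """1:1 matching: exact on sex and AF, calipers on age and BMI."""

    age_caliper: float = 2.0
    bmi_caliper: float = 1.0

    def __post_init__(self) -> None:
        if self.age_caliper <= 0 or self.bmi_caliper <= 0:
            raise ValueError("calipers must be positive")


@dataclass
class MatchedCohort:
    pairs: pd.DataFrame  # pair_id, case_id, control_id, distance
    cohort: pd.DataFrame  # matched subjects with a 'group' column
    unmatched_cases: list[str]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """a: exposed outcome+, b: exposed outcome-, c: unexposed outcome+,
    d: unexposed outcome-."""

    a: int
    b: int
    c: int
    d: int
    stratum: str | None = None

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


def apply_cohort_filters(
    registry: pd.DataFrame,
) -> tuple[pd.DataFrame, CohortFilterReport]:
    """Apply the inclusion/exclusion rules to a registry.

    Removes subjects with any missing required field, heart failure of
    NYHA class 2-4, or age outside [20, 80]. When an ``exam_date`` column
    exists, only the most recent record per subject is kept (else the last
    record wins) before filtering.
    """
    for col in REQUIRED_FIELDS:
        if col not in registry.columns:
            raise KeyError(f"registry lacks required column {col!r}")
    df = registry.copy()
    if "exam_date" in df.columns:
        df = df.sort_values("exam_date").groupby("subject_id", as_index=False).tail(1)
    elif "subject_id" in df.columns:
        df = df.groupby("subject_id", as_index=False).tail(1)
    n_input = len(df)

    missing = df[list(REQUIRED_FIELDS)].isna().any(axis=1)
    hf = df.get("hf_nyha", pd.Series(np.nan, index=df.index)).isin([2, 3, 4])
    age_bad = (df["age"] < 20) | (df["age"] > 80)

    # precedence: missing -> HF -> age
    excl_missing = missing
    excl_hf = hf & ~excl_missing
    excl_age = age_bad & ~excl_missing & ~excl_hf
    keep = ~(excl_missing | excl_hf | excl_age)

    filtered = df[keep].reset_index(drop=True)
    report = CohortFilterReport(
        n_input=n_input,
        n_excluded_missing=int(excl_missing.sum()),
        n_excluded_hf=int(excl_hf.sum()),
        n_excluded_age=int(excl_age.sum()),
        n_remaining=len(filtered),
        n_exposed_remaining=int(filtered["digoxin"].sum()),
    )
    return filtered, report


def match_case_control(
    registry: pd.DataFrame,
    criteria: MatchingCriteria | None = None,
    seed: int = 0,
    *,
    exposure: str = "digoxin",
) -> MatchedCohort:
    """Greedy 1:1 nearest-neighbor matching without replacement.

    Exact on sex and AF; candidate controls must be within both the age and
    BMI calipers; the matched control minimizes
    ``|d_age|/age_caliper + |d_bmi|/bmi_caliper``. Cases with the fewest
    eligible controls are matched first; ties in distance are broken by the
    lowest control subject_id. Unmatched cases are dropped and reported.
    The procedure is deterministic (the seed is accepted for interface
    stability; no random choices remain after the tie-breaking rules).
    """
    criteria = criteria or MatchingCriteria()
    cases = registry[registry[exposure].astype(bool)]
    controls = registry[~registry[exposure].astype(bool)]
    if cases.empty or controls.empty:
        raise ValueError("both exposed and unexposed pools must be non-empty")

    pairs: list[dict] = []
    unmatched: list[str] = []
    for (sex, af), case_grp in cases.groupby(["sex", "af"], sort=True):
        ctrl_grp = controls[(controls["sex"] == sex) & (controls["af"] == af)]
        ctrl_grp = ctrl_grp.sort_values("subject_id")
        if ctrl_grp.empty:
            unmatched.extend(case_grp["subject_id"].tolist())
            continue
        c_age = ctrl_grp["age"].to_numpy(dtype=float)
        c_bmi = ctrl_grp["bmi"].to_numpy(dtype=float)
        c_ids = ctrl_grp["subject_id"].to_numpy()
        available = np.ones(len(ctrl_grp), dtype=bool)

        a_age = case_grp["age"].to_numpy(dtype=float)
        a_bmi = case_grp["bmi"].to_numpy(dtype=float)
        a_ids = case_grp["subject_id"].to_numpy()
        # scarcity-first: order cases by initial eligible-control count
        n_elig = np.array(
            [
                int(
                    (
                        (np.abs(c_age - ca) <= criteria.age_caliper)
                        & (np.abs(c_bmi - cb) <= criteria.bmi_caliper)
                    ).sum()
                )
                for ca, cb in zip(a_age, a_bmi)
            ]
        )
        order = np.lexsort((a_ids, n_elig))
        for i in order:
            d_age = np.abs(c_age - a_age[i])
            d_bmi = np.abs(c_bmi - a_bmi[i])
            ok = (
                available
                & (d_age <= criteria.age_caliper)
                & (d_bmi <= criteria.bmi_caliper)
            )
            if not ok.any():
                unmatched.append(a_ids[i])
                continue
            dist = d_age / criteria.age_caliper + d_bmi / criteria.bmi_caliper
            dist = np.where(ok, dist, np.inf)
            j = int(np.argmin(dist))  # controls sorted by id => lowest id on ties
            available[j] = False
            pairs.append(
                {
                    "case_id": a_ids[i],
                    "control_id": c_ids[j],
                    "distance": float(dist[j]),
                    "sex": sex,
                    "af": bool(af),
                }
            )

    pairs_df = pd.DataFrame(pairs, columns=["case_id", "control_id", "distance", "sex", "af"])
    pairs_df = pairs_df.sort_values("case_id").reset_index(drop=True)
    pairs_df.insert(0, "pair_id", np.arange(len(pairs_df)))

    matched_ids = pd.concat([pairs_df["case_id"], pairs_df["control_id"]])
    cohort = registry[registry["subject_id"].isin(matched_ids)].copy()
    cohort["group"] = np.where(cohort[exposure].astype(bool), "case", "control")
    return MatchedCohort(pairs=pairs_df, cohort=cohort, unmatched_cases=sorted(unmatched))


def build_contingency(
    subjects: pd.DataFrame,
    exposure: str = "digoxin",
    outcome: str = "fatty_liver",
    stratum: str | None = None,
) -> ContingencyTable2x2:
    """Cross-tabulate boolean exposure and outcome columns."""
    for col in (exposure, outcome):
        vals = subjects[col]
        if not set(vals.dropna().unique()) <= {True, False, 0, 1}:
            raise TypeError(f"column {col!r} is not boolean")
    e = subjects[exposure].astype(bool).to_numpy()
    o = subjects[outcome].astype(bool).to_numpy()
    return ContingencyTable2x2(
        a=int((e & o).sum()),
        b=int((e & ~o).sum()),
        c=int((~e & o).sum()),
        d=int((~e & ~o).sum()),
        stratum=stratum,
    )


def prevalence(table: ContingencyTable2x2) -> tuple[float, float]:
    """Outcome prevalence (%) in the exposed and unexposed groups, one
    decimal."""
    n_exp = table.a + table.b
    n_unexp = table.c + table.d
    if n_exp == 0 or n_unexp == 0:
        raise ZeroDivisionError("prevalence needs non-empty groups")
    return (
        round(100.0 * table.a / n_exp, 1),
        round(100.0 * table.c / n_unexp, 1),
    )


def chi_square_2x2(
    table: ContingencyTable2x2, continuity: bool = False
) -> tuple[float, float]:
    """Pearson chi-square (optional Yates correction), 1 df."""
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1, c2 = table.margins()
    if min(r1, r2, c1, c2) == 0:
        raise ZeroDivisionError("chi-square undefined with a zero margin")
    n = table.n
    diff = abs(a * d - b * c)
    if continuity:
        diff = max(diff - n / 2.0, 0.0)
    statistic = n * diff**2 / (r1 * r2 * c1 * c2)
    return float(statistic), float(stats.chi2.sf(statistic, df=1))


def odds_ratio(table: ContingencyTable2x2) -> float:
    if table.b == 0 or table.c == 0:
        return float("inf") if table.a * table.d > 0 else float("nan")
    return (table.a * table.d) / (table.b * table.c)


def mantel_haenszel(
    tables: Sequence[ContingencyTable2x2], continuity: bool = False
) -> tuple[float, float, float]:
    """Cochran-Mantel-Haenszel test and common odds ratio over strata.

    Returns ``(statistic, common_or, p)``. The common OR is
    ``sum(a*d/n) / sum(b*c/n)``; the statistic is
    ``(|sum(a) - sum(E[a])| - cc)^2 / sum(Var[a])`` with the continuity
    correction ``cc = 0.5`` off by default.
    """
    if len(tables) == 0:
        raise ValueError("mantel_haenszel needs at least one stratum")
    sum_a = sum_ea = sum_var = 0.0
    num = den = 0.0
    any_informative = False
    for t in tables:
        r1, r2, c1, c2 = t.margins()
        n = t.n
        if n == 0:
            continue
        if min(r1, r2, c1, c2) == 0:
            continue  # degenerate stratum contributes nothing
        any_informative = True
        sum_a += t.a
        sum_ea += r1 * c1 / n
        sum_var += r1 * r2 * c1 * c2 / (n * n * (n - 1))
        num += t.a * t.d / n
        den += t.b * t.c / n
    if not any_informative or sum_var == 0:
        raise ZeroDivisionError("all strata degenerate; MH test undefined")
    diff = abs(sum_a - sum_ea)
    if continuity:
        diff = max(diff - 0.5, 0.0)
    statistic = diff**2 / sum_var
    common_or = num / den if den > 0 else float("inf")
    return float(statistic), float(common_or), float(stats.chi2.sf(statistic, df=1))


def stratified_tables(
    cohort: pd.DataFrame,
    exposure: str = "digoxin",
    outcome: str = "fatty_liver",
    strata: Sequence[str] = ("sex", "af"),
) -> list[ContingencyTable2x2]:
    """One 2x2 table per combination of stratifying variables."""
    out = []
    for key, grp in cohort.groupby(list(strata), sort=True):
        label = "/".join(str(k) for k in (key if isinstance(key, tuple) else (key,)))
        out.append(build_contingency(grp, exposure, outcome, stratum=label))
    return out


def covariate_balance(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    variables: Sequence[str],
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-variable mean +/- SD per group and a two-sided t-test p.

    Welch's test by default. Two degenerate-variance groups with equal
    means report p = 1 by convention.
    """
    rows = []
    for var in variables:
        x = group_a[var].dropna().to_numpy(dtype=float)
        y = group_b[var].dropna().to_numpy(dtype=float)
        if len(x) < 2 or len(y) < 2:
            raise ValueError(f"variable {var!r}: need >= 2 observations per group")
        if np.std(x) == 0 and np.std(y) == 0:
            p = 1.0 if np.mean(x) == np.mean(y) else 0.0
            t = 0.0 if p == 1.0 else float("inf")
        else:
            t, p = stats.ttest_ind(x, y, equal_var=equal_var)
        rows.append(
            {
                "variable": var,
                "mean_a": float(np.mean(x)),
                "sd_a": float(np.std(x, ddof=1)),
                "mean_b": float(np.mean(y)),
                "sd_b": float(np.std(y, ddof=1)),
                "t": float(t),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)
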