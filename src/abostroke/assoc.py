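"""Blood-type association machinery: contingency tables, rank tests, odds ratios.

Categorical comparisons between the O and non-O groups (stroke subtype
distributions, risk-factor prevalences) use the Pearson chi-square test of
independence without continuity correction; continuous biomarkers use the
Wilcoxon rank-sum (Mann-Whitney) test with exact enumeration for small
groups and a tie- and continuity-corrected normal approximation otherwise.
Row percentages are rounded half-up to two decimals to match conventional
clinical-table formatting.

The module also ships the published CCS-subtype-by-blood-type counts for
the 9,542-patient ischaemic stroke cohort as a fixture
(:data:`TABLE1_COUNTS`), so the association stage is exercisable with zero
external inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bloodtype import BloodType, BloodTypeCall

SUBTYPES = ("LAA", "CE", "SAO", "OE", "UE")

#: Published CCS classification counts by blood type (rows O, non-O; columns
#: LAA, CE, SAO, OE, UE) for the 9,542 ischaemic stroke patients.
TABLE1_COUNTS = pd.DataFrame(
    [[708, 193, 806, 21, 1091], [2030, 475, 1770, 55, 2393]],
    index=pd.Index(["O", "non_O"], name="blood_type"),
    columns=list(SUBTYPES),
)

#: First-ever-stroke subtype totals (LAA, CE, SAO, OE, UE) out of 7,368.
FIRST_EVER_SUBTYPE_TOTALS = pd.Series(
    [2055, 502, 2060, 59, 2692], index=list(SUBTYPES), name="first_ever"
)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), as used in printed tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ContingencyTable:
    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray
    row_percents: np.ndarray
    chi2: float
    df: int
    p_value: float

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for i, r in enumerate(self.row_labels):
            rows[r] = {
                c: f"{self.counts[i, j]} ({self.row_percents[i, j]:.2f})"
                for j, c in enumerate(self.col_labels)
            }
        df = pd.DataFrame(rows).T
        df.index.name = "blood_type"
        return df


def chi_square_test(counts: np.ndarray, yates: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square of independence on an r x c count matrix.

    Uncorrected by default (``yates`` enables the 2x2 continuity
    correction).  Zero marginals, or any zero expected count, are an error:
    collapse the offending category first.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.min() < 0:
        raise ValueError("counts must be non-negative")
    if counts.sum(axis=0).min() == 0 or counts.sum(axis=1).min() == 0:
        raise ValueError("zero marginal total; collapse the empty category")
    chi2, p, df, expected = stats.chi2_contingency(counts, correction=yates)
    if expected.min() <= 0:
        raise ValueError("zero expected cell count; collapse categories")
    return float(chi2), int(df), float(p)


def build_contingency(
    calls: Sequence[BloodTypeCall],
    labels: dict[str, str],
    col_labels: Sequence[str] = SUBTYPES,
    min_posterior: float = 0.0,
) -> ContingencyTable:
    """Cross-tabulate blood type against a per-sample categorical label.

    Missing blood-type calls (and calls below ``min_posterior``) are
    excluded.  Every non-missing call must have a label.
    """
    counts = np.zeros((2, len(col_labels)), dtype=np.int64)
    col_idx = {c: j for j, c in enumerate(col_labels)}
    n_missing = 0
    for c in calls:
        if c.blood_type is BloodType.MISSING or c.posterior < min_posterior:
            n_missing += 1
            continue
        if c.sample_id not in labels:
            raise ValueError(f"sample {c.sample_id} has no category label")
        row = 0 if c.blood_type is BloodType.O else 1
        counts[row, col_idx[labels[c.sample_id]]] += 1
    if n_missing:
        import logging

        logging.getLogger(__name__).info("excluded %d missing/low-posterior calls", n_missing)
    return contingency_from_counts(counts, ["O", "non_O"], list(col_labels))


def contingency_from_counts(
    counts: np.ndarray, row_labels: Sequence[str], col_labels: Sequence[str]
) -> ContingencyTable:
    counts = np.asarray(counts)
    chi2, df, p = chi_square_test(counts)
    row_tot = counts.sum(axis=1, keepdims=True)
    pct = np.vectorize(round_half_up)(100.0 * counts / row_tot)
    return ContingencyTable(list(row_labels), list(col_labels), counts, pct, chi2, df, p)


def odds_ratio(table2x2: np.ndarray) -> tuple[float, float, float]:
    """Odds ratio with 95% CI by Woolf's log method.

    Any zero cell triggers the Haldane-Anscombe +0.5 correction applied to
    all four cells.
    """
    t = np.asarray(table2x2, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("odds_ratio requires a 2x2 table")
    if t.min() < 0:
        raise ValueError("counts must be non-negative")
    if (t == 0).any():
        t = t + 0.5
    a, b = t[0]
    c, d = t[1]
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = math.exp(math.log(or_) - 1.959964 * se), math.exp(math.log(or_) + 1.959964 * se)
    return or_, lo, hi


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns the rank sum W of ``x`` (midranks for ties) and the two-sided p.
    Small samples (min group < 20) are evaluated by exact enumeration of the
    permutation distribution; larger samples use the normal approximation
    with tie correction and continuity correction.  Identical constant data
    in both groups gives p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([x, y]))
    w = float(ranks[: len(x)].sum())
    if np.ptp(np.concatenate([x, y])) == 0:
        return w, 1.0
    if min(len(x), len(y)) < 20:
        n_perm = math.comb(len(x) + len(y), len(x))
        method = stats.PermutationMethod(n_resamples=max(n_perm + 1, 10000))
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return w, float(res.pvalue)


def cohort_filter(
    n_total: int, n_failed_abo: int, n_tia: int, n_prior_stroke: int
) -> tuple[int, int]:
    """Apply the cohort exclusion arithmetic.

    From ``n_total`` genotyped patients, those failing ABO-locus sequencing
    and those with transient ischaemic attack are excluded to give the
    ischaemic-stroke cohort; removing patients with prior stroke gives the
    first-ever-stroke subset.
    """
    for v in (n_total, n_failed_abo, n_tia, n_prior_stroke):
        if v < 0:
            raise ValueError("counts must be non-negative")
    n_is = n_total - n_failed_abo - n_tia
    if n_is < 0:
        raise ValueError("exclusions exceed the running total")
    n_first = n_is - n_prior_stroke
    if n_first < 0:
        raise ValueError("exclusions exceed the running total")
    return n_is, n_first


@dataclass
class GroupComparison:
    variable: str
    group_summaries: dict[str, str]
    test: str
    p_value: float


def compare_groups(
    sheet: pd.DataFrame,
    calls: Sequence[BloodTypeCall],
    continuous: Sequence[str] = (),
    categorical: Sequence[str] = (),
    bh: bool = False,
) -> pd.DataFrame:
    """Baseline-characteristics comparison between O and non-O samples.

    Continuous variables are summarised as median (IQR) and tested by
    Wilcoxon rank-sum; categorical ones as n (%) per level with chi-square.
    Missing values are dropped pairwise per variable.  Raw p-values are
    reported; ``bh=True`` appends a Benjamini-Hochberg column.
    """
    bt = {c.sample_id: c.blood_type for c in calls}
    df = sheet.copy()
    df["_bt"] = df["sample_id"].map(bt)
    df = df[df["_bt"].isin([BloodType.O, BloodType.NON_O])]
    rows = []
    for var in continuous:
        sub = df[["_bt", var]].dropna()
        xo = sub.loc[sub["_bt"] == BloodType.O, var].to_numpy()
        xn = sub.loc[sub["_bt"] == BloodType.NON_O, var].to_numpy()
        _, p = wilcoxon_rank_sum(xo, xn)
        summ = {
            g.value: _median_iqr(v)
            for g, v in ((BloodType.O, xo), (BloodType.NON_O, xn))
        }
        rows.append(GroupComparison(var, summ, "wilcoxon", p))
    for var in categorical:
        sub = df[["_bt", var]].dropna()
        tab = pd.crosstab(sub["_bt"].map(lambda b: b.value), sub[var])
        chi2, _, p = chi_square_test(tab.to_numpy())
        summ = {
            r: "; ".join(
                f"{c}: {tab.loc[r, c]} ({round_half_up(100 * tab.loc[r, c] / tab.loc[r].sum()):.2f}%)"
                for c in tab.columns
            )
            for r in tab.index
        }
        rows.append(GroupComparison(var, summ, "chi_square", p))
    out = pd.DataFrame(
        {
            "variable": [r.variable for r in rows],
            "O": [r.group_summaries.get("O", "") for r in rows],
            "non_O": [r.group_summaries.get("non_O", "") for r in rows],
            "test": [r.test for r in rows],
            "p_value": [r.p_value for r in rows],
        }
    )
    if bh and len(out):
        from statsmodels.stats.multitest import multipletests

        out["q_value_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def _median_iqr(v: np.ndarray) -> str:
    if len(v) == 0:
        return "NA"
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return f"{med:.1f} ({q1:.1f}-{q3:.1f})"
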