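"""Normality-gated two-sample comparisons, Fisher tests, and the
cross-cohort relative-difference summary.

Numeric markers are compared with a Welch t-test when an Anderson-Darling
test accepts normality in both groups, and a tie-corrected Wilcoxon
rank-sum otherwise.  Binary traits (hub status, per-disease-class
association) use Fisher's exact test.  Significance is reported in two
tiers, p < 0.05 and p < 0.0001, and no multiple-testing correction is
applied to the pairwise marker comparisons (the enrichment analysis applies
its own FDR separately).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._util import iqr, log

AD_ALPHA = 0.05
TIER_STRONG = 1e-4
TIER_WEAK = 0.05
MIN_N_FOR_NORMALITY = 8

#: Cohort pairs compared for every numeric marker.
COHORT_PAIRS = [
    (a, b) for a in ("Dh", "Dl", "D", "Dplus") for b in ("N", "Nd", "Nn")
] + [("Nd", "Nn")]


@dataclasses.dataclass
class ComparisonResult:
    marker: str
    pair: tuple
    test: str  # 't' | 'wilcoxon' | 'fisher'
    statistic: float
    p_value: float
    tier: str  # 'ns' | 'p<0.05' | 'p<0.0001'
    median_a: float | None = None
    median_b: float | None = None
    iqr_a: float | None = None
    iqr_b: float | None = None
    n_a: int = 0
    n_b: int = 0
    normality_gate: str | None = None  # which branch was taken and why


def significance_tier(p: float) -> str:
    if p < TIER_STRONG:
        return "p<0.0001"
    if p < TIER_WEAK:
        return "p<0.05"
    return "ns"


def anderson_darling(sample) -> tuple:
    """Anderson-Darling normality test, case 3 (mean and variance estimated).

    Returns the small-sample adjusted statistic A2* = A2 (1 + 0.75/n +
    2.25/n^2) and a p-value from the standard piecewise exponential
    approximation.  Constant samples are reported as non-normal (p = 0).
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < MIN_N_FOR_NORMALITY:
        raise ValueError(f"Anderson-Darling requires n >= {MIN_N_FOR_NORMALITY}, got {n}")
    mean = x.mean()
    std = x.std(ddof=1)
    if std == 0:
        log.warning("anderson_darling: constant sample treated as non-normal")
        return math.inf, 0.0
    z = sps.norm.cdf((x - mean) / std)
    z = np.clip(z, 1e-300, 1 - 1e-16)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (np.log(z) + np.log1p(-z[::-1])))
    a2_star = a2 * (1 + 0.75 / n + 2.25 / n**2)
    p = _ad_p_value(a2_star)
    return float(a2_star), float(p)


def _ad_p_value(a2: float) -> float:
    # D'Agostino & Stephens piecewise exponential approximation
    if a2 >= 0.6:
        p = math.exp(1.2937 - 5.709 * a2 + 0.0186 * a2 * a2)
    elif a2 > 0.34:
        p = math.exp(0.9177 - 4.279 * a2 - 1.38 * a2 * a2)
    elif a2 > 0.2:
        p = 1 - math.exp(-8.318 + 42.796 * a2 - 59.938 * a2 * a2)
    else:
        p = 1 - math.exp(-13.436 + 101.14 * a2 - 223.73 * a2 * a2)
    return min(max(p, 0.0), 1.0)


def compare_numeric(x, y, marker: str = "", pair: tuple = ("A", "B")) -> ComparisonResult:
    """Two-sided two-sample comparison with a normality gate.

    Welch's t-test when Anderson-Darling accepts normality (p >= 0.05) in
    both samples; otherwise the Wilcoxon rank-sum test with tie-corrected
    normal approximation and continuity correction.  Samples smaller than 8
    force the rank-sum branch (the normality test is unreliable there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample in compare_numeric")
    if x.size < MIN_N_FOR_NORMALITY or y.size < MIN_N_FOR_NORMALITY:
        gate = "rank-sum forced (n < 8)"
        log.info("compare_numeric %s %s: %s", marker, pair, gate)
        normal = False
    else:
        p_x = anderson_darling(x)[1]
        p_y = anderson_darling(y)[1]
        normal = p_x >= AD_ALPHA and p_y >= AD_ALPHA
        gate = f"AD p=({p_x:.3g}, {p_y:.3g}) -> {'t' if normal else 'wilcoxon'}"
    if normal:
        stat, p = sps.ttest_ind(x, y, equal_var=False)
        test = "t"
    else:
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            stat, p = 0.0, 1.0  # both samples constant and identical
        else:
            stat, p = sps.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            )
        test = "wilcoxon"
    return ComparisonResult(
        marker=marker,
        pair=tuple(pair),
        test=test,
        statistic=float(stat),
        p_value=float(p),
        tier=significance_tier(float(p)),
        median_a=float(np.median(x)),
        median_b=float(np.median(y)),
        iqr_a=iqr(x),
        iqr_b=iqr(y),
        n_a=int(x.size),
        n_b=int(y.size),
        normality_gate=gate,
    )


def fisher_exact(a: int, b: int, c: int, d: int, alternative: str = "two-sided") -> tuple:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Two-sided p sums hypergeometric probabilities of all tables (margins
    fixed) no more probable than the observed one.  Odds ratio is ad/bc with
    inf when bc = 0 (and nan for the empty 0/0 case).
    """
    table = np.array([[a, b], [c, d]])
    if np.any(table < 0):
        raise ValueError("negative cell count")
    if table.sum() == 0:
        raise ValueError("all-zero contingency table")
    odds, p = sps.fisher_exact(table, alternative=alternative)
    bc = b * c
    odds = math.inf if bc == 0 and a * d > 0 else (a * d / bc if bc else math.nan)
    return odds, float(p)


def compare_binary(x_pos, x_n, y_pos, y_n, marker: str = "", pair: tuple = ("A", "B")):
    """Fisher comparison of a binary trait between two cohorts."""
    odds, p = fisher_exact(x_pos, x_n - x_pos, y_pos, y_n - y_pos)
    return ComparisonResult(
        marker=marker,
        pair=tuple(pair),
        test="fisher",
        statistic=odds,
        p_value=p,
        tier=significance_tier(p),
        n_a=int(x_n),
        n_b=int(y_n),
    )


def relative_difference(
    markers: pd.DataFrame, partition, columns=None, reference: str = "D"
) -> pd.DataFrame:
    """Cross-cohort summary (median(X) - median(D)) / IQR(D) per marker.

    The reference cohort's row is identically zero; entries are absent (NaN)
    when the reference IQR is zero or either side lacks values.
    """
    ref_ids = sorted(partition[reference])
    if columns is None:
        columns = [c for c in markers.columns if markers[c].dtype.kind in "fi"
                   and c not in ("length", "is_hub")]
    out = {}
    ref = markers.loc[[p for p in ref_ids if p in markers.index]]
    for cohort, members in partition.cohorts.items():
        ids = [p for p in sorted(members) if p in markers.index]
        row = {}
        for col in columns:
            ref_vals = ref[col].dropna().to_numpy()
            vals = markers.loc[ids, col].dropna().to_numpy()
            if ref_vals.size < 4 or vals.size == 0:
                row[col] = np.nan
                continue
            ref_iqr = iqr(ref_vals)
            if ref_iqr == 0:
                log.warning("relative_difference: IQR(%s)=0 for %s, entry absent",
                            reference, col)
                row[col] = np.nan
                continue
            row[col] = (float(np.median(vals)) - float(np.median(ref_vals))) / ref_iqr
        out[cohort] = row
    return pd.DataFrame(out).T[list(columns)]


def compare_all(
    markers: pd.DataFrame,
    partition,
    numeric_columns=None,
    binary_columns=("is_hub",),
    disease_classes: pd.DataFrame | None = None,
    pairs=None,
) -> list:
    """Every numeric marker for every cohort pair, plus Fisher tests for
    binary traits and (optionally) per-disease-class association.

    ``disease_classes`` is the protein/disease-class table; when given, the
    D-vs-N association rate is Fisher-tested per class.
    """
    pairs = COHORT_PAIRS if pairs is None else pairs
    if numeric_columns is None:
        numeric_columns = [
            c for c in markers.columns
            if c not in binary_columns and c != "length" and markers[c].dtype.kind in "fi"
        ]
    results = []
    members = {name: [p for p in sorted(ids) if p in markers.index]
               for name, ids in partition.cohorts.items()}
    for col in numeric_columns:
        for a, b in pairs:
            x = markers.loc[members[a], col].dropna()
            y = markers.loc[members[b], col].dropna()
            if x.empty or y.empty:
                log.info("compare_all: skipping %s %s vs %s (no values)", col, a, b)
                continue
            results.append(compare_numeric(x, y, marker=col, pair=(a, b)))
    for col in binary_columns:
        if col not in markers.columns:
            continue
        for a, b in pairs:
            x = markers.loc[members[a], col].dropna()
            y = markers.loc[members[b], col].dropna()
            if x.empty or y.empty:
                continue
            results.append(
                compare_binary(int(x.sum()), len(x), int(y.sum()), len(y),
                               marker=col, pair=(a, b))
            )
    if disease_classes is not None and not disease_classes.empty:
        d_ids, n_ids = set(partition["D"]), set(partition["N"])
        for cls, grp in disease_classes.groupby("disease_class"):
            assoc = set(grp["protein_id"])
            results.append(
                compare_binary(
                    len(d_ids & assoc), len(d_ids), len(n_ids & assoc), len(n_ids),
                    marker=f"disease_class:{cls}", pair=("D", "N"),
                )
            )
    return results


def results_to_frame(results) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in results]
    df = pd.DataFrame(rows)
    if not df.empty:
        df["cohort_a"] = [p[0] for p in df["pair"]]
        df["cohort_b"] = [p[1] for p in df["pair"]]
        df = df.drop(columns=["pair"])
    return df
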