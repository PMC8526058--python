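"""Paired and group statistics for double-patch circuit-mapping data.

The centrepiece is the normality-gated test selection used throughout the
analysis: each dataset is screened with two omnibus normality tests
(D'Agostino-Pearson and Anderson-Darling) and only datasets passing *both*
receive parametric tests (paired/unpaired t); otherwise the rank-based
analogue is used (Wilcoxon matched pairs / Mann-Whitney).  Double-patch
data are always compared with paired statistics, since the two neurons of
a pair share stimulation and slice.

Also here: the coefficient of variation of repeated evoked EPSC amplitudes
(inversely related to release probability and synapse number), percent
change between group means, a sign-flip permutation test used as an
assumption-free cross-check, and the genotype x condition interaction
ANOVA with Sidak-corrected pairwise comparisons.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import InvalidParameterError

__all__ = [
    "PairedMeasure", "TestResult",
    "coefficient_of_variation", "percent_change",
    "normality_tests", "choose_paired_test", "paired_compare",
    "unpaired_compare", "sign_flip_test", "interaction_anova",
    "sidak_pairwise", "binomial_cv",
]

log = logging.getLogger(__name__)

#: below this many pairs the omnibus normality tests are uninformative and
#: the nonparametric branch is taken directly
MIN_N_FOR_NORMALITY = 8


@dataclass
class PairedMeasure:
    """One metric evaluated on a WT/KO neighbouring pair."""

    pair_id: str
    wt_value: float
    ko_value: float
    metric: str = ""
    condition: dict = field(default_factory=dict)

    @property
    def complete(self) -> bool:
        return (self.wt_value is not None and self.ko_value is not None
                and math.isfinite(self.wt_value) and math.isfinite(self.ko_value))

    @property
    def difference(self) -> float:
        return self.ko_value - self.wt_value

    @property
    def ratio(self) -> float:
        return self.ko_value / self.wt_value


@dataclass
class TestResult:
    """Outcome of one statistical comparison."""

    test: str                    # paired t | Wilcoxon | unpaired t | Mann-Whitney | ANOVA interaction
    statistic: float
    pvalue: float
    n: int
    df: Optional[tuple] = None
    normality: dict = field(default_factory=dict)
    alpha: float = 0.05
    notes: str = ""

    def __post_init__(self):
        if not (0.0 <= self.pvalue <= 1.0):
            raise InvalidParameterError(f"p-value {self.pvalue} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.pvalue < self.alpha


# ---------------------------------------------------------------------------
# simple summaries

def coefficient_of_variation(amplitudes) -> float:
    """Sample SD / mean of repeated evoked EPSC amplitudes of one cell.

    C.V. is inversely related to release probability and release-site
    number, so an increase indicates a presynaptic weakening.  Requires at
    least 3 trials and a positive mean.
    """
    a = np.asarray(amplitudes, dtype=float)
    if a.size < 3:
        raise InvalidParameterError("CV needs at least 3 trials")
    m = a.mean()
    if m <= 0:
        raise InvalidParameterError("CV undefined for non-positive mean")
    return float(a.std(ddof=1) / m)


def binomial_cv(n_sites: int, p_release: float) -> float:
    """Closed-form CV of binomial release with fixed quantal size:
    ``sqrt((1 - p) / (N p))``."""
    if n_sites < 1 or not (0 < p_release <= 1):
        raise InvalidParameterError("invalid binomial parameters")
    return math.sqrt((1.0 - p_release) / (n_sites * p_release))


def percent_change(reference: float, test: float,
                   rounding_step: Optional[float] = None) -> float:
    """Percent reduction of ``test`` relative to ``reference``:
    ``100 * (1 - test/reference)``, optionally rounded to the nearest
    ``rounding_step`` percent (e.g. 5 for "~40 %"-style statements)."""
    if reference <= 0:
        raise InvalidParameterError("reference must be positive")
    pc = 100.0 * (1.0 - test / reference)
    if rounding_step is not None:
        if rounding_step <= 0:
            raise InvalidParameterError("rounding_step must be positive")
        pc = rounding_step * np.round(pc / rounding_step)
    return float(pc)


# ---------------------------------------------------------------------------
# normality gate

def normality_tests(x, alpha: float = 0.05) -> dict:
    """Run both omnibus normality tests on one sample.

    Returns the D'Agostino-Pearson (statistic, p) and Anderson-Darling
    (statistic, critical value at ``alpha``) results plus the combined
    verdict ``both_normal`` — True only if both tests fail to reject.
    """
    x = np.asarray(x, dtype=float)
    if x.size < MIN_N_FOR_NORMALITY:
        raise InvalidParameterError(
            f"normality tests need n >= {MIN_N_FOR_NORMALITY}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dag_stat, dag_p = sps.normaltest(x)
        ad = sps.anderson(x, dist="norm", method="interpolate")
    return {
        "dagostino_stat": float(dag_stat),
        "dagostino_p": float(dag_p),
        "anderson_stat": float(ad.statistic),
        "anderson_p": float(ad.pvalue),
        "alpha": alpha,
        "both_normal": bool(dag_p > alpha and ad.pvalue > alpha),
    }


def choose_paired_test(differences, alpha: float = 0.05) -> tuple:
    """Gated test selection on the paired differences.

    Returns ``(test_name, normality_info)``.  Parametric ("paired t") only
    when both normality tests pass at ``alpha``; tiny samples (< 8) and
    degenerate (zero-variance) samples fall back to "Wilcoxon".
    """
    d = np.asarray(differences, dtype=float)
    if d.size < MIN_N_FOR_NORMALITY:
        log.warning("n=%d too small for normality testing; using Wilcoxon", d.size)
        return "Wilcoxon", {"both_normal": False,
                            "reason": f"n < {MIN_N_FOR_NORMALITY}"}
    if np.allclose(d, d[0]):
        return "Wilcoxon", {"both_normal": False, "reason": "zero variance"}
    info = normality_tests(d, alpha=alpha)
    return ("paired t" if info["both_normal"] else "Wilcoxon"), info


def _wilcoxon(d: np.ndarray) -> tuple:
    """Two-sided Wilcoxon matched-pairs on differences; all-zero -> (0, 1)."""
    if np.all(d == 0):
        return 0.0, 1.0
    res = sps.wilcoxon(d, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def paired_compare(pairs: list, alpha: float = 0.05,
                   metric: str = "") -> TestResult:
    """Normality-gated two-sided paired comparison of WT vs KO values.

    Incomplete pairs (a missing or non-finite member) are dropped with a
    log entry.  Needs at least 3 complete pairs.
    """
    complete = [p for p in pairs if p.complete]
    dropped = len(pairs) - len(complete)
    if dropped:
        log.info("paired_compare(%s): dropped %d incomplete pair(s)", metric, dropped)
    if len(complete) < 3:
        raise InvalidParameterError("need at least 3 complete pairs")
    d = np.array([p.difference for p in complete])
    test, info = choose_paired_test(d, alpha=alpha)
    if test == "paired t":
        wt = np.array([p.wt_value for p in complete])
        ko = np.array([p.ko_value for p in complete])
        res = sps.ttest_rel(ko, wt)
        stat, p = float(res.statistic), float(res.pvalue)
        dfree = (len(complete) - 1,)
    else:
        stat, p = _wilcoxon(d)
        dfree = None
    return TestResult(test=test, statistic=stat, pvalue=p, n=len(complete),
                      df=dfree, normality=info, alpha=alpha,
                      notes=f"dropped={dropped}" if dropped else "")


def unpaired_compare(group_a, group_b, alpha: float = 0.05) -> TestResult:
    """Normality-gated two-sided unpaired comparison (t / Mann-Whitney).

    Parametric only if *both* groups pass both normality tests.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 3 or b.size < 3:
        raise InvalidParameterError("need at least 3 values per group")
    normal = False
    info = {}
    if a.size >= MIN_N_FOR_NORMALITY and b.size >= MIN_N_FOR_NORMALITY \
            and not np.allclose(a, a[0]) and not np.allclose(b, b[0]):
        ia = normality_tests(a, alpha)
        ib = normality_tests(b, alpha)
        normal = ia["both_normal"] and ib["both_normal"]
        info = {"group_a": ia, "group_b": ib, "both_normal": normal}
    if normal:
        res = sps.ttest_ind(a, b)
        return TestResult(test="unpaired t", statistic=float(res.statistic),
                          pvalue=float(res.pvalue), n=a.size + b.size,
                          df=(a.size + b.size - 2,), normality=info, alpha=alpha)
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return TestResult(test="Mann-Whitney", statistic=float(res.statistic),
                      pvalue=float(res.pvalue), n=a.size + b.size,
                      normality=info, alpha=alpha)


def sign_flip_test(differences, n_perm: int = 10000,
                   rng: Optional[np.random.Generator] = None) -> float:
    """Exact-style sign-flip permutation p-value for paired differences.

    Distribution-free companion to the gated paired test: the mean
    difference is compared with its distribution under random sign flips
    of each pair.  Two-sided; add-one correction keeps p in (0, 1].
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise InvalidParameterError("need at least 2 differences")
    if rng is None:
        rng = np.random.default_rng(0)
    obs = abs(d.mean())
    signs = rng.choice([-1.0, 1.0], size=(n_perm, d.size))
    perm = np.abs(signs @ d) / d.size
    return float((1 + np.sum(perm >= obs - 1e-12)) / (n_perm + 1))


# ---------------------------------------------------------------------------
# two-way interaction ANOVA

def interaction_anova(data: pd.DataFrame, value: str, factor_a: str,
                      factor_b: str, alpha: float = 0.05) -> TestResult:
    """Classical two-way ANOVA; returns the A x B interaction.

    ``data`` is tidy, one row per cell, with ``value`` the (power-
    normalised) metric and two two-level categorical factors (e.g.
    genotype and age group or deprivation condition).  Every design cell
    must be populated.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = data[[value, factor_a, factor_b]].dropna().copy()
    counts = df.groupby([factor_a, factor_b], observed=True).size()
    la = df[factor_a].nunique()
    lb = df[factor_b].nunique()
    if la < 2 or lb < 2 or len(counts) < la * lb:
        raise InvalidParameterError("empty cell in the two-way design")
    df = df.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
    if np.var(df["_y"].to_numpy()) == 0:
        # identical values everywhere: no variance to partition
        n_cells = la * lb
        return TestResult(test="ANOVA interaction", statistic=0.0, pvalue=1.0,
                          n=len(df), df=((la - 1) * (lb - 1),
                                         len(df) - n_cells), alpha=alpha,
                          notes=f"{factor_a} x {factor_b} (degenerate)")
    model = smf.ols("_y ~ C(_a) * C(_b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    row = table.loc["C(_a):C(_b)"]
    df_num = int(row["df"])
    df_den = int(table.loc["Residual", "df"])
    fstat = float(row["F"])
    p = float(row["PR(>F)"])
    if math.isnan(fstat):  # identical values everywhere -> zero SS
        fstat, p = 0.0, 1.0
    return TestResult(test="ANOVA interaction", statistic=fstat, pvalue=p,
                      n=len(df), df=(df_num, df_den), alpha=alpha,
                      notes=f"{factor_a} x {factor_b}")


def sidak_pairwise(data: pd.DataFrame, value: str, factor_a: str,
                   factor_b: str, alpha: float = 0.05) -> pd.DataFrame:
    """Sidak-corrected pairwise comparisons between the design cells.

    Unpaired two-sided t-tests between every pair of (factor_a, factor_b)
    cells, with p-values adjusted as ``1 - (1 - p)^m``.
    """
    groups = {k: g[value].dropna().to_numpy()
              for k, g in data.groupby([factor_a, factor_b], observed=True)}
    keys = sorted(groups)
    rows = []
    combos = [(i, j) for i in range(len(keys)) for j in range(i + 1, len(keys))]
    m = len(combos)
    for i, j in combos:
        a, b = groups[keys[i]], groups[keys[j]]
        res = sps.ttest_ind(a, b)
        p_adj = 1.0 - (1.0 - float(res.pvalue)) ** m
        rows.append({"cell_a": keys[i], "cell_b": keys[j],
                     "t": float(res.statistic), "p_raw": float(res.pvalue),
                     "p_sidak": min(p_adj, 1.0),
                     "significant": p_adj < alpha})
    return pd.DataFrame(rows)
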