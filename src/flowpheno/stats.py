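"""Per-sample cell-type proportions and group comparison statistics.

Cell-type abundance is compared between groups on per-sample proportions
(each cell type relative to its declared parent population, e.g. CD62L-
high CD4 T cells within CD4 T cells). Two nonparametric two-sided tests
are run per cell type — the Wilcoxon rank-sum (Mann-Whitney U) and the
two-sample Kolmogorov-Smirnov — and Benjamini-Hochberg q-values are
computed across cell types separately within each test family. Welch's
unequal-variance t-test is provided both on raw values and on published
summary statistics (mean, sd, n), which is how hematology tables report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigError, FlowPhenoError

#: WRS switches from exact enumeration to the tie-corrected normal
#: approximation above this combined sample size (or whenever ties occur).
WRS_EXACT_MAX_N = 12

#: KS uses exact path-counting p-values when both samples are at most this big.
KS_EXACT_MAX_N = 10


@dataclass
class TestResult:
    """One two-sample test outcome."""

    statistic: float
    statistic_name: str      # "WRS U" | "KS D" | "Welch t"
    p_value: float
    n1: int
    n2: int
    direction: int           # sign of (location(x) - location(y))

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise FlowPhenoError(f"p-value {self.p_value} outside [0, 1]")


def _check_groups(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ConfigError("both groups need at least one value")
    return x, y


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact p by enumeration when n1 + n2 <= 12 and the pooled sample is
    tie-free; otherwise the normal approximation with tie and continuity
    corrections.
    """
    x, y = _check_groups(x, y)
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= WRS_EXACT_MAX_N and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return TestResult(statistic=float(res.statistic), statistic_name="WRS U",
                      p_value=float(min(res.pvalue, 1.0)),
                      n1=len(x), n2=len(y),
                      direction=int(np.sign(np.median(x) - np.median(y))))


def ks_two_sample(x, y) -> TestResult:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    D = sup |ECDF_x - ECDF_y|. Exact p when n1, n2 <= 10, otherwise the
    asymptotic Kolmogorov distribution with effective size
    n1*n2/(n1+n2).
    """
    x, y = _check_groups(x, y)
    method = "exact" if max(len(x), len(y)) <= KS_EXACT_MAX_N else "asymp"
    res = sps.ks_2samp(x, y, alternative="two-sided", method=method)
    return TestResult(statistic=float(res.statistic), statistic_name="KS D",
                      p_value=float(min(res.pvalue, 1.0)),
                      n1=len(x), n2=len(y),
                      direction=int(np.sign(np.median(x) - np.median(y))))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ConfigError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def welch_t(mean1: float, sd1: float, n1: int,
            mean2: float, sd2: float, n2: int) -> TestResult:
    """Welch's unequal-variance t-test from summary statistics.

    t = (mean1 - mean2) / sqrt(sd1^2/n1 + sd2^2/n2), Welch-Satterthwaite
    degrees of freedom, two-sided p. Degenerate inputs (both sds zero)
    give p = 1 when the means agree and p = 0 otherwise.
    """
    if n1 < 2 or n2 < 2:
        raise ConfigError("Welch's t needs n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ConfigError("standard deviations must be >= 0")
    if sd1 == 0 and sd2 == 0:
        import warnings
        if mean1 == mean2:
            t, p = 0.0, 1.0
        else:
            warnings.warn("zero variance in both groups with differing means",
                          stacklevel=2)
            t, p = np.inf * np.sign(mean1 - mean2), 0.0
    else:
        t, p = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                        equal_var=False)
    return TestResult(statistic=float(t), statistic_name="Welch t",
                      p_value=float(p), n1=n1, n2=n2,
                      direction=int(np.sign(mean1 - mean2)))


def welch_t_values(x, y) -> TestResult:
    """Welch's t-test on raw values (summary-statistic overload above)."""
    x, y = _check_groups(x, y)
    return welch_t(float(x.mean()), float(x.std(ddof=1)), len(x),
                   float(y.mean()), float(y.std(ddof=1)), len(y))


def cell_proportions(cell_labels, event_meta: pd.DataFrame,
                     parent_spec: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-sample cell-type proportions relative to declared parents.

    ``cell_labels`` is the final cell-type label per retained event (array
    aligned with ``event_meta`` rows). ``parent_spec`` maps each cell type
    to its denominator population: the name of another cell-type label
    whose members (plus all labels mapping to it) form the parent, or the
    reserved name ``"all"`` (all retained events in the sample, the
    default). Samples with a zero parent count get a missing proportion.

    Returns columns: sample_id, group, parent, cell_type, count,
    parent_count, proportion.
    """
    labels = np.asarray(cell_labels, dtype=object)
    if len(labels) != len(event_meta):
        raise FlowPhenoError("cell_labels length must match event_meta rows")
    parent_spec = parent_spec or {}
    df = pd.DataFrame({
        "sample_id": event_meta["sample_id"].astype(str).to_numpy(),
        "group": event_meta["group"].astype(str).to_numpy(),
        "cell_type": labels.astype(str),
    })
    samples = df.groupby("sample_id", sort=True)
    sample_groups = df.drop_duplicates("sample_id").set_index("sample_id")["group"]
    cell_types = sorted(df["cell_type"].unique())

    rows = []
    for sample_id, sub in samples:
        counts = sub["cell_type"].value_counts()
        total = len(sub)
        for ct in cell_types:
            parent = parent_spec.get(ct, "all")
            if parent == "all":
                parent_count = total
            else:
                # parent population = events labeled with the parent type
                # itself or with any type that declares it as parent
                children = {c for c, p in parent_spec.items() if p == parent}
                children.add(parent)
                parent_count = int(counts.reindex(sorted(children)).fillna(0).sum())
            count = int(counts.get(ct, 0))
            rows.append({
                "sample_id": sample_id,
                "group": sample_groups[sample_id],
                "parent": parent,
                "cell_type": ct,
                "count": count,
                "parent_count": parent_count,
                "proportion": count / parent_count if parent_count else np.nan,
            })
    return pd.DataFrame(rows, columns=["sample_id", "group", "parent",
                                       "cell_type", "count", "parent_count",
                                       "proportion"])


def compare_groups(proportions: pd.DataFrame,
                   group_pair: tuple[str, str],
                   tests: tuple[str, ...] = ("wrs", "ks"),
                   min_samples: int = 2) -> pd.DataFrame:
    """WRS and KS tests per cell type on per-sample proportions.

    BH adjustment is applied across cell types separately within each test
    family. Cell types with fewer than ``min_samples`` valid samples in
    either group are flagged (``tested = False``) and excluded from the BH
    family. Output rows are ordered (cell_type, test) regardless of input
    ordering.
    """
    g1, g2 = map(str, group_pair)
    test_fns = {"wrs": wilcoxon_rank_sum, "ks": ks_two_sample,
                "welch": welch_t_values}
    for t in tests:
        if t not in test_fns:
            raise ConfigError(f"unknown test {t!r}")

    prop = proportions.dropna(subset=["proportion"])
    rows = []
    for test_name in tests:
        fn = test_fns[test_name]
        for (ct, parent), sub in sorted(prop.groupby(["cell_type", "parent"])):
            x = np.sort(sub.loc[sub["group"] == g1, "proportion"].to_numpy())
            y = np.sort(sub.loc[sub["group"] == g2, "proportion"].to_numpy())
            base = {"cell_type": ct, "parent": parent, "test": test_name,
                    "n1": len(x), "n2": len(y)}
            if len(x) < min_samples or len(y) < min_samples:
                rows.append({**base, "statistic": np.nan, "p_value": np.nan,
                             "direction": 0, "tested": False})
                continue
            res = fn(x, y)
            rows.append({**base, "statistic": res.statistic,
                         "p_value": res.p_value, "direction": res.direction,
                         "tested": True})
    out = pd.DataFrame(rows)
    out["q_value"] = np.nan
    for test_name in tests:
        fam = out.index[(out["test"] == test_name) & out["tested"]]
        if len(fam):
            out.loc[fam, "q_value"] = bh_adjust(out.loc[fam, "p_value"].to_numpy())
    out = out.sort_values(["cell_type", "parent", "test"], kind="stable")
    return out.reset_index(drop=True)[
        ["cell_type", "parent", "test", "statistic", "p_value", "q_value",
         "direction", "n1", "n2", "tested"]]
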