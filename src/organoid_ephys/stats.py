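"""Group-comparison decision tree and multiple-comparison machinery.

The branching rule, applied to per-slice or per-cell summary values:

* Shapiro-Wilk on every group at alpha = 0.05;
* all groups normal, 2 groups  -> Welch's unpaired two-tailed t-test;
* any group non-normal, 2 groups -> Mann-Whitney U;
* all normal, >2 groups        -> one-way ANOVA + Tukey HSD;
* any non-normal, >2 groups    -> Kruskal-Wallis + Dunn's post hoc;
* kinetic designs (a family of per-timepoint two-group t-tests) use Welch
  tests corrected with the step-down Holm-Sidak method.

Outliers can be screened beforehand with a ROUT-style rule (robust biweight
location/scale, then FDR on t-distributed robust residuals at level Q);
removed points are always reported, never silently dropped.

Dunn's z statistics use rank sums with the standard tie correction; the
multiplicity-adjusted p is Bonferroni-style (p_raw * m, clamped to 1), the
convention of the common "Dunn's multiple comparisons" implementations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "StatReport",
    "star_code",
    "auto_compare",
    "kinetic_compare",
    "welch_t",
    "mann_whitney",
    "anova_tukey",
    "kruskal_dunn",
    "holm_sidak_adjust",
    "rout_outliers",
]

ALPHA = 0.05


@dataclass
class GroupSample:
    group: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float).ravel()
        if self.values.size < 1:
            raise ValueError(f"group {self.group!r} is empty")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"group {self.group!r} contains non-finite values")

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass
class StatReport:
    """Outcome of a group comparison.

    ``comparisons`` has one row per pair with columns
    group_a, group_b, statistic, df, p_raw, p_adj, stars.
    """

    test_name: str
    comparisons: pd.DataFrame
    normality_p: dict[str, float] = field(default_factory=dict)
    omnibus: dict[str, float] | None = None
    outliers_removed: dict[str, list[float]] = field(default_factory=dict)
    alpha: float = ALPHA

    def __post_init__(self) -> None:
        p = self.comparisons
        if len(p):
            if ((p["p_raw"] < 0) | (p["p_raw"] > 1)).any():
                raise ValueError("p_raw outside [0, 1]")
            if (p["p_adj"] + 1e-12 < p["p_raw"]).any():
                raise ValueError("adjusted p-values must be >= raw p-values")


def star_code(p: float) -> str:
    """Significance stars: * <=0.05, ** <=0.01, *** <=0.001, **** <=0.0001."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value {p!r} outside [0, 1]")
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p <= cut:
            return stars
    return "n.s."


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Two-tailed unpaired t-test with Welch's correction: (t, df, p)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t requires n >= 2 per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both groups have zero variance; use a nonparametric test")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (asymptotic, tie- and continuity-corrected)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def anova_tukey(groups: list[GroupSample]) -> StatReport:
    """One-way ANOVA with Tukey's HSD multiple-comparison correction.

    Per pair, ``statistic`` is the studentized-range q (Tukey-Kramer
    standard error), ``p_adj`` the Tukey p over all k groups, and
    ``p_raw`` the same q referred to a 2-group range distribution — the
    unadjusted analogue, which the k-group p can only exceed.
    """
    if len(groups) < 3:
        raise ValueError("anova_tukey requires more than two groups")
    arrays = [g.values for g in groups]
    if all(a.var(ddof=1) == 0 for a in arrays):
        raise ValueError("all groups have zero variance; use a nonparametric test")
    f_stat, f_p = sps.f_oneway(*arrays)
    hsd = sps.tukey_hsd(*arrays)
    n_total = sum(g.n for g in groups)
    df_within = n_total - len(groups)
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df_within
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(mse / 2.0 * (1.0 / groups[i].n + 1.0 / groups[j].n))
            q = abs(float(hsd.statistic[i, j])) / se
            p_adj = float(hsd.pvalue[i, j])
            p_raw = float(sps.studentized_range.sf(q, 2, df_within))
            rows.append({
                "group_a": groups[i].group,
                "group_b": groups[j].group,
                "statistic": q,
                "df": float(df_within),
                "p_raw": p_raw,
                "p_adj": p_adj,
                "stars": star_code(p_adj),
            })
    return StatReport(
        test_name="anova_tukey",
        comparisons=pd.DataFrame(rows),
        omnibus={"F": float(f_stat), "p": float(f_p),
                 "df_between": len(groups) - 1.0,
                 "df_within": float(n_total - len(groups))},
    )


def _dunn_z(groups: list[GroupSample]) -> dict[tuple[int, int], float]:
    """Dunn's pairwise z statistics from pooled ranks with tie correction."""
    pooled = np.concatenate([g.values for g in groups])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    # tie correction term: sum(t^3 - t) / (12 (N - 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(float(ranks[start:start + g.n].mean()))
        start += g.n
    out = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(var_base * (1.0 / groups[i].n + 1.0 / groups[j].n))
            out[(i, j)] = (mean_ranks[i] - mean_ranks[j]) / se
    return out


def kruskal_dunn(groups: list[GroupSample]) -> StatReport:
    """Kruskal-Wallis omnibus with Dunn's multiple-comparison post hoc."""
    if len(groups) < 3:
        raise ValueError("kruskal_dunn requires more than two groups")
    h_stat, h_p = sps.kruskal(*[g.values for g in groups])
    zs = _dunn_z(groups)
    m = len(zs)
    rows = []
    for (i, j), z in zs.items():
        p_raw = float(2.0 * sps.norm.sf(abs(z)))
        p_adj = min(1.0, p_raw * m)
        rows.append({
            "group_a": groups[i].group,
            "group_b": groups[j].group,
            "statistic": float(z),
            "df": np.nan,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "stars": star_code(p_adj),
        })
    return StatReport(
        test_name="kruskal_dunn",
        comparisons=pd.DataFrame(rows),
        omnibus={"H": float(h_stat), "p": float(h_p),
                 "df": len(groups) - 1.0},
    )


def holm_sidak_adjust(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Step-down Holm-Sidak adjustment of a family of p-values.

    With p sorted ascending, the i-th (1-based) adjusted value is
    max_{j<=i} [1 - (1 - p_(j))^(m - j + 1)], clamped to [p_raw, 1].
    """
    p = np.asarray(p_values, float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return np.clip(np.maximum(adj, p), 0.0, 1.0)


# ---------------------------------------------------------------------------
# outlier screening
# ---------------------------------------------------------------------------


def _biweight_location(x: np.ndarray, c: float = 6.0, n_iter: int = 10) -> float:
    loc = float(np.median(x))
    for _ in range(n_iter):
        mad = float(np.median(np.abs(x - loc)))
        if mad == 0:
            return loc
        u = (x - loc) / (c * mad)
        w = (1 - u ** 2) ** 2
        w[np.abs(u) >= 1] = 0.0
        if w.sum() == 0:
            return loc
        loc = float(np.sum(w * x) / np.sum(w))
    return loc


def rout_outliers(
    values: np.ndarray, q: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """ROUT-style outlier screen for a univariate sample: (kept, removed).

    A robust biweight location and MAD scale are fitted, residuals are
    referred to a t distribution (df = n - 2), and points are flagged by
    Benjamini-Hochberg FDR at level ``q`` (Q = 1% by default).  This is the
    univariate collapse of the robust-regression-plus-FDR procedure.
    """
    x = np.asarray(values, float).ravel()
    if x.size < 3:
        raise ValueError("rout_outliers requires n >= 3")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    loc = _biweight_location(x)
    scale = 1.4826 * float(np.median(np.abs(x - loc)))
    if scale == 0:
        return x.copy(), np.array([])
    t_res = (x - loc) / scale
    p = 2.0 * sps.t.sf(np.abs(t_res), df=max(x.size - 2, 1))
    # Benjamini-Hochberg at level q
    order = np.argsort(p)
    thresh = q * (np.arange(1, x.size + 1)) / x.size
    below = p[order] <= thresh
    flagged = np.zeros(x.size, bool)
    if below.any():
        k = int(np.max(np.nonzero(below)[0]))
        flagged[order[: k + 1]] = True
    return x[~flagged], x[flagged]


# ---------------------------------------------------------------------------
# decision tree
# ---------------------------------------------------------------------------


def _two_group_report(test_name: str, a: GroupSample, b: GroupSample,
                      statistic: float, df: float, p: float,
                      normality: dict[str, float]) -> StatReport:
    rows = [{
        "group_a": a.group,
        "group_b": b.group,
        "statistic": statistic,
        "df": df,
        "p_raw": p,
        "p_adj": p,
        "stars": star_code(p),
    }]
    return StatReport(test_name=test_name, comparisons=pd.DataFrame(rows),
                      normality_p=normality)


def auto_compare(
    samples: list[GroupSample],
    design: str | None = None,
    kinetic: bool = False,
    alpha: float = ALPHA,
    rout_q: float | None = None,
) -> StatReport:
    """Run the full decision tree on a list of group samples.

    ``design`` (``"two_group"``/``"multi_group"``) is inferred from the
    number of groups when omitted and cross-checked otherwise.  With
    ``rout_q`` set, each group is ROUT-screened first and removed points are
    reported in the result.  ``kinetic=True`` is not valid here; use
    :func:`kinetic_compare` with per-timepoint pairs.
    """
    if kinetic:
        raise ValueError("for kinetic designs call kinetic_compare(pairs)")
    if len(samples) < 2:
        raise ValueError("auto_compare requires at least two groups")
    names = [s.group for s in samples]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate group labels: {names}")
    inferred = "two_group" if len(samples) == 2 else "multi_group"
    if design is not None and design != inferred:
        raise ValueError(
            f"design {design!r} does not match {len(samples)} groups"
        )

    outliers: dict[str, list[float]] = {}
    if rout_q is not None:
        screened = []
        for s in samples:
            kept, removed = rout_outliers(s.values, rout_q)
            if removed.size:
                outliers[s.group] = removed.tolist()
            screened.append(GroupSample(s.group, kept))
        samples = screened

    for s in samples:
        if s.n < 3:
            raise ValueError(
                f"group {s.group!r} has n={s.n} < 3; too small for the "
                "normality gate"
            )
    normality = {}
    for s in samples:
        if s.values.var(ddof=1) == 0:
            normality[s.group] = 0.0  # constant sample: certainly non-Gaussian fit
        else:
            normality[s.group] = float(sps.shapiro(s.values).pvalue)
    all_normal = all(p > alpha for p in normality.values())

    if len(samples) == 2:
        a, b = samples
        if all_normal:
            t, df, p = welch_t(a.values, b.values)
            report = _two_group_report("welch_t", a, b, t, df, p, normality)
        else:
            u, p = mann_whitney(a.values, b.values)
            report = _two_group_report("mann_whitney", a, b, u, np.nan, p, normality)
    else:
        report = anova_tukey(samples) if all_normal else kruskal_dunn(samples)
        report.normality_p = normality
    report.outliers_removed = outliers
    return report


def kinetic_compare(
    pairs: list[tuple[GroupSample, GroupSample]],
    labels: list[str] | None = None,
) -> StatReport:
    """Per-timepoint Welch t-tests corrected with Holm-Sidak.

    ``pairs`` holds one (test, control) pair per timepoint; equal SDs are
    not assumed (Welch).  Returns one comparison row per timepoint with the
    family-adjusted p-value.
    """
    if not pairs:
        raise ValueError("kinetic_compare requires at least one timepoint pair")
    labels = labels or [f"t{i}" for i in range(len(pairs))]
    stats, dfs, raws = [], [], []
    for a, b in pairs:
        t, df, p = welch_t(a.values, b.values)
        stats.append(t)
        dfs.append(df)
        raws.append(p)
    adj = holm_sidak_adjust(raws)
    rows = []
    for lab, (a, b), t, df, p_raw, p_adj in zip(labels, pairs, stats, dfs, raws, adj):
        rows.append({
            "group_a": f"{a.group}@{lab}",
            "group_b": f"{b.group}@{lab}",
            "statistic": t,
            "df": df,
            "p_raw": p_raw,
            "p_adj": float(p_adj),
            "stars": star_code(float(p_adj)),
        })
    return StatReport(test_name="multiple_t_holm_sidak",
                      comparisons=pd.DataFrame(rows))
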