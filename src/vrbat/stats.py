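"""Group-level statistics for cohort readouts.

Provides the analyses used on the behavioral readouts: between-subjects and
mixed repeated-measures ANOVA with partial and generalized eta-squared,
two-sample and one-sample t tests with Glass' Delta and Hedges' g1,
Kruskal-Wallis and Mann-Whitney U with Cohen's U3, Pearson/Spearman and
partial Spearman correlations, and the Bonferroni family threshold.

The mixed ANOVA handles one between-subjects factor (unbalanced group sizes
allowed) fully crossed with up to three within-subject factors (complete
cells required).  It works on orthonormal within-cell contrasts: for each
within-effect stratum the subject data are projected onto that effect's
contrast subspace and a one-way between-groups decomposition is run on the
projections.  Hypothesis sums of squares use Type III tests with
sum-to-zero contrasts, so within effects are tested on unweighted group
means when group sizes differ.

Effect sizes follow the conventions:

* partial eta-squared  ``SS_effect / (SS_effect + SS_error(effect))``
* generalized eta-squared ``SS_effect / (SS_effect + sum of all error SS)``
* Glass' Delta uses the second (reference) sample's SD
* Cohen's U3 is the proportion of the first sample's values strictly below
  the median of the second sample, ties counted half -- so a group lying
  entirely above the reference has U3 = 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln


class StatsError(ValueError):
    """Invalid input to a statistical routine."""


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    """ANOVA table plus error strata and partition bookkeeping.

    ``table`` has one row per tested effect (columns ``ss, df, F, p,
    partial_eta_sq, generalized_eta_sq`` and, for one-way designs,
    ``eta_sq``); ``errors`` one row per error stratum (``ss, df``).
    ``stratum_totals`` records the total SS of each orthonormal contrast
    stratum and ``stratum_decomp`` its exact (weighted) decomposition, so
    that the complete partition to ``total_ss`` can be verified.
    """

    table: pd.DataFrame
    errors: pd.DataFrame
    total_ss: float
    stratum_totals: dict = field(default_factory=dict)
    stratum_decomp: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "effects": {
                str(ix): {k: _jsonify(v) for k, v in row.items()}
                for ix, row in self.table.iterrows()
            },
            "errors": {
                str(ix): {k: _jsonify(v) for k, v in row.items()}
                for ix, row in self.errors.iterrows()
            },
        }


@dataclass
class TestResult:
    """A single test statistic with its effect size."""

    name: str
    statistic: float
    p: float
    df: float | tuple | None = None
    n: tuple | int | None = None
    effect_size: float | None = None
    effect_size_name: str | None = None
    tails: int = 2
    note: str | None = None

    def to_dict(self) -> dict:
        return {k: _jsonify(v) for k, v in self.__dict__.items()}


def _jsonify(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, tuple):
        return list(v)
    if isinstance(v, float) and np.isnan(v):
        return None
    return v


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------


def oneway_anova(groups) -> AnovaResult:
    """Classical one-way between-subjects ANOVA with eta-squared."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise StatsError("need at least 2 groups")
    for i, g in enumerate(groups):
        if g.size < 2:
            raise StatsError(f"group {i} has fewer than 2 values")
    all_v = np.concatenate(groups)
    grand = all_v.mean()
    ss_total = float(np.sum((all_v - grand) ** 2))
    ss_between = float(sum(g.size * (g.mean() - grand) ** 2 for g in groups))
    ss_within = float(sum(np.sum((g - g.mean()) ** 2) for g in groups))
    df_b = len(groups) - 1
    df_w = all_v.size - len(groups)
    if ss_between == 0:
        f, p = 0.0, 1.0
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
        p = float(sps.f.sf(f, df_b, df_w))
    eta = ss_between / ss_total if ss_total > 0 else 0.0
    table = pd.DataFrame(
        {"ss": [ss_between], "df": [df_b], "F": [f], "p": [p],
         "eta_sq": [eta], "partial_eta_sq": [eta], "generalized_eta_sq": [eta]},
        index=["group"],
    )
    errors = pd.DataFrame({"ss": [ss_within], "df": [df_w]}, index=["within"])
    return AnovaResult(
        table=table, errors=errors, total_ss=ss_total + all_v.size * grand**2,
        stratum_totals={"between": float(np.sum(all_v**2))},
        stratum_decomp={"between": (float(all_v.size * grand**2), ss_between, ss_within)},
    )


def _orthonormal_contrasts(levels: int) -> np.ndarray:
    """Orthonormal Helmert basis of the contrast space (exactly ⊥ constant)."""
    c = np.zeros((levels, levels - 1))
    for j in range(1, levels):
        c[:j, j - 1] = 1.0
        c[j, j - 1] = -float(j)
        c[:, j - 1] /= np.sqrt(j * (j + 1))
    return c


def mixed_rm_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    between: str | None = None,
    within: list | None = None,
) -> AnovaResult:
    """Mixed repeated-measures ANOVA (one between factor, 0-3 within factors).

    ``data`` is long format with one observation per subject and within
    cell.  Between effects are tested against the subject-within-group
    stratum, within effects against their factor-x-subject stratum.  With
    unbalanced groups, Type III (sum-to-zero, unweighted-means) hypothesis
    SS are reported.
    """
    within = list(within or [])
    if len(within) > 3:
        raise StatsError("at most 3 within factors supported")
    df = data.copy()
    if between is None:
        between = "_all"
        df[between] = "all"

    # subject -> group map must be unique
    gmap = df.groupby(subject)[between].nunique()
    if (gmap > 1).any():
        raise StatsError("a subject appears in more than one group")

    if within:
        counts = df.groupby([subject] + within, observed=True)[dv].count()
        levels = [np.sort(df[w].unique()) for w in within]
        full = list(itertools.product(np.sort(df[subject].unique()),
                                      *levels))
        missing = [c for c in full if counts.get(c, 0) == 0]
        if missing:
            raise StatsError(f"missing within cell(s), e.g. subject/cell {missing[0]}")
        if (counts > 1).any():
            raise StatsError("duplicate observation for a subject/cell")
        wide = df.pivot_table(index=subject, columns=within, values=dv, observed=True)
        wide = wide.sort_index(axis=1)
        y = wide.to_numpy(dtype=float)
        n_levels = [len(lv) for lv in levels]
    else:
        grouped = df.groupby(subject)[dv]
        if (grouped.count() > 1).any():
            raise StatsError("duplicate observation for a subject")
        wide = grouped.first().to_frame()
        y = wide.to_numpy(dtype=float)
        n_levels = []

    grp = df.groupby(subject)[between].first().loc[wide.index].to_numpy()
    glabels = np.unique(grp)
    k = glabels.size
    n_g = np.array([(grp == g).sum() for g in glabels], dtype=float)
    n_subj = y.shape[0]
    if np.any(n_g < 1) or (k < 2 and between != "_all"):
        raise StatsError("need at least 2 groups with data")

    const = [np.full((l, 1), 1 / np.sqrt(l)) for l in n_levels]
    contr = [_orthonormal_contrasts(l) for l in n_levels]

    rows, err_rows = [], []
    stratum_totals, stratum_decomp = {}, {}

    def one_way(z):
        """Per-column one-way decomposition; returns summed SS pieces."""
        means = np.stack([z[grp == g].mean(axis=0) for g in glabels])
        zbar_w = z.mean(axis=0)
        rss = float(sum(np.sum((z[grp == g] - means[i]) ** 2)
                        for i, g in enumerate(glabels)))
        ss_group = float(np.sum(n_g[:, None] * (means - zbar_w) ** 2))
        mu_unw = means.mean(axis=0)
        ss_int3 = float(k**2 / np.sum(1.0 / n_g) * np.sum(mu_unw**2))
        ss_mean_w = float(n_subj * np.sum(zbar_w**2))
        return ss_int3, ss_mean_w, ss_group, rss

    for r in range(len(within) + 1):
        for combo in itertools.combinations(range(len(within)), r):
            mats = [contr[j] if j in combo else const[j] for j in range(len(within))]
            c = np.ones((1, 1))
            for m in mats:
                c = np.kron(c, m)
            z = y @ c if len(within) else y
            d = c.shape[1] if len(within) else 1
            ss_int3, ss_mean_w, ss_group, rss = one_way(z)
            name = ":".join(within[j] for j in combo)
            stratum = name or "between"
            stratum_totals[stratum] = float(np.sum(z**2))
            stratum_decomp[stratum] = (ss_mean_w, ss_group, rss)
            err_name = "subject" if not combo else f"{name}:subject"
            df_err = d * (n_subj - k)
            err_rows.append({"stratum": err_name, "ss": rss, "df": df_err})
            effects = []
            if combo:
                effects.append((name, ss_int3, d))
                if between != "_all":
                    effects.append((f"{between}:{name}", ss_group, d * (k - 1)))
            elif between != "_all":
                effects.append((between, ss_group, k - 1))
            for ename, ss, dfe in effects:
                rows.append({"effect": ename, "ss": ss, "df": dfe,
                             "err_ss": rss, "err_df": df_err})

    table = pd.DataFrame(rows).set_index("effect")
    errors = pd.DataFrame(err_rows).set_index("stratum")
    total_err_ss = float(errors["ss"].sum())

    ss_tol = 1e-12 * max(float(np.sum(y**2)), 1.0)

    def f_and_p(row):
        if row["ss"] <= ss_tol:
            return pd.Series({"F": 0.0, "p": 1.0})
        if row["err_ss"] <= ss_tol or row["err_df"] <= 0:
            return pd.Series({"F": np.inf, "p": 0.0})
        f = (row["ss"] / row["df"]) / (row["err_ss"] / row["err_df"])
        return pd.Series({"F": f, "p": float(sps.f.sf(f, row["df"], row["err_df"]))})

    fp = table.apply(f_and_p, axis=1)
    table["F"], table["p"] = fp["F"], fp["p"]
    with np.errstate(invalid="ignore", divide="ignore"):
        table["partial_eta_sq"] = np.where(
            table["ss"] + table["err_ss"] > 0,
            table["ss"] / (table["ss"] + table["err_ss"]), 0.0
        )
        table["generalized_eta_sq"] = np.where(
            table["ss"] + total_err_ss > 0,
            table["ss"] / (table["ss"] + total_err_ss), 0.0
        )
    table = table.drop(columns=["err_ss", "err_df"])
    return AnovaResult(
        table=table,
        errors=errors,
        total_ss=float(np.sum(y**2)),
        stratum_totals=stratum_totals,
        stratum_decomp=stratum_decomp,
    )


# ---------------------------------------------------------------------------
# t tests
# ---------------------------------------------------------------------------


def two_sample_t(a, b) -> TestResult:
    """Independent two-sample t test (pooled variance) with Glass' Delta.

    Delta standardizes the mean difference by the SD of ``b``, the
    reference sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("need >= 2 values per sample")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    sd_b = b.std(ddof=1)
    note = None
    if sd_b == 0:
        delta, note = float("nan"), "reference SD is zero; Glass Delta undefined"
    else:
        delta = (a.mean() - b.mean()) / sd_b
    return TestResult(
        name="two_sample_t", statistic=float(t), p=float(p),
        df=a.size + b.size - 2, n=(a.size, b.size),
        effect_size=float(delta), effect_size_name="glass_delta", note=note,
    )


def one_sample_t(a, mu: float = 0.0) -> TestResult:
    """One-sample t test vs ``mu`` with bias-corrected Hedges' g1."""
    a = np.asarray(a, dtype=float)
    if a.size < 2:
        raise StatsError("need >= 2 values")
    t, p = sps.ttest_1samp(a, mu)
    sd = a.std(ddof=1)
    df = a.size - 1
    if sd == 0:
        g1, note = float("nan"), "zero SD; Hedges g1 undefined"
    else:
        # exact small-sample bias correction J(df)
        j = np.exp(gammaln(df / 2) - 0.5 * np.log(df / 2) - gammaln((df - 1) / 2))
        g1, note = j * (a.mean() - mu) / sd, None
    return TestResult(
        name="one_sample_t", statistic=float(t), p=float(p), df=df, n=a.size,
        effect_size=float(g1), effect_size_name="hedges_g1", note=note,
    )


# ---------------------------------------------------------------------------
# nonparametric tests
# ---------------------------------------------------------------------------


def mann_whitney_u(a, b) -> TestResult:
    """Mann-Whitney U test with Cohen's U3.

    U counts pairs with a > b plus half ties and is reported with the
    ``max(U, n1*n2 - U)`` convention.  The p value is exact when
    ``n1*n2 <= 400`` and the data are tie-free, otherwise a
    continuity-and-tie-corrected normal approximation is used.  U3 is the
    proportion of ``a`` values strictly below the median of ``b`` (ties
    half): a sample lying wholly above its reference gives U3 = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatsError("empty group")
    n1, n2 = a.size, b.size
    ranks = sps.rankdata(np.concatenate([a, b]))
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2
    u_reported = max(u1, n1 * n2 - u1)
    has_ties = np.unique(np.concatenate([a, b])).size < n1 + n2
    method = "exact" if (n1 * n2 <= 400 and not has_ties) else "asymptotic"
    p = float(sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
    med_b = float(np.median(b))
    u3 = float((np.sum(a < med_b) + 0.5 * np.sum(a == med_b)) / n1)
    return TestResult(
        name="mann_whitney_u", statistic=float(u_reported), p=p, n=(n1, n2),
        effect_size=u3, effect_size_name="cohens_u3",
    )


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test with tie correction."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in groups) or len(groups) < 2:
        raise StatsError("need >= 2 groups with >= 2 values each")
    h, p = sps.kruskal(*groups)
    n = int(sum(g.size for g in groups))
    return TestResult(
        name="kruskal_wallis", statistic=float(h), p=float(p),
        df=len(groups) - 1, n=n,
    )


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------


def correlation(x, y, method: str = "pearson") -> TestResult:
    """Pearson or Spearman correlation with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise StatsError("need equal-length samples of >= 4 values")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise StatsError(f"unknown method {method!r}")
    return TestResult(name=method, statistic=float(r), p=float(p), n=x.size,
                      effect_size=float(r), effect_size_name=f"r_{method[0]}")


def partial_spearman(x, y, z) -> TestResult:
    """First-order partial Spearman correlation of x and y controlling z.

    Ranks (ties averaged) are taken first; the partial correlation follows
    the standard first-order recursion and the p value a t approximation
    with ``n - 3`` degrees of freedom.
    """
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    n = x.size
    if not (y.size == n and z.size == n) or n < 5:
        raise StatsError("need equal-length samples of >= 5 values")
    rx, ry, rz = (sps.rankdata(v) for v in (x, y, z))
    if any(np.std(r) == 0 for r in (rx, ry, rz)):
        return TestResult(name="partial_spearman", statistic=float("nan"),
                          p=float("nan"), n=n, note="zero variance in ranks")
    rxy = np.corrcoef(rx, ry)[0, 1]
    rxz = np.corrcoef(rx, rz)[0, 1]
    ryz = np.corrcoef(ry, rz)[0, 1]
    denom = np.sqrt((1 - rxz**2) * (1 - ryz**2))
    if denom == 0:
        return TestResult(name="partial_spearman", statistic=float("nan"),
                          p=float("nan"), n=n, note="control collinear with inputs")
    r = float((rxy - rxz * ryz) / denom)
    df = n - 3
    if abs(r) >= 1:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1 - r**2))
        p = float(2 * sps.t.sf(abs(t), df))
    return TestResult(name="partial_spearman", statistic=r, p=p, df=df, n=n,
                      effect_size=r, effect_size_name="r_s_partial")


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold ``alpha / m``."""
    if m < 1:
        raise StatsError("number of comparisons must be >= 1")
    return alpha / m
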