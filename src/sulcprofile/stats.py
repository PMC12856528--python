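"""Group statistics over the per-hemisphere PPfpm feature table.

The battery mirrors a repeated-measures design with two 2-level
within-subject factors (feature PPfpm-I/PPfpm-II and hemisphere left/right)
and one 2-level between-subject factor (sex, or handedness):

* three-way mixed ANOVA with type-3 sums of squares, computed from
  per-subject contrast scores — each within-subject effect and its
  interaction with the between factor are tested in their own error
  stratum, the between factor against the subject stratum.  With sum-to-zero
  coding the main within effects test the unweighted grand mean of group
  means, which is what makes the decomposition type-3 under an unbalanced
  between factor;
* Bonferroni-corrected two-sided paired t post hocs;
* a balanced mirrored-index resampling ANOVA for handedness (each
  left-hander matched to a right-hander with the mirrored Oldfield index),
  reporting per-effect medians of F and p across iterations;
* a label-permutation ANOVA with empirical p = (b+1)/(m+1);
* a random-intercept linear mixed model (REML) as sensitivity analysis;
* Pearson correlation and Shapiro-Wilk / Levene assumption checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaTable",
    "PostHocResult",
    "ResamplingSummary",
    "PermutationResult",
    "LmmResult",
    "CorrelationResult",
    "mixed_anova_3way",
    "posthoc_paired_t",
    "balanced_resample_anova",
    "permutation_anova",
    "lmm_random_intercept",
    "pearson_correlation",
    "assumption_checks",
    "percentage",
]


def percentage(count: int, total: int, decimals: int = 2) -> float:
    """Bookkeeping percentage, rounded to the reported precision."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, decimals)


# ---------------------------------------------------------------------------
# mixed ANOVA


@dataclass
class AnovaTable:
    effects: list[str]
    F: dict[str, float]
    df_num: dict[str, int]
    df_den: dict[str, int]
    p: dict[str, float]
    n_subjects: int = 0
    dropped_subjects: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "effect": self.effects,
                "F": [self.F[e] for e in self.effects],
                "df_num": [self.df_num[e] for e in self.effects],
                "df_den": [self.df_den[e] for e in self.effects],
                "p": [self.p[e] for e in self.effects],
            }
        )

    summary = to_frame


def _subject_scores(
    table: pd.DataFrame,
    response: str,
    within: tuple[str, str],
    between: str,
    subject: str,
) -> tuple[pd.DataFrame, list[str]]:
    """Collapse the 2x2 within cells to per-subject contrast scores.

    Returns one row per complete-case subject with the subject mean ``m``,
    within-factor scores ``sA``/``sB``, their interaction score ``sAB`` and
    the between-factor level; subjects missing any cell (or the between
    level) are dropped and reported.
    """
    a_name, b_name = within
    lev_a = sorted(table[a_name].dropna().unique())
    lev_b = sorted(table[b_name].dropna().unique())
    if len(lev_a) != 2 or len(lev_b) != 2:
        raise ValueError("both within factors must have exactly 2 levels")
    wide = table.pivot_table(
        index=subject, columns=[a_name, b_name], values=response, aggfunc="first"
    )
    grp = table.groupby(subject)[between].first()
    complete = wide.notna().all(axis=1) & grp.notna()
    dropped = sorted(wide.index[~complete].astype(str))
    wide, grp = wide.loc[complete], grp.loc[complete]
    c = {
        (la, lb): wide[(la, lb)].to_numpy(dtype=float)
        for la in lev_a
        for lb in lev_b
    }
    scores = pd.DataFrame(
        {
            "m": (c[lev_a[0], lev_b[0]] + c[lev_a[0], lev_b[1]] + c[lev_a[1], lev_b[0]] + c[lev_a[1], lev_b[1]]) / 4.0,
            "sA": (c[lev_a[0], lev_b[0]] + c[lev_a[0], lev_b[1]] - c[lev_a[1], lev_b[0]] - c[lev_a[1], lev_b[1]]) / 2.0,
            "sB": (c[lev_a[0], lev_b[0]] - c[lev_a[0], lev_b[1]] + c[lev_a[1], lev_b[0]] - c[lev_a[1], lev_b[1]]) / 2.0,
            "sAB": (c[lev_a[0], lev_b[0]] - c[lev_a[0], lev_b[1]] - c[lev_a[1], lev_b[0]] + c[lev_a[1], lev_b[1]]) / 2.0,
            "group": grp.to_numpy(),
        },
        index=wide.index,
    )
    return scores, dropped


def _stratum_tests(s: np.ndarray, g: np.ndarray) -> tuple[float, float, float]:
    """Type-3 F tests within one error stratum.

    Regress the score on the sum-coded between factor; returns
    (F_intercept, F_group, df_den).  The intercept test is the within
    effect, the slope test its interaction with the between factor.
    """
    levels = np.unique(g)
    if levels.size != 2:
        raise ValueError("between factor must have exactly 2 non-empty levels")
    s1, s2 = s[g == levels[0]], s[g == levels[1]]
    n1, n2 = s1.size, s2.size
    if min(n1, n2) < 1 or n1 + n2 < 3:
        raise ValueError("need at least one subject per between level and 3 total")
    df_den = n1 + n2 - 2
    sse = float(np.sum((s1 - s1.mean()) ** 2) + np.sum((s2 - s2.mean()) ** 2))
    mse = sse / df_den
    vfac = 0.25 * (1.0 / n1 + 1.0 / n2)
    b0 = 0.5 * (s1.mean() + s2.mean())
    b1 = 0.5 * (s1.mean() - s2.mean())

    def f_of(b: float) -> float:
        num = b * b
        if num == 0.0:
            return 0.0
        if mse == 0.0:
            return float("inf")
        return num / (mse * vfac)

    return f_of(b0), f_of(b1), df_den


def mixed_anova_3way(
    table: pd.DataFrame,
    response: str,
    within: tuple[str, str] = ("feature", "hemisphere"),
    between: str = "sex",
    subject: str = "subject_id",
) -> AnovaTable:
    """Three-way mixed ANOVA (2 within x 2 within x 2 between, type-3 SS)."""
    scores, dropped = _subject_scores(table, response, within, between, subject)
    g = scores["group"].to_numpy()
    a_name, b_name = within
    names = [
        a_name,
        b_name,
        between,
        f"{a_name}:{b_name}",
        f"{a_name}:{between}",
        f"{b_name}:{between}",
        f"{a_name}:{b_name}:{between}",
    ]
    F: dict[str, float] = {}
    dfd: dict[str, int] = {}
    f0, f1, d = _stratum_tests(scores["m"].to_numpy(), g)
    F[between], dfd[between] = f1, d
    f0, f1, d = _stratum_tests(scores["sA"].to_numpy(), g)
    F[a_name], F[f"{a_name}:{between}"] = f0, f1
    dfd[a_name] = dfd[f"{a_name}:{between}"] = d
    f0, f1, d = _stratum_tests(scores["sB"].to_numpy(), g)
    F[b_name], F[f"{b_name}:{between}"] = f0, f1
    dfd[b_name] = dfd[f"{b_name}:{between}"] = d
    f0, f1, d = _stratum_tests(scores["sAB"].to_numpy(), g)
    F[f"{a_name}:{b_name}"], F[f"{a_name}:{b_name}:{between}"] = f0, f1
    dfd[f"{a_name}:{b_name}"] = dfd[f"{a_name}:{b_name}:{between}"] = d
    p = {e: float(sps.f.sf(F[e], 1, dfd[e])) if np.isfinite(F[e]) else 0.0 for e in names}
    return AnovaTable(
        effects=names,
        F={e: float(F[e]) for e in names},
        df_num={e: 1 for e in names},
        df_den={e: int(dfd[e]) for e in names},
        p=p,
        n_subjects=len(scores),
        dropped_subjects=dropped,
    )


# ---------------------------------------------------------------------------
# post hoc paired t


@dataclass
class PostHocResult:
    table: pd.DataFrame
    p_crit: float

    def to_frame(self) -> pd.DataFrame:
        return self.table


def posthoc_paired_t(
    comparisons: list[tuple[str, np.ndarray, np.ndarray]], alpha: float = 0.05
) -> PostHocResult:
    """Two-sided paired t-tests with Bonferroni-adjusted threshold.

    ``comparisons`` is a list of (label, x, y) paired samples.  The
    significance threshold is alpha / number of comparisons.  A comparison
    whose paired differences have zero variance is returned with the mean
    difference and an undefined t, flagged ``degenerate``.
    """
    if not comparisons:
        raise ValueError("no comparisons given")
    p_crit = alpha / len(comparisons)
    rows = []
    for label, x, y in comparisons:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size != y.size or x.size < 2:
            raise ValueError(f"comparison {label!r}: need >= 2 complete pairs")
        d = x - y
        n = d.size
        delta = float(d.mean())
        sd = float(d.std(ddof=1))
        degenerate = sd == 0.0
        if degenerate and delta == 0.0:
            t, p, lo, hi = 0.0, 1.0, 0.0, 0.0
        elif degenerate:
            t, p, lo, hi = np.nan, np.nan, delta, delta
        else:
            sem = sd / np.sqrt(n)
            t = delta / sem
            p = 2.0 * sps.t.sf(abs(t), n - 1)
            tc = sps.t.ppf(1.0 - alpha / 2.0, n - 1)
            lo, hi = delta - tc * sem, delta + tc * sem
        rows.append(
            {
                "comparison": label,
                "n": n,
                "mean_x": x.mean(),
                "sd_x": x.std(ddof=1),
                "sem_x": x.std(ddof=1) / np.sqrt(n),
                "mean_y": y.mean(),
                "sd_y": y.std(ddof=1),
                "sem_y": y.std(ddof=1) / np.sqrt(n),
                "delta": delta,
                "t": t,
                "p": p,
                "ci_low": lo,
                "ci_high": hi,
                "significant": bool(p < p_crit) if np.isfinite(p) else False,
                "degenerate": degenerate,
            }
        )
    return PostHocResult(table=pd.DataFrame(rows), p_crit=p_crit)


# ---------------------------------------------------------------------------
# handedness: balanced mirrored-index resampling


@dataclass
class ResamplingSummary:
    median_F: dict[str, float]
    median_p: dict[str, float]
    iterations: int
    seed: int
    n_matched: int
    unmatched_warnings: int

    def to_frame(self) -> pd.DataFrame:
        eff = list(self.median_F)
        return pd.DataFrame(
            {
                "effect": eff,
                "median_F": [self.median_F[e] for e in eff],
                "median_p": [self.median_p[e] for e in eff],
            }
        )


def _match_mirrored(
    left: pd.Series, right: pd.Series, rng: np.random.Generator
) -> tuple[list, int]:
    """Match each left-hander (index v) to a right-hander with index -v.

    Sampling is uniform without replacement within one iteration; when no
    right-hander with the exact mirrored index remains, the nearest
    available index is used (ties toward the smaller index), counted as a
    warning.
    """
    available: dict[int, list] = {}
    for sid, v in right.items():
        available.setdefault(int(v), []).append(sid)
    matched, warnings_n = [], 0
    order = list(left.index)
    rng.shuffle(order)
    for sid in order:
        target = -int(left[sid])
        pool = available.get(target)
        if not pool:
            keys = [k for k, v in available.items() if v]
            if not keys:
                raise ValueError("no right-handed subjects left to match")
            target = min(keys, key=lambda k: (abs(k - (-int(left[sid]))), k))
            pool = available[target]
            warnings_n += 1
        pick = pool[int(rng.integers(len(pool)))]
        pool.remove(pick)
        matched.append(pick)
    return matched, warnings_n


def balanced_resample_anova(
    table: pd.DataFrame,
    response: str,
    iterations: int = 10_000,
    seed: int = 0,
    within: tuple[str, str] = ("feature", "hemisphere"),
    subject: str = "subject_id",
    oldfield: str = "oldfield",
) -> ResamplingSummary:
    """Balanced mirrored-Oldfield resampling ANOVA for the handedness effect.

    Per iteration, every left-hander is paired with a right-hander of
    mirrored index; the three-way mixed ANOVA (between = handedness) runs on
    the balanced set, and per-effect medians of F and p are reported over
    all iterations.  Fully reproducible from the seed.
    """
    subj = table.groupby(subject)[oldfield].first().dropna()
    left = subj[subj < 0]
    right = subj[subj > 0]
    if len(left) < 2 or len(right) < 2:
        raise ValueError("need >= 2 subjects per handedness class")
    work = table.copy()
    work["handedness"] = np.where(
        work[oldfield] < 0, "left_handed", np.where(work[oldfield] > 0, "right_handed", None)
    )
    rng = np.random.default_rng(seed)
    all_F: dict[str, list[float]] = {}
    all_p: dict[str, list[float]] = {}
    warn_total = 0
    for _ in range(iterations):
        matched, w = _match_mirrored(left, right, rng)
        warn_total += w
        keep = list(left.index) + matched
        sub = work[work[subject].isin(keep)]
        res = mixed_anova_3way(sub, response, within=within, between="handedness", subject=subject)
        for e in res.effects:
            all_F.setdefault(e, []).append(res.F[e])
            all_p.setdefault(e, []).append(res.p[e])
    return ResamplingSummary(
        median_F={e: float(np.median(v)) for e, v in all_F.items()},
        median_p={e: float(np.median(v)) for e, v in all_p.items()},
        iterations=iterations,
        seed=seed,
        n_matched=2 * len(left),
        unmatched_warnings=warn_total,
    )


# ---------------------------------------------------------------------------
# handedness: permutation ANOVA


@dataclass
class PermutationResult:
    effect: str
    observed_F: float
    iterations: int
    exceed_count: int

    @property
    def p_empirical(self) -> float:
        """Empirical p = (b+1)/(m+1), never exactly 0."""
        return (self.exceed_count + 1) / (self.iterations + 1)


def permutation_anova(
    table: pd.DataFrame,
    response: str,
    iterations: int = 10_000,
    seed: int = 0,
    within: tuple[str, str] = ("feature", "hemisphere"),
    between: str = "handedness",
    subject: str = "subject_id",
) -> dict[str, PermutationResult]:
    """Subject-level label permutation of the between factor.

    Group sizes are preserved; for every permutation the mixed ANOVA is
    recomputed and, for each effect involving the between factor, the count
    b of permuted F >= observed F yields the empirical p = (b+1)/(m+1).
    """
    scores, _ = _subject_scores(table, response, within, between, subject)
    g = scores["group"].to_numpy().copy()
    a_name, b_name = within
    eff_names = [
        between,
        f"{a_name}:{between}",
        f"{b_name}:{between}",
        f"{a_name}:{b_name}:{between}",
    ]
    score_cols = ["m", "sA", "sB", "sAB"]

    def between_Fs(gv: np.ndarray) -> dict[str, float]:
        out = {}
        for name, col in zip(eff_names, score_cols):
            _, f1, _ = _stratum_tests(scores[col].to_numpy(), gv)
            out[name] = f1
        return out

    observed = between_Fs(g)
    exceed = {e: 0 for e in eff_names}
    rng = np.random.default_rng(seed)
    for _ in range(iterations):
        perm = rng.permutation(g)
        fs = between_Fs(perm)
        for e in eff_names:
            if fs[e] >= observed[e]:
                exceed[e] += 1
    return {
        e: PermutationResult(
            effect=e,
            observed_F=float(observed[e]),
            iterations=iterations,
            exceed_count=exceed[e],
        )
        for e in eff_names
    }


# ---------------------------------------------------------------------------
# linear mixed model


@dataclass
class LmmResult:
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    var_intercept: float
    var_residual: float
    reml_loglike: float
    boundary: bool
    formula: str
    var_intercept_se: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.params, "SE": self.bse, "t": self.tvalues}
        )

    summary = to_frame


def lmm_random_intercept(
    table: pd.DataFrame,
    response: str,
    fixed: str = "feature * hemisphere * handedness",
    subject: str = "subject_id",
) -> LmmResult:
    """Random-intercept linear mixed model fitted by REML.

    Fixed effects are the full factorial given by ``fixed``; the random
    intercept per subject absorbs repeated measurements across hemispheres
    and features.  t = beta/SE is reported without denominator df, as is
    conventional for this model family.  A fitted intercept variance at the
    zero boundary is returned with ``boundary=True`` rather than an error.
    """
    import statsmodels.formula.api as smf

    data = table.dropna(subset=[response]).copy()
    counts = data.groupby(subject).size()
    if (counts < 2).all():
        raise ValueError("need >= 2 observations for at least some subjects")
    formula = f"{response} ~ {fixed}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary fits warn; reported via flag
        model = smf.mixedlm(formula, data, groups=data[subject])
        res = None
        err: Exception | None = None
        # gradient methods can hit singular information matrices on small
        # unbalanced designs; fall back to derivative-free search
        for method in ("lbfgs", "powell", "nm"):
            try:
                res = model.fit(reml=True, method=method)
                break
            except np.linalg.LinAlgError as e:
                err = e
        if res is None:
            raise ValueError(f"mixed model fit failed: {err}")
    var_int = float(res.cov_re.iloc[0, 0])
    var_res = float(res.scale)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # boundary fits yield sqrt(<0) here
            var_int_se = float(res.bse_re.iloc[0])
    except Exception:
        var_int_se = float("nan")
    return LmmResult(
        var_intercept_se=var_int_se,
        params=res.fe_params,
        bse=res.bse_fe,
        tvalues=res.fe_params / res.bse_fe,
        var_intercept=var_int,
        var_residual=var_res,
        reml_loglike=float(res.llf),
        boundary=var_int < 1e-6 * max(var_res, 1e-12),
        formula=formula,
    )


# ---------------------------------------------------------------------------
# correlation and assumption checks


@dataclass
class CorrelationResult:
    r: float
    p_two_tailed: float
    n: int
    degenerate: bool = False


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Pearson product-moment correlation with t-based two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need >= 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(r=np.nan, p_two_tailed=np.nan, n=x.size, degenerate=True)
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), p_two_tailed=float(p), n=int(x.size))


def assumption_checks(
    groups: dict[str, np.ndarray], levene_center: str = "mean"
) -> pd.DataFrame:
    """Shapiro-Wilk per group plus a Levene test across all groups.

    Informational only — results never gate the main analyses.  Groups with
    fewer than 3 observations or zero variance are skipped with a note.
    Rows: one per group (test='shapiro') and one overall (test='levene',
    centred on the mean).
    """
    rows = []
    usable = []
    for name, v in groups.items():
        v = np.asarray(v, dtype=float)
        v = v[np.isfinite(v)]
        if v.size < 3:
            rows.append({"group": name, "test": "shapiro", "stat": np.nan, "p": np.nan, "note": "skipped: n < 3"})
            continue
        if np.ptp(v) == 0:
            rows.append({"group": name, "test": "shapiro", "stat": np.nan, "p": np.nan, "note": "skipped: constant"})
            continue
        w, p = sps.shapiro(v)
        rows.append({"group": name, "test": "shapiro", "stat": float(w), "p": float(p), "note": ""})
        usable.append(v)
    if len(usable) >= 2:
        f, p = sps.levene(*usable, center=levene_center)
        rows.append({"group": "all", "test": "levene", "stat": float(f), "p": float(p), "note": f"center={levene_center}"})
    else:
        rows.append({"group": "all", "test": "levene", "stat": np.nan, "p": np.nan, "note": "skipped: < 2 usable groups"})
    return pd.DataFrame(rows)
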