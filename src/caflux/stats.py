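"""Normality-gated group comparison and qPCR fold change.

The decision procedure mirrors the study design: per-group Shapiro–Wilk at
α = 0.05 gates the parametric path; if every group passes, features are
compared by one-way ANOVA with Tukey's HSD post hoc; if any group fails,
the comparison falls back to Kruskal–Wallis with Dunn's rank post hoc —
the source protocol is silent on the failure branch, so the fallback is
always flagged in the procedure log rather than substituted silently.
Two-group contrasts use Student's t (Welch when the variance ratio
exceeds 4).  ``ddct_fold_change`` implements the comparative-Ct (2^−ΔΔCt)
formula for relative gene expression.

Features are compared one at a time with no cross-feature multiplicity
correction, matching per-metric reporting; a log note records this.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, ValidationError

__all__ = [
    "GroupedSample",
    "ComparisonResult",
    "shapiro_wilk",
    "one_way_anova",
    "tukey_hsd",
    "kruskal_wallis",
    "dunn_posthoc",
    "two_group_t",
    "ddct_fold_change",
    "compare_conditions",
]

GroupedSample = Mapping[str, Sequence[float]]


def _as_groups(groups: GroupedSample, min_n: int = 2) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    out = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.ndim != 1 or len(arr) < min_n:
            raise ValidationError(f"group {name!r} needs at least {min_n} observations")
        if not np.isfinite(arr).all():
            raise ValidationError(f"group {name!r} contains non-finite values")
        out[str(name)] = arr
    return out


def shapiro_wilk(x: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk W and p for a sample of 3 ≤ n ≤ 5000.

    Raises on smaller or constant samples, where the statistic is undefined.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or not (3 <= len(arr) <= 5000):
        raise ValidationError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={arr.size}")
    if not np.isfinite(arr).all():
        raise ValidationError("sample contains non-finite values")
    if np.ptp(arr) == 0:
        raise ValidationError("Shapiro-Wilk is undefined for a constant sample")
    w, p = sps.shapiro(arr)
    return float(w), float(p)


def one_way_anova(groups: GroupedSample) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA: (F, df_between, df_within, p)."""
    g = _as_groups(groups)
    ns = [len(v) for v in g.values()]
    k = len(g)
    n_total = sum(ns)
    if n_total <= k:
        raise ValidationError("total sample size must exceed the number of groups")
    ssw = sum(float(((v - v.mean()) ** 2).sum()) for v in g.values())
    if ssw == 0:
        raise DegenerateDataError("zero within-group variance; ANOVA undefined")
    f, p = sps.f_oneway(*g.values())
    return float(f), k - 1, n_total - k, float(p)


def _msw(g: dict[str, np.ndarray]) -> tuple[float, int]:
    df = sum(len(v) for v in g.values()) - len(g)
    ssw = sum(float(((v - v.mean()) ** 2).sum()) for v in g.values())
    return ssw / df, df


def tukey_hsd(groups: GroupedSample, alpha: float = 0.05) -> pd.DataFrame:
    """All-pairs Tukey HSD table.

    One row per unordered pair: mean difference, studentized-range statistic
    q = |Δmean| / sqrt(MSW/2 · (1/n_i + 1/n_j)), adjusted p from the
    studentized-range distribution, and a reject flag at ``alpha``.
    Symmetric under group relabeling.
    """
    g = _as_groups(groups)
    msw, df = _msw(g)
    if msw == 0:
        raise DegenerateDataError("zero within-group variance; Tukey HSD undefined")
    k = len(g)
    rows = []
    for (na, va), (nb, vb) in itertools.combinations(g.items(), 2):
        diff = float(vb.mean() - va.mean())
        se = math.sqrt(msw / 2.0 * (1.0 / len(va) + 1.0 / len(vb)))
        q = abs(diff) / se
        p = float(sps.studentized_range.sf(q, k, df))
        rows.append(
            {
                "group_a": na, "group_b": nb, "mean_diff": diff,
                "q": q, "p_adj": min(max(p, 0.0), 1.0), "reject": p < alpha,
            }
        )
    return pd.DataFrame(rows)


def kruskal_wallis(groups: GroupedSample) -> tuple[float, float]:
    """Kruskal–Wallis H and p (tie-corrected)."""
    g = _as_groups(groups)
    h, p = sps.kruskal(*g.values())
    return float(h), float(p)


def dunn_posthoc(groups: GroupedSample, alpha: float = 0.05) -> pd.DataFrame:
    """Dunn's rank-based all-pairs post hoc with Bonferroni adjustment.

    z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T) · (1/n_i + 1/n_j)), where T is
    the tie correction Σ(t³−t) / (12(N−1)) over tied-value groups.
    """
    g = _as_groups(groups)
    all_vals = np.concatenate(list(g.values()))
    n_total = len(all_vals)
    ranks = sps.rankdata(all_vals)
    mean_ranks = {}
    start = 0
    for name, v in g.items():
        mean_ranks[name] = float(ranks[start : start + len(v)].mean())
        start += len(v)
    _, counts = np.unique(all_vals, return_counts=True)
    tie_corr = float(((counts**3 - counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_corr
    if var_base <= 0:
        raise DegenerateDataError("all observations tied; Dunn test undefined")
    m = len(g) * (len(g) - 1) // 2
    rows = []
    for (na, va), (nb, vb) in itertools.combinations(g.items(), 2):
        se = math.sqrt(var_base * (1.0 / len(va) + 1.0 / len(vb)))
        z = (mean_ranks[nb] - mean_ranks[na]) / se
        p = min(2.0 * float(sps.norm.sf(abs(z))) * m, 1.0)
        rows.append(
            {
                "group_a": na, "group_b": nb,
                "mean_rank_diff": mean_ranks[nb] - mean_ranks[na],
                "z": z, "p_adj": p, "reject": p < alpha,
            }
        )
    return pd.DataFrame(rows)


def two_group_t(
    x: Sequence[float],
    y: Sequence[float],
    variant: Optional[str] = None,
) -> tuple[float, float, float]:
    """Two-sample t test: (t, df, p).

    ``variant`` is "student" (pooled variance) or "welch"; when None, Welch
    is used if the sample-variance ratio exceeds 4, Student otherwise.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(xa) < 2 or len(ya) < 2:
        raise ValidationError("each group needs at least 2 observations")
    if variant is None:
        vx, vy = xa.var(ddof=1), ya.var(ddof=1)
        if min(vx, vy) == 0:
            variant = "student"
        else:
            variant = "welch" if max(vx, vy) / min(vx, vy) > 4.0 else "student"
    if variant not in ("student", "welch"):
        raise ValidationError(f"unknown t-test variant {variant!r}")
    equal_var = variant == "student"
    res = sps.ttest_ind(xa, ya, equal_var=equal_var)
    if equal_var:
        df = float(len(xa) + len(ya) - 2)
    else:
        df = float(res.df)
    return float(res.statistic), df, float(res.pvalue)


def ddct_fold_change(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression by the comparative-Ct method, 2^−ΔΔCt.

    ΔΔCt = (Ct_target − Ct_ref)_sample − (Ct_target − Ct_ref)_control.
    """
    for v in (ct_target_sample, ct_ref_sample, ct_target_control, ct_ref_control):
        if not math.isfinite(v):
            raise ValidationError("all Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_control - ct_ref_control)
    return 2.0 ** (-ddct)


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of the gated comparison for one feature."""

    feature: str
    normality: dict[str, dict]          # group -> {W, p, passed}
    omnibus: dict                        # {test, statistic, p, df...}
    pairwise: pd.DataFrame               # Tukey or Dunn table
    procedure_log: list[str]
    ttests: list[dict] = field(default_factory=list)

    @property
    def parametric_path(self) -> bool:
        return self.omnibus.get("test") == "anova"

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "normality": self.normality,
            "omnibus": self.omnibus,
            "pairwise": self.pairwise.to_dict(orient="records"),
            "ttests": self.ttests,
            "procedure_log": list(self.procedure_log),
        }


def _compare_one(
    feature: str,
    groups: dict[str, np.ndarray],
    alpha: float,
    t_pairs: Sequence[tuple[str, str]],
    log: list[str],
) -> ComparisonResult:
    normality = {}
    all_pass = True
    for name, vals in groups.items():
        w, p = shapiro_wilk(vals)
        passed = p >= alpha
        normality[name] = {"W": w, "p": p, "passed": bool(passed)}
        log.append(f"Shapiro-Wilk [{name}]: W={w:.4f}, p={p:.4g} -> {'pass' if passed else 'FAIL'}")
        all_pass &= passed
    if all_pass:
        f, dfb, dfw, p = one_way_anova(groups)
        omnibus = {"test": "anova", "statistic": f, "df_between": dfb, "df_within": dfw, "p": p}
        log.append(f"all groups normal at {alpha}: one-way ANOVA F({dfb},{dfw})={f:.4f}, p={p:.4g}")
        pairwise = tukey_hsd(groups, alpha=alpha)
        log.append(f"Tukey HSD post hoc at alpha={alpha}")
    else:
        h, p = kruskal_wallis(groups)
        omnibus = {"test": "kruskal", "statistic": h, "p": p}
        log.append(
            f"normality failed for >=1 group: falling back to Kruskal-Wallis H={h:.4f}, "
            f"p={p:.4g} (DEVIATION: protocol specifies no non-normal branch)"
        )
        pairwise = dunn_posthoc(groups, alpha=alpha)
        log.append(f"Dunn post hoc (Bonferroni) at alpha={alpha}")
    ttests = []
    for ga, gb in t_pairs:
        t, df, p = two_group_t(groups[ga], groups[gb])
        ttests.append({"group_a": ga, "group_b": gb, "t": t, "df": df, "p": p})
        log.append(f"designated pair t-test {ga} vs {gb}: t={t:.4f}, df={df:.1f}, p={p:.4g}")
    return ComparisonResult(
        feature=feature, normality=normality, omnibus=omnibus,
        pairwise=pairwise, procedure_log=log, ttests=ttests,
    )


def compare_conditions(
    feature_table: pd.DataFrame,
    features: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    pair_overrides: Optional[Mapping[str, Sequence[tuple[str, str]]]] = None,
    group_column: str = "condition",
) -> list[ComparisonResult]:
    """Run the gated comparison for each feature column of a per-cell table.

    ``feature_table`` is the output of ``featurize_cohort`` (or any table
    with a group column and numeric feature columns).  Cells with a missing
    value for a feature are dropped from that feature's comparison only, and
    the drop is logged.  ``pair_overrides`` maps a feature name to pairs of
    groups that should additionally be compared with a two-group t test.
    """
    if group_column not in feature_table.columns:
        raise ValidationError(f"feature table lacks the {group_column!r} column")
    conditions = list(dict.fromkeys(feature_table[group_column]))
    if len(conditions) < 2:
        raise ValidationError("need at least 2 conditions to compare")
    if features is None:
        from .features import FEATURE_COLUMNS

        features = [c for c in FEATURE_COLUMNS if c in feature_table.columns]
    pair_overrides = pair_overrides or {}
    results = []
    for feat in features:
        log = [
            f"feature {feat!r}: groups {conditions}",
            "per-metric reporting; no cross-feature multiplicity correction applied",
        ]
        groups: dict[str, np.ndarray] = {}
        for cond in conditions:
            vals = feature_table.loc[feature_table[group_column] == cond, feat].to_numpy(float)
            n_missing = int(np.isnan(vals).sum())
            if n_missing:
                log.append(f"dropped {n_missing} missing value(s) in group {cond!r}")
                vals = vals[~np.isnan(vals)]
            if len(vals) < 3:
                raise ValidationError(
                    f"group {cond!r} has fewer than 3 usable values for feature {feat!r}"
                )
            groups[cond] = vals
        results.append(
            _compare_one(feat, groups, alpha, pair_overrides.get(feat, ()), log)
        )
    return results
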