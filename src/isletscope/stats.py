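"""Study-level statistics for two-group islet studies.

Implements the analyses applied to per-sample pancreas summaries:

* percent change between group means;
* pooled-variance unpaired Student's t-test (two-sided);
* the two-sample Hotelling T² test, used for the per-bin (islet count,
  beta volume) pairs because the two measures are correlated:
  ``T² = (n1 n2/(n1+n2)) d' S⁻¹ d`` with pooled covariance S, transformed to
  an F statistic ``F = T² (n1+n2-p-1) / (p (n1+n2-2))`` on (p, n1+n2-p-1) df;
* Mauchly's sphericity test and the Greenhouse–Geisser ε on the pooled
  covariance of k-1 orthonormal within-subject contrasts;
* the two-way 2x4 mixed ANOVA (treatment between subjects, size category
  within subjects), with GG correction of the within-subject p-values when
  Mauchly's test rejects sphericity at α = 0.05.

With n = 7 subjects per group and k = 4 size categories the uncorrected
degrees of freedom are (1, 12) for the treatment effect and (3, 36) for the
category and interaction effects.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .isletquant import BIN_NAMES, PancreasResult

logger = logging.getLogger("isletscope")

ALPHA_SPHERICITY = 0.05


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class HotellingResult:
    T2: float
    F: float
    df1: int
    df2: int
    p: float


@dataclass(frozen=True)
class SphericityResult:
    W: float
    chi2: float
    df: int
    p: float
    epsilon_gg: float


@dataclass(frozen=True)
class EffectResult:
    F: float
    df1: float
    df2: float
    p: float
    gg_corrected: bool = False


@dataclass(frozen=True)
class MixedAnovaResult:
    treatment: EffectResult
    category: EffectResult
    interaction: EffectResult
    sphericity: SphericityResult
    ss: dict[str, float] = field(default_factory=dict)


def percent_increase(mean_ref: float, mean_trt: float) -> float:
    """Percent change of the treated mean relative to the reference mean."""
    if mean_ref <= 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * (mean_trt - mean_ref) / mean_ref


def sem(values: Sequence[float]) -> float:
    """Standard error of the mean, sd(ddof=1)/sqrt(n)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        return float("nan")
    return float(v.std(ddof=1) / math.sqrt(len(v)))


def unpaired_t(group_a: Sequence[float], group_b: Sequence[float]) -> TTestResult:
    """Classic pooled-variance unpaired Student's t (two-sided).

    Sign convention: positive t when group_a's mean exceeds group_b's.
    Zero pooled variance with equal means gives t = 0, p = 1; with unequal
    means the statistic is undefined and an error is raised.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        if diff == 0:
            return TTestResult(0.0, df, 1.0)
        raise ValueError("zero pooled variance with unequal means: t undefined")
    t = diff / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(float(t), df, float(p))


def hotelling_two_sample(a: np.ndarray, b: np.ndarray) -> HotellingResult:
    """Two-sample Hotelling T² on n1 x p and n2 x p observation matrices."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share the same number of variables")
    n1, p = a.shape
    n2 = b.shape[0]
    if n1 + n2 <= p + 1:
        raise ValueError(f"need n1+n2 > p+1 (got n1+n2={n1 + n2}, p={p})")
    d = a.mean(axis=0) - b.mean(axis=0)
    s_pooled = (((n1 - 1) * np.cov(a, rowvar=False, ddof=1).reshape(p, p)
                 + (n2 - 1) * np.cov(b, rowvar=False, ddof=1).reshape(p, p))
                / (n1 + n2 - 2))
    try:
        solve = np.linalg.solve(s_pooled, d)
    except np.linalg.LinAlgError:
        raise ValueError(
            "pooled covariance is singular; reduce the dimension or drop "
            "collinear variables"
        ) from None
    if not np.all(np.isfinite(solve)):
        raise ValueError("pooled covariance is singular; reduce the dimension")
    t2 = float(n1 * n2 / (n1 + n2) * d @ solve)
    df1, df2 = p, n1 + n2 - p - 1
    f = t2 * df2 / (p * (n1 + n2 - 2))
    p_val = float(sps.f.sf(f, df1, df2)) if t2 > 0 else 1.0
    return HotellingResult(t2, float(f), df1, df2, p_val)


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (rows orthonormal, each
    orthogonal to the unit vector); Helmert contrasts, normalized."""
    c = np.zeros((k - 1, k))
    for i in range(k - 1):
        c[i, : i + 1] = 1.0
        c[i, i + 1] = -(i + 1.0)
        c[i] /= np.linalg.norm(c[i])
    return c


def mauchly_and_epsilon(
    data: np.ndarray,
    groups: Sequence | None = None,
) -> SphericityResult:
    """Mauchly's W and the Greenhouse–Geisser ε for an n x k within-subject
    matrix.

    The contrast covariance is pooled within groups when group labels are
    given (the standard treatment for mixed designs).  W is the ratio of the
    determinant of the contrast covariance to the (k-1)-th power of its mean
    eigenvalue; the χ² approximation uses the pooled error df.  ε is computed
    from the eigenvalues λ of the contrast covariance as (Σλ)²/((k-1)Σλ²).
    With k = 2 sphericity holds trivially (W = 1, ε = 1).
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected an n x k within-subject matrix")
    n, k = x.shape
    if k < 2:
        raise ValueError("need at least 2 within-subject levels")
    if groups is None:
        groups = np.zeros(n)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    g = len(labels)
    if n - g < k - 1:
        raise ValueError("too few subjects for the contrast covariance")

    c = _orthonormal_contrasts(k)
    y = x @ c.T                                   # n x (k-1) contrast scores
    s = np.zeros((k - 1, k - 1))
    for lab in labels:
        yg = y[groups == lab]
        dev = yg - yg.mean(axis=0)
        s += dev.T @ dev
    s /= (n - g)                                  # pooled contrast covariance

    eig = np.linalg.eigvalsh(s)
    eig = np.clip(eig, 0.0, None)
    mean_eig = eig.mean()
    epsilon = float(eig.sum() ** 2 / ((k - 1) * (eig ** 2).sum()))

    if k == 2:
        return SphericityResult(1.0, 0.0, 0, 1.0, 1.0)

    w = float(np.prod(eig) / mean_eig ** (k - 1)) if mean_eig > 0 else 0.0
    w = min(w, 1.0)
    d_err = n - g
    df = (k - 1) * k // 2 - 1
    # standard χ² approximation with the Bartlett-style correction factor
    f_corr = 1.0 - (2.0 * (k - 1) ** 2 + (k - 1) + 2.0) / (6.0 * (k - 1) * d_err)
    chi2 = -f_corr * d_err * math.log(max(w, 1e-300))
    p = float(sps.chi2.sf(chi2, df))
    return SphericityResult(w, float(chi2), df, p, epsilon)


def mixed_anova_2x4(
    data: np.ndarray,
    groups: Sequence,
    alpha_sphericity: float = ALPHA_SPHERICITY,
) -> MixedAnovaResult:
    """Two-way mixed ANOVA: one between-subject factor (two treatments), one
    within-subject factor (the k size categories).

    ``data`` is a subjects x k table with every subject observed at all k
    levels (missing cells raise); ``groups`` assigns each subject (row) to a
    treatment.  The sums of squares decompose as between-subjects (treatment
    vs subjects-within-groups) and within-subjects (category and
    category x treatment vs category x subjects-within-groups).  The GG
    correction multiplies the within-subject dfs by ε when Mauchly's test
    rejects sphericity at ``alpha_sphericity``.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a subjects x categories table")
    if np.any(~np.isfinite(x)):
        raise ValueError("missing cell in the within-subject table (no imputation)")
    n, k = x.shape
    groups = np.asarray(groups)
    if len(groups) != n:
        raise ValueError("one group label per subject is required")
    labels = np.unique(groups)
    g = len(labels)
    if g != 2:
        raise ValueError(f"expected exactly two treatment groups, got {g}")
    if min((groups == lab).sum() for lab in labels) < 2:
        raise ValueError("need at least 2 subjects per group")

    grand = x.mean()
    subj_means = x.mean(axis=1)
    cat_means = x.mean(axis=0)

    n_g = {lab: int((groups == lab).sum()) for lab in labels}
    grp_means = {lab: x[groups == lab].mean() for lab in labels}
    cell_means = {lab: x[groups == lab].mean(axis=0) for lab in labels}

    ss_total = float(((x - grand) ** 2).sum())
    ss_between_subj = float(k * ((subj_means - grand) ** 2).sum())
    ss_treatment = float(k * sum(n_g[lab] * (grp_means[lab] - grand) ** 2 for lab in labels))
    ss_subj_within = ss_between_subj - ss_treatment

    ss_category = float(n * ((cat_means - grand) ** 2).sum())
    ss_cells = float(sum(n_g[lab] * ((cell_means[lab] - grand) ** 2).sum() for lab in labels))
    ss_interaction = ss_cells - ss_category - ss_treatment
    ss_error_within = ss_total - ss_between_subj - ss_category - ss_interaction

    df_treat = (g - 1, n - g)
    df_within = (k - 1, (n - g) * (k - 1))
    df_inter = ((g - 1) * (k - 1), (n - g) * (k - 1))

    if ss_subj_within <= 0 or ss_error_within <= 0:
        raise ValueError(
            "degenerate design: zero between-subject or within-subject error "
            "variance; F statistics are undefined"
        )
    ms = lambda ss, df: ss / df
    f_treat = ms(ss_treatment, df_treat[0]) / ms(ss_subj_within, df_treat[1])
    f_cat = ms(ss_category, df_within[0]) / ms(ss_error_within, df_within[1])
    f_inter = ms(ss_interaction, df_inter[0]) / ms(ss_error_within, df_inter[1])

    sph = mauchly_and_epsilon(x, groups)
    correct = k > 2 and sph.p < alpha_sphericity
    eps = sph.epsilon_gg if correct else 1.0

    p_treat = float(sps.f.sf(f_treat, *df_treat))
    p_cat = float(sps.f.sf(f_cat, eps * df_within[0], eps * df_within[1]))
    p_inter = float(sps.f.sf(f_inter, eps * df_inter[0], eps * df_inter[1]))

    ss = {
        "treatment": ss_treatment, "subjects_within_groups": ss_subj_within,
        "category": ss_category, "interaction": ss_interaction,
        "error_within": ss_error_within, "total": ss_total,
    }
    return MixedAnovaResult(
        treatment=EffectResult(float(f_treat), *map(float, df_treat), p_treat),
        category=EffectResult(float(f_cat), eps * df_within[0], eps * df_within[1],
                              p_cat, gg_corrected=correct),
        interaction=EffectResult(float(f_inter), eps * df_inter[0], eps * df_inter[1],
                                 p_inter, gg_corrected=correct),
        sphericity=sph,
        ss=ss,
    )


# ---------------------------------------------------------------------------
# Study report
# ---------------------------------------------------------------------------

@dataclass
class GroupDesign:
    """Sample-to-group assignment plus the per-sample pancreas summaries."""

    groups: Mapping[str, str]                     # sample_id -> group label
    results: Mapping[str, PancreasResult]         # sample_id -> summary
    reference_group: str | None = None            # denominator of % changes

    def __post_init__(self):
        labels = sorted(set(self.groups.values()))
        if len(labels) != 2:
            raise ValueError(f"exactly two groups required, got {labels}")
        missing = set(self.groups) - set(self.results)
        if missing:
            raise ValueError(f"samples without results: {sorted(missing)}")
        if self.reference_group is None:
            self.reference_group = labels[0]
        if self.reference_group not in labels:
            raise ValueError(f"reference group {self.reference_group!r} not in {labels}")
        self.labels = labels

    def values(self, metric, group: str) -> list:
        return [metric(self.results[s]) for s, gp in sorted(self.groups.items())
                if gp == group]


def _group_summary(design: GroupDesign, metric) -> dict:
    ref = design.reference_group
    trt = next(l for l in design.labels if l != ref)
    a = design.values(metric, trt)
    b = design.values(metric, ref)
    out = {
        "groups": {
            ref: {"mean": float(np.mean(b)), "sem": sem(b), "n": len(b)},
            trt: {"mean": float(np.mean(a)), "sem": sem(a), "n": len(a)},
        },
    }
    if np.mean(b) > 0:
        out["percent_increase"] = percent_increase(float(np.mean(b)), float(np.mean(a)))
    if len(a) >= 2 and len(b) >= 2:
        try:
            t = unpaired_t(a, b)
            out["t_test"] = {"t": t.t, "df": t.df, "p": t.p}
        except ValueError as e:
            logger.warning("t-test skipped: %s", e)
    else:
        logger.warning("t-test skipped: a group has < 2 samples")
    return out


def study_report(design: GroupDesign) -> dict:
    """Full two-group statistical report over the per-sample summaries.

    For every metric (total islet count, total beta volume, Ki67⁺ islet
    count; overall and per size bin): group mean ± s.e.m., percent increase
    of the treated group, unpaired t-test.  Per bin, a Hotelling T² on the
    correlated (count, volume) pair; over bins, the 2x4 mixed ANOVA for
    counts, volumes and Ki67⁺ counts.
    """
    ref = design.reference_group
    trt = next(l for l in design.labels if l != ref)
    report: dict = {"reference_group": ref, "treated_group": trt, "metrics": {},
                    "per_bin": {}, "hotelling": {}, "mixed_anova": {}}

    metrics = {
        "total_islets": lambda r: r.total_islets,
        "total_beta_volume_mm3": lambda r: r.total_beta_volume_mm3,
    }
    has_ki67 = all(r.total_ki67_cells is not None for r in design.results.values())
    if has_ki67:
        metrics["total_ki67_cells"] = lambda r: r.total_ki67_cells
        metrics["total_ki67_islets"] = lambda r: sum(r.bin_ki67_positive.values())
    for name, metric in metrics.items():
        report["metrics"][name] = _group_summary(design, metric)

    for b in BIN_NAMES:
        per = {
            "count": _group_summary(design, lambda r, b=b: r.bin_counts[b]),
            "volume_mm3": _group_summary(design, lambda r, b=b: r.bin_volumes_mm3[b]),
        }
        if has_ki67:
            per["ki67_islets"] = _group_summary(design, lambda r, b=b: r.bin_ki67_positive[b])
        report["per_bin"][b] = per

        a = np.column_stack([
            design.values(lambda r, b=b: r.bin_counts[b], trt),
            design.values(lambda r, b=b: r.bin_volumes_mm3[b], trt),
        ])
        c = np.column_stack([
            design.values(lambda r, b=b: r.bin_counts[b], ref),
            design.values(lambda r, b=b: r.bin_volumes_mm3[b], ref),
        ])
        if len(a) >= 2 and len(c) >= 2:
            try:
                h = hotelling_two_sample(a, c)
                report["hotelling"][b] = {"T2": h.T2, "F": h.F, "df1": h.df1,
                                          "df2": h.df2, "p": h.p}
            except ValueError as e:
                logger.warning("Hotelling test skipped for bin %s: %s", b, e)

    anova_metrics = {
        "counts": lambda r: [r.bin_counts[b] for b in BIN_NAMES],
        "volumes_mm3": lambda r: [r.bin_volumes_mm3[b] for b in BIN_NAMES],
    }
    if has_ki67:
        anova_metrics["ki67_islets"] = lambda r: [r.bin_ki67_positive[b] for b in BIN_NAMES]
    sample_ids = sorted(design.groups)
    group_labels = [design.groups[s] for s in sample_ids]
    for name, rows in anova_metrics.items():
        x = np.array([rows(design.results[s]) for s in sample_ids], dtype=float)
        try:
            res = mixed_anova_2x4(x, group_labels)
        except ValueError as e:
            logger.warning("mixed ANOVA skipped for %s: %s", name, e)
            continue
        report["mixed_anova"][name] = {
            "treatment": res.treatment.__dict__,
            "category": res.category.__dict__,
            "interaction": res.interaction.__dict__,
            "sphericity": res.sphericity.__dict__,
        }
    return report


def format_report(report: dict) -> str:
    """Human-readable text table of a study report."""
    lines = [f"Study report: {report['treated_group']} vs {report['reference_group']}", ""]
    for name, m in report["metrics"].items():
        gtxt = ", ".join(
            f"{g}: {v['mean']:.4g}±{v['sem']:.3g} (n={v['n']})"
            for g, v in m["groups"].items()
        )
        extra = ""
        if "percent_increase" in m:
            extra += f"  Δ={m['percent_increase']:+.1f}%"
        if "t_test" in m:
            extra += f"  t({m['t_test']['df']})={m['t_test']['t']:.2f}, p={m['t_test']['p']:.4g}"
        lines.append(f"{name:24s} {gtxt}{extra}")
    lines.append("")
    for b, per in report["per_bin"].items():
        for mname, m in per.items():
            extra = f"  Δ={m['percent_increase']:+.1f}%" if "percent_increase" in m else ""
            if "t_test" in m:
                extra += f"  p={m['t_test']['p']:.4g}"
            lines.append(f"{b:11s} {mname:12s}{extra}")
        if b in report["hotelling"]:
            h = report["hotelling"][b]
            lines.append(f"{b:11s} Hotelling T2={h['T2']:.3f}, "
                         f"F({h['df1']},{h['df2']})={h['F']:.3f}, p={h['p']:.4g}")
    lines.append("")
    for name, a in report.get("mixed_anova", {}).items():
        t, c, i = a["treatment"], a["category"], a["interaction"]
        lines.append(
            f"mixed ANOVA [{name}]: treatment F({t['df1']:.0f},{t['df2']:.0f})="
            f"{t['F']:.2f}, p={t['p']:.4g}; category F({c['df1']:.2f},{c['df2']:.2f})="
            f"{c['F']:.2f}, p={c['p']:.4g}{' (GG)' if c['gg_corrected'] else ''}; "
            f"interaction F({i['df1']:.2f},{i['df2']:.2f})={i['F']:.2f}, "
            f"p={i['p']:.4g}{' (GG)' if i['gg_corrected'] else ''}"
        )
    return "\n".join(lines)
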