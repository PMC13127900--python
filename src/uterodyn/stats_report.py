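"""Group comparisons and cohort-style summaries.

Placental and uterine contraction features are compared per feature with a
two-sided Mann-Whitney U test: exact by full enumeration of group
assignments (midranks for ties) when the pooled sample is small, normal
approximation with tie correction otherwise. Significance is reported as an
uncorrected p value against a Bonferroni-adjusted threshold (base 0.01 over
the five features -> 0.002), mirroring the convention of reporting raw p
values with a corrected threshold rather than corrected p values.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

COMPARISON_FEATURES = (
    "halfmax_duration_min",
    "max_volume_drop_pct",
    "dr2s_change_per_ms",
    "max_wall_area_change_pct",
    "max_sphericity_change",
)

EXACT_MAX_POOLED_N = 16
DEFAULT_ALPHA_BASE = 0.01


@dataclass
class GroupComparisonResult:
    feature: str
    n_placental: int
    n_uterine: int
    median_placental: float
    iqr_placental: tuple[float, float]
    median_uterine: float
    iqr_uterine: tuple[float, float]
    u_statistic: float
    p_value: float
    alpha_base: float
    alpha_bonferroni: float
    significant: bool
    method: str


def u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x over y with midrank handling of ties."""
    x = np.asarray(x, dtype=float)[:, None]
    y = np.asarray(y, dtype=float)[None, :]
    return float(np.sum(x > y) + 0.5 * np.sum(x == y))


def mann_whitney_u(
    x, y, method: str = "auto"
) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U test.

    method "exact" enumerates every assignment of the pooled values into the
    two groups and counts assignments at least as far from the null mean
    n_x * n_y / 2 as the observed U (valid with ties via midranks); method
    "asymptotic" uses the tie-corrected normal approximation. "auto"
    switches at a pooled sample size of 16.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if method == "auto":
        method = "exact" if x.size + y.size <= EXACT_MAX_POOLED_N else "asymptotic"
    u_obs = u_statistic(x, y)
    if method == "exact":
        pooled = np.concatenate([x, y])
        n = x.size
        mu = n * y.size / 2.0
        dev_obs = abs(u_obs - mu)
        # U(S) over a subset S of size n is sum_{i in S} R_i - n^2 / 2 where
        # G_ij = 1{v_i > v_j} + 0.5 * 1{v_i = v_j} and R is its row sum
        # (within-subset terms of G always total n^2 / 2).
        g = (pooled[:, None] > pooled[None, :]) + 0.5 * (
            pooled[:, None] == pooled[None, :]
        )
        row_sums = g.sum(axis=1)
        combos = np.array(list(combinations(range(pooled.size), n)))
        u_all = row_sums[combos].sum(axis=1) - n * n / 2.0
        p = float(np.mean(np.abs(u_all - mu) >= dev_obs - 1e-12))
        return u_obs, p, "exact"
    if method == "asymptotic":
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        return u_obs, float(res.pvalue), "asymptotic"
    raise ValueError(f"unknown method {method!r}")


def _median_iqr(values: np.ndarray) -> tuple[float, tuple[float, float]]:
    # quartiles by linear interpolation between order statistics (type 7)
    med = float(np.median(values))
    lq, uq = np.percentile(values, [25.0, 75.0])
    return med, (float(lq), float(uq))


def compare_groups(
    events: pd.DataFrame,
    features: tuple[str, ...] = COMPARISON_FEATURES,
    alpha_base: float = DEFAULT_ALPHA_BASE,
    label_col: str = "label",
    method: str = "auto",
) -> list[GroupComparisonResult]:
    """Placental-vs-uterine comparison of each contraction feature.

    Bonferroni adjustment divides the base threshold by the number of
    configured comparisons (5 features at 0.01 -> 0.002).
    """
    n_comparisons = len(features)
    if n_comparisons == 0:
        raise ValueError("no features to compare")
    alpha_bonf = alpha_base / n_comparisons
    results: list[GroupComparisonResult] = []
    for feat in features:
        sub = events[[label_col, feat]].dropna()
        xs = sub.loc[sub[label_col] == "placental", feat].to_numpy(dtype=float)
        ys = sub.loc[sub[label_col] == "uterine", feat].to_numpy(dtype=float)
        if xs.size == 0 or ys.size == 0:
            import warnings

            warnings.warn(f"comparison for {feat!r} skipped: empty group")
            continue
        u, p, used = mann_whitney_u(xs, ys, method=method)
        med_x, iqr_x = _median_iqr(xs)
        med_y, iqr_y = _median_iqr(ys)
        results.append(
            GroupComparisonResult(
                feature=feat,
                n_placental=int(xs.size),
                n_uterine=int(ys.size),
                median_placental=med_x,
                iqr_placental=iqr_x,
                median_uterine=med_y,
                iqr_uterine=iqr_y,
                u_statistic=u,
                p_value=p,
                alpha_base=alpha_base,
                alpha_bonferroni=alpha_bonf,
                significant=p < alpha_bonf,
                method=used,
            )
        )
    return results


def comparisons_to_frame(results: list[GroupComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "n_placental": r.n_placental,
                "n_uterine": r.n_uterine,
                "median_placental": r.median_placental,
                "lq_placental": r.iqr_placental[0],
                "uq_placental": r.iqr_placental[1],
                "median_uterine": r.median_uterine,
                "lq_uterine": r.iqr_uterine[0],
                "uq_uterine": r.iqr_uterine[1],
                "U": r.u_statistic,
                "p_value": r.p_value,
                "alpha_base": r.alpha_base,
                "alpha_bonferroni": r.alpha_bonferroni,
                "significant": r.significant,
                "method": r.method,
            }
            for r in results
        ]
    )


def summarize_cohort(
    sessions: list[dict],
    event_features: tuple[str, ...] = COMPARISON_FEATURES,
    gate_pct: float = 10.0,
) -> pd.DataFrame:
    """Median (LQ, UQ) of per-session rates and per-event features.

    ``sessions`` is a list of dicts with keys "duration_s" and "events"
    (a classified-event DataFrame). Rows cover all events and the subset
    whose placental volume drop exceeds the gate.
    """
    if not sessions:
        raise ValueError("need at least one session")
    rows = []
    rates_all = []
    rates_gated = []
    frames = []
    for s in sessions:
        dur = float(s["duration_s"])
        ev = s["events"]
        frames.append(ev)
        rates_all.append(3600.0 * len(ev) / dur)
        if "max_volume_drop_pct" in ev.columns and len(ev):
            n_gated = int((ev["max_volume_drop_pct"] > gate_pct).sum())
        else:
            n_gated = 0
        rates_gated.append(3600.0 * n_gated / dur)
    all_events = (
        pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    )

    def _row(name: str, values: np.ndarray, subset: str, notice: str = ""):
        if values.size == 0:
            return {
                "quantity": name, "subset": subset, "n": 0,
                "median": np.nan, "lq": np.nan, "uq": np.nan,
                "notice": notice or "empty subset",
            }
        med, (lq, uq) = _median_iqr(values)
        return {
            "quantity": name, "subset": subset, "n": int(values.size),
            "median": med, "lq": lq, "uq": uq, "notice": notice,
        }

    rows.append(_row("rate_per_h", np.asarray(rates_all), "all"))
    rows.append(_row("rate_per_h", np.asarray(rates_gated), f">{gate_pct:g}%"))
    for feat in event_features:
        if feat not in all_events.columns:
            continue
        vals = all_events[feat].dropna().to_numpy(dtype=float)
        rows.append(_row(feat, vals, "all"))
        gated = all_events[all_events["max_volume_drop_pct"] > gate_pct]
        rows.append(
            _row(feat, gated[feat].dropna().to_numpy(dtype=float), f">{gate_pct:g}%")
        )
    return pd.DataFrame(rows)


def format_report(
    comparisons: list[GroupComparisonResult], cohort: pd.DataFrame | None = None
) -> str:
    """Plain-text report of the group comparisons and cohort summary."""
    lines = ["Group comparisons (placental vs uterine, two-sided Mann-Whitney U)"]
    if comparisons:
        a = comparisons[0]
        lines.append(
            f"base threshold p = {a.alpha_base:g}, Bonferroni-adjusted to "
            f"p = {a.alpha_bonferroni:g} over {len(comparisons)} comparisons"
        )
    for r in comparisons:
        mark = "*" if r.significant else " "
        lines.append(
            f"{mark} {r.feature}: placental {r.median_placental:.4g} "
            f"({r.iqr_placental[0]:.4g}, {r.iqr_placental[1]:.4g}) n={r.n_placental}"
            f" vs uterine {r.median_uterine:.4g} "
            f"({r.iqr_uterine[0]:.4g}, {r.iqr_uterine[1]:.4g}) n={r.n_uterine}; "
            f"U = {r.u_statistic:g}, p = {r.p_value:.4g} [{r.method}]"
        )
    if cohort is not None and len(cohort):
        lines.append("")
        lines.append("Cohort summary: median (LQ, UQ)")
        for _, row in cohort.iterrows():
            lines.append(
                f"  {row['quantity']} [{row['subset']}]: {row['median']:.4g} "
                f"({row['lq']:.4g}, {row['uq']:.4g}) n={row['n']}"
            )
    return "\n".join(lines)
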