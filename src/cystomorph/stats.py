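"""Statistical layer: paired and two-sample t tests, ΔΔCt fold change, and
the paired before/after spherical-agreement analysis over tracked arms.

The t statistics are computed from their textbook definitions (sample sd
with ``n-1``; pooled variance for the two-sample Student test) and tail
probabilities from the regularized incomplete beta function, so the layer
is self-contained and checkable against independent references to high
precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from . import morphometry
from .tracking import Track

__all__ = [
    "TestResult",
    "DdctResult",
    "paired_t_test",
    "two_sample_t_test",
    "ddct_fold_change",
    "paired_agreement_analysis",
    "t_sf",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a t test."""

    statistic: float
    df: int
    p_value: float
    tail: str
    n: int
    mean_effect: float
    n2: int | None = None


@dataclass(frozen=True)
class DdctResult:
    """Relative qPCR quantification by the ΔΔCt method."""

    delta_delta_ct: float
    fold_change: float
    target_label: str = ""
    reference_label: str = ""


def t_sf(t: float, df: int) -> float:
    """Upper-tail probability P(T > t) of Student's t via the regularized
    incomplete beta function I_x(df/2, 1/2) with x = df/(df + t²)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    x = df / (df + t * t)
    p_two_sided_half = 0.5 * special.betainc(df / 2.0, 0.5, x)
    return p_two_sided_half if t >= 0 else 1.0 - p_two_sided_half


def _tail_p(t: float, df: int, tail: str) -> float:
    if tail == "two":
        return min(1.0, 2.0 * t_sf(abs(t), df))
    if tail == "one":
        # one-tailed in the hypothesized (positive-effect) direction
        return t_sf(t, df)
    raise ValueError("tail must be 'one' or 'two'")


def paired_t_test(before, after, tail: str = "two") -> TestResult:
    """Paired t test on index-aligned before/after samples.

    ``t = mean(d) / (sd(d)/sqrt(n))`` with ``d = after - before`` and the
    ``n-1`` sample sd; ``df = n - 1``.  A one-tailed test is directional for
    ``mean(d) > 0`` (the "more cyst-like" direction).
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.ndim != 1:
        raise ValueError("before and after must be equal-length 1-D samples")
    n = before.size
    if n < 2:
        raise ValueError("paired test needs n >= 2")
    d = after - before
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: paired t is degenerate")
    t = float(d.mean() / (sd / math.sqrt(n)))
    return TestResult(
        statistic=t,
        df=n - 1,
        p_value=_tail_p(t, n - 1, tail),
        tail=tail,
        n=n,
        mean_effect=float(d.mean()),
    )


def two_sample_t_test(group1, group2, tail: str = "two") -> TestResult:
    """Two-sample Student t test with pooled variance.

    ``t = (m1 - m2) / (s_p * sqrt(1/n1 + 1/n2))``, ``df = n1 + n2 - 2``.
    A one-tailed test is directional for ``m1 > m2``.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    n1, n2 = g1.size, g2.size
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    v1 = g1.var(ddof=1)
    v2 = g2.var(ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance: two-sample t is degenerate")
    t = float((g1.mean() - g2.mean()) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2)))
    df = n1 + n2 - 2
    return TestResult(
        statistic=t,
        df=df,
        p_value=_tail_p(t, df, tail),
        tail=tail,
        n=n1,
        n2=n2,
        mean_effect=float(g1.mean() - g2.mean()),
    )


def ddct_fold_change(
    ct_target_exp: float,
    ct_ref_exp: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
    target_label: str = "",
    reference_label: str = "",
) -> DdctResult:
    """ΔΔCt relative quantification: fold change ``2**(-ΔΔCt)``.

    ``ΔΔCt = (Ct_target,exp − Ct_ref,exp) − (Ct_target,ctrl − Ct_ref,ctrl)``.
    """
    cts = (ct_target_exp, ct_ref_exp, ct_target_ctrl, ct_ref_ctrl)
    if not all(math.isfinite(c) for c in cts):
        raise ValueError("all Ct values must be finite")
    ddct = (ct_target_exp - ct_ref_exp) - (ct_target_ctrl - ct_ref_ctrl)
    return DdctResult(
        delta_delta_ct=float(ddct),
        fold_change=float(2.0 ** (-ddct)),
        target_label=target_label,
        reference_label=reference_label,
    )


def _track_score(track: Track, timepoint_h: float, convention: str):
    rec = track.record_at(timepoint_h)
    if rec is None:
        return None
    return morphometry.spherical_agreement(
        rec.width_um, rec.height_um, rec.area_um2, convention=convention
    )


def paired_agreement_analysis(
    tracks: list[Track],
    convention: str = "normalized",
    eval_time_h: float = 168.0,
    tail: str = "two",
) -> tuple[dict[str, TestResult], pd.DataFrame]:
    """Per-arm paired t test on spherical agreement before vs after treatment.

    For every complete track, "before" is the last timepoint at or before
    induction, "after" the post-induction timepoint closest to
    ``induction + eval_time_h``.  Returns per-arm test results plus a tidy
    per-track table (before, after, delta) mirroring a before/after
    line plot.
    """
    rows = []
    for tr in tracks:
        if not tr.complete:
            continue
        t0 = tr.induction_time_h
        pre_ts = [t for t in tr.timepoints_h if t <= t0]
        post_ts = [t for t in tr.timepoints_h if t > t0]
        if not pre_ts or not post_ts:
            continue
        t_before = max(pre_ts)
        t_after = min(post_ts, key=lambda t: abs(t - (t0 + eval_time_h)))
        s_before = _track_score(tr, t_before, convention)
        s_after = _track_score(tr, t_after, convention)
        rows.append(
            {
                "track_id": tr.track_id,
                "arm": tr.arm,
                "t_before_h": t_before,
                "t_after_h": t_after,
                "agreement_before": s_before.agreement,
                "agreement_after": s_after.agreement,
                "delta_agreement": morphometry.agreement_delta(s_before, s_after),
            }
        )
    table = pd.DataFrame(rows)
    results: dict[str, TestResult] = {}
    for arm in sorted(table["arm"].unique()) if len(table) else []:
        sub = table[table["arm"] == arm]
        if len(sub) < 2:
            raise ValueError(
                f"arm {arm!r} has {len(sub)} complete tracks; need >= 2"
            )
        results[arm] = paired_t_test(
            sub["agreement_before"].to_numpy(),
            sub["agreement_after"].to_numpy(),
            tail=tail,
        )
    return results, table
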