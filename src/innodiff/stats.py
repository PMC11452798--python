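"""Across-session statistics: coefficient summaries, mean-difference tests,
outlier detection, stubborn-participant identification, and the linear
decay-law summary.

The fitted influence strengths c_d vary across sessions; their per-setting
mean ± sd is the study-level estimate of how peer pressure decays with
social distance.  Sessions whose fitted coefficient deviates strongly from
the rest — typically those containing stubborn participants, whom the
consensus model cannot represent — are flagged by three detectors
(Z-score, Tukey fences, leave-one-out mean regression) so the summary can
be recomputed without them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

__all__ = [
    "CoefficientSummary",
    "OutlierReport",
    "summarize_coefficients",
    "mean_difference_test",
    "detect_outliers",
    "detect_stubborn",
    "linear_decay_fit",
]


@dataclass(frozen=True)
class CoefficientSummary:
    """Per-setting mean, sample sd (n−1) and per-session fitted values."""

    mean: dict[str, float]
    sd: dict[str, float]
    values: dict[str, np.ndarray] = field(repr=False)

    def model_string(self) -> str:
        """Human-readable empirical model, e.g.
        'du/dt = -(L1 + (0.65±0.35) L2 + (0.37±0.43) L3) u'."""
        order = {"II": 2, "III": 3, "IV": 4}
        terms = ["L1"]
        for setting, d in order.items():
            if setting in self.mean:
                terms.append(f"({self.mean[setting]:.3f}±{self.sd[setting]:.3f}) L{d}")
        return "du/dt = -(" + " + ".join(terms) + ") u"


@dataclass(frozen=True)
class OutlierReport:
    method: str
    flagged: list[str]
    scores: dict[str, float]
    stubborn_counts: dict[str, int] = field(default_factory=dict)


def summarize_coefficients(fits: pd.DataFrame) -> CoefficientSummary:
    """Mean and sample standard deviation of the fitted c_d per setting.

    ``fits`` is a frame with columns setting, c (as produced by
    ``fitting.fit_session_frame``); setting I rows (no free coefficient)
    are ignored.
    """
    mean, sd, values = {}, {}, {}
    for setting, sub in fits.dropna(subset=["c"]).groupby("setting"):
        v = sub["c"].to_numpy(float)
        if len(v) < 2:
            raise ValueError(f"setting {setting}: need ≥ 2 fitted values, got {len(v)}")
        mean[setting] = float(v.mean())
        sd[setting] = 0.0 if np.ptp(v) == 0 else float(v.std(ddof=1))
        values[setting] = v
    return CoefficientSummary(mean=mean, sd=sd, values=values)


def mean_difference_test(a, b, *, method: str = "welch", n_perm: int = 10_000,
                         seed: int = 0) -> float:
    """Two-sided p-value for the null of equal means.

    Default is Welch's unequal-variance t-test; ``method="permutation"``
    uses a seeded permutation of group labels with the mean difference as
    statistic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if a.std() == 0 and b.std() == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    if method == "welch":
        return float(sps.ttest_ind(a, b, equal_var=False).pvalue)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        hits = 0
        for _ in range(n_perm):
            rng.shuffle(pooled)
            hits += abs(pooled[: len(a)].mean() - pooled[len(a):].mean()) >= obs
        return float((hits + 1) / (n_perm + 1))
    raise ValueError(f"unknown method {method!r}")


def detect_outliers(
    values: dict[str, float] | pd.Series,
    method: str,
    *,
    z_cut: float = 2.0,
    tukey_k: float = 1.5,
    mr_k: float = 3.0,
) -> OutlierReport:
    """Flag outlying sessions by one of three detectors.

    zscore: |x − mean| / sd ≥ z_cut.  tukey: outside
    [Q1 − k·IQR, Q3 + k·IQR].  mean_regression: the leave-one-out score
    s_i = |mean(all) − mean(all \\ i)| exceeds mr_k · median(s).
    """
    s = pd.Series(values, dtype=float)
    if len(s) < 4:
        raise ValueError(f"need ≥ 4 values, got {len(s)}")
    x = s.to_numpy()
    if np.ptp(x) == 0:
        warnings.warn("constant values: no outliers detectable")
        return OutlierReport(method=method, flagged=[], scores={k: 0.0 for k in s.index})
    if method == "zscore":
        sd = x.std()  # population sd: the classic z-score normalization
        scores = np.abs(x - x.mean()) / sd
        mask = scores >= z_cut
    elif method == "tukey":
        q1, q3 = np.percentile(x, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - tukey_k * iqr, q3 + tukey_k * iqr
        # score: fence exceedance in IQR units (0 inside the fences)
        scores = np.where(x < lo, (lo - x), np.where(x > hi, x - hi, 0.0))
        scores = scores / iqr if iqr > 0 else scores
        mask = (x < lo) | (x > hi)
    elif method == "mean_regression":
        n = len(x)
        loo_means = (x.sum() - x) / (n - 1)
        scores = np.abs(x.mean() - loo_means)
        med = np.median(scores)
        mask = scores > mr_k * med if med > 0 else scores > 0
    else:
        raise ValueError(f"unknown method {method!r}; use zscore, tukey or mean_regression")
    flagged = [str(k) for k, m in zip(s.index, mask) if m]
    return OutlierReport(
        method=method,
        flagged=flagged,
        scores={str(k): float(v) for k, v in zip(s.index, scores)},
    )


def detect_stubborn(
    records: pd.DataFrame,
    *,
    consensus_share: float = 0.8,
    include_bots: bool = False,
) -> list[int]:
    """Participants who did not join the group consensus in one setting.

    Let m be the modal colour in the final round.  If m covers at least
    ``consensus_share`` of seats there is a group consensus to defect
    from, and every participant whose colour differs from m in *both* of
    the last two rounds is flagged.  Bot seats are excluded unless
    ``include_bots``.
    """
    if records["setting"].nunique() != 1:
        raise ValueError("expected records for exactly one setting")
    last = int(records["round"].max())
    final = records[records["round"] == last]
    counts = final["chosen_color"].value_counts()
    modal = int(counts.idxmax())
    if counts.max() / len(final) < consensus_share:
        return []
    pool = records if include_bots else records[records["role"] != "bot"]
    flagged = []
    for node, sub in pool[pool["round"] >= last - 1].groupby("node"):
        if len(sub) >= 2 and (sub["chosen_color"] != modal).all():
            flagged.append(int(node))
    return sorted(flagged)


def linear_decay_fit(summary: CoefficientSummary) -> tuple[float, float]:
    """Least-squares line through (d, c̄_d), anchored at (1, 1) — the fixed
    direct-influence strength.  Returns (slope, intercept); the study-level
    decay law is c_d ≈ slope·d + intercept."""
    order = {"II": 2, "III": 3, "IV": 4}
    pts = [(1.0, 1.0)] + [
        (float(order[s]), summary.mean[s]) for s in order if s in summary.mean
    ]
    if len(pts) < 2:
        raise ValueError("need means for at least one indirect setting")
    d, c = np.array(pts).T
    slope, intercept = np.polyfit(d, c, 1)
    return float(slope), float(intercept)


def outlier_table(
    fits: pd.DataFrame,
    records: pd.DataFrame | None = None,
    *,
    methods: tuple[str, ...] = ("zscore", "tukey", "mean_regression"),
    **cuts,
) -> list[OutlierReport]:
    """Run all three detectors on the per-session fitted coefficient of
    each indirect setting, attaching stubborn counts per flagged session
    when round records are supplied."""
    reports = []
    for setting, sub in fits.dropna(subset=["c"]).groupby("setting"):
        values = dict(zip(sub["session"].astype(str), sub["c"]))
        if len(values) < 4:
            log.info("setting %s: only %d sessions, skipping outlier detection", setting, len(values))
            continue
        for method in methods:
            rep = detect_outliers(values, method, **cuts)
            stub: dict[str, int] = {}
            if records is not None:
                for sid in rep.flagged:
                    sel = records[
                        (records["session_id"].astype(str) == sid)
                        & (records["setting"] == setting)
                    ]
                    stub[sid] = len(detect_stubborn(sel)) if len(sel) else 0
            reports.append(
                OutlierReport(
                    method=f"{method}[{setting}]",
                    flagged=rep.flagged,
                    scores=rep.scores,
                    stubborn_counts=stub,
                )
            )
    return reports
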