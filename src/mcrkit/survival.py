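"""Cross-platform concordance and outcome analysis for copy-state groups.

Concordance compares the direction (sign) of the qPCR log2 fold change with
the mean aCGH log2 ratio per sample; agreement strength is quantified by
Pearson's r.  Outcome analysis contrasts two copy-state groups (by default
amplified vs diploid) with Kaplan-Meier curves, the log-rank test, and the
Mantel-Haenszel hazard ratio

    HR = (O1/E1) / (O2/E2),   95% CI = exp(ln HR +/- 1.96 sqrt(1/E1 + 1/E2))

where O and E are observed and expected event counts over the pooled risk
sets, with the standard hypergeometric variance under ties.  A Cox
proportional-hazards HR is available as a sensitivity option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats


@dataclass(frozen=True)
class PlatformPair:
    """One sample measured on both platforms, on the log2 scale."""

    sample_id: str
    log2_qpcr: float
    log2_acgh: float

    def __post_init__(self):
        if not (math.isfinite(self.log2_qpcr) and math.isfinite(self.log2_acgh)):
            raise ValueError(f"{self.sample_id}: non-finite log2 value")


@dataclass(frozen=True)
class ConcordanceResult:
    n: int
    n_consistent: int
    consistent_by_sample: tuple[tuple[str, bool], ...]

    @property
    def n_inconsistent(self) -> int:
        return self.n - self.n_consistent


def _sign(value: float, epsilon: float) -> int:
    if abs(value) <= epsilon:
        return 0
    return 1 if value > 0 else -1


def direction_concordance(
    pairs: Sequence[PlatformPair], epsilon: float = 0.0
) -> ConcordanceResult:
    """Count samples whose copy-number change points the same way on both
    platforms.

    Values with absolute magnitude <= ``epsilon`` are treated as zero; zero
    matches zero only.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    flags = tuple(
        (p.sample_id, _sign(p.log2_qpcr, epsilon) == _sign(p.log2_acgh, epsilon))
        for p in pairs
    )
    return ConcordanceResult(len(flags), sum(ok for _, ok in flags), flags)


def pearson(pairs: Sequence[PlatformPair]) -> tuple[float, float]:
    """Pearson product-moment correlation of the two platforms' log2 values,
    with its two-sided p from the t distribution (n-2 df)."""
    if len(pairs) < 3:
        raise ValueError("pearson: need >=3 pairs")
    x = np.array([p.log2_qpcr for p in pairs])
    y = np.array([p.log2_acgh for p in pairs])
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson on midranks)."""
    if len(x) != len(y):
        raise ValueError("spearman: length mismatch")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    timeline: tuple[float, ...]
    survival: tuple[float, ...]

    def at(self, t: float) -> float:
        s = 1.0
        for ti, si in zip(self.timeline, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s


def km_curve(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Kaplan-Meier estimate; survival starts at 1 and is non-increasing."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape or times.size == 0:
        raise ValueError("km_curve: times and events must be same-length, non-empty")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    return KMCurve(tuple(timeline), tuple(surv))


@dataclass(frozen=True)
class SurvivalComparison:
    """Two-group survival contrast: KM curves, log-rank, Mantel-Haenszel HR."""

    label1: str
    label2: str
    n1: int
    n2: int
    observed1: float
    observed2: float
    expected1: float
    expected2: float
    logrank_chi2: float
    logrank_p: float
    hr: float            # group1 / group2
    hr_ci95: tuple[float, float]
    km1: KMCurve
    km2: KMCurve
    hr_computable: bool = True


def _risk_set_table(times1, events1, times2, events2):
    """Observed/expected/variance over pooled event-time risk sets."""
    t1 = np.asarray(times1, dtype=float)
    e1 = np.asarray(events1, dtype=int)
    t2 = np.asarray(times2, dtype=float)
    e2 = np.asarray(events2, dtype=int)
    event_times = np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))
    O1 = O2 = E1 = E2 = V = 0.0
    for t in event_times:
        n1 = float(np.sum(t1 >= t))
        n2 = float(np.sum(t2 >= t))
        d1 = float(np.sum((t1 == t) & (e1 == 1)))
        d2 = float(np.sum((t2 == t) & (e2 == 1)))
        n = n1 + n2
        d = d1 + d2
        if n == 0 or d == 0:
            continue
        O1 += d1
        O2 += d2
        E1 += d * n1 / n
        E2 += d * n2 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return O1, O2, E1, E2, V


def logrank_and_hr(
    times1: Sequence[float],
    events1: Sequence[int],
    times2: Sequence[float],
    events2: Sequence[int],
    label1: str = "group1",
    label2: str = "group2",
    method: str = "mantel-haenszel",
) -> SurvivalComparison:
    """Log-rank test and hazard ratio between two groups.

    ``method='mantel-haenszel'`` (default) estimates HR = (O1/E1)/(O2/E2)
    with CI exp(ln HR +/- 1.96 sqrt(1/E1 + 1/E2)); ``method='cox'`` fits a
    one-covariate Cox model instead.  A group with zero expected events makes
    the HR not-computable (flagged, nan), never an exception.
    """
    O1, O2, E1, E2, V = _risk_set_table(times1, events1, times2, events2)
    if V > 0:
        chi2 = (O1 - E1) ** 2 / V
        p = float(stats.chi2.sf(chi2, df=1))
    else:
        chi2, p = 0.0, 1.0
    hr_computable = E1 > 0 and E2 > 0 and O1 > 0 and O2 > 0
    if not hr_computable:
        hr, ci = float("nan"), (float("nan"), float("nan"))
    elif method == "cox":
        hr, ci = _cox_hr(times1, events1, times2, events2)
    elif method == "mantel-haenszel":
        hr = (O1 / E1) / (O2 / E2)
        half = 1.96 * math.sqrt(1.0 / E1 + 1.0 / E2)
        ci = (hr * math.exp(-half), hr * math.exp(half))
    else:
        raise ValueError(f"unknown HR method {method!r}")
    return SurvivalComparison(
        label1=label1,
        label2=label2,
        n1=len(times1),
        n2=len(times2),
        observed1=O1,
        observed2=O2,
        expected1=E1,
        expected2=E2,
        logrank_chi2=float(chi2),
        logrank_p=p,
        hr=float(hr),
        hr_ci95=ci,
        km1=km_curve(times1, events1),
        km2=km_curve(times2, events2),
        hr_computable=hr_computable,
    )


def _cox_hr(times1, events1, times2, events2) -> tuple[float, tuple[float, float]]:
    import pandas as pd

    df = pd.DataFrame(
        {
            "time": np.concatenate([np.asarray(times1, float), np.asarray(times2, float)]),
            "event": np.concatenate([np.asarray(events1, int), np.asarray(events2, int)]),
            "group1": np.concatenate(
                [np.ones(len(times1)), np.zeros(len(times2))]
            ),
        }
    )
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    hr = float(np.exp(cph.params_["group1"]))
    ci_df = cph.confidence_intervals_
    lo = float(np.exp(ci_df.iloc[0, 0]))
    hi = float(np.exp(ci_df.iloc[0, 1]))
    return hr, (lo, hi)
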