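"""Copy-number quantification from genomic qPCR and segment log2 ratios.

The quantification chain is the efficiency-corrected relative ratio
(Pfaffl / E^dCt):

    ratio = E_target^(Ct_cal,target - Ct_sample,target)
            / E_ref^(Ct_cal,ref - Ct_sample,ref)

with per-assay efficiencies E fitted from calibrator dilution-series
standard curves (E = 10^(-1/slope)).  The ddCt method is the special case
E_target = E_ref = 2.  Fold changes over the diploid calibrator are binned
into five copy states:

    ratio <  0.50          homozygous deletion
    0.50 <= ratio <= 0.75  hemizygous deletion
    0.75 <  ratio <  1.25  diploid
    1.25 <= ratio <= 1.75  gain (one extra copy)
    ratio >  1.75          amplification

Boundary values belong to the non-diploid state (amplification strictly
above 1.75).  Segment log2 ratios are classified through the same bins via
ratio = 2**log2.
"""

from __future__ import annotations

import enum
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io import CtRecord, ValidationError


class CopyState(enum.IntEnum):
    """Discrete copy state, ordered by dosage."""

    HOMOZYGOUS_DELETION = 0
    HEMIZYGOUS_DELETION = 1
    DIPLOID = 2
    GAIN = 3
    AMPLIFICATION = 4

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass(frozen=True)
class CopyThresholds:
    """Fold-change boundaries of the five copy states (over diploid = 1)."""

    homozygous: float = 0.5
    hemizygous: float = 0.75
    gain: float = 1.25
    amplification: float = 1.75

    def __post_init__(self):
        t = (self.homozygous, self.hemizygous, self.gain, self.amplification)
        if not (0 < t[0] < t[1] < t[2] < t[3]):
            raise ValueError(f"thresholds must be strictly increasing and positive: {t}")


DEFAULT_THRESHOLDS = CopyThresholds()


def classify_fold_change(ratio: float, thresholds: CopyThresholds = DEFAULT_THRESHOLDS) -> CopyState:
    """Classify a fold change over the diploid calibrator into a copy state."""
    if not ratio > 0 or not math.isfinite(ratio):
        raise ValueError(f"fold change must be positive and finite, got {ratio}")
    t = thresholds
    if ratio < t.homozygous:
        return CopyState.HOMOZYGOUS_DELETION
    if ratio <= t.hemizygous:
        return CopyState.HEMIZYGOUS_DELETION
    if ratio < t.gain:
        return CopyState.DIPLOID
    if ratio <= t.amplification:
        return CopyState.GAIN
    return CopyState.AMPLIFICATION


def call_segment_state(log2_ratio: float, thresholds: CopyThresholds = DEFAULT_THRESHOLDS) -> CopyState:
    """Classify a segment mean log2 ratio (ratio = 2**log2) into a copy state.

    Thresholds are independently configurable; the defaults equal the qPCR
    fold-change thresholds.
    """
    return classify_fold_change(2.0 ** log2_ratio, thresholds)


# ---------------------------------------------------------------------------
# Ct aggregation


@dataclass(frozen=True)
class CtAggregate:
    """Mean Ct for one sample x assay, aggregated replicate-then-experiment."""

    mean: float
    sd: float  # across experiment means; nan if undefined
    n_experiments: int
    n_wells: int
    flags: tuple[str, ...] = ()


def aggregate_ct(
    records: Sequence[CtRecord],
    qc_sd_cutoff: float = 0.5,
) -> CtAggregate:
    """Aggregate Ct wells of one sample x assay.

    Internal replicates are averaged within each experiment, then experiment
    means are averaged.  Experiments whose internal-replicate SD exceeds
    ``qc_sd_cutoff`` cycles are flagged (``high_replicate_sd:<exp>``), and a
    single-well input is flagged ``sd_undefined``.
    """
    if not records:
        raise ValueError("aggregate_ct: empty input")
    keys = {(r.sample_id, r.assay) for r in records}
    if len(keys) > 1:
        raise ValueError(f"aggregate_ct: mixed sample/assay input: {sorted(keys)}")
    by_exp: dict[str, list[float]] = defaultdict(list)
    for r in records:
        by_exp[r.experiment_id].append(r.ct)
    flags: list[str] = []
    exp_means = []
    for exp in sorted(by_exp):
        cts = np.asarray(by_exp[exp], dtype=float)
        exp_means.append(float(cts.mean()))
        if cts.size > 1 and float(cts.std(ddof=1)) > qc_sd_cutoff:
            flags.append(f"high_replicate_sd:{exp}")
    exp_means_arr = np.asarray(exp_means)
    mean = float(exp_means_arr.mean())
    if exp_means_arr.size > 1:
        sd = float(exp_means_arr.std(ddof=1))
    elif len(records) > 1:
        sd = float(np.std([r.ct for r in records], ddof=1))
    else:
        sd = float("nan")
        flags.append("sd_undefined")
    return CtAggregate(mean, sd, len(by_exp), len(records), tuple(flags))


# ---------------------------------------------------------------------------
# standard curves and ratios


@dataclass(frozen=True)
class StandardCurve:
    """Dilution-series calibration line: Ct vs log10(dilution)."""

    assay: str
    slope: float
    intercept: float
    efficiency: float
    r_squared: float
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if self.slope >= 0:
            raise ValidationError(f"{self.assay}: standard-curve slope must be negative")


def fit_standard_curve(dilution_records: Sequence[CtRecord], assay: str | None = None) -> StandardCurve:
    """Least-squares fit of mean Ct against log10(dilution factor).

    Requires >=3 distinct dilution factors.  The per-cycle amplification
    factor is E = 10^(-1/slope); curves with E > 2.1 are flagged
    ``super_efficient`` but not rejected.
    """
    recs = [r for r in dilution_records if r.role == "dilution"]
    if assay is not None:
        recs = [r for r in recs if r.assay == assay]
    if not recs:
        raise ValueError("fit_standard_curve: no dilution wells")
    assays = {r.assay for r in recs}
    if len(assays) > 1:
        raise ValueError(f"fit_standard_curve: mixed assays {sorted(assays)}; pass assay=")
    by_dil: dict[float, list[float]] = defaultdict(list)
    for r in recs:
        by_dil[r.dilution_factor].append(r.ct)
    if len(by_dil) < 3:
        raise ValueError(
            f"fit_standard_curve: need >=3 distinct dilutions, got {len(by_dil)}"
        )
    x = np.log10(np.array(sorted(by_dil), dtype=float))
    y = np.array([np.mean(by_dil[d]) for d in sorted(by_dil)], dtype=float)
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValidationError(
            f"fit_standard_curve: non-negative slope {fit.slope:.3f} "
            "(Ct must rise with dilution)"
        )
    eff = 10.0 ** (-1.0 / fit.slope)
    flags = ("super_efficient",) if eff > 2.1 else ()
    return StandardCurve(
        assay=recs[0].assay,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        efficiency=float(eff),
        r_squared=float(fit.rvalue**2),
        flags=flags,
    )


def efficiency_corrected_ratio(
    ct_sample_target: float,
    ct_cal_target: float,
    ct_sample_ref: float,
    ct_cal_ref: float,
    e_target: float,
    e_ref: float,
) -> float:
    """Efficiency-corrected relative ratio of target vs reference gene.

    ratio = e_target**(ct_cal_target - ct_sample_target)
            / e_ref**(ct_cal_ref - ct_sample_ref)
    """
    if e_target <= 1 or e_ref <= 1:
        raise ValueError("PCR efficiencies must exceed 1")
    return (e_target ** (ct_cal_target - ct_sample_target)) / (
        e_ref ** (ct_cal_ref - ct_sample_ref)
    )


def ddct_ratio(
    ct_sample_target: float,
    ct_sample_ref: float,
    ct_cal_target: float,
    ct_cal_ref: float,
) -> float:
    """Relative ratio 2**(-ddCt): perfect-doubling special case."""
    ddct = (ct_sample_target - ct_sample_ref) - (ct_cal_target - ct_cal_ref)
    return 2.0 ** (-ddct)


# ---------------------------------------------------------------------------
# full qPCR calling pipeline


@dataclass(frozen=True)
class FoldChange:
    """Efficiency-corrected fold change over the diploid calibrator."""

    sample_id: str
    assay: str
    ratio: float
    log2_ratio: float
    state: CopyState
    qc_flags: tuple[str, ...] = ()

    def __post_init__(self):
        if self.ratio <= 0:
            raise ValidationError(f"{self.sample_id}/{self.assay}: non-positive ratio")


def compute_fold_changes(
    records: Iterable[CtRecord],
    reference_assay: str = "LAMA1",
    calibrator_id: str = "CALIBRATOR",
    thresholds: CopyThresholds = DEFAULT_THRESHOLDS,
    mode: str = "ratio_of_means",
    qc_sd_cutoff: float = 0.5,
) -> tuple[list[FoldChange], dict[str, StandardCurve]]:
    """Run the full qPCR copy-calling chain on a Ct table.

    Per assay: fit the standard curve from dilution wells (falling back to
    E = 2 with a ``no_standard_curve`` flag when none exist); aggregate Ct of
    each sample and of the calibrator; form the efficiency-corrected ratio of
    each target assay over ``reference_assay`` and classify it.

    ``mode='ratio_of_means'`` (default) computes one ratio from the fully
    aggregated Cts; ``mode='mean_of_ratios'`` computes a ratio per experiment
    (experiments present for all four Ct terms) and averages those.
    """
    if mode not in {"ratio_of_means", "mean_of_ratios"}:
        raise ValueError(f"unknown mode {mode!r}")
    records = list(records)
    assays = sorted({r.assay for r in records})
    if reference_assay not in assays:
        raise ValueError(f"reference assay {reference_assay!r} absent from Ct table")

    curves: dict[str, StandardCurve] = {}
    eff_flags: dict[str, tuple[str, ...]] = {}
    for assay in assays:
        dil = [r for r in records if r.assay == assay and r.role == "dilution"]
        if dil:
            curve = fit_standard_curve(dil)
            curves[assay] = curve
            eff_flags[assay] = curve.flags
        else:
            eff_flags[assay] = ("no_standard_curve",)

    def efficiency(assay: str) -> float:
        return curves[assay].efficiency if assay in curves else 2.0

    def wells(sample: str, assay: str, role: str) -> list[CtRecord]:
        return [
            r for r in records
            if r.sample_id == sample and r.assay == assay and r.role == role
        ]

    sample_ids = sorted(
        {r.sample_id for r in records if r.role == "sample" and r.sample_id != calibrator_id}
    )
    results: list[FoldChange] = []
    for assay in assays:
        if assay == reference_assay:
            continue
        cal_t = wells(calibrator_id, assay, "calibrator") or wells(calibrator_id, assay, "sample")
        cal_r = wells(calibrator_id, reference_assay, "calibrator") or wells(
            calibrator_id, reference_assay, "sample"
        )
        if not cal_t or not cal_r:
            raise ValueError(
                f"calibrator {calibrator_id!r} has no wells for {assay} and/or "
                f"{reference_assay}"
            )
        e_t, e_r = efficiency(assay), efficiency(reference_assay)
        for sample in sample_ids:
            s_t = wells(sample, assay, "sample")
            s_r = wells(sample, reference_assay, "sample")
            if not s_t or not s_r:
                continue
            flags = set(eff_flags[assay]) | set(eff_flags[reference_assay])
            if mode == "ratio_of_means":
                aggs = [aggregate_ct(w, qc_sd_cutoff) for w in (s_t, cal_t, s_r, cal_r)]
                for a in aggs:
                    flags.update(a.flags)
                ratio = efficiency_corrected_ratio(
                    aggs[0].mean, aggs[1].mean, aggs[2].mean, aggs[3].mean, e_t, e_r
                )
            else:
                per_exp = []
                exps = sorted(
                    {r.experiment_id for r in s_t}
                    & {r.experiment_id for r in s_r}
                    & {r.experiment_id for r in cal_t}
                    & {r.experiment_id for r in cal_r}
                )
                if not exps:
                    raise ValueError(
                        f"{sample}/{assay}: no experiment shared by all four Ct terms"
                    )
                for exp in exps:
                    sel = lambda ws: [r for r in ws if r.experiment_id == exp]
                    aggs = [
                        aggregate_ct(sel(w), qc_sd_cutoff)
                        for w in (s_t, cal_t, s_r, cal_r)
                    ]
                    for a in aggs:
                        flags.update(a.flags)
                    per_exp.append(
                        efficiency_corrected_ratio(
                            aggs[0].mean, aggs[1].mean, aggs[2].mean, aggs[3].mean,
                            e_t, e_r,
                        )
                    )
                ratio = float(np.mean(per_exp))
            results.append(
                FoldChange(
                    sample_id=sample,
                    assay=assay,
                    ratio=float(ratio),
                    log2_ratio=float(np.log2(ratio)),
                    state=classify_fold_change(ratio, thresholds),
                    qc_flags=tuple(sorted(flags)),
                )
            )
    return results, curves
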