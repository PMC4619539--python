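"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator plants recurrent amplicons at configurable loci and cohort
fractions, scatters passenger amplicons at the scale observed in primary
melanoma genomes (a handful of sub-megabase amplicons per genome), shifts
log-thickness by copy state, draws exponential event times with a
configurable hazard ratio between amplified and diploid patients, and
emits qPCR Ct tables through the generative inverse of the
efficiency-corrected ratio method:

    Ct = Ct_base - log_E(input quantity) + Gaussian(0, ct_sd)

where the input quantity is the true copy ratio (sample wells), 1
(calibrator wells), or the dilution factor (standard-curve wells).  With
ct_sd = 0 the full calling chain returns the planted ratios to machine
precision.

Copy states are allocated by exact quota (round(fraction x n) samples per
state after a seeded shuffle) so that small-cohort tests are deterministic;
``bernoulli=True`` switches to independent coin flips for power studies.
All randomness fans out from one seed through numpy's SeedSequence spawning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .copy_calling import CopyState, CopyThresholds, DEFAULT_THRESHOLDS
from .io import ClinicalRecord, CtRecord, GenomicInterval, SegmentRecord

CALIBRATOR_ID = "CALIBRATOR"


@dataclass(frozen=True)
class PlantedHotspot:
    """A recurrent amplicon to plant: locus plus cohort state fractions."""

    interval: GenomicInterval
    fraction_amplified: float
    fraction_gained: float = 0.0

    def __post_init__(self):
        if not (0 <= self.fraction_amplified <= 1 and 0 <= self.fraction_gained <= 1):
            raise ValueError("state fractions must lie in [0, 1]")
        if self.fraction_amplified + self.fraction_gained > 1:
            raise ValueError("fraction_amplified + fraction_gained must be <= 1")


@dataclass(frozen=True)
class CohortSpec:
    """Genome layout and alteration rates of a simulated cohort.

    Passenger defaults echo the scale reported for primary melanoma genomes:
    about 5.7 amplicons per genome with a mean size near 0.47 Mb (log-normal
    with log-mean ln(350 kb) and log-sd 0.8).  ``probe_spacing`` mimics the
    resolution of an 8x60K CGH array (~50 kb); all alteration boundaries
    snap to the probe grid.
    """

    n_samples: int
    chrom_lengths: Mapping[str, int]
    planted_hotspots: Sequence[PlantedHotspot] = ()
    passenger_rate: float = 5.7
    passenger_log_mean: float = math.log(350_000.0)
    passenger_log_sd: float = 0.8
    probe_spacing: int = 50_000
    seed: int = 0
    bernoulli: bool = False

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.passenger_rate < 0:
            raise ValueError("passenger_rate must be >= 0")
        for h in self.planted_hotspots:
            length = self.chrom_lengths.get(h.interval.chrom)
            if length is None or h.interval.end > length or h.interval.start < 1:
                raise ValueError(
                    f"planted hotspot {h.interval} outside chrom_lengths"
                )


@dataclass(frozen=True)
class ThicknessModel:
    """Log-normal Breslow thickness, shifted additively on the log scale by
    copy state at the index locus.

    Defaults reproduce the ordering of published group medians
    (diploid ~2.3 mm < gained ~3.0 mm < amplified ~4.7 mm).
    """

    base_log_mean: float = math.log(2.3)
    base_log_sd: float = 0.35
    shift_gain: float = math.log(3.0 / 2.3)
    shift_amp: float = math.log(4.7 / 2.3)

    def __post_init__(self):
        if self.base_log_sd <= 0:
            raise ValueError("base_log_sd must be > 0")


@dataclass(frozen=True)
class SurvivalModel:
    """Exponential event times with hazard baseline_rate * hr_amp^(amplified),
    administratively censored at ``censor_time`` months.

    The same structure drives both endpoints; overall-survival times use the
    baseline rate scaled by ``os_rate_scale``.
    """

    baseline_rate: float = 0.010  # events per month; diploid median ~69 months
    hr_amp: float = 1.0 / 0.30   # amplified patients progress earlier
    censor_time: float = 120.0
    os_rate_scale: float = 0.5

    def __post_init__(self):
        if self.baseline_rate <= 0 or self.hr_amp <= 0 or self.os_rate_scale <= 0:
            raise ValueError("rates and hazard ratios must be > 0")
        if self.censor_time <= 0:
            raise ValueError("censor_time must be > 0")


@dataclass(frozen=True)
class QpcrNoiseModel:
    """Efficiency and noise structure of the simulated qPCR experiment.

    Defaults mirror the published design: two independent experiments of
    three internal replicates each, with a 10-fold calibrator dilution
    series for the standard curves.
    """

    e_target: float = 1.95
    e_ref: float = 2.0
    ct_base_target: float = 26.0
    ct_base_ref: float = 25.0
    ct_sd: float = 0.15
    n_internal_replicates: int = 3
    n_experiments: int = 2
    dilution_series: Sequence[float] = (1.0, 0.1, 0.01, 0.001)

    def __post_init__(self):
        for e in (self.e_target, self.e_ref):
            if not (1.0 < e <= 2.0):
                raise ValueError(f"efficiency {e} outside (1, 2]")
        if self.ct_sd < 0:
            raise ValueError("ct_sd must be >= 0")
        if self.n_internal_replicates < 1 or self.n_experiments < 1:
            raise ValueError("replicate counts must be >= 1")


# ---------------------------------------------------------------------------
# helpers


def _state_bands(
    thresholds: CopyThresholds, margin: float
) -> dict[CopyState, tuple[float, float]]:
    """Fold-change band per state, shrunk by ``margin`` at every boundary."""
    t = thresholds
    return {
        CopyState.DIPLOID: (t.hemizygous + margin, t.gain - margin),
        CopyState.GAIN: (t.gain + margin, t.amplification - margin),
        CopyState.AMPLIFICATION: (t.amplification + margin, 2.0 * t.amplification),
    }


def _draw_ratio(rng: np.random.Generator, band: tuple[float, float]) -> float:
    """Uniform on the log2 scale inside a fold-change band."""
    lo, hi = math.log2(band[0]), math.log2(band[1])
    return float(2.0 ** rng.uniform(lo, hi))


def _snap_down(pos: int, spacing: int) -> int:
    return max(1, ((pos - 1) // spacing) * spacing + 1)


def _snap_up(pos: int, spacing: int, chrom_len: int) -> int:
    snapped = ((pos + spacing - 1) // spacing) * spacing
    return min(snapped, chrom_len)


def _allocate_states(
    rng: np.random.Generator, n: int, hotspot: PlantedHotspot, bernoulli: bool
) -> list[CopyState]:
    if bernoulli:
        u = rng.random(n)
        states = []
        for ui in u:
            if ui < hotspot.fraction_amplified:
                states.append(CopyState.AMPLIFICATION)
            elif ui < hotspot.fraction_amplified + hotspot.fraction_gained:
                states.append(CopyState.GAIN)
            else:
                states.append(CopyState.DIPLOID)
        return states
    n_amp = round(hotspot.fraction_amplified * n)
    n_gain = round(hotspot.fraction_gained * n)
    order = rng.permutation(n)
    states = [CopyState.DIPLOID] * n
    for idx in order[:n_amp]:
        states[idx] = CopyState.AMPLIFICATION
    for idx in order[n_amp : n_amp + n_gain]:
        states[idx] = CopyState.GAIN
    return states


# ---------------------------------------------------------------------------
# cohort simulation


def simulate_cohort(
    spec: CohortSpec,
    thickness: ThicknessModel | None = None,
    survival: SurvivalModel | None = None,
    thresholds: CopyThresholds = DEFAULT_THRESHOLDS,
    guard_margin: float = 0.05,
) -> tuple[list[SegmentRecord], list[ClinicalRecord], pd.DataFrame]:
    """Simulate segment tables, clinical records, and a truth table.

    Each sample's segments tile its chromosomes without overlap.  Samples
    amplified at a planted hotspot carry an amplified segment containing the
    planted interval, extended outward by random whole-probe offsets; per
    side, the smallest extension among amplified samples is forced to zero,
    so the common overlap of the amplified set equals the planted interval
    exactly.  Passenger amplicons are placed uniformly, away from planted
    loci so that planted truth stays unambiguous.  Log2 ratios are drawn
    uniformly (log2 scale) inside state bands shrunk by ``guard_margin``
    (fold-change units), guaranteeing caller-truth agreement.

    The clinical model keys on the copy state at the *first* planted hotspot
    (the index locus).  Thickness is log-normal with state shifts; event
    times are exponential with hazard ``baseline_rate * hr_amp^(amplified)``,
    administratively censored at ``censor_time``.

    Returns (segments, clinical records, truth table) where the truth table
    has one row per sample x planted hotspot with the planted state and the
    exact fold-change ratio used for that sample at that locus.
    """
    thickness = thickness or ThicknessModel()
    survival = survival or SurvivalModel()
    ss = np.random.SeedSequence(spec.seed)
    (
        rng_states,
        rng_extend,
        rng_passenger,
        rng_log2,
        rng_thickness,
        rng_survival,
    ) = (np.random.default_rng(child) for child in ss.spawn(6))

    n = spec.n_samples
    sample_ids = [f"S{i+1:03d}" for i in range(n)]
    bands = _state_bands(thresholds, guard_margin)
    chroms = list(spec.chrom_lengths)
    chrom_lens = np.array([spec.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_probs = chrom_lens / chrom_lens.sum()

    # --- plant recurrent hotspots ------------------------------------------
    truth_rows = []
    # per sample, per chrom: list of (interval, ratio)
    alterations: dict[str, dict[str, list[tuple[GenomicInterval, float]]]] = {
        s: {c: [] for c in chroms} for s in sample_ids
    }
    # forbidden zones for passengers: planted loci +/- max extension
    max_ext_probes = 20
    forbidden: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    for h_idx, hotspot in enumerate(spec.planted_hotspots):
        states = _allocate_states(rng_states, n, hotspot, spec.bernoulli)
        chrom = hotspot.interval.chrom
        chrom_len = spec.chrom_lengths[chrom]
        pad = (max_ext_probes + 1) * spec.probe_spacing
        forbidden[chrom].append(
            (max(1, hotspot.interval.start - pad), min(chrom_len, hotspot.interval.end + pad))
        )
        altered = [i for i, st in enumerate(states) if st != CopyState.DIPLOID]
        amp_idx = [i for i, st in enumerate(states) if st == CopyState.AMPLIFICATION]
        left_ext = {i: int(rng_extend.integers(0, max_ext_probes + 1)) for i in altered}
        right_ext = {i: int(rng_extend.integers(0, max_ext_probes + 1)) for i in altered}
        if amp_idx:
            # force the minimal common overlap of the amplified set to equal
            # the planted interval exactly
            lmin = min(left_ext[i] for i in amp_idx)
            rmin = min(right_ext[i] for i in amp_idx)
            for i in amp_idx:
                left_ext[i] -= lmin
                right_ext[i] -= rmin
        for i, state in enumerate(states):
            ratio = (
                _draw_ratio(rng_log2, bands[state])
                if state != CopyState.DIPLOID
                else _draw_ratio(rng_log2, bands[CopyState.DIPLOID])
            )
            truth_rows.append(
                {
                    "sample_id": sample_ids[i],
                    "hotspot_id": f"H{h_idx+1}",
                    "chrom": chrom,
                    "start": hotspot.interval.start,
                    "end": hotspot.interval.end,
                    "state": CopyState(state).name,
                    "ratio": ratio,
                }
            )
            if state == CopyState.DIPLOID:
                continue
            start = max(1, hotspot.interval.start - left_ext[i] * spec.probe_spacing)
            end = min(chrom_len, hotspot.interval.end + right_ext[i] * spec.probe_spacing)
            alterations[sample_ids[i]][chrom].append(
                (GenomicInterval(chrom, start, end), ratio)
            )

    # --- passenger amplicons ----------------------------------------------
    for s in sample_ids:
        n_pass = int(rng_passenger.poisson(spec.passenger_rate))
        placed = 0
        attempts = 0
        while placed < n_pass and attempts < 50 * max(n_pass, 1):
            attempts += 1
            ci = int(rng_passenger.choice(len(chroms), p=chrom_probs))
            chrom = chroms[ci]
            chrom_len = spec.chrom_lengths[chrom]
            length = float(
                rng_passenger.lognormal(spec.passenger_log_mean, spec.passenger_log_sd)
            )
            length = int(max(2 * spec.probe_spacing, min(length, chrom_len // 2)))
            start_raw = int(rng_passenger.integers(1, max(2, chrom_len - length)))
            start = _snap_down(start_raw, spec.probe_spacing)
            end = _snap_up(start + length, spec.probe_spacing, chrom_len)
            iv = GenomicInterval(chrom, start, end)
            clash = any(
                iv.start <= fe and fs <= iv.end for fs, fe in forbidden[chrom]
            ) or any(
                iv.overlaps(other) for other, _ in alterations[s][chrom]
            )
            if clash:
                continue
            ratio = _draw_ratio(rng_log2, bands[CopyState.AMPLIFICATION])
            alterations[s][chrom].append((iv, ratio))
            placed += 1

    # --- tile segments -----------------------------------------------------
    segments: list[SegmentRecord] = []
    for s in sample_ids:
        for chrom in chroms:
            chrom_len = spec.chrom_lengths[chrom]
            ivs = sorted(alterations[s][chrom], key=lambda t: t[0].start)
            cursor = 1
            for iv, ratio in ivs:
                if iv.start - cursor == 1:
                    # absorb 1-bp gaps (cannot form a segment) into the amplicon
                    iv = GenomicInterval(chrom, cursor, iv.end)
                elif iv.start > cursor:
                    segments.append(
                        SegmentRecord(
                            s, chrom, cursor, iv.start - 1,
                            math.log2(_draw_ratio(rng_log2, bands[CopyState.DIPLOID])),
                        )
                    )
                segments.append(SegmentRecord(s, chrom, iv.start, iv.end, math.log2(ratio)))
                cursor = iv.end + 1
            if chrom_len - cursor >= 1:
                segments.append(
                    SegmentRecord(
                        s, chrom, cursor, chrom_len,
                        math.log2(_draw_ratio(rng_log2, bands[CopyState.DIPLOID])),
                    )
                )
            elif chrom_len == cursor and segments and segments[-1].sample_id == s:
                last = segments.pop()
                segments.append(
                    SegmentRecord(s, chrom, last.start, chrom_len, last.log2_ratio)
                )

    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "hotspot_id", "chrom", "start", "end", "state", "ratio"],
    )

    # --- clinical covariates keyed on the index locus ----------------------
    if len(spec.planted_hotspots) > 0:
        index_state = {
            row["sample_id"]: CopyState[row["state"]]
            for _, row in truth[truth["hotspot_id"] == "H1"].iterrows()
        }
    else:
        index_state = {s: CopyState.DIPLOID for s in sample_ids}

    clinical: list[ClinicalRecord] = []
    for s in sample_ids:
        state = index_state[s]
        shift = (
            thickness.shift_amp
            if state == CopyState.AMPLIFICATION
            else thickness.shift_gain if state == CopyState.GAIN else 0.0
        )
        thick = float(
            np.exp(rng_thickness.normal(thickness.base_log_mean + shift, thickness.base_log_sd))
        )
        amp = state == CopyState.AMPLIFICATION
        rate_mfs = survival.baseline_rate * (survival.hr_amp if amp else 1.0)
        rate_os = rate_mfs * survival.os_rate_scale
        raw_mfs = float(rng_survival.exponential(1.0 / rate_mfs))
        raw_os = float(rng_survival.exponential(1.0 / rate_os))
        mfs_time = min(raw_mfs, survival.censor_time)
        os_time = min(raw_os, survival.censor_time)
        clinical.append(
            ClinicalRecord(
                sample_id=s,
                thickness_mm=thick,
                mfs_time=mfs_time,
                mfs_event=int(raw_mfs <= survival.censor_time),
                os_time=os_time,
                os_event=int(raw_os <= survival.censor_time),
            )
        )

    segments.sort(key=lambda r: (r.sample_id, r.chrom, r.start))
    return segments, clinical, truth


# ---------------------------------------------------------------------------
# qPCR simulation


def simulate_qpcr(
    ratios: Mapping[str, float],
    noise: QpcrNoiseModel | None = None,
    seed: int = 0,
    target_assay: str = "NTRK1",
    reference_assay: str = "LAMA1",
    calibrator_id: str = CALIBRATOR_ID,
) -> list[CtRecord]:
    """Generate a Ct table from true target copy ratios per sample.

    Emits sample wells for the target and reference assays (reference ratio
    is 1 in every sample), calibrator wells (input quantity 1), and a
    dilution series for each assay, each in ``n_experiments`` experiments of
    ``n_internal_replicates`` wells.
    """
    noise = noise or QpcrNoiseModel()
    for s, r in ratios.items():
        if not r > 0:
            raise ValueError(f"copy ratio for {s} must be > 0, got {r}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    records: list[CtRecord] = []

    assay_params = {
        target_assay: (noise.e_target, noise.ct_base_target),
        reference_assay: (noise.e_ref, noise.ct_base_ref),
    }

    def emit(sample_id, assay, role, quantity, dilution_factor=None):
        e, base = assay_params[assay]
        for exp in range(1, noise.n_experiments + 1):
            for rep in range(1, noise.n_internal_replicates + 1):
                ct = base - math.log(quantity, e)
                if noise.ct_sd > 0:
                    ct += float(rng.normal(0.0, noise.ct_sd))
                records.append(
                    CtRecord(
                        sample_id=sample_id,
                        assay=assay,
                        role=role,
                        dilution_factor=dilution_factor,
                        experiment_id=f"E{exp}",
                        replicate_id=f"R{rep}" if role != "dilution" else f"R{rep}",
                        ct=ct,
                    )
                )

    for sample_id in sorted(ratios):
        emit(sample_id, target_assay, "sample", float(ratios[sample_id]))
        emit(sample_id, reference_assay, "sample", 1.0)
    emit(calibrator_id, target_assay, "calibrator", 1.0)
    emit(calibrator_id, reference_assay, "calibrator", 1.0)
    for assay in (target_assay, reference_assay):
        for d in noise.dilution_series:
            emit(calibrator_id, assay, "dilution", float(d), dilution_factor=float(d))
    return records
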