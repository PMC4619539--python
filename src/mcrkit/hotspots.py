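"""Minimal common regions (MCRs) of recurrent amplification.

A support profile counts, at every base of a chromosome, how many distinct
samples carry an amplified interval covering that base (sweep line over
interval endpoints).  Within each maximal run of support >= ``min_support``,
the hotspot is the locally-maximal-depth plateau: the sub-region shared by
the largest set of samples, which is by construction the minimal common
overlap of that set.  Hotspots longer than ``max_length`` (default 2.5 Mb)
are discarded.  Defaults realize the published rule: overlap shared by at
least three samples, maximum length 2.5 Mb.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .copy_calling import CopyState, call_segment_state
from .io import GeneRecord, GenomicInterval, SegmentRecord, chrom_sort_key


@dataclass(frozen=True)
class SupportProfile:
    """Piecewise-constant amplification support along one chromosome.

    ``starts[i]..ends[i]`` (1-based inclusive, contiguity not required) is an
    elementary interval on which exactly ``samples[i]`` (a frozenset of
    sample ids) carry amplified coverage; ``depth[i] == len(samples[i])``.
    Zero-support gaps are not stored.
    """

    chrom: str
    starts: tuple[int, ...]
    ends: tuple[int, ...]
    samples: tuple[frozenset, ...]

    def __post_init__(self):
        if not (len(self.starts) == len(self.ends) == len(self.samples)):
            raise ValueError("ragged support profile")

    @property
    def depth(self) -> tuple[int, ...]:
        return tuple(len(s) for s in self.samples)

    @property
    def breakpoints(self) -> tuple[int, ...]:
        bp = []
        for s, e in zip(self.starts, self.ends):
            bp.append(s)
            bp.append(e + 1)
        return tuple(sorted(set(bp)))

    def depth_at(self, pos: int) -> int:
        """Number of distinct supporting samples covering ``pos``."""
        for s, e, smp in zip(self.starts, self.ends, self.samples):
            if s <= pos <= e:
                return len(smp)
        return 0


@dataclass(frozen=True)
class Hotspot:
    """A minimal common region of amplification and its supporting samples.

    ``support`` is the number of distinct samples covering each base of the
    hotspot (the plateau depth); ``supporting_samples`` is the set of samples
    whose amplified intervals contain the *entire* hotspot.  The two agree
    unless equal-depth plateaus with different sample sets were merged.
    """

    interval: GenomicInterval
    support: int
    supporting_samples: frozenset
    genes: tuple[str, ...] = ()

    @property
    def length_bp(self) -> int:
        return self.interval.length


def amplified_intervals(
    segments: Sequence[SegmentRecord],
    state_caller: Callable[[float], CopyState] = call_segment_state,
    merge_gap: int = 0,
    include_gain: bool = False,
    target_state: CopyState = CopyState.AMPLIFICATION,
) -> dict[str, list[GenomicInterval]]:
    """Extract each sample's amplified intervals from its segment calls.

    Adjacent qualifying segments of one sample are merged when the gap
    between them is <= ``merge_gap`` bases (abutting segments have gap 0).
    ``include_gain=True`` lets GAIN segments qualify alongside the target
    state; ``target_state`` can be repointed (e.g. at deletions).
    """
    wanted = {target_state}
    if include_gain:
        wanted.add(CopyState.GAIN)
    by_sample: dict[str, list[GenomicInterval]] = defaultdict(list)
    for seg in segments:
        if state_caller(seg.log2_ratio) in wanted:
            by_sample[seg.sample_id].append(seg.interval)
    merged: dict[str, list[GenomicInterval]] = {}
    for sample, ivs in by_sample.items():
        ivs.sort(key=lambda iv: (chrom_sort_key(iv.chrom), iv.start))
        out: list[GenomicInterval] = []
        for iv in ivs:
            if (
                out
                and out[-1].chrom == iv.chrom
                and iv.start - out[-1].end - 1 <= merge_gap
            ):
                out[-1] = GenomicInterval(
                    iv.chrom, out[-1].start, max(out[-1].end, iv.end)
                )
            else:
                out.append(iv)
        merged[sample] = out
    return merged


def build_support_profile(
    amplicons_by_sample: Mapping[str, Iterable[GenomicInterval]],
    chrom: str,
) -> SupportProfile:
    """Sweep-line support profile of one chromosome.

    Depth at every base equals the number of *distinct* samples whose
    amplified intervals cover it; overlapping intervals of one sample count
    once.
    """
    events: list[tuple[int, int, str]] = []  # (position, +1/-1, sample)
    for sample, intervals in amplicons_by_sample.items():
        for iv in intervals:
            if iv.chrom != chrom:
                raise ValueError(f"interval on {iv.chrom}, profile is for {chrom}")
            events.append((iv.start, +1, sample))
            events.append((iv.end + 1, -1, sample))
    if not events:
        return SupportProfile(chrom, (), (), ())
    positions = sorted({p for p, _, _ in events})
    by_pos: dict[int, list[tuple[int, str]]] = defaultdict(list)
    for p, delta, sample in events:
        by_pos[p].append((delta, sample))
    counts: dict[str, int] = defaultdict(int)
    starts, ends, sample_sets = [], [], []
    for i, pos in enumerate(positions):
        for delta, sample in by_pos[pos]:
            counts[sample] += delta
        active = frozenset(s for s, c in counts.items() if c > 0)
        if not active:
            continue
        seg_end = (positions[i + 1] - 1) if i + 1 < len(positions) else pos
        starts.append(pos)
        ends.append(seg_end)
        sample_sets.append(active)
    # merge adjacent elementary intervals with identical sample sets
    m_starts, m_ends, m_sets = [], [], []
    for s, e, smp in zip(starts, ends, sample_sets):
        if m_sets and m_sets[-1] == smp and m_ends[-1] + 1 == s:
            m_ends[-1] = e
        else:
            m_starts.append(s)
            m_ends.append(e)
            m_sets.append(smp)
    return SupportProfile(chrom, tuple(m_starts), tuple(m_ends), tuple(m_sets))


MAX_HOTSPOT_LENGTH = 2_500_000
MIN_HOTSPOT_SUPPORT = 3


def find_hotspots(
    profile: SupportProfile,
    min_support: int = MIN_HOTSPOT_SUPPORT,
    max_length: int = MAX_HOTSPOT_LENGTH,
) -> list[Hotspot]:
    """Extract minimal common regions from a support profile.

    Within each maximal contiguous run of depth >= ``min_support``, plateaus
    of locally maximal depth become hotspots (adjacent equal-depth plateaus
    merged); hotspots longer than ``max_length`` bp are discarded.  Output is
    sorted by (chrom, start).
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    # contiguous runs of qualifying elementary intervals
    runs: list[list[int]] = []
    current: list[int] = []
    for i, smp in enumerate(profile.samples):
        if len(smp) >= min_support:
            if current and profile.ends[current[-1]] + 1 != profile.starts[i]:
                runs.append(current)
                current = []
            current.append(i)
        else:
            if current:
                runs.append(current)
                current = []
    if current:
        runs.append(current)

    hotspots: list[Hotspot] = []
    for run in runs:
        depths = [len(profile.samples[i]) for i in run]
        # plateaus: maximal stretches of equal depth within the run
        plateaus: list[tuple[int, int]] = []  # (run-index start, run-index end)
        j = 0
        while j < len(run):
            k = j
            while k + 1 < len(run) and depths[k + 1] == depths[j]:
                k += 1
            plateaus.append((j, k))
            j = k + 1
        for p_idx, (a, b) in enumerate(plateaus):
            d = depths[a]
            left = depths[plateaus[p_idx - 1][0]] if p_idx > 0 else -1
            right = depths[plateaus[p_idx + 1][0]] if p_idx + 1 < len(plateaus) else -1
            if d > left and d > right:
                idxs = run[a : b + 1]
                interval = GenomicInterval(
                    profile.chrom, profile.starts[idxs[0]], profile.ends[idxs[-1]]
                )
                covering = frozenset.intersection(
                    *(profile.samples[i] for i in idxs)
                )
                if interval.length <= max_length:
                    hotspots.append(Hotspot(interval, d, covering))
    hotspots.sort(key=lambda h: (chrom_sort_key(h.interval.chrom), h.interval.start))
    return hotspots


def find_hotspots_multi(
    amplicons_by_sample: Mapping[str, Iterable[GenomicInterval]],
    min_support: int = MIN_HOTSPOT_SUPPORT,
    max_length: int = MAX_HOTSPOT_LENGTH,
) -> list[Hotspot]:
    """Convenience wrapper: build profiles and find hotspots on every
    chromosome present in the amplicon map."""
    chroms = sorted(
        {iv.chrom for ivs in amplicons_by_sample.values() for iv in ivs},
        key=chrom_sort_key,
    )
    out: list[Hotspot] = []
    for chrom in chroms:
        per_chrom = {
            s: [iv for iv in ivs if iv.chrom == chrom]
            for s, ivs in amplicons_by_sample.items()
        }
        profile = build_support_profile(per_chrom, chrom)
        out.extend(find_hotspots(profile, min_support, max_length))
    return out


def annotate_genes(
    hotspots: Sequence[Hotspot],
    genes: Sequence[GeneRecord],
) -> tuple[list[Hotspot], int]:
    """Assign genes overlapping each hotspot by >=1 bp.

    Returns annotated hotspots (gene ids ordered by genomic position) and
    the cohort-level count of unique genes across all hotspots.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        # tree uses half-open coords; inclusive [start, end] -> [start, end+1)
        trees[g.chrom].addi(g.start, g.end + 1, g)
    annotated: list[Hotspot] = []
    unique: set[str] = set()
    for h in hotspots:
        hits = trees[h.interval.chrom].overlap(h.interval.start, h.interval.end + 1)
        hit_genes = sorted((iv.data for iv in hits), key=lambda g: (g.start, g.gene_id))
        ids = tuple(g.gene_id for g in hit_genes)
        unique.update(ids)
        annotated.append(replace(h, genes=ids))
    return annotated, len(unique)


@dataclass(frozen=True)
class ContrastResult:
    """Mann-Whitney comparison of a covariate between two copy-state groups."""

    group1: CopyState
    group2: CopyState
    n1: int
    n2: int
    u_statistic: float
    p_value: float
    median1: float
    median2: float
    range1: tuple[float, float]
    range2: tuple[float, float]
    computable: bool = True
    method: str = ""


def _mannwhitney(x: np.ndarray, y: np.ndarray, alternative: str) -> tuple[float, float, str]:
    # exact null when both groups small and untied; normal approximation with
    # tie correction otherwise
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if len(x) <= 8 and len(y) <= 8 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue), method


def associate_with_covariate(
    states_by_sample: Mapping[str, CopyState],
    covariate_by_sample: Mapping[str, float],
    contrasts: Sequence[tuple[CopyState, CopyState]] = (
        (CopyState.GAIN, CopyState.DIPLOID),
        (CopyState.AMPLIFICATION, CopyState.DIPLOID),
    ),
    alternative: str = "two-sided",
) -> list[ContrastResult]:
    """Mann-Whitney association of a covariate (e.g. tumor thickness in mm)
    with copy state at one locus.

    An empty group yields a flagged, not-computable result rather than an
    exception.
    """
    results = []
    for g1, g2 in contrasts:
        x = np.array(
            [covariate_by_sample[s] for s, st in states_by_sample.items()
             if st == g1 and s in covariate_by_sample],
            dtype=float,
        )
        y = np.array(
            [covariate_by_sample[s] for s, st in states_by_sample.items()
             if st == g2 and s in covariate_by_sample],
            dtype=float,
        )
        if len(x) == 0 or len(y) == 0:
            results.append(
                ContrastResult(
                    g1, g2, len(x), len(y), float("nan"), float("nan"),
                    float(np.median(x)) if len(x) else float("nan"),
                    float(np.median(y)) if len(y) else float("nan"),
                    (float(x.min()), float(x.max())) if len(x) else (float("nan"),) * 2,
                    (float(y.min()), float(y.max())) if len(y) else (float("nan"),) * 2,
                    computable=False,
                    method="empty_group",
                )
            )
            continue
        u, p, method = _mannwhitney(x, y, alternative)
        results.append(
            ContrastResult(
                g1, g2, len(x), len(y), u, p,
                float(np.median(x)), float(np.median(y)),
                (float(x.min()), float(x.max())),
                (float(y.min()), float(y.max())),
                computable=True,
                method=method,
            )
        )
    return results
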