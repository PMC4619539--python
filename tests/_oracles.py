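"""Independent brute-force oracles used to check the fast implementations.

These deliberately share no code with the package: per-base counting with
numpy arrays, hand rank enumeration, closed-form survival curves.
"""

from __future__ import annotations

import numpy as np


def per_base_depth(amplicons_by_sample, chrom_length: int) -> np.ndarray:
    """depth[b] = number of distinct samples covering base b (1-based)."""
    depth = np.zeros(chrom_length + 2, dtype=int)
    for intervals in amplicons_by_sample.values():
        covered = np.zeros(chrom_length + 2, dtype=bool)
        for iv in intervals:
            covered[iv.start : iv.end + 1] = True
        depth += covered
    return depth


def brute_force_hotspots(amplicons_by_sample, chrom_length, min_support, max_length):
    """Per-base realization of the MCR rule.

    Returns [(start, end, depth)] for every locally-maximal-depth plateau
    inside each maximal run of depth >= min_support, dropping plateaus
    longer than max_length.
    """
    depth = per_base_depth(amplicons_by_sample, chrom_length)
    out = []
    b = 1
    while b <= chrom_length:
        if depth[b] < min_support:
            b += 1
            continue
        run_start = b
        while b <= chrom_length and depth[b] >= min_support:
            b += 1
        run_end = b - 1
        # plateaus of constant depth within the run
        plateaus = []
        p = run_start
        while p <= run_end:
            q = p
            while q + 1 <= run_end and depth[q + 1] == depth[p]:
                q += 1
            plateaus.append((p, q, depth[p]))
            p = q + 1
        for i, (ps, pe, d) in enumerate(plateaus):
            left = plateaus[i - 1][2] if i > 0 else -1
            right = plateaus[i + 1][2] if i + 1 < len(plateaus) else -1
            if d > left and d > right and (pe - ps + 1) <= max_length:
                out.append((ps, pe, d))
    return out


def no_censor_survival(times) -> list[tuple[float, float]]:
    """Empirical survival S(t) = #(T > t)/n at each distinct event time."""
    t = np.sort(np.asarray(times, dtype=float))
    n = len(t)
    return [(float(ti), float(np.sum(t > ti)) / n) for ti in np.unique(t)]


def midranks(values) -> np.ndarray:
    """Average ranks with ties, by enumeration."""
    v = np.asarray(values, dtype=float)
    ranks = np.empty(len(v))
    order = np.argsort(v, kind="stable")
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks
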