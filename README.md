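# mcrkit

Copy-number hotspot discovery and validation for tumor cohorts: minimal
common regions (MCRs) of recurrent amplification from segmented aCGH
profiles, efficiency-corrected genomic qPCR copy calling, cross-platform
concordance, and association of copy state with tumor thickness and
survival. It is written for cancer-genomics analysts who have per-sample
segment tables (not raw arrays) and TaqMan-style Ct exports, and want the
whole chain — hotspot detection, validation and outcome analysis — as one
reproducible, scriptable pipeline.

## The methods

**MCR hotspots.** Each sample's amplified intervals (segments whose mean
log2 ratio converts to fold change > 1.75) enter a sweep line that counts,
at every base, the number of distinct samples covering it. Within each
maximal run of support ≥ `min_support` (default 3), the hotspot is the
plateau of locally maximal depth — the region shared by the largest
supporting set, which is by construction the minimal common overlap of that
set. Hotspots longer than `max_length` (default 2.5 Mb) are discarded.
Genes overlapping a hotspot by ≥ 1 bp are annotated from BED/GFF3.

**qPCR copy calling.** Per-assay PCR efficiency is fitted from calibrator
dilution series, *E* = 10^(−1/slope) of the Ct vs log₁₀(dilution)
regression. The copy-number ratio of a target gene over a reference gene
(default *LAMA1*), each relative to a diploid calibrator, is the
efficiency-corrected (Pfaffl) ratio

&nbsp;&nbsp;ratio = *E*ₜ^(Ctᶜᵃˡₜ − Ctˢₜ) / *E*ᵣ^(Ctᶜᵃˡᵣ − Ctˢᵣ)

with ΔΔCt (both efficiencies fixed at 2) as the special case. Fold changes
classify into five copy states: homozygous deletion (< 0.5), hemizygous
deletion (0.5–0.75), diploid (0.75–1.25), gain (1.25–1.75), amplification
(> 1.75).

**Outcome analysis.** Direction concordance and Pearson's *r* compare qPCR
log2 fold changes with aCGH log2 ratios per sample; Mann–Whitney U tests
copy state against Breslow thickness; Kaplan–Meier curves, the log-rank
test, and the Mantel–Haenszel hazard ratio HR = (O₁/E₁)/(O₂/E₂) with
95% CI exp(ln HR ± 1.96·√(1/E₁ + 1/E₂)) contrast amplified against diploid
patients (a Cox HR is available as a sensitivity option).

**Synthetic cohorts.** A first-class generator plants recurrent amplicons
at chosen loci and cohort fractions, adds passenger amplicons at the scale
seen in primary melanoma genomes, shifts log-thickness by copy state, draws
exponential survival with a configurable hazard ratio, and emits Ct tables
through the generative inverse of the Pfaffl method — so the whole pipeline
is testable end-to-end with no external data.

## Worked example

```python
from mcrkit import (CohortSpec, PlantedHotspot, GenomicInterval, simulate_cohort,
                    simulate_qpcr, QpcrNoiseModel, compute_fold_changes,
                    amplified_intervals, logrank_and_hr, CopyState)
from mcrkit.hotspots import find_hotspots_multi, associate_with_covariate

locus = GenomicInterval("chr1", 156_826_196, 157_106_439)   # ~280 kb on 1q23.1
spec = CohortSpec(n_samples=64, chrom_lengths={"chr1": 249_000_000},
                  planted_hotspots=[PlantedHotspot(locus, fraction_amplified=0.5,
                                                   fraction_gained=0.2)],
                  seed=1)
segments, clinical, truth = simulate_cohort(spec)

hotspots = find_hotspots_multi(amplified_intervals(segments), min_support=3)
h = next(x for x in hotspots if x.interval.contains(locus) or locus.contains(x.interval))
print(f"hotspot {h.interval.chrom}:{h.interval.start}-{h.interval.end} "
      f"({h.length_bp/1000:.0f} kb), support {h.support}/{spec.n_samples}")

ct = simulate_qpcr(dict(zip(truth.sample_id, truth.ratio)), QpcrNoiseModel(), seed=1)
calls, curves = compute_fold_changes(ct)
state = {f.sample_id: f.state for f in calls if f.assay == "NTRK1"}
print(f"amplified by qPCR: {sum(s == CopyState.AMPLIFICATION for s in state.values())}/64")

thick = {c.sample_id: c.thickness_mm for c in clinical}
gain_res, amp_res = associate_with_covariate(state, thick)
print(f"thickness, amplified vs diploid: median {amp_res.median1:.1f} vs "
      f"{amp_res.median2:.1f} mm (Mann-Whitney p = {amp_res.p_value:.2g})")

cdict = {c.sample_id: c for c in clinical}
amp = [s for s, st in state.items() if st == CopyState.AMPLIFICATION]
dip = [s for s, st in state.items() if st == CopyState.DIPLOID]
cmp = logrank_and_hr(
    [cdict[s].mfs_time for s in dip], [cdict[s].mfs_event for s in dip],
    [cdict[s].mfs_time for s in amp], [cdict[s].mfs_event for s in amp])
print(f"metastasis-free survival, diploid vs amplified: HR = {cmp.hr:.2f} "
      f"(95% CI {cmp.hr_ci95[0]:.2f}-{cmp.hr_ci95[1]:.2f})")
```

prints

```
hotspot chr1:156826196-157106439 (280 kb), support 32/64
amplified by qPCR: 34/64
thickness, amplified vs diploid: median 4.9 vs 2.0 mm (Mann-Whitney p = 3.6e-08)
metastasis-free survival, diploid vs amplified: HR = 0.29 (95% CI 0.16-0.52)
```

The planted 280-kb amplicon is recovered at its exact boundaries with the
planted support of 32/64; the qPCR caller labels 34/64 samples amplified
(the planted 32 plus two gains pushed over the threshold by measurement
noise); amplified tumors are markedly thicker; and diploid patients carry
about 0.3 times the metastasis hazard of amplified patients, the hazard
ratio the generator was configured to produce.

The same stages run from the shell — `mcrkit simulate | qpcr-call |
hotspots | concord | survival`, each with `--config config.yaml --out DIR
--seed N` — reading and writing plain TSV with a provenance header.

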