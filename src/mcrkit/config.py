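"""Pipeline configuration: plain YAML, every threshold surfaced.

Nothing analytic is hard-coded in the CLI: copy-state boundaries, the MCR
support/length rule, merge gap, concordance epsilon, reference gene and
calibrator ids, and the simulation models all live here.  Outputs embed a
short hash of the resolved configuration in their commented header.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .copy_calling import CopyThresholds
from .io import GenomicInterval, config_hash
from .synthetic import (
    CohortSpec,
    PlantedHotspot,
    QpcrNoiseModel,
    SurvivalModel,
    ThicknessModel,
)

DEFAULT_CHROM_LENGTHS = {
    "chr1": 249_000_000,
    "chr6": 171_000_000,
    "chr8": 146_000_000,
}


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "out"
    inputs: dict = field(default_factory=dict)
    thresholds: CopyThresholds = field(default_factory=CopyThresholds)
    min_support: int = 3
    max_length: int = 2_500_000
    merge_gap: int = 0
    include_gain: bool = False
    reference_assay: str = "LAMA1"
    target_assay: str = "NTRK1"
    calibrator_id: str = "CALIBRATOR"
    qpcr_mode: str = "ratio_of_means"
    qc_sd_cutoff: float = 0.5
    epsilon: float = 0.0
    concordance_locus: GenomicInterval | None = None
    simulate: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if self.max_length < 1:
            raise ValueError("max_length must be >= 1")
        if self.merge_gap < 0 or self.epsilon < 0:
            raise ValueError("merge_gap and epsilon must be >= 0")

    @property
    def hash(self) -> str:
        return config_hash(self.raw) if self.raw else config_hash(self._safe_dict())

    def _safe_dict(self) -> dict:
        return {
            k: str(v)
            for k, v in self.__dict__.items()
            if k not in {"raw", "simulate", "inputs"}
        }

    def header_params(self, **extra) -> dict:
        params = {"config": self.hash, "seed": self.seed}
        params.update(extra)
        return params

    def cohort_spec(self) -> CohortSpec:
        sim = dict(self.simulate)
        hotspots = [
            PlantedHotspot(
                GenomicInterval(h["chrom"], int(h["start"]), int(h["end"])),
                float(h.get("fraction_amplified", 0.0)),
                float(h.get("fraction_gained", 0.0)),
            )
            for h in sim.get("planted_hotspots", [])
        ]
        return CohortSpec(
            n_samples=int(sim.get("n_samples", 64)),
            chrom_lengths=sim.get("chrom_lengths", DEFAULT_CHROM_LENGTHS),
            planted_hotspots=hotspots,
            passenger_rate=float(sim.get("passenger_rate", 5.7)),
            probe_spacing=int(sim.get("probe_spacing", 50_000)),
            seed=int(sim.get("seed", self.seed)),
            bernoulli=bool(sim.get("bernoulli", False)),
        )

    def thickness_model(self) -> ThicknessModel:
        kw = self.simulate.get("thickness", {})
        return ThicknessModel(**kw) if kw else ThicknessModel()

    def survival_model(self) -> SurvivalModel:
        kw = self.simulate.get("survival", {})
        return SurvivalModel(**kw) if kw else SurvivalModel()

    def qpcr_noise_model(self) -> QpcrNoiseModel:
        kw = dict(self.simulate.get("qpcr", {}))
        if "dilution_series" in kw:
            kw["dilution_series"] = tuple(float(d) for d in kw["dilution_series"])
        return QpcrNoiseModel(**kw) if kw else QpcrNoiseModel()


def load_config(path) -> PipelineConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    thr = raw.get("thresholds", {})
    hot = raw.get("hotspots", {})
    qpcr = raw.get("qpcr", {})
    conc = raw.get("concordance", {})
    locus = conc.get("locus")
    return PipelineConfig(
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", "out")),
        inputs=raw.get("inputs", {}),
        thresholds=CopyThresholds(
            homozygous=float(thr.get("homozygous", 0.5)),
            hemizygous=float(thr.get("hemizygous", 0.75)),
            gain=float(thr.get("gain", 1.25)),
            amplification=float(thr.get("amplification", 1.75)),
        ),
        min_support=int(hot.get("min_support", 3)),
        max_length=int(hot.get("max_length", 2_500_000)),
        merge_gap=int(hot.get("merge_gap", 0)),
        include_gain=bool(hot.get("include_gain", False)),
        reference_assay=str(qpcr.get("reference_assay", "LAMA1")),
        target_assay=str(qpcr.get("target_assay", conc.get("target_assay", "NTRK1"))),
        calibrator_id=str(qpcr.get("calibrator_id", "CALIBRATOR")),
        qpcr_mode=str(qpcr.get("mode", "ratio_of_means")),
        qc_sd_cutoff=float(qpcr.get("qc_sd_cutoff", 0.5)),
        epsilon=float(conc.get("epsilon", 0.0)),
        concordance_locus=(
            GenomicInterval(locus["chrom"], int(locus["start"]), int(locus["end"]))
            if locus
            else None
        ),
        simulate=raw.get("simulate", {}),
        raw=raw,
    )
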