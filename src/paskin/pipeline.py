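"""End-to-end per-subject analysis and cohort orchestration.

Stage order per subject: spectral unmixing → slice-wise segmentation →
analysis-depth determination and 3-layer partition → skeleton morphometry
(layers 1–2) → oximetry averaging → melanin quantification.  One failed
subject is recorded and skipped; it never aborts a cohort run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import morphometry as mm
from .io import (
    FEATURE_COLUMNS,
    MultiwavelengthScan,
    validate_feature_table,
)
from .segmentation import SegmentationParams, segment_slices
from .spectra import ChromophoreSpectra, default_phantom_spectra
from .unmixing import compute_so2, melanin_channel, vessel_channel

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "SubjectReport", "analyze_subject", "cohort_feature_table"]

_ALLOWED_KEYS = {
    "segmenter",
    "seg_sigma_vox",
    "seg_k_low",
    "seg_k_high",
    "seg_min_component_voxels",
    "depth_floor_frac",
    "depth_override_slices",
    "melanin_depth_band_um",
    "so2_mask_to_vessels",
    "so2_floor_frac",
    "direction_window",
    "prune_len",
    "alpha",
    "seed",
}


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline knobs (YAML-loadable; unknown keys rejected)."""

    segmenter: str = "baseline"
    seg_sigma_vox: float = 1.0
    seg_k_low: float = 3.5
    seg_k_high: float = 5.0
    seg_min_component_voxels: int = 27
    depth_floor_frac: float = 0.1
    depth_override_slices: int | None = None
    melanin_depth_band_um: tuple[float, float] = (0.0, 300.0)
    so2_mask_to_vessels: bool = True
    #: voxels whose 586 nm amplitude is below this fraction of the volume
    #: maximum are excluded from SO2 averaging: under amplitude noise the
    #: ratio at near-zero denominators is meaningless, and the segmentation
    #: mask can extend a voxel past the true vessel boundary
    so2_floor_frac: float = 0.15
    direction_window: int = 3
    prune_len: int = 3
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineConfig":
        unknown = set(cfg) - _ALLOWED_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}; allowed: {sorted(_ALLOWED_KEYS)}")
        if "melanin_depth_band_um" in cfg:
            cfg = {**cfg, "melanin_depth_band_um": tuple(cfg["melanin_depth_band_um"])}
        return cls(**cfg)

    def seg_params(self) -> SegmentationParams:
        return SegmentationParams(
            sigma_vox=self.seg_sigma_vox,
            k_low=self.seg_k_low,
            k_high=self.seg_k_high,
            min_component_voxels=self.seg_min_component_voxels,
        )

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class SubjectReport:
    """Everything the pipeline measured for one subject."""

    subject_id: str
    age: float | None
    analysis_depth: int
    layer_boundaries: tuple[int, int, int, int]
    features: list[mm.VesselFeatures] = field(default_factory=list)
    mean_so2: dict[int, float | None] = field(default_factory=dict)
    melanin_volume_voxels: int = 0
    melanin_volume_um3: float | None = None
    error: str | None = None

    def to_rows(self) -> list[dict]:
        rows = []
        for f in self.features:
            rows.append(
                {
                    "subject_id": self.subject_id,
                    "age": self.age,
                    "layer": f.layer,
                    "mean_thickness_um": f.mean_thickness_um,
                    "total_volume_voxels": f.total_volume_voxels,
                    "branch_count": f.branch_count,
                    "mean_so2": self.mean_so2.get(f.layer),
                    "melanin_volume_voxels": self.melanin_volume_voxels,
                }
            )
        return rows

    def to_json(self) -> str:
        d = {
            "subject_id": self.subject_id,
            "age": self.age,
            "analysis_depth_slices": self.analysis_depth,
            "layer_boundaries": list(self.layer_boundaries),
            "layers": [
                {
                    "layer": f.layer,
                    "mean_thickness_um": f.mean_thickness_um,
                    "total_volume_voxels": f.total_volume_voxels,
                    "total_volume_um3": f.total_volume_um3,
                    "branch_count": f.branch_count,
                    "mean_so2": self.mean_so2.get(f.layer),
                }
                for f in self.features
            ],
            "melanin_volume_voxels": self.melanin_volume_voxels,
            "melanin_volume_um3": self.melanin_volume_um3,
            "error": self.error,
        }
        return json.dumps(d, indent=1)


def analyze_subject(
    scan: MultiwavelengthScan,
    config: PipelineConfig | None = None,
    spectra: ChromophoreSpectra | None = None,
    age: float | None = None,
    truth_vessel_mask: np.ndarray | None = None,
    truth_melanin_mask: np.ndarray | None = None,
    compute_radii: bool = True,
) -> SubjectReport:
    """Run the full analysis on one scan.

    ``config.segmenter='truth'`` bypasses segmentation with the supplied
    ground-truth masks.  SO2 features are simply missing (None) when the
    586 nm volume is absent; vessel features only need 575 and 650 nm.
    """
    config = config or PipelineConfig()
    spectra = spectra or default_phantom_spectra()
    spacing = scan.spacing_um

    vessels = segment_slices(
        vessel_channel(scan),
        spacing,
        backend=config.segmenter,
        params=config.seg_params(),
        source="vessel",
        truth_mask=truth_vessel_mask,
    )
    depth = mm.determine_analysis_depth(
        vessels.mask, floor_frac=config.depth_floor_frac, override=config.depth_override_slices
    )
    partition = mm.partition_layers(depth)
    skel = mm.skeletonize(vessels, window=config.direction_window, compute_radii=compute_radii)
    features = mm.extract_vessel_features(
        vessels, partition, skel=skel, prune_len=config.prune_len
    )

    mean_so2: dict[int, float | None] = {1: None, 2: None}
    if scan.has_wavelength(586.0) and scan.has_wavelength(575.0):
        so2map = compute_so2(scan, spectra, denominator_floor_frac=config.so2_floor_frac)
        mask = vessels.mask if config.so2_mask_to_vessels else None
        mean_so2 = mm.mean_so2_per_layer(so2map, mask, partition)
    else:
        logger.info("subject %s: 586 nm missing, SO2 features left missing", scan.subject_id)

    melanin_voxels, melanin_um3 = 0, 0.0
    if scan.has_wavelength(650.0):
        mel_struct = segment_slices(
            melanin_channel(scan, depth_band_um=config.melanin_depth_band_um),
            spacing,
            backend=config.segmenter,
            params=config.seg_params(),
            source="melanin",
            truth_mask=truth_melanin_mask,
        )
        melanin_voxels, melanin_um3 = mm.melanin_volume(mel_struct.mask, spacing)

    return SubjectReport(
        subject_id=scan.subject_id,
        age=age,
        analysis_depth=depth,
        layer_boundaries=partition.boundaries,
        features=features,
        mean_so2=mean_so2,
        melanin_volume_voxels=melanin_voxels,
        melanin_volume_um3=melanin_um3,
    )


def cohort_feature_table(reports: list[SubjectReport]) -> pd.DataFrame:
    """Stack per-subject reports into the canonical feature table."""
    rows: list[dict] = []
    for rep in reports:
        if rep.error is not None:
            logger.warning("subject %s skipped: %s", rep.subject_id, rep.error)
            continue
        rows.extend(rep.to_rows())
    table = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    return validate_feature_table(table)
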