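"""Parameter schema for the full analysis pipeline.

A :class:`ParameterSet` collects one block per pipeline stage (camera,
detection, fit, filter, tracking, mobility, clustering, batch).  It
serializes losslessly to a plain JSON document and back; unknown keys are
rejected so that a results file always parses against the schema it was
written with.  Every numeric parameter carries its unit in the key name
(``max_link_distance_nm``, ``frame_interval_s``, ...).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

_STRICT = ConfigDict(extra="forbid", validate_assignment=True)


class CameraParams(BaseModel):
    model_config = _STRICT
    pixel_size_nm: float = Field(100.0, gt=0)
    frame_interval_s: float = Field(0.05, gt=0)
    offset_adu: float = 100.0
    e_per_adu: float = Field(0.5, gt=0)
    qe: float = Field(1.0, gt=0, le=1.0)


class DetectionParams(BaseModel):
    model_config = _STRICT
    dog_sigma_small_px: float = Field(1.0, gt=0)
    dog_sigma_large_px: float = Field(2.5, gt=0)
    threshold_factor: float = Field(4.0, gt=0)
    roi_halfsize_px: int = Field(3, ge=1)

    @model_validator(mode="after")
    def _ordered_sigmas(self) -> "DetectionParams":
        if self.dog_sigma_small_px >= self.dog_sigma_large_px:
            raise ValueError("dog_sigma_small_px must be < dog_sigma_large_px")
        return self


class FitParams(BaseModel):
    model_config = _STRICT
    initial_sigma_px: float = Field(1.3, gt=0)
    max_iterations: int = Field(30, ge=1)
    tol: float = Field(1e-6, gt=0)
    use_scmos: bool = True


class FilterParams(BaseModel):
    """Quality filter on fitted localizations; ``None`` bounds are open."""

    model_config = _STRICT
    sigma_min_nm: float = Field(80.0, ge=0)
    sigma_max_nm: Optional[float] = 250.0
    photons_min: float = Field(100.0, ge=0)
    photons_max: Optional[float] = None
    precision_max_nm: Optional[float] = 50.0

    @model_validator(mode="after")
    def _ordered(self) -> "FilterParams":
        if self.sigma_max_nm is not None and self.sigma_min_nm > self.sigma_max_nm:
            raise ValueError("sigma range inverted")
        if self.photons_max is not None and self.photons_min > self.photons_max:
            raise ValueError("photon range inverted")
        return self


class TrackingParams(BaseModel):
    model_config = _STRICT
    max_link_distance_nm: float = Field(500.0, gt=0)
    max_gap_frames: int = Field(1, ge=0)
    max_gap_distance_nm: float = Field(500.0, gt=0)
    min_track_length: int = Field(8, ge=2)


class MobilityParams(BaseModel):
    model_config = _STRICT
    n_fit_points: int = Field(4, ge=2)
    max_lag: int = Field(10, ge=2)
    adj_r2_min: float = Field(0.7, ge=0.0, le=1.0)
    threshold_logD: float = -2.0
    max_components: Literal[1, 2] = 2


class DBSCANParams(BaseModel):
    model_config = _STRICT
    eps_nm: float = Field(50.0, gt=0)
    min_pts: int = Field(5, ge=1)


class VoronoiParams(BaseModel):
    model_config = _STRICT
    density_factor: float = Field(2.0, gt=0)
    min_pts: int = Field(5, ge=1)


class NASTICParams(BaseModel):
    model_config = _STRICT
    radius_factor: float = Field(1.2, gt=0)
    min_tracks: int = Field(3, ge=1)
    temporal_window_s: Optional[float] = None


class ClusteringParams(BaseModel):
    model_config = _STRICT
    algorithm: Literal["nastic", "dbscan", "voronoi"] = "nastic"
    input_mode: Literal["all_localizations", "track_centroids", "tracks"] = "tracks"
    dbscan: DBSCANParams = Field(default_factory=DBSCANParams)
    voronoi: VoronoiParams = Field(default_factory=VoronoiParams)
    nastic: NASTICParams = Field(default_factory=NASTICParams)


class BatchParams(BaseModel):
    model_config = _STRICT
    run_tracking: bool = True
    run_mobility: bool = True
    run_clustering: bool = True


class ParameterSet(BaseModel):
    """Frozen set of all stage parameters; the unit of FAIR provenance."""

    model_config = _STRICT
    schema_version: int = 1
    camera: CameraParams = Field(default_factory=CameraParams)
    detection: DetectionParams = Field(default_factory=DetectionParams)
    fit: FitParams = Field(default_factory=FitParams)
    filter: FilterParams = Field(default_factory=FilterParams)
    tracking: TrackingParams = Field(default_factory=TrackingParams)
    mobility: MobilityParams = Field(default_factory=MobilityParams)
    clustering: ClusteringParams = Field(default_factory=ClusteringParams)
    batch: BatchParams = Field(default_factory=BatchParams)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.model_dump(mode="json"), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ParameterSet":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.model_validate(json.loads(text))

    def digest(self) -> str:
        """Short stable hash of the canonical JSON form, used in logs."""
        canon = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
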