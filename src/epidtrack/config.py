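"""Run configuration: one YAML file drives the whole analysis.

Every knob has a documented default; a run writes the resolved config
next to its outputs so re-running it is bit-identical.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .epid_io import GeometryConfig, RawDialect
from .marker_detection import MarkerFilterRules
from .preprocessing import LoGParams

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Resolved configuration of an analysis run.

    Attributes
    ----------
    geometry
        Imager geometry (SDD, pixel pitch at isocenter, frame rate,
        matrix size).
    log_params, k_sigma
        LoG filter scale/truncation and the robust threshold multiplier
        (median + k_sigma x MAD-scale) for marker candidates.
    edge_threshold
        Field-edge grey cut; None means per-frame half-maximum estimate.
    min_field_area_px2
        Smallest region accepted as the radiation field.
    marker_rules
        Blob plausibility filters (area, elongation, edge margin,
        completeness requirement).
    connectivity
        4 or 8 for candidate labeling.
    interior_erosion_px
        Candidate masks are restricted to the aperture interior eroded
        by this many pixels, suppressing the LoG ridge along the field
        edge itself.
    dialect
        Raw-file layout for ``.raw`` input.
    """

    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    log_params: LoGParams = field(default_factory=LoGParams)
    k_sigma: float = 5.0
    edge_threshold: float | None = None
    min_field_area_px2: float = 400.0
    marker_rules: MarkerFilterRules = field(default_factory=MarkerFilterRules)
    connectivity: int = 8
    interior_erosion_px: int = 8
    dialect: RawDialect = field(default_factory=RawDialect)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "geometry": asdict(self.geometry),
            "preprocessing": {
                "sigma_px": self.log_params.sigma_px,
                "kernel_halfwidth_px": self.log_params.kernel_halfwidth_px,
                "k_sigma": self.k_sigma,
            },
            "aperture": {
                "edge_threshold": self.edge_threshold,
                "min_field_area_px2": self.min_field_area_px2,
            },
            "markers": {
                **asdict(self.marker_rules),
                "connectivity": self.connectivity,
                "interior_erosion_px": self.interior_erosion_px,
            },
            "io": asdict(self.dialect),
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        geometry = GeometryConfig(**doc.get("geometry", {}))
        pre = doc.get("preprocessing", {})
        log_params = LoGParams(
            sigma_px=pre.get("sigma_px", 2.0),
            kernel_halfwidth_px=pre.get("kernel_halfwidth_px"),
        )
        ap = doc.get("aperture", {})
        mk = dict(doc.get("markers", {}))
        connectivity = mk.pop("connectivity", 8)
        erosion = mk.pop("interior_erosion_px", 8)
        return cls(
            geometry=geometry,
            log_params=log_params,
            k_sigma=pre.get("k_sigma", 5.0),
            edge_threshold=ap.get("edge_threshold"),
            min_field_area_px2=ap.get("min_field_area_px2", 400.0),
            marker_rules=MarkerFilterRules(**mk),
            connectivity=connectivity,
            interior_erosion_px=erosion,
            dialect=RawDialect(**doc.get("io", {})),
        )
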