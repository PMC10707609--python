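"""Run configuration: one JSON document driving a full reproducible run."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .geometry import GeometryParams
from .segmentation import SegmentationParams
from .synthetic import CohortSimSpec


@dataclass
class StatsParams:
    loa_multiplier: float = 1.96
    max_discrepancy_mm: float = 1.0
    reference_method: str = "rgb"
    significance_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.loa_multiplier <= 0:
            raise ValueError("loa_multiplier must be positive")
        if self.max_discrepancy_mm <= 0:
            raise ValueError("max_discrepancy_mm must be positive")


@dataclass
class RunConfig:
    """Everything a batch run needs, serializable to a single JSON file.

    ``seed`` drives the synthetic cohort; ``n_eyes`` is the number of
    eyes simulated (and rendered) when no input images are supplied.
    """

    seed: int = 0
    n_eyes: int = 50
    out_dir: str = "mrdeye_run"
    noise_sd: float = 8.0
    px_per_mm: float = 12.0
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    geometry: GeometryParams = field(default_factory=GeometryParams)
    stats: StatsParams = field(default_factory=StatsParams)
    cohort: CohortSimSpec = field(default_factory=CohortSimSpec)

    def to_json(self, path=None) -> str:
        doc = json.dumps(asdict(self), indent=2, default=_jsonable)
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        p = Path(source)
        doc = json.loads(p.read_text() if p.exists() else source)
        return cls(
            seed=doc.get("seed", 0),
            n_eyes=doc.get("n_eyes", 50),
            out_dir=doc.get("out_dir", "mrdeye_run"),
            noise_sd=doc.get("noise_sd", 8.0),
            px_per_mm=doc.get("px_per_mm", 12.0),
            segmentation=SegmentationParams(**_tupled(doc.get("segmentation", {}), ("fixed_thresholds",))),
            geometry=GeometryParams(**_tupled(doc.get("geometry", {}), ("dot_area_window_px",))),
            stats=StatsParams(**doc.get("stats", {})),
            cohort=CohortSimSpec(**doc.get("cohort", {})),
        )


def _jsonable(obj):
    if isinstance(obj, (set, tuple)):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _tupled(d: dict, keys) -> dict:
    out = dict(d)
    for k in keys:
        if out.get(k) is not None:
            out[k] = tuple(out[k])
    return out
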