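"""Pipeline configuration: every threshold the stages apply, in one place.

The defaults are the analysis constants of the reference procedure:
10 mm surface / 6 mm volume smoothing, vertex p < 0.001 with 30 mm^2
minimum cluster size, 3 mm seed spheres, 1000 bootstrap iterations at a
99% CI, voxel p < 0.001 / cluster p < 0.05 random-field correction, 10
discarded volumes, and cohort sizes of 11 patients vs 24 (thickness) /
15 (functional) controls.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # seeds
    seed: int = 0
    # surface stage
    fwhm_surface: float = 10.0
    p_thresh: float = 0.001
    min_area: float = 30.0
    # covariance stage
    ci_level: float = 0.99
    iters: int = 1000
    alpha_patient: float = 0.05
    bonferroni: bool = False
    # functional stage
    discard: int = 10
    smooth_fwhm: float = 6.0
    roi_radius: float = 3.0
    voxel_alpha: float = 0.001
    cluster_alpha: float = 0.05
    mask_alpha: float = 0.001
    mask_rule: str = "union"            # union | intersection
    correction: str = "rft"             # rft | permutation
    global_signal: bool = True
    n_perm: int = 1000
    motion_exclusion_mm: float = 2.5
    motion_exclusion_deg: float = 2.5
    # synthetic cohort
    n_patients: int = 11
    n_controls_thickness: int = 24
    n_controls_fc: int = 15
    n_volumes: int = 240
    tr: float = 2.25
    grid: tuple[int, int, int] = (12, 14, 12)
    mesh_subdivisions: int = 3
    mesh_radius: float = 50.0
    acuity_scale: str = "decimal"       # decimal | logmar

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        probs = ["p_thresh", "ci_level", "alpha_patient", "voxel_alpha",
                 "cluster_alpha", "mask_alpha"]
        for name in probs:
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.min_area < 0:
            raise ValueError("min_area must be >= 0")
        if self.iters < 100:
            raise ValueError("iters must be >= 100")
        if self.mask_rule not in ("union", "intersection"):
            raise ValueError("mask_rule must be union|intersection")
        if self.correction not in ("rft", "permutation"):
            raise ValueError("correction must be rft|permutation")
        if self.acuity_scale not in ("decimal", "logmar"):
            raise ValueError("acuity_scale must be decimal|logmar")
        for name in ("fwhm_surface", "smooth_fwhm", "roi_radius", "tr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["grid"] = list(self.grid)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "grid" in d:
            d["grid"] = tuple(d["grid"])
        return cls(**d)
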