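"""Pipeline configuration: defaults, YAML loading, validation.

All tunable thresholds of the quantification stages live here so that a
single config object (or YAML file) fully determines a run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

#: Fixed binarization threshold for marker channels, on a [0, 1] intensity
#: scale.  Applied with a strict ``>`` comparison.
DEFAULT_MARKER_THRESHOLD = 0.30

#: Minimum connected-component area (pixels, inclusive) for an object to be
#: counted as a nucleus / cell.
DEFAULT_MIN_NUCLEUS_AREA = 15

#: Component area (pixels, inclusive) at which a labeled object is classified
#: as a clone rather than a single cell.
DEFAULT_CLONE_MIN_AREA = 2000

#: Density threshold above which a tissue pixel counts as collagen-positive
#: in the unmixed trichrome-blue plane.
DEFAULT_COLLAGEN_THRESHOLD = 0.15

#: Total optical density below which a pixel is treated as blank background
#: (excluded from the tissue mask).
DEFAULT_TISSUE_OD_MIN = 0.05

#: Gaussian smoothing scale (pixels) of the structure tensor.
DEFAULT_FIBER_SIGMA = 2.0

#: Minimum structure-tensor coherence for a pixel's orientation to enter the
#: alignment statistics.  Pixels where differently-oriented fibers cross or
#: blur carry intermediate coherence and contaminate the angle sample; on
#: resolvable-fiber phantoms a cutoff of 0.65 removes the resulting
#: systematic alignment bias while retaining ample angle samples.
DEFAULT_COHERENCE_MIN = 0.65

#: Box edge lengths (pixels) used for box-counting.
DEFAULT_BOX_SIZES = (2, 4, 8, 16, 32, 64)


@dataclass
class PipelineConfig:
    """Bundle of every tunable parameter consumed by the pipeline stages."""

    stain_matrix: str = "builtin"  # "builtin" or a path to a YAML matrix file
    marker_threshold: float = DEFAULT_MARKER_THRESHOLD
    min_nucleus_area: int = DEFAULT_MIN_NUCLEUS_AREA
    clone_min_area: int = DEFAULT_CLONE_MIN_AREA
    collagen_threshold: float = DEFAULT_COLLAGEN_THRESHOLD
    tissue_od_min: float = DEFAULT_TISSUE_OD_MIN
    fiber_sigma: float = DEFAULT_FIBER_SIGMA
    coherence_min: float = DEFAULT_COHERENCE_MIN
    box_sizes: Sequence[int] = DEFAULT_BOX_SIZES
    posthoc: str = "tukey"  # "tukey" or "bh"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.marker_threshold < 1.0:
            raise ValueError("marker_threshold must lie in (0, 1)")
        if self.min_nucleus_area < 1:
            raise ValueError("min_nucleus_area must be >= 1")
        if self.clone_min_area < 1:
            raise ValueError("clone_min_area must be >= 1")
        if self.posthoc not in ("tukey", "bh"):
            raise ValueError(f"posthoc must be 'tukey' or 'bh', got {self.posthoc!r}")
        self.box_sizes = tuple(int(s) for s in self.box_sizes)
        if any(s < 1 for s in self.box_sizes):
            raise ValueError("box sizes must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a YAML mapping; unknown keys are rejected."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["box_sizes"] = list(self.box_sizes)
        return d
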