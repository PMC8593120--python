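"""Run configuration: schema-validated parameter blocks (YAML/JSON).

Every block mirrors one stage of the pipeline; unknown keys are rejected
so typos fail loudly.  Units are fixed package-wide (nm, ps, kJ/mol, K)
and declared in the serialized form for the benefit of humans.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class EngineBlock(_Strict):
    dt: float = 0.02
    gamma: float = 1.0
    temperature: float = 310.0


class BuildBlock(_Strict):
    lipids_per_leaflet: int = 64
    tail_beads: int = 3
    area_per_lipid: float = 0.26
    separation: float = 1.2
    n_solvent: int = 0
    equilibration_steps: int = 2000
    com_halfwidth: float = 0.2        # membrane COM-z flat-bottom half width
    com_k: float = 1000.0


class CoordinateBlock(_Strict):
    radius: float = 1.2
    slice_thickness: float = 0.1
    n0: float = 2.0
    zeta: float = 0.025
    eps_r: float = 0.05
    cap_h: float = 0.25
    center_mode: str = "dynamic"
    target_flat_xi: float = 0.2


class SamplingBlock(_Strict):
    n_windows: int = 19
    xi_range: Tuple[float, float] = (0.2, 1.0)
    kappa: float = 5000.0
    steps_per_window: int = 4000
    equil_fraction: float = 0.2
    pull_rate: float = 0.005          # xi per ps
    pull_rate_backward: Optional[float] = None   # default: 0.4 * pull_rate
    pull_kappa: float = 5000.0
    sequential: bool = False          # chain windows from each other


class WhamBlock(_Strict):
    bin_width: float = 0.008
    tol: float = 1e-8
    max_iter: int = 100_000
    n_boot: int = 50
    flat_window: Tuple[float, float] = (0.1, 0.4)
    stalk_window: Tuple[float, float] = (0.8, 1.05)


class KineticsBlock(_Strict):
    xi_flat_core: float = 0.4
    xi_stalk_core: float = 0.8


class AnalysisBlock(_Strict):
    stalk_r: Tuple[float, float] = (0.0, 1.0)
    stalk_z: Tuple[float, float] = (-1.5, 1.5)
    ref_r: Tuple[float, float] = (3.0, 4.0)
    ref_z: Tuple[float, float] = (-1.5, 1.5)
    r_max: float = 2.0
    dr: float = 0.1
    dz: float = 0.1


class RunConfig(_Strict):
    seed: int = 0
    units: str = "nm ps kJ/mol K"
    engine: EngineBlock = Field(default_factory=EngineBlock)
    build: BuildBlock = Field(default_factory=BuildBlock)
    coordinate: CoordinateBlock = Field(default_factory=CoordinateBlock)
    sampling: SamplingBlock = Field(default_factory=SamplingBlock)
    wham: WhamBlock = Field(default_factory=WhamBlock)
    kinetics: KineticsBlock = Field(default_factory=KineticsBlock)
    analysis: AnalysisBlock = Field(default_factory=AnalysisBlock)


def load_config(path: Optional[str] = None) -> RunConfig:
    if path is None:
        return RunConfig()
    text = Path(path).read_text(encoding="utf-8")
    data = (json.loads(text) if str(path).endswith(".json")
            else yaml.safe_load(text)) or {}
    return RunConfig.model_validate(data)


def dump_config(cfg: RunConfig, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False),
                    encoding="utf-8")
    return path
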