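"""Run configuration: every tunable of the pipeline in one flat record.

Defaults are the method's standard values: erosion radius r_s = 6,
tubularity scales {2, 4, 6}, maxima tolerance tau = 10, N = 20 particles,
direction concentration kappa = 3, step size d = 3, scale variance
zeta = 1, likelihood sensitivity K = 20, correlation threshold
c_min = 0.5, iteration limit L = 200, node density limit delta_9 = 4 and
grouping radius r_g = 2.  Configurations round-trip through flat YAML;
command-line flags override file values.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .seeds import SeedParams
from .soma import SomaParams
from .tracer import TracerParams

__all__ = ["PnrConfig", "load_config", "save_config"]


@dataclass
class PnrConfig:
    r_s: float = 6.0
    scales: tuple[float, ...] = (2.0, 4.0, 6.0)
    tau: float = 10.0
    n_particles: int = 20
    kappa: float = 3.0
    step: float = 3.0
    zeta: float = 1.0
    sensitivity: float = 20.0
    c_min: float = 0.5
    max_iters: int = 200
    density_limit: int = 4
    density_neighborhood: int = 9
    r_g: float = 2.0
    seed: int = 0
    voxel_aspect: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mean_shift_iterations: int = 5
    min_component: int = 3
    prune_single_terminals: bool = True

    def soma_params(self) -> SomaParams:
        return SomaParams(r_s=self.r_s)

    def seed_params(self) -> SeedParams:
        return SeedParams(scales=tuple(self.scales), tau=self.tau, c_min=self.c_min)

    def tracer_params(self) -> TracerParams:
        return TracerParams(
            n_particles=self.n_particles,
            kappa=self.kappa,
            step=self.step,
            zeta=self.zeta,
            sensitivity=self.sensitivity,
            c_min=self.c_min,
            max_iters=self.max_iters,
            density_limit=self.density_limit,
            density_neighborhood=self.density_neighborhood,
            sigma_max=max(self.scales) + 3.0 * self.zeta,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scales"] = list(self.scales)
        d["voxel_aspect"] = list(self.voxel_aspect)
        return d


def load_config(path: str | Path) -> PnrConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in PnrConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "scales" in data:
        data["scales"] = tuple(data["scales"])
    if "voxel_aspect" in data:
        data["voxel_aspect"] = tuple(data["voxel_aspect"])
    return PnrConfig(**data)


def save_config(config: PnrConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
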