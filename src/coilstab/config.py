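"""Pipeline configuration.

Every numeric constant of the analysis (cutoffs, pKa values, ladder,
analysis window, clustering and WHAM parameters) is a configurable
default here; call sites never hard-code them. Configs load from a
nested key/value YAML file; unknown keys are rejected by name so typos
cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .constants import DEFAULT_PKA, HYDROPHOBIC_SET


@dataclass
class Cutoffs:
    hbond_d: float = 3.5  # A, donor-acceptor
    hbond_a: float = 30.0  # deg, deviation from linearity at H
    salt_d: float = 4.0  # A
    hydroph_d: float = 7.0  # A, side-chain COM

    def __post_init__(self):
        for name in ("hbond_d", "hbond_a", "salt_d", "hydroph_d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cutoff {name} must be positive")


@dataclass
class LadderSpec:
    t_min: float = 303.15
    t_max: float = 809.57
    n: int = 64


@dataclass
class ClusterSpec:
    top_n: int = 400
    rms_cutoff: float = 3.0


@dataclass
class WhamSpec:
    e_bins: int = 200
    x_bins: int = 50
    y_bins: int = 50
    tol: float = 1e-7
    max_iter: int = 10000
    t0: float = 303.15


@dataclass
class MeltingSpec:
    """Parameters forwarded to the synthetic replica generator."""

    tm_association: float = 454.52
    tm_helix: float = 556.59
    width_association: float = 20.0
    width_helix: float = 15.0
    frames_per_temperature: int = 200
    energy_scale_helix: float = 2.0
    energy_scale_contact: float = 4.0
    noise_sd: float = 5.0
    separation_distance: float = 25.0


@dataclass
class PipelineConfig:
    sequence: str | None = None
    r0: float = 6.1
    symmetry_order: int = 3
    registry_offset: int = 0
    ph_acidic: float = 1.6
    ph_neutral: float = 7.4
    hydrophobic_set: str = "".join(sorted(HYDROPHOBIC_SET))
    window_fraction: float = 0.5
    seed: int = 0
    cutoffs: Cutoffs = field(default_factory=Cutoffs)
    pka: dict = field(default_factory=lambda: dict(DEFAULT_PKA))
    ladder: LadderSpec = field(default_factory=LadderSpec)
    cluster: ClusterSpec = field(default_factory=ClusterSpec)
    wham: WhamSpec = field(default_factory=WhamSpec)
    melting: MeltingSpec = field(default_factory=MeltingSpec)

    def __post_init__(self):
        if not 0 < self.window_fraction <= 1:
            raise ValueError("window_fraction must be in (0, 1]")

    def require(self, key: str):
        value = getattr(self, key, None)
        if value is None:
            raise KeyError(f"missing required config key: {key!r}")
        return value

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _from_dict(cls, data, path="")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def _from_dict(dc_type, data: dict, path: str):
    if not isinstance(data, dict):
        raise ValueError(f"config section {path or '<root>'} must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(dc_type)}
    unknown = set(data) - set(fields)
    if unknown:
        where = f" in section {path!r}" if path else ""
        raise KeyError(f"unknown config key(s){where}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        sub = {
            "cutoffs": Cutoffs,
            "ladder": LadderSpec,
            "cluster": ClusterSpec,
            "wham": WhamSpec,
            "melting": MeltingSpec,
        }.get(name)
        if sub is not None:
            kwargs[name] = _from_dict(sub, value, path=f"{path}{name}." if path else name)
        else:
            kwargs[name] = value
        del ftype
    return dc_type(**kwargs)
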