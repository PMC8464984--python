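"""Run configuration: one serializable object holding every stage's knobs.

The configuration round-trips losslessly through YAML and rejects unknown
keys, so a typo in a config file fails loudly instead of silently falling
back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import ConfigurationError
from .simulate import SimConfig, SpeciesSpec

__all__ = ["RunConfig", "BurstParams", "MixtureParams", "BindingParams", "SaxsParams", "FcsParams"]

SCHEMA_VERSION = "1"


@dataclass
class BurstParams:
    bin_width: float = 1e-3
    threshold_k: float = 2.0
    threshold_clamp: tuple[int, int] = (3, 7)
    merge_gap: int = 0
    min_photons: int = 25
    s_window: tuple[float, float] = (0.3, 0.7)


@dataclass
class MixtureParams:
    n_components: int | str = 2
    n_init: int = 20
    tol: float = 1e-8
    sigma_floor: float = 0.01
    share_components: bool = True
    invert_states: bool = False  # True for label sites where low-E = state 2


@dataclass
class BindingParams:
    n_boot: int = 200
    model: str = "hyperbolic"
    receptor_conc: float | None = None
    enriched_state: str = "state1"
    ligand_label: str = ""


@dataclass
class SaxsParams:
    qrg_max: float = 1.3
    n_r: int = 101
    alpha: float | str = "auto"
    dmax_candidates: list[float] = field(default_factory=list)
    porod_divisor: float = 1.66
    mw_method: str = "porod"


@dataclass
class FcsParams:
    base_bin: float = 1e-5
    n_stages: int = 8
    m: int = 16
    decay_model: str = "exp"


@dataclass
class RunConfig:
    """Parameters for every pipeline stage plus workflow inputs."""

    schema_version: str = SCHEMA_VERSION
    seed: int = 0
    sim: SimConfig | None = None
    bursts: BurstParams = field(default_factory=BurstParams)
    mixture: MixtureParams = field(default_factory=MixtureParams)
    binding: BindingParams = field(default_factory=BindingParams)
    saxs: SaxsParams = field(default_factory=SaxsParams)
    fcs: FcsParams = field(default_factory=FcsParams)
    # workflow inputs
    inputs: list[str] = field(default_factory=list)  # data files, one per titration point
    concentrations: list[float] = field(default_factory=list)  # molar
    concentration_unit: str = "M"  # concentrations are always stored in molar

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"] = self.sim.to_dict()
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return _build(cls, data, "config")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        return cls.from_dict(data)


_TUPLE_FIELDS = {"threshold_clamp", "s_window", "background_rates"}


def _build(cls, data, where: str):
    """Instantiate a (possibly nested) dataclass, rejecting unknown keys."""
    if data is None:
        return cls()
    if not isinstance(data, dict):
        raise ConfigurationError(f"{where}: expected a mapping, got {type(data).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigurationError(f"{where}: unknown keys {sorted(unknown)}")
    kwargs = {}
    nested = {
        "sim": SimConfig,
        "bursts": BurstParams,
        "mixture": MixtureParams,
        "binding": BindingParams,
        "saxs": SaxsParams,
        "fcs": FcsParams,
    }
    for key, val in data.items():
        if key in nested and val is not None:
            if key == "sim":
                species = [
                    _build(SpeciesSpec, s, f"{where}.sim.species[{i}]")
                    for i, s in enumerate(val.get("species", []))
                ]
                rest = {k: v for k, v in val.items() if k != "species"}
                sim = _build(SimConfig, rest, f"{where}.sim")
                kwargs[key] = dataclasses.replace(sim, species=species)
            else:
                kwargs[key] = _build(nested[key], val, f"{where}.{key}")
        elif key in _TUPLE_FIELDS and isinstance(val, list):
            kwargs[key] = tuple(val)
        else:
            kwargs[key] = val
    obj = cls(**kwargs)
    for name in _TUPLE_FIELDS & set(fields):
        v = getattr(obj, name)
        if isinstance(v, list):
            object.__setattr__(obj, name, tuple(v))
    return obj
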