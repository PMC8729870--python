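"""Run configuration: one YAML file binding every stage's settings.

Unknown keys are rejected (typos should fail loudly, not silently fall back
to defaults), and a loaded config round-trips losslessly through the file.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cgan import CGANConfig
from .idif import PostprocessConfig
from .kinetics import KineticParams, PatlakConfig
from .phantom import PhantomSpec
from .registration import RegistrationConfig

_TUPLE_FIELDS = {"intervals"}


def _build(cls, data: dict):
    """Instantiate a dataclass from a dict, rejecting unknown keys and
    coercing YAML lists back to tuples where the field expects one."""
    if data is None:
        return cls()
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    defaults = {f.name: f.default for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if cls is PhantomSpec and key == "kinetics":
            value = {name: KineticParams(**p) for name, p in value.items()}
        elif isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        kwargs[key] = value
    return cls(**kwargs)


def _dump(obj) -> dict:
    d = dataclasses.asdict(obj)

    def conv(v):
        if isinstance(v, tuple):
            return [conv(x) for x in v]
        if isinstance(v, dict):
            return {k: conv(x) for k, x in v.items()}
        return v

    return {k: conv(v) for k, v in d.items()}


@dataclass
class RunConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    cgan: CGANConfig = field(default_factory=CGANConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    patlak: PatlakConfig = field(default_factory=PatlakConfig)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    seed: int = 0
    verbosity: str = "info"

    def to_dict(self) -> dict:
        return {
            "phantom": _dump(self.phantom),
            "cgan": _dump(self.cgan),
            "registration": _dump(self.registration),
            "patlak": _dump(self.patlak),
            "postprocess": _dump(self.postprocess),
            "seed": self.seed,
            "verbosity": self.verbosity,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        known = {"phantom", "cgan", "registration", "patlak", "postprocess",
                 "seed", "verbosity"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        return cls(
            phantom=_build(PhantomSpec, data.get("phantom")),
            cgan=_build(CGANConfig, data.get("cgan")),
            registration=_build(RegistrationConfig, data.get("registration")),
            patlak=_build(PatlakConfig, data.get("patlak")),
            postprocess=_build(PostprocessConfig, data.get("postprocess")),
            seed=int(data.get("seed", 0)),
            verbosity=str(data.get("verbosity", "info")),
        )

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
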