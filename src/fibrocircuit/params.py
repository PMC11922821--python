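"""Parameter set of the myofibroblast-macrophage growth-factor circuit.

The circuit couples two cell populations (fibroblasts/myofibroblasts F and
macrophages M, in cells) through two growth factors: c12, secreted by
myofibroblasts and sensed by macrophages, and c21, which drives myofibroblast
proliferation and is produced both paracrinely (by macrophages, rate beta21)
and autocrinely (by myofibroblasts themselves, rate beta11).
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path

#: Names of the 13 circuit constants, in canonical serialisation order.
PARAMETER_NAMES = (
    "beta12", "beta11", "beta21",
    "alpha12", "alpha21",
    "gamma", "k12", "k21",
    "lambda1", "lambda2", "mu1", "mu2", "K",
)


@dataclasses.dataclass(frozen=True)
class CircuitParameters:
    """The 13 constants of the four-variable circuit.

    Units: production rates beta* in molecules/cell/day; endocytosis rates
    alpha* in molecules/cell/day; degradation gamma in 1/day; binding
    affinities k* in molecules; maximal proliferation rates lambda* and death
    rates mu* in 1/day; fibroblast carrying capacity K in cells.
    """

    beta12: float
    beta11: float
    beta21: float
    alpha12: float
    alpha21: float
    gamma: float
    k12: float
    k21: float
    lambda1: float
    lambda2: float
    mu1: float
    mu2: float
    K: float

    def __post_init__(self) -> None:
        for name in PARAMETER_NAMES:
            value = getattr(self, name)
            if not (value > 0):
                raise ValueError(f"parameter {name} must be strictly positive, got {value!r}")

    @classmethod
    def wildtype(cls) -> "CircuitParameters":
        """Reference (wild-type) parameterisation of the circuit."""
        return cls(
            beta12=6_768.0,
            beta11=345_600.0,
            beta21=100_800.0,
            alpha12=1_353_600.0,
            alpha21=734_400.0,
            gamma=2.0,
            k12=3.6e9,
            k21=1.3e7,
            lambda1=1.08,
            lambda2=0.8,
            mu1=0.3,
            mu2=0.3,
            K=1e6,
        )

    def replace(self, **changes: float) -> "CircuitParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAMETER_NAMES}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "CircuitParameters":
        missing = set(PARAMETER_NAMES) - set(d)
        if missing:
            raise KeyError(f"missing circuit parameters: {sorted(missing)}")
        extra = set(d) - set(PARAMETER_NAMES)
        if extra:
            raise KeyError(f"unknown circuit parameters: {sorted(extra)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CircuitParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))


def load_wildtype_json() -> CircuitParameters:
    """Load the packaged wildtype.json (identical to :meth:`CircuitParameters.wildtype`)."""
    ref = resources.files("fibrocircuit").joinpath("data/wildtype.json")
    return CircuitParameters.from_dict(json.loads(ref.read_text()))


def perturb_parameter(params: CircuitParameters, name: str, scale: float) -> CircuitParameters:
    """Return a copy of ``params`` with one constant multiplied by ``scale``.

    Used for the in-silico intervention scans, e.g. a 30% decrease in the
    autocrine production rate is ``perturb_parameter(wt, "beta11", 0.7)``.
    """
    if name not in PARAMETER_NAMES:
        raise KeyError(f"unknown circuit parameter {name!r}")
    if not (scale > 0):
        raise ValueError(f"scale must be strictly positive, got {scale!r}")
    return params.replace(**{name: getattr(params, name) * scale})
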