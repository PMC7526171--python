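"""Parameter sets, nutrient signals, and model state records.

Units are fixed at µM for concentrations and minutes for time throughout
the package; there is no unit-conversion layer.  The default
:class:`ParameterSet` is the published calibration of the *C. crescentus*
second-messenger network and round-trips bit-exactly through the bundled
``data/default_params.json``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import Iterator, Sequence

__all__ = [
    "ParameterSet",
    "NutrientSignal",
    "SignalSchedule",
    "ModelState",
    "STATE_VARS",
    "default_params",
    "initial_conditions",
]

#: Ordering of the seven dynamic variables everywhere an array is used.
STATE_VARS = ("cdG", "GTP", "ppGpp", "GMP", "EIP_tot", "NPrP", "EIIAP")


@dataclass(frozen=True)
class ParameterSet:
    """All rate and binding constants of the model, in µM / min units.

    Attributes
    ----------
    k_s_cdG, k_d_cdG :
        Scaled synthesis / degradation rate constants of c-di-GMP (1/min).
    K1 :
        Dissociation constant for c-di-GMP product inhibition at the DGC
        I-site (µM); inhibition is cooperative with Hill exponent 2.
    Km1, Km2 :
        GTP affinity of the DGC and c-di-GMP affinity of the PDE (µM).
    DgcB, basalPDE :
        Constant (scaled) DgcB and basal-PDE abundances (µM).
    k_s_ppGpp, k_d_ppGpp :
        SpoT synthetase / hydrolase maximal rates (µM/min).
    K2, K3, K_SpoT :
        NPr~P activation constant, EIIA~P inhibition constant (µM) and the
        dimensionless prefactor of the SpoT synthetase:hydrolase ratio α.
    Km3, Km4 :
        GTP and (p)ppGpp affinities of SpoT (µM).
    K4, eps :
        Glutamine-inhibition constant (µM) and residual activity fraction ε
        of EI autophosphorylation at saturating glutamine.
    k_s_GTP, k_d_GTP :
        GMP→GTP and GTP→GMP interconversion rate constants (1/min).
    EI_T, NPr_T, EIIA_T :
        Total PTS(Ntr) enzyme pools (µM), conserved.
    k1, k_1 :
        EI autophosphorylation / reverse rate constants (1/min).
    k2, k3 :
        Bimolecular phosphotransfer constants EI↔NPr and NPr↔EIIA
        (1/(min·µM)); forward and back rates are equal for each step.
    Kd1, Kd2 :
        Dissociation constants of EI·PEP and EI~P·Pyr (µM).
    """

    k_s_cdG: float = 33.5
    k_d_cdG: float = 100.0
    K1: float = 0.5
    Km1: float = 1500.0
    Km2: float = 0.06
    DgcB: float = 0.7
    basalPDE: float = 0.2
    k_s_ppGpp: float = 170.0
    k_d_ppGpp: float = 160.0
    K2: float = 75.0
    K3: float = 10.0
    K_SpoT: float = 4.0
    Km3: float = 1000.0
    Km4: float = 2000.0
    K4: float = 75.63
    eps: float = 0.1
    k_s_GTP: float = 1500.0
    k_d_GTP: float = 100.0
    EI_T: float = 10.0
    NPr_T: float = 30.0
    EIIA_T: float = 30.0
    k1: float = 52.4
    k_1: float = 67.2
    k2: float = 1.2e4
    k3: float = 3.7e3
    Kd1: float = 350.0
    Kd2: float = 670.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"parameter {f.name} must be finite and > 0, got {v!r}")
        if self.eps > 1:
            raise ValueError(f"eps must satisfy 0 < eps <= 1, got {self.eps!r}")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ParameterSet":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown parameter names: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ParameterSet":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def replace(self, **changes: float) -> "ParameterSet":
        return replace(self, **changes)


def default_params() -> ParameterSet:
    """The published calibration, loaded from the bundled JSON file."""
    with resources.files("caulomsg.data").joinpath("default_params.json").open() as fh:
        return ParameterSet.from_dict(json.load(fh))


@dataclass(frozen=True)
class NutrientSignal:
    """External nutrient levels (µM): glutamine, PEP and pyruvate.

    Glutamine reports nitrogen availability (binds the EI GAF domain and
    inhibits autophosphorylation); the PEP:Pyr ratio sets the phosphoryl
    flux through the relay and reports carbon availability.
    """

    Gln: float
    PEP: float
    Pyr: float

    def __post_init__(self) -> None:
        for name in ("Gln", "PEP", "Pyr"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"signal {name} must be finite and >= 0, got {v!r}")

    def with_gln(self, Gln: float) -> "NutrientSignal":
        return NutrientSignal(Gln, self.PEP, self.Pyr)


@dataclass(frozen=True)
class SignalSchedule:
    """Piecewise-constant nutrient schedule: ordered ``(t_start, signal)``.

    The first breakpoint must be at t=0 and breakpoints must be strictly
    increasing.  The integrator restarts at every breakpoint so the
    discontinuity is not smoothed over.
    """

    entries: tuple[tuple[float, NutrientSignal], ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("schedule needs at least one entry")
        object.__setattr__(self, "entries", tuple((float(t), s) for t, s in self.entries))
        if self.entries[0][0] != 0.0:
            raise ValueError("first schedule entry must start at t=0")
        ts = [t for t, _ in self.entries]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("schedule breakpoints must be strictly increasing")

    @classmethod
    def constant(cls, signal: NutrientSignal) -> "SignalSchedule":
        return cls(((0.0, signal),))

    def signal_at(self, t: float) -> NutrientSignal:
        sig = self.entries[0][1]
        for t0, s in self.entries:
            if t0 <= t:
                sig = s
            else:
                break
        return sig

    def segments(self, t_end: float) -> Iterator[tuple[float, float, NutrientSignal]]:
        """Yield (t0, t1, signal) pieces covering [0, t_end]."""
        ts = [t for t, _ in self.entries if t < t_end] + [t_end]
        for (t0, sig), t1 in zip(self.entries, ts[1:]):
            yield t0, t1, sig


@dataclass(frozen=True)
class ModelState:
    """The seven dynamic concentrations (µM).

    ``EIP_tot`` is the lumped phosphorylated EI pool (free EI~P plus the
    EI~P·Pyr complex); ``GTP`` lumps GDP and GTP; ``ppGpp`` lumps ppGpp and
    pppGpp.  Phospho-pools are bounded by the conserved enzyme totals.
    """

    cdG: float
    GTP: float
    ppGpp: float
    GMP: float
    EIP_tot: float
    NPrP: float
    EIIAP: float

    #: absolute slack (µM) tolerated below 0 / above a pool total before a
    #: state is rejected as invalid
    _TOL = 1e-8

    def as_array(self) -> "np.ndarray":
        import numpy as np

        return np.array([getattr(self, v) for v in STATE_VARS], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "ModelState":
        if len(y) != 7:
            raise ValueError(f"expected 7 components, got {len(y)}")
        return cls(*map(float, y))

    def validate(self, params: ParameterSet) -> None:
        """Raise ``ValueError`` if any component breaches its bounds."""
        tol = self._TOL
        for v in STATE_VARS:
            if getattr(self, v) < -tol:
                raise ValueError(f"state {v}={getattr(self, v)!r} is negative")
        for v, total in (("EIP_tot", params.EI_T), ("NPrP", params.NPr_T), ("EIIAP", params.EIIA_T)):
            if getattr(self, v) > total + tol:
                raise ValueError(f"state {v}={getattr(self, v)!r} exceeds pool total {total}")


def initial_conditions() -> ModelState:
    """Published initial conditions: nucleotide pools at basal Gram-negative
    levels and a fully phosphorylated relay."""
    return ModelState(cdG=0.3, GTP=1300.0, ppGpp=100.0, GMP=20.0,
                      EIP_tot=10.0, NPrP=30.0, EIIAP=30.0)
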