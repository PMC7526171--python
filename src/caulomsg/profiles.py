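"""Cell-cycle enzyme abundance profiles and sinusoid fitting.

Over the 150-min *C. crescentus* cell cycle the diguanylate cyclase PleD
and the phosphodiesterase PdeA vary in abundance while DgcB and a basal
PDE pool stay constant.  Total DGC is DgcB + PleD(t) and total PDE is
basal + PdeA(t), with PleD/PdeA modelled as fitted sinusoids
A·sin(ωt+φ)+c sharing angular frequency ω = π/75 rad/min.

The bundled default profiles are the published fits (immunoblot-derived
time courses): the PleD refit with its second time point masked, and the
PdeA fit.  ``fit_sinusoid`` is a utility for refitting such curves from
point sets; it is not on the simulation path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .params import ParameterSet

__all__ = [
    "SinusoidProfile",
    "ProfilePoints",
    "PLED_ORIGINAL",
    "PLED_REFIT",
    "PDEA_FIT",
    "CELL_CYCLE_PERIOD",
    "eval_profile",
    "dgc_total",
    "pde_total",
    "fit_sinusoid",
    "synth_profile_points",
]

#: Cell-cycle period implied by the shared fitted frequency π/75 rad/min.
CELL_CYCLE_PERIOD = 150.0


@dataclass(frozen=True)
class SinusoidProfile:
    """Abundance curve amplitude·sin(angular_freq·t + phase) + offset.

    Levels are in the scaled µM units of the enzyme calibration.  The
    offset need not exceed |amplitude|: the PdeA fit dips to ~0 but total
    PDE stays positive through the basal pool.
    """

    amplitude: float
    angular_freq: float
    phase: float
    offset: float

    def __post_init__(self) -> None:
        if self.angular_freq <= 0:
            raise ValueError("angular_freq must be > 0")

    @property
    def period(self) -> float:
        return 2.0 * math.pi / self.angular_freq

    def __call__(self, t):
        return self.amplitude * np.sin(self.angular_freq * t + self.phase) + self.offset


#: PleD fit to all immunoblot points.
PLED_ORIGINAL = SinusoidProfile(0.1442, math.pi / 75, 0.5037, 0.7384)
#: PleD refit with the (implausible) second time point masked — the
#: profile used by the simulations.
PLED_REFIT = SinusoidProfile(0.1834, math.pi / 75, 0.5587, 0.7579)
#: PdeA fit — negative amplitude: PdeA is low when PleD is high.
PDEA_FIT = SinusoidProfile(-0.3605, math.pi / 75, 0.1767, 0.361)


@dataclass(frozen=True)
class ProfilePoints:
    """Time course of a (scaled) enzyme level: strictly increasing t (min)."""

    t: np.ndarray
    level: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        level = np.asarray(self.level, dtype=float)
        if t.ndim != 1 or t.shape != level.shape:
            raise ValueError("t and level must be 1-D arrays of equal length")
        if t.size and (t[0] < 0 or np.any(np.diff(t) <= 0)):
            raise ValueError("t must be non-negative and strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "level", level)

    def __len__(self) -> int:
        return self.t.size

    def to_csv(self, path: str | Path) -> None:
        lines = ["t_min,level"] + [f"{t:.10g},{v:.10g}" for t, v in zip(self.t, self.level)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ProfilePoints":
        rows = Path(path).read_text().strip().splitlines()
        if not rows or rows[0].strip().lower() != "t_min,level":
            raise ValueError("expected header 't_min,level'")
        data = np.array([[float(x) for x in r.split(",")] for r in rows[1:]])
        return cls(t=data[:, 0], level=data[:, 1])


def eval_profile(profile: SinusoidProfile, t):
    """Evaluate the sinusoid at time(s) t (min)."""
    return profile(t)


def dgc_total(t, params: ParameterSet, pled: SinusoidProfile = PLED_REFIT):
    """Total diguanylate cyclase abundance DgcB + PleD(t) (scaled µM)."""
    return params.DgcB + pled(t)


def pde_total(t, params: ParameterSet, pdea: SinusoidProfile = PDEA_FIT):
    """Total phosphodiesterase abundance basal + PdeA(t) (scaled µM)."""
    return params.basalPDE + pdea(t)


def _linear_fit(t: np.ndarray, y: np.ndarray, omega: float) -> tuple[float, float, float, float]:
    """LSQ of a·sin(ωt)+b·cos(ωt)+c; returns (a, b, c, ss_res)."""
    X = np.column_stack([np.sin(omega * t), np.cos(omega * t), np.ones_like(t)])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    ss_res = float(np.sum((y - X @ coef) ** 2))
    return float(coef[0]), float(coef[1]), float(coef[2]), ss_res


def fit_sinusoid(points: ProfilePoints,
                 fix_freq: Optional[float] = math.pi / 75,
                 mask: Optional[Sequence[int]] = None,
                 ) -> tuple[SinusoidProfile, float]:
    """Least-squares fit of A·sin(ωt+φ)+c to a time course.

    Parameters
    ----------
    points :
        Observed (t, level) pairs; at least 4 (3 if ω is fixed).
    fix_freq :
        Angular frequency to hold fixed (default π/75 rad/min, the shared
        frequency of the published fits — with ≤9 points a free frequency
        is poorly identifiable).  Pass ``None`` to fit ω too, initialised
        at π/75.
    mask :
        Indices of points to exclude from the fit (manual outlier
        judgement is left to the caller).

    Returns
    -------
    (profile, r_squared) :
        The fit canonicalised to amplitude ≥ 0 and phase in [0, 2π), and
        the coefficient of determination R² = 1 − SS_res/SS_tot.  R² is
        ``nan`` when SS_tot = 0 (constant data).
    """
    t = points.t
    y = points.level
    if mask is not None:
        keep = np.setdiff1d(np.arange(t.size), np.asarray(mask, dtype=int))
        t, y = t[keep], y[keep]
    n_min = 3 if fix_freq is not None else 4
    if t.size < n_min:
        raise ValueError(f"need at least {n_min} points, got {t.size}")
    if np.all(t == t[0]):
        raise ValueError("degenerate points: all at the same time")

    if fix_freq is not None:
        omega = float(fix_freq)
        a, b, c, ss_res = _linear_fit(t, y, omega)
    else:
        # variable projection: optimise ω only, solving the linear
        # subproblem exactly at each iterate
        def resid(w):
            a, b, c, _ = _linear_fit(t, y, w[0])
            return y - (a * np.sin(w[0] * t) + b * np.cos(w[0] * t) + c)

        sol = least_squares(resid, x0=[math.pi / 75], bounds=([1e-6], [np.inf]))
        if not sol.success:
            raise RuntimeError(f"frequency optimisation failed: {sol.message}")
        omega = float(sol.x[0])
        a, b, c, ss_res = _linear_fit(t, y, omega)

    amplitude = math.hypot(a, b)
    phase = math.atan2(b, a) % (2.0 * math.pi)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    # SS_tot at rounding-noise scale means constant data: R² is undefined
    degenerate = ss_tot <= 1e-12 * max(1.0, float(np.sum(y * y)))
    r2 = math.nan if degenerate else 1.0 - ss_res / ss_tot
    return SinusoidProfile(amplitude, omega, phase, c), r2


def synth_profile_points(profile: SinusoidProfile, n: int, noise_sd: float,
                         seed: int) -> ProfilePoints:
    """Synthetic fixture: n points over one period with Gaussian noise.

    Times are evenly spaced on [0, period); reproducible for a given seed.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, profile.period, n, endpoint=False)
    level = profile(t) + rng.normal(0.0, noise_sd, size=n)
    return ProfilePoints(t=t, level=level)
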