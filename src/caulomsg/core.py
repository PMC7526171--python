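"""Right-hand side of the seven-ODE second-messenger network.

The model couples three layers:

* c-di-GMP turnover — synthesis from 2 GTP by diguanylate cyclases (DGC),
  product-inhibited cooperatively (Hill exponent 2) at the I-site, and
  hydrolysis to 2 GMP by phosphodiesterases (PDE);
* the (p)ppGpp stringent layer — the bifunctional enzyme SpoT, whose total
  activity is partitioned between synthetase and hydrolase fractions by the
  ratio α set by the phosphorylation state of the PTS(Ntr) relay;
* the PTS(Ntr) phosphorelay — PEP → EI → NPr → EIIA reversible phosphoryl
  transfer, with glutamine allosterically inhibiting EI autophosphorylation
  and PEP/Pyr binding treated at quasi-steady state.

GTP lumps GDP+GTP; (p)ppGpp lumps the tetra- and pentaphosphate; the pGpG
intermediate of c-di-GMP hydrolysis is lumped out (product taken as 2 GMP).
The stoichiometry conserves total guanine, 2·[cdG]+[GTP]+[GMP]+[(p)ppGpp].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import ModelState, NutrientSignal, ParameterSet, STATE_VARS

__all__ = [
    "EIPartition",
    "SpoTSplit",
    "glutamine_factor",
    "partition_EI",
    "spot_split",
    "rhs",
    "rhs_array",
    "gross_fluxes",
    "total_guanine",
]

# slack below 0 / above a pool total tolerated inside the fast RHS
_TOL = 1e-8


@dataclass(frozen=True)
class EIPartition:
    """Quasi-steady-state split of the EI pool (µM).

    The unphosphorylated pool ``EI_T − EIP_tot`` partitions between free EI
    and the EI·PEP complex according to Kd1; the phosphorylated pool
    partitions between free EI~P and EI~P·Pyr according to Kd2.
    """

    EI_free: float
    EI_PEP: float
    EIP_free: float
    EIP_Pyr: float


@dataclass(frozen=True)
class SpoTSplit:
    """Partition of total SpoT into synthetase and hydrolase fractions.

    ``alpha`` is the synthetase:hydrolase activity ratio; NPr~P activates
    the synthetase arm (saturably, constant K2) and EIIA~P relieves the
    hydrolase arm (constant K3).
    """

    alpha: float
    f_sd: float
    f_hd: float


def glutamine_factor(Gln: float, params: ParameterSet) -> float:
    """Fractional EI autophosphorylation activity, (K4 + ε·Gln)/(K4 + Gln).

    Decreases monotonically from 1 (no glutamine) to ε at saturation;
    glutamine is the intracellular nitrogen signal.
    """
    if Gln < 0 or not math.isfinite(Gln):
        raise ValueError(f"Gln must be finite and >= 0, got {Gln!r}")
    return (params.K4 + params.eps * Gln) / (params.K4 + Gln)


def partition_EI(EIP_tot: float, signal: NutrientSignal, params: ParameterSet) -> EIPartition:
    """Split total EI into free/complexed forms at binding equilibrium."""
    if EIP_tot < -_TOL or EIP_tot > params.EI_T + _TOL:
        raise ValueError(f"EIP_tot={EIP_tot!r} outside [0, EI_T={params.EI_T}]")
    U = max(params.EI_T - EIP_tot, 0.0)
    P = max(EIP_tot, 0.0)
    b_pep = (signal.PEP / params.Kd1) / (1.0 + signal.PEP / params.Kd1)
    b_pyr = (signal.Pyr / params.Kd2) / (1.0 + signal.Pyr / params.Kd2)
    EI_PEP = U * b_pep
    EIP_Pyr = P * b_pyr
    return EIPartition(EI_free=U - EI_PEP, EI_PEP=EI_PEP,
                       EIP_free=P - EIP_Pyr, EIP_Pyr=EIP_Pyr)


def spot_split(NPrP: float, EIIAP: float, params: ParameterSet) -> SpoTSplit:
    """SpoT synthetase/hydrolase fractions from the relay phospho-state.

    α = K_SpoT · [NPr~P]/([NPr~P]+K2) · ([EIIA~P]+K3)/K3; the synthetase
    fraction α/(1+α) increases with both phospho-pools.
    """
    if NPrP < -_TOL or EIIAP < -_TOL:
        raise ValueError("NPrP and EIIAP must be >= 0")
    NPrP = max(NPrP, 0.0)
    EIIAP = max(EIIAP, 0.0)
    alpha = params.K_SpoT * (NPrP / (NPrP + params.K2)) * ((EIIAP + params.K3) / params.K3)
    return SpoTSplit(alpha=alpha, f_sd=alpha / (1.0 + alpha), f_hd=1.0 / (1.0 + alpha))


def _fluxes(y: np.ndarray, Gln: float, PEP: float, Pyr: float,
            dgc: float, pde: float, p: ParameterSet) -> tuple[float, ...]:
    """All gross fluxes (µM/min) at a raw state vector.

    Returns (cdg_syn, cdg_deg, ppgpp_syn, ppgpp_hyd, gmp_to_gtp, gtp_to_gmp,
    ei_auto, ei_rev, ei_to_npr, npr_to_ei, npr_to_eiia, eiia_to_npr).
    """
    cdG, GTP, ppGpp, GMP, EIP_tot, NPrP, EIIAP = y

    cdg_syn = (p.k_s_cdG * dgc
               * p.K1 ** 2 / (p.K1 ** 2 + cdG * cdG)
               * GTP * GTP / (GTP * GTP + p.Km1 ** 2))
    cdg_deg = p.k_d_cdG * pde * cdG / (cdG + p.Km2)

    alpha = p.K_SpoT * (NPrP / (NPrP + p.K2)) * ((EIIAP + p.K3) / p.K3)
    f_sd = alpha / (1.0 + alpha)
    ppgpp_syn = p.k_s_ppGpp * f_sd * GTP / (GTP + p.Km3)
    ppgpp_hyd = p.k_d_ppGpp * (1.0 - f_sd) * ppGpp / (ppGpp + p.Km4)

    gmp_to_gtp = p.k_s_GTP * GMP
    gtp_to_gmp = p.k_d_GTP * GTP

    U = p.EI_T - EIP_tot
    b_pep = (PEP / p.Kd1) / (1.0 + PEP / p.Kd1)
    b_pyr = (Pyr / p.Kd2) / (1.0 + Pyr / p.Kd2)
    EI_PEP = U * b_pep
    EIP_Pyr = EIP_tot * b_pyr
    NPr = p.NPr_T - NPrP
    EIIA = p.EIIA_T - EIIAP
    g = (p.K4 + p.eps * Gln) / (p.K4 + Gln)

    ei_auto = p.k1 * g * EI_PEP          # PEP-dependent EI autophosphorylation
    ei_rev = p.k_1 * EIP_Pyr             # reverse transfer to pyruvate
    ei_to_npr = p.k2 * EIP_tot * NPr     # EI~P (either form) -> NPr
    npr_to_ei = p.k2 * NPrP * U          # NPr~P -> EI or EI·PEP
    npr_to_eiia = p.k3 * NPrP * EIIA
    eiia_to_npr = p.k3 * NPr * EIIAP

    return (cdg_syn, cdg_deg, ppgpp_syn, ppgpp_hyd, gmp_to_gtp, gtp_to_gmp,
            ei_auto, ei_rev, ei_to_npr, npr_to_ei, npr_to_eiia, eiia_to_npr)


def rhs_array(y: np.ndarray, Gln: float, PEP: float, Pyr: float,
              dgc: float, pde: float, p: ParameterSet,
              check: bool = True) -> np.ndarray:
    """Derivative vector at a raw 7-component state (fast path)."""
    if check:
        if (y[0] < -_TOL or y[1] < -_TOL or y[2] < -_TOL or y[3] < -_TOL
                or not -_TOL <= y[4] <= p.EI_T + _TOL
                or not -_TOL <= y[5] <= p.NPr_T + _TOL
                or not -_TOL <= y[6] <= p.EIIA_T + _TOL):
            raise ValueError(f"state outside physical bounds: {y!r}")
    (cdg_syn, cdg_deg, ppgpp_syn, ppgpp_hyd, gmp_to_gtp, gtp_to_gmp,
     ei_auto, ei_rev, ei_to_npr, npr_to_ei, npr_to_eiia, eiia_to_npr) = _fluxes(
        y, Gln, PEP, Pyr, dgc, pde, p)
    return np.array([
        cdg_syn - cdg_deg,
        gmp_to_gtp - gtp_to_gmp - ppgpp_syn + ppgpp_hyd - 2.0 * cdg_syn,
        ppgpp_syn - ppgpp_hyd,
        2.0 * cdg_deg + gtp_to_gmp - gmp_to_gtp,
        ei_auto - ei_rev - ei_to_npr + npr_to_ei,
        ei_to_npr - npr_to_ei - (npr_to_eiia - eiia_to_npr),
        npr_to_eiia - eiia_to_npr,
    ])


def rhs(state: ModelState, signal: NutrientSignal, dgc_level: float,
        pde_level: float, params: ParameterSet) -> np.ndarray:
    """Time derivatives (µM/min) of the seven state variables.

    ``dgc_level`` and ``pde_level`` are the instantaneous total DGC and PDE
    abundances (constant DgcB + PleD(t), basal PDE + PdeA(t)).  The
    stoichiometric combination 2·d[cdG]+d[GTP]+d[GMP]+d[(p)ppGpp] cancels
    identically (guanine conservation).
    """
    if dgc_level < 0 or pde_level < 0:
        raise ValueError("enzyme levels must be >= 0")
    state.validate(params)
    return rhs_array(state.as_array(), signal.Gln, signal.PEP, signal.Pyr,
                     dgc_level, pde_level, params)


def gross_fluxes(state: ModelState, signal: NutrientSignal, dgc_level: float,
                 pde_level: float, params: ParameterSet) -> dict[str, float]:
    """Named gross fluxes (µM/min) — useful for residual diagnostics."""
    vals = _fluxes(state.as_array(), signal.Gln, signal.PEP, signal.Pyr,
                   dgc_level, pde_level, params)
    names = ("cdg_syn", "cdg_deg", "ppgpp_syn", "ppgpp_hyd", "gmp_to_gtp",
             "gtp_to_gmp", "ei_auto", "ei_rev", "ei_to_npr", "npr_to_ei",
             "npr_to_eiia", "eiia_to_npr")
    return dict(zip(names, vals))


def total_guanine(state: ModelState) -> float:
    """Conserved guanine moiety 2·[cdG] + [GTP] + [GMP] + [(p)ppGpp] (µM)."""
    return 2.0 * state.cdG + state.GTP + state.GMP + state.ppGpp
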