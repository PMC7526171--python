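"""Closed-form steady states of the second-messenger network.

Derived independently of the numerical integrator, these serve both as the
verification oracle for the ODE solution and as the direct engine for the
nutrient-condition tables and the PEP:Pyr sweep.

Phosphorelay
------------
At steady state every reversible transfer step balances individually, and
because the forward and back bimolecular constants are equal for each step
(k±2, k±3), all three enzymes share one phosphorylated:unphosphorylated
ratio

    r = k1·g(Gln)·fPEP / (k_1·fPyr),

where g is the glutamine inhibition factor and fPEP, fPyr are the bound
fractions of the PEP/Pyr binding equilibria.  Each phospho-pool is then
total·r/(1+r).

Nucleotides
-----------
With the SpoT split fixed by the relay, the (p)ppGpp balance
k_s·f_sd·G/(G+Km3) = k_d·f_hd·P/(P+Km4), the GMP balance
k_s_GTP·GMP = k_d_GTP·G + 2·J_c (J_c the steady c-di-GMP through-flux,
which returns guanine to the GMP pool), and conservation of total guanine
2·cdG + GTP + GMP + (p)ppGpp = const reduce to a bracketed scalar root in
GTP; the small c-di-GMP terms (pool ≤ 0.6 µM, flux correction ≈ 0.03 µM on
GMP) are resolved by fixed-point refinement against the c-di-GMP
synthesis/degradation balance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from scipy.optimize import brentq

from .core import SpoTSplit, glutamine_factor, spot_split
from .params import ModelState, NutrientSignal, ParameterSet
from .profiles import PDEA_FIT, PLED_REFIT

__all__ = [
    "PhosphorelayEquilibrium",
    "NucleotideEquilibrium",
    "GUANINE_TOTAL",
    "pts_equilibrium",
    "cdg_steady_state",
    "nucleotide_equilibrium",
    "full_equilibrium",
    "reproduce_table4",
    "pep_pyr_sweep",
]

#: Default conserved guanine total (µM), fixed by the initial conditions:
#: 2·0.3 + 1300 + 100 + 20.
GUANINE_TOTAL = 1420.6


@dataclass(frozen=True)
class PhosphorelayEquilibrium:
    """Common phospho:unphospho ratio r and the resulting pools (µM)."""

    r: float
    EIP_tot: float
    NPrP: float
    EIIAP: float


@dataclass(frozen=True)
class NucleotideEquilibrium:
    """Steady nucleotide pools (µM) at a given SpoT split and guanine total."""

    GTP: float
    GMP: float
    ppGpp: float
    cdG: float
    guanine_total: float


def pts_equilibrium(signal: NutrientSignal, params: ParameterSet,
                    EI_T: Optional[float] = None,
                    NPr_T: Optional[float] = None,
                    EIIA_T: Optional[float] = None) -> PhosphorelayEquilibrium:
    """Steady state of the PEP→EI→NPr→EIIA relay.

    Pool totals default to the parameter set; r is independent of the
    totals, so pools scale linearly with them.  Pyr=0 (with PEP>0) is the
    fully phosphorylated limit, returned with r = inf.
    """
    EI_T = params.EI_T if EI_T is None else EI_T
    NPr_T = params.NPr_T if NPr_T is None else NPr_T
    EIIA_T = params.EIIA_T if EIIA_T is None else EIIA_T
    if min(EI_T, NPr_T, EIIA_T) < 0:
        raise ValueError("pool totals must be >= 0")
    if signal.PEP == 0 and signal.Pyr == 0:
        raise ValueError("equilibrium undefined: PEP and Pyr both zero "
                         "(no phosphoryl source or sink)")
    g = glutamine_factor(signal.Gln, params)
    fPEP = (signal.PEP / params.Kd1) / (1.0 + signal.PEP / params.Kd1)
    fPyr = (signal.Pyr / params.Kd2) / (1.0 + signal.Pyr / params.Kd2)
    if fPyr == 0.0:
        return PhosphorelayEquilibrium(math.inf, EI_T, NPr_T, EIIA_T)
    r = params.k1 * g * fPEP / (params.k_1 * fPyr)
    frac = r / (1.0 + r)
    return PhosphorelayEquilibrium(r, EI_T * frac, NPr_T * frac, EIIA_T * frac)


def cdg_steady_state(GTP: float, dgc_level: float, pde_level: float,
                     params: ParameterSet) -> float:
    """c-di-GMP level balancing synthesis and degradation at fixed GTP.

    Synthesis is product-inhibited (decreasing in cdG) and degradation
    saturable (increasing), so the root is unique; it is bracketed by
    doubling the upper bound until the balance changes sign.
    """
    if pde_level <= 0:
        raise ValueError("pde_level must be > 0 for a finite cdG steady state")
    hill_gtp = GTP * GTP / (GTP * GTP + params.Km1 ** 2)

    def balance(c: float) -> float:
        syn = params.k_s_cdG * dgc_level * params.K1 ** 2 / (params.K1 ** 2 + c * c) * hill_gtp
        deg = params.k_d_cdG * pde_level * c / (c + params.Km2)
        return syn - deg

    if balance(0.0) <= 0.0:
        return 0.0
    hi = 1.0
    while balance(hi) > 0.0:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover - unreachable with positive params
            raise RuntimeError("failed to bracket cdG steady state")
    return brentq(balance, 0.0, hi, xtol=1e-14, rtol=1e-14)


def nucleotide_equilibrium(split: SpoTSplit, guanine_total: float,
                           params: ParameterSet,
                           dgc_level: Optional[float] = None,
                           pde_level: Optional[float] = None,
                           n_refine: int = 5) -> NucleotideEquilibrium:
    """Steady GTP/GMP/(p)ppGpp pools at a fixed SpoT split.

    ``dgc_level``/``pde_level`` (total enzyme abundances) default to the
    cycle-mean levels DgcB + mean PleD and basal + mean PdeA; they only
    matter through the ≤0.6 µM c-di-GMP term of the guanine balance,
    handled by ``n_refine`` fixed-point passes (second-order corrections
    are < 0.1 %).
    """
    if guanine_total <= 0:
        raise ValueError("guanine_total must be > 0")
    if split.f_hd <= 0.0:
        raise ValueError("no finite equilibrium: SpoT hydrolase fraction is 0, "
                         "(p)ppGpp grows without bound")
    dgc = params.DgcB + PLED_REFIT.offset if dgc_level is None else dgc_level
    pde = params.basalPDE + PDEA_FIT.offset if pde_level is None else pde_level
    gmp_ratio = params.k_d_GTP / params.k_s_GTP

    cdG, flux_corr = 0.0, 0.0  # flux_corr = 2·J_c/k_s_GTP, µM added to GMP
    for _ in range(max(n_refine, 1)):
        # GMP(G) = gmp_ratio·G + flux_corr; guanine pool: G + GMP + P + 2·cdG
        avail = guanine_total - 2.0 * cdG - flux_corr
        if avail <= 0:
            raise RuntimeError("cdG exceeds the guanine budget")
        if split.f_sd == 0.0:
            G = avail / (1.0 + gmp_ratio)
            P = 0.0
        else:
            def balance(G: float) -> float:
                P = avail - G * (1.0 + gmp_ratio)
                syn = params.k_s_ppGpp * split.f_sd * G / (G + params.Km3)
                hyd = params.k_d_ppGpp * split.f_hd * P / (P + params.Km4)
                return syn - hyd

            G_max = avail / (1.0 + gmp_ratio)
            G = brentq(balance, 1e-12 * G_max, G_max * (1.0 - 1e-12),
                       xtol=1e-12, rtol=1e-14)
            P = avail - G * (1.0 + gmp_ratio)
        cdG = cdg_steady_state(G, dgc, pde, params)
        flux_c = params.k_d_cdG * pde * cdG / (cdG + params.Km2)
        flux_corr = 2.0 * flux_c / params.k_s_GTP

    return NucleotideEquilibrium(GTP=G, GMP=gmp_ratio * G + flux_corr,
                                 ppGpp=P, cdG=cdG,
                                 guanine_total=guanine_total)


def full_equilibrium(signal: NutrientSignal, params: ParameterSet,
                     dgc_level: Optional[float] = None,
                     pde_level: Optional[float] = None,
                     guanine_total: float = GUANINE_TOTAL) -> ModelState:
    """Closed-form fixed point of the whole 7-variable system."""
    relay = pts_equilibrium(signal, params)
    split = spot_split(relay.NPrP, relay.EIIAP, params)
    nuc = nucleotide_equilibrium(split, guanine_total, params,
                                 dgc_level=dgc_level, pde_level=pde_level)
    return ModelState(cdG=nuc.cdG, GTP=nuc.GTP, ppGpp=nuc.ppGpp, GMP=nuc.GMP,
                      EIP_tot=relay.EIP_tot, NPrP=relay.NPrP, EIIAP=relay.EIIAP)


def reproduce_table4(EI_T: float, NPr_T: float, params: ParameterSet,
                     Gln: float = 10000.0, PEP: float = 160.0,
                     Pyr: float = 48.5) -> float:
    """Predicted EI~P + NPr~P (µM) for the carbon-PTS calibration assay.

    The assay conditions are PEP = 160 µM with Pyr = 48.5 µM (estimated
    from one row of the published measurements).  EIIA plays no role in
    the equilibrium sum.  Gln defaults to the nutrient-rich level, the
    value under which the published simulated column (and the Pyr
    estimate) is self-consistent; see the methods note for discussion.
    """
    relay = pts_equilibrium(NutrientSignal(Gln=Gln, PEP=PEP, Pyr=Pyr), params,
                            EI_T=EI_T, NPr_T=NPr_T, EIIA_T=0.0)
    return relay.EIP_tot + relay.NPrP


def pep_pyr_sweep(ratio_grid: Sequence[float], params: ParameterSet,
                  Gln: float = 1000.0, fixed_pyr: Optional[float] = 1500.0,
                  pep_pyr_product: Optional[float] = None) -> pd.DataFrame:
    """Relay phosphorylation and SpoT split along a PEP:Pyr ratio grid.

    Anchor either Pyr (``fixed_pyr``, default 1500 µM, PEP = ratio·Pyr) or
    the product PEP·Pyr (``pep_pyr_product``).  Because the binding
    fractions saturate, r — and hence every phospho-pool and the SpoT
    synthetase fraction — depends non-linearly but monotonically on the
    ratio.
    """
    if pep_pyr_product is not None:
        fixed_pyr = None
    rows = []
    for ratio in ratio_grid:
        if ratio <= 0:
            raise ValueError("ratios must be > 0")
        if fixed_pyr is not None:
            pyr = fixed_pyr
            pep = ratio * pyr
        else:
            # PEP·Pyr = product, PEP/Pyr = ratio
            pyr = math.sqrt(pep_pyr_product / ratio)
            pep = ratio * pyr
        relay = pts_equilibrium(NutrientSignal(Gln=Gln, PEP=pep, Pyr=pyr), params)
        split = spot_split(relay.NPrP, relay.EIIAP, params)
        rows.append(dict(ratio=ratio, PEP=pep, Pyr=pyr, r=relay.r,
                         EIP_tot=relay.EIP_tot, NPrP=relay.NPrP,
                         EIIAP=relay.EIIAP, f_sd=split.f_sd))
    return pd.DataFrame(rows)
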