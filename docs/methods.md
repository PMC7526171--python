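# Methods

## Model structure and assumptions

The simulator integrates seven concentrations (µM): c-di-GMP (cdG), a
lumped GTP pool (GTP+GDP), a lumped alarmone pool (ppGpp+pppGpp), GMP, and
the three phosphorylated PTS<sup>Ntr</sup> enzymes EI∼P (total, i.e. free
plus pyruvate-bound), NPr∼P and EIIA∼P. Nutrients — glutamine, PEP and
pyruvate — are external signals, not state variables; they may change as a
piecewise-constant schedule but are never consumed.

Key modelling assumptions, inherited from the biology:

* DGCs act as dimers; cdG binds the I-site cooperatively, so product
  inhibition is a Hill function with exponent 2. PDEs are monomeric and
  treated as GTP-saturated; the pGpG intermediate of cdG hydrolysis is
  lumped out (2 GMP per cdG cleaved).
* SpoT is the single RelA/SpoT-homologue; its total activity partitions
  into synthetase and hydrolase fractions α/(1+α), 1/(1+α) with
  α = K_SpoT · [NPr∼P]/([NPr∼P]+K2) · ([EIIA∼P]+K3)/K3 — NPr∼P activates
  synthesis indirectly, EIIA∼P inhibits hydrolysis directly.
* PEP/pyruvate binding to EI is fast relative to phosphotransfer, so the
  EI·PEP and EI∼P·Pyr complexes are algebraic (dissociation constants Kd1,
  Kd2). EI and EI·PEP are equally good phosphoacceptors from NPr∼P, and
  EI∼P and EI∼P·Pyr equally good donors; the forward and back bimolecular
  constants of each relay step are equal (k±2, k±3 single values).
* Glutamine inhibits EI autophosphorylation by (K4+ε·Gln)/(K4+Gln),
  saturating at the residual activity ε = 0.1.
* Alarmone feedback on GMP synthesis and GTP activation of PDEs are both
  omitted (saturated in the regimes of interest); there is no phosphoryl
  sink downstream of EIIA∼P.

The stoichiometry conserves total guanine 2[cdG]+[GTP]+[GMP]+[(p)ppGpp];
with the standard initial conditions (0.3, 1300, 100, 20 µM) the conserved
total is 1420.6 µM, and every steady state in the package is consistent
with that value. The relay pools are separately conserved (EI_T = 10,
NPr_T = 30, EIIA_T = 30 µM). The initial cdG of 0.3 µM slightly exceeds
the 0.28 µM orbit peak; it is a transient initial condition, not an error.

## Cell-cycle enzyme forcing

Total DGC is constant DgcB (0.7 µM, scaled) plus a PleD sinusoid; total
PDE is a basal pool (0.2 µM) plus a PdeA sinusoid. The bundled profiles
are the published immunoblot fits, all sharing ω = π/75 rad/min (period
150 min, t = 0 at swarmer birth):

* PleD, all points: 0.1442·sin(πt/75+0.5037)+0.7384;
* PleD, refit with the implausible second point masked (used by the
  simulations): 0.1834·sin(πt/75+0.5587)+0.7579;
* PdeA: −0.3605·sin(πt/75+0.1767)+0.361.

`fit_sinusoid` refits such curves by variable projection: for each trial
ω the amplitude/phase/offset subproblem is solved exactly by linear least
squares; ω is fixed at π/75 by default (with ≤9 points a free frequency is
poorly identifiable) and optimised from that initial value when requested.
Fits are canonicalised to A ≥ 0, φ ∈ [0, 2π). R² is reported as NaN when
SS_tot is at rounding-noise scale (constant data). Outlier handling is a
point mask supplied by the caller — excluding a blot point is a manual
judgement, not an automated rule. The synthetic fixture generator samples
a known sinusoid at n evenly spaced times over one period with i.i.d.
Gaussian noise; it reproduces the *shape* of the digitised time courses
but not their irregular sampling or blot-quantification error structure,
so fit-recovery tests demonstrate correctness of the fitter, not the
fidelity of the published curves to the underlying blots.

## Numerical integration

The system is stiff: the bimolecular relay constants (k2 = 1.2×10⁴
/(min·µM)) put sub-minute modes next to nucleotide relaxation over
hundreds of minutes. `integrate` uses LSODA with rtol = 10⁻⁸ and
atol = 10⁻¹⁰ µM; at these tolerances the conserved guanine total drifts by
~10⁻¹³ relative over 750 min, far inside the enforced 10⁻⁴ budget (drift
beyond 10⁻⁶ is logged as a warning, beyond 10⁻⁴ is an error). Integration
restarts at every schedule breakpoint so signal steps are exact. The
right-hand side validates the state on every call and raises if any
component drops below −10⁻⁸ µM or any relay pool exceeds its total by
more than 10⁻⁸ µM; no clipping is applied.

`steady_state` integrates in doubling chunks until the scaled residual
max|dxᵢ/dt|/(|xᵢ|+1 µM) < 10⁻⁹/min, then applies a Newton polish in which
the (rank-deficient) GMP row is replaced by the guanine-conservation
constraint, pinning the fixed point on the conserved manifold.

## Closed-form steady-state oracle

Derived independently of the integrator. At steady state every reversible
relay step balances, and because k₊ = k₋ for both bimolecular steps, all
three enzymes share one phosphorylated:unphosphorylated ratio
r = k₁·g(Gln)·f_PEP/(k₋₁·f_Pyr) with f_PEP, f_Pyr the bound fractions;
each pool is total·r/(1+r). Pyr = 0 is the fully phosphorylated limit
(r → ∞); PEP = Pyr = 0 has no defined equilibrium and raises.

With the SpoT split fixed by the relay, the nucleotide fixed point solves
the scalar alarmone balance k_s·f_sd·G/(G+Km3) = k_d·f_hd·P/(P+Km4)
jointly with the GMP balance and guanine conservation by bracketed Brent
root-finding in G. Two refinements matter at the 10⁻⁶ level:

* the cdG pool (≤ 0.6 µM) occupies part of the conserved total, and
* the steady cdG through-flux J_c returns guanine via GMP, so the exact
  GMP relation is k_s_GTP·GMP = k_d_GTP·GTP + 2·J_c — the naive
  GMP = (k_d/k_s)·GTP is only zeroth-order (≈0.026 µM short).

Both are handled by a five-pass fixed-point refinement against the cdG
synthesis/degradation balance; the result matches the integrated fixed
point to ~10⁻¹² relative.

Single-number steady pools in the nutrient-grid table use constant
enzymes at the cycle-mean levels (DGC = 0.7+0.7579, PDE = 0.2+0.361); only
the cdG range row uses the oscillating profiles, because the large
nucleotide pools vary by well under 1 % over the cycle (tested property)
while cdG spans an order of magnitude.

## Protocols

* **Periodic range**: 600-min transient (four forcing periods) then one
  150-min window sampled at 0.1 min; the orbit repeats cycle-to-cycle to
  ~10⁻⁸ µM by then, so the window placement is immaterial.
* **Nutrient shifts**: glutamine steps on a fixed PEP/Pyr background (PEP
  and pyruvate are stable under nitrogen shifts); each segment starts from
  the previous end state. The default downshift/recovery run is
  10000 → 100 µM at t = 600 and back at t = 1200.
* **PTS calibration**: the relay equilibrium evaluated at the carbon-PTS
  assay conditions PEP = 160 µM, Pyr = 48.5 µM (pyruvate back-estimated
  from one measured row), reporting EI∼P+NPr∼P. The glutamine factor
  defaults to its nutrient-rich value (Gln = 10000 µM, factor ≈ 0.107):
  although the calibration is described as glutamine-free, the published
  simulated column — and the self-consistency of the Pyr estimate — are
  reproduced only under the rich-condition factor; with Gln = 0 the
  predicted sums come out ≈2.8× larger. `reproduce_table4` therefore
  exposes Gln as an argument with the rich default.

## Parameters

All defaults live in `caulomsg/data/default_params.json` (µM, min).
The ones that shape behaviour most:

| symbol | default | meaning |
|---|---|---|
| k_s_cdG, k_d_cdG | 33.5, 100 /min | scaled cdG synthesis/degradation |
| K1, Km2 | 0.5, 0.06 µM | I-site inhibition; PDE affinity for cdG |
| k_s_ppGpp, k_d_ppGpp | 170, 160 µM/min | SpoT synthetase/hydrolase Vmax |
| K_SpoT, K2, K3 | 4, 75, 10 | SpoT split prefactor and relay constants |
| K4, ε | 75.63 µM, 0.1 | glutamine inhibition of EI |
| k_s_GTP, k_d_GTP | 1500, 100 /min | GMP↔GTP interconversion (15:1 ratio) |
| k1, k₋1 | 52.4, 67.2 /min | EI (de)phosphorylation |
| k±2, k±3 | 1.2e4, 3.7e3 /(min·µM) | relay phosphotransfer |
| Kd1, Kd2 | 350, 670 µM | EI·PEP and EI∼P·Pyr dissociation |

Nutrient presets: rich (Gln 10000, PEP 300, Pyr 1500), nitrogen-starved
(Gln 1, same carbon), carbon-limited (Gln 1000 — the pinned value of the
proposed 1000–2000 µM range — PEP 2800, Pyr 900).

## Known limitations

* No downstream cell-cycle machinery (CtrA, DnaA, division); the 150-min
  period is imposed by the enzyme forcing, not generated by a cycle model.
* PEP and pyruvate are signals, not dynamic metabolites; carbon-PTS
  cross-talk is absent.
* The relay kinetic constants are borrowed from the carbon PTS of other
  organisms; the PTS<sup>Ntr</sup> pools themselves have not been measured
  dynamically, so the relay trajectories are predictions.
* The equilibrium is unique in every regime exercised here; no
  continuation/bifurcation machinery is provided.
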