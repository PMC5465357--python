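# Methods

## Scope and model

`n2opart` partitions a steady-state sediment N₂O efflux among four
production processes using three isotopic tracers measured on the effluent
of flow-through core incubations. The model is a linear endmember mixing
model on the 4-simplex with a prescribed correction for bacterial N₂O
reduction; it is *not* a kinetic or reaction–diffusion model. Its core
assumptions:

1. **Steady state.** Effluent composition is time-invariant over the
   analysis window, so mass and isotope balances close without storage
   terms. Steady state is detected (or prescribed) on the concentration
   time series; isotope records are taken as steady-state values with a
   standard deviation.
2. **Linear mixing.** Each process contributes N₂O with a fixed endmember
   composition (Δδ¹⁵N on the nitrate-referenced scale, SP, and an O-atom
   transfer coefficient γ ∈ [0, 1] multiplying the steady-state Δ¹⁷O of
   NO₂⁻). Measured Δδ¹⁵N, SP and Δ¹⁷O_N₂O/Δ¹⁷O_NO₂ are
   fraction-weighted sums.
3. **Reduction as a prescribed offset.** N₂O reduction consumes a fraction
   f_red of gross production and shifts SP of the residual pool by
   −f_red·ˢᵖε_red with ˢᵖε_red = −6 ‰ (an open-system, linearised
   treatment; no Rayleigh closed-system model). With four equations and
   four unknown fractions, f_red cannot be solved for and is swept as a
   scenario input (default 0.1 and 0.9). The bulk-¹⁵N effect of reduction
   (¹⁵ε_red) defaults to 0 but is configurable. Because reduction is mass
   dependent, the Δ¹⁷O balance row is exactly invariant to f_red.
4. **Δ¹⁷O conservation.** The ¹⁷O anomaly is conserved through
   mass-dependent fractionation and diluted only by O-atom incorporation
   from O₂/H₂O (anomaly ≈ 0). The anomaly convention is configurable:
   linear (default, Δ¹⁷O = δ¹⁷O − λ·δ¹⁸O with λ = 0.52) or logarithmic.
   The two conventions agree to ~0.05 ‰ only for |δ| ≲ 10 ‰ (the
   difference grows as (δ¹⁷O² − λ·δ¹⁸O²)/2000), so one form must be used
   consistently; all shipped defaults use the linear form.
5. **TRN as NH₄⁺ proxy.** The δ¹⁵N of total reduced nitrogen (TDN minus
   NO₃⁻ and NO₂⁻, by concentration-weighted mass balance) stands in for
   the δ¹⁵N of the ammonium substrate when deriving the AMO endmember
   (Δδ¹⁵N_AMO = (δ¹⁵N_NO₃ − δ¹⁵N_NH₄) + ε_NH₃→N₂O). Output rows carry the
   endmember-config hash so this substitution is traceable.

## Solving, clipping, feasibility

The 4×4 system is solved exactly (LAPACK). Raw fractions may fall outside
[0, 1]; they are retained for diagnostics (`raw_*` columns) and flagged
infeasible when outside [−0.02, 1.02]. For presentation, negative entries
are set to zero and the remainder renormalized to sum to 1 (idempotent;
an error if no entry is positive). A measured anomaly ratio above the
maximum attainable Σ fᵢγᵢ (e.g. Δ¹⁷O_N₂O > Δ¹⁷O_NO₂ with γ ≤ 1)
necessarily produces negative raw fractions — the model's way of saying the
record violates mass balance under the assumed endmembers.

Clip-renormalization is a projection onto the simplex and therefore biases
small contributions upward when noise is present: in simulation at the
default noise levels the clipped AMO share carries a mean bias of about
+0.02 while the raw solution is unbiased to < 0.02 in every coordinate.
Uncertainty statements should be read from the Monte Carlo quantiles of
clipped draws, which inherit the same boundary treatment as the point
estimates.

A precursor Δ¹⁷O smaller in magnitude than 1 ‰ (configurable floor) makes
the anomaly ratio uninformative; such records (all low-nitrate treatments,
where no anomalous nitrate was amended) are rejected with an explicit
missing-measurement or uninformative-tracer error rather than partitioned.

## Endmember defaults and uncertainty

The shipped endmember table (`data/endmembers_default.yaml`) is explicitly
non-authoritative — literature-guided placeholders, overridable per run:

| process | Δδ¹⁵N (‰) | SP (‰) | γ |
|---|---|---|---|
| bDNF | 0 ± 2 | −5 ± 5 | 1 |
| fDNF | 0 ± 2 | 37 ± 3 | 1 |
| cDNF | 0 ± 2 | 16 ± 5 | 1 |
| AMO | derived ± 3 | 33 ± 4 | 0 |
| nDNF | 56.9 ± 5 | −5 ± 5 | 0 |

Denitrification Δδ¹⁵N endmembers are set low because diffusion limitation
in organic-rich sediment suppresses expression of intrinsic enzyme-level
isotope effects. ε_NH₃→N₂O = 3.7 ± 3 ‰ (product depleted). The built-in
sensitivity scenarios sweep the least certain of these: nDNF Δδ¹⁵N down to
28 and 14 ‰, fungal SP down to 30.3 ‰, nDNF γ from 0 to 1, and case 2
(cDNF replacing fDNF).

Monte Carlo propagation (default 10,000 draws; 2,000 in the calibration
tests) perturbs **both** the measured compositions (by their recorded
standard deviations) and the endmember parameters (by their configured
standard deviations) with independent Gaussians — no covariance is modelled.
Draws are solved and clipped individually; draws that cannot be clipped
(all fractions non-positive), fail to solve, or whose perturbed precursor
anomaly falls below the floor are counted, reported as an infeasible-draw
fraction, and excluded from the summaries; a flag is raised when they
exceed 50 %. Results are bit-reproducible for a fixed seed (a single
`numpy` Generator with a documented draw order).

## Flux computation

Flux = mean(effluent − influent) × flow / area over the steady-state
window, in mmol m⁻² d⁻¹ (μmol m⁻² d⁻¹ for N₂O, matching its much smaller
magnitude); negative = uptake by the sediment. Core area is the inner
cross-section of the liner (default 10 cm OD, 1/8″ wall → 6.887×10⁻³ m²).
The standard deviation combines, to first order and assuming independence
(different instruments), the standard errors of the windowed mean
concentration difference and mean flow rate. Per-timepoint averaging and
flux-from-averaged-concentrations are identical under steady flow; the
implementation averages concentrations and flow separately.

Steady state is a trailing-window trend test: the largest window starting
at or after day 3 (default) whose fitted |slope| of (effluent − influent),
relative to a robust magnitude scale of the window (the larger of |mean|
and RMS, floored), is below 0.05 d⁻¹. This is deliberately a simple,
reported, overridable rule, not a changepoint model. With noisy data the
test rejects a genuinely steady series a few percent of the time near its
threshold; callers (and the bias tests) may prescribe the window instead.

## Synthetic data generator

The generator emulates the statistical structure the inversion assumes:
per-core true fractions (default Dirichlet around a
denitrification-dominated pattern 0.45/0.36/0.12/0.07, concentration 25),
true f_red (default 0.1), source compositions and steady concentrations by
treatment (high-nitrate treatments carry a positive nitrate anomaly near
+15 ‰; low-nitrate treatments none, so their records are — correctly —
rejected by the partitioner), exponential approach to steady state
(c(t) = c_ss + (c₀ − c_ss)e^(−t/τ), default τ = 0.5 d over 8 days with 16
samples), flow 1.8 ± 0.06 mL min⁻¹, and independent Gaussian measurement
noise. Default noise levels (1 s.d.): δ¹⁵N of NO₃⁻ 0.2 ‰, NO₂⁻ 1.8 ‰,
TRN 1.1 ‰, N₂O 0.6 ‰; SP 3 ‰; Δ¹⁷O of NO₃⁻ 0.7 ‰, of NO₂⁻ and N₂O 1.2 ‰;
concentrations 3 % relative. The Δ¹⁷O level reflects per-core measurement
reproducibility rather than the larger between-core spread of
treatment-mean tables. The default study is 3 sites × 4 treatments × 2
cores = 24 cores.

For interval-calibration studies each synthetic core's record is generated
under a per-core "true world" endmember realisation drawn from the
endmember uncertainty model (`perturb_endmembers=True`), because the
analysis Monte Carlo treats endmember uncertainty as real spread; with 200
cores and 2,000 draws per core the central 95 % intervals cover each true
fraction for 93–97 % of cores.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: correlated errors between pools measured on the
same instrument run, non-Gaussian or drifting noise, NO₂⁻–water oxygen
equilibration dynamics, within-core spatial heterogeneity (truths are
prescribed fractions, not mechanistic rates), and any misfit between the
true endmembers of a real sediment community and the Gaussian families
assumed here.

## Numerical choices

- Collinearity: the system matrix is rejected at condition number > 10¹⁰,
  naming the duplicated processes when the degeneracy is pairwise.
- Feasibility tolerance on raw fractions: 0.02.
- Clip-renormalization is applied per Monte Carlo draw, then summarized
  (means, s.d., 2.5/50/97.5 percentiles over feasible draws).
- Test problem sizes: 1,000 truths × 3 reduction levels for the
  forward–inverse identity; 50 instances against a 0.01-resolution simplex
  grid oracle (~1.8×10⁵ points), with agreement asserted to two grid steps
  because the squared-residual metric's anisotropy can prefer a
  next-nearest lattice point; 200 cores × 2,000 draws for coverage; 200
  replicates for flux unbiasedness. The full suite runs in a few seconds
  on one CPU.

## Known limitations

- f_red is prescribed, never inferred; results are always conditional on
  the assumed reduction extent.
- No covariance among endmember parameters or among measurements.
- The default endmember table is a placeholder; quantitative shares from
  real data are only as good as the endmember set supplied.
- The open-system reduction correction is linear in f_red; strongly closed
  systems (Rayleigh behaviour) are out of scope.
- Case 1 (fDNF) and case 2 (cDNF) are alternatives, not jointly resolved:
  the tracers cannot separate two high-SP NO₂⁻-consuming processes in one
  solve.
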