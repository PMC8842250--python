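# Methods

## Kinetic model

Aggregation is modelled as two competing irreversible routes out of the
native monomer N. The low-temperature (LT) route is initiated by slow
chemical modification, `N → I` (first order, rate constant k_I), followed
by bimolecular dimerisation `N + I → NI` (k_NI). The high-temperature
(HT) route is initiated by partial unfolding, `N → D` (k_D), followed by
`D + D → D2` (k_D2) and stepwise growth `D2 + D → D3`, `D3 + D → HMW`
(both drawing on one parameter, k_Dn). Aggregation is treated as fully
irreversible: no reverse reactions appear in the scheme. Two scheme
variants exist: the trimer-capped scheme (6 species, 5 reactions) and the
default HMW scheme (7 species, 6 reactions) in which HMW lumps all
aggregates of four or more monomer units at an accounting size of 4.

Each reaction carries an Arrhenius pair — the rate constant at the 5 °C
reference temperature (units h⁻¹ for first order, M⁻¹h⁻¹ for second
order) and an activation energy in kcal/mol. Parameterising at 5 °C
rather than with a pre-exponential factor keeps the fitted pair weakly
correlated over the 25–75 °C span of typical studies and makes the
storage-temperature rate an (almost) directly fitted quantity.

Concentrations are molar internally; interface concentrations in mg/mL
are converted with a configurable molecular weight (default 150 kDa, an
IgG). The SEC observable maps species to peaks by size only: N, I and D
in the monomer peak, NI and D2 in the dimer peak (mass weight 2), D3 in
the trimer peak (weight 3), HMW at weight 4; mass fractions are reported
in percent and sum to 100.

## Integration

The production integrator is the fixed-step forward-Euler scheme
("linear propagation"): the interval from 0 to the last observation of
each (temperature, concentration) series is divided into 3000 equal
parts and concentrations are updated linearly in each. Model values at
observation times are linearly interpolated from the grid. Euler is
first-order accurate; with the default 3000 steps the deviation from the
adaptive reference integrator stays below 10⁻³ in fraction units
(≤ 0.001 % points per percent of signal) on all presets, and halving the
step roughly halves the error (verified in the test suite). Monomer-unit
mass balance is monitored at every step; a relative drift above 10⁻⁶
aborts the run. A concentration falling below −10⁻¹²·c_total raises a
stiffness error that names the remedy (more steps) instead of clamping
silently.

The reference oracle is SciPy's LSODA with relative tolerance 10⁻¹⁰; it
backs the generator (so that synthetic "experiments" are not produced by
the integrator under test), the convergence tests, and nothing else.
The branched topology is compiled with numba; arbitrary user schemes
fall back to a generic mass-action propagator.

## Global fitting

One Arrhenius pair per reaction is fitted jointly to all subsets. The
objective is the unweighted mean over (temperature, concentration)
subsets of the subset RMS residual in % points across monomer, dimer and
trimer fractions. HMW is excluded by default because it is computed as a
remainder and would double-count error. Averaging per subset first stops
densely sampled high-temperature series from drowning out the sparse
low-temperature ones.

Parameters are optimised as (log₁₀ k_ref, E_a) within box bounds
(log₁₀ k_ref ∈ [−12, 3], E_a ∈ [0, 200] kcal/mol). The optimiser is a
bound-constrained trust-region least-squares pass on residuals scaled so
that the squared norm equals the quadratic mean of subset RMS values —
on clean data this shares its minimiser with the stated objective, and on
noisy data the two agree to well within the statistical uncertainty
(verified on multiple seeds). An optional quasi-Newton polish of the
exact mean-RMS objective is available (`FitOptions(polish=True)`) but off
by default, because Monte Carlo replica refits must share the original
fit's optimisation surface for the σ→0 degeneracy contract (replicas of
an unperturbed dataset must return the original parameters). Multi-start
(default 8 starts, log-uniform in the bounds, seeded) guards against bad
initialisations; with an informed start a single start suffices and is
what the worked examples use.

## Monte Carlo prediction intervals

Every observed fraction is perturbed with i.i.d. Gaussian noise (SD equal
to the SEC measurement error, default 0.1 % points or per-point errors
when stored), rows are clipped at zero and renormalised to 100 % (the
SEC closure the model assumes), and the model is refitted per replica
starting at the original optimum (default 2000 replicas; the acceptance
checks use 200). Replica refits cap the trust-region iterations; since
perturbations are at the noise scale, refits converge in a few steps.
Failed replicas are excluded and counted; more than 10 % failures is an
error.

The band at a storage condition simulates every replica, ranks curves by
the mean absolute deviation of total aggregate fraction from the central
(original-fit) curve, keeps the closest ⌈coverage·n⌉ curves and takes
their pointwise envelope. Curve-wise retention with a pointwise envelope
was chosen over pointwise quantiles so that the band is generated by
actual model trajectories. Calibration on synthetic replicate studies
(50 studies, 200 replicas, generator-matched σ) puts the true 24-month
5 °C fraction inside the 95 % band in ≥ 80 % of studies.

## Pseudo-first-order shortcut

At a single concentration the observable total-aggregate curve is fitted
per temperature with f_agg(t) = f₀ + (1−f₀)(1−e^(−k_app·t)) (f₀ fitted by
default, fixable), apparent rates are regressed as ln k_app on 1/T over
the user-declared LT-only temperatures, and the line is evaluated at the
storage temperature. The reduction is exact only when the LT
intermediate is at quasi-steady state (fast dimerisation, k_NI·c ≫ k_I)
and the HT flux is negligible at the included temperatures. A convexity
diagnostic on the regression residuals (positive extremes, negative
interior, positive quadratic coefficient in 1/T) warns when the upper
temperatures reach into the HT regime; per the platform's philosophy the
user declares which temperatures to include, the package only warns.

## Thermodynamic stability and the phase space

Urea-denaturation curves are fitted with the linear-extrapolation model:
2-state (native/denatured populations from K = exp(−(ΔG_d − m·u)/RT),
linear baselines) or 3-state with a second transition and a flat
intermediate baseline; the first-transition ΔG_d is reported. "No
resolvable transition" (midpoint outside the urea range, or no
improvement over a straight line) is an error, not a silent fit.

Stability propagates to other temperatures via Gibbs–Helmholtz,
ΔG(T) = ΔH_m(1 − T/T_m) − ΔC_p[(T_m − T) + T·ln(T/T_m)]. The phase-space
stability axis is ΔG_d at 25 °C; for each axis value the melting
temperature T_m is solved (ascending branch) with ΔH_m and ΔC_p held at
their defaults (150 kcal/mol, 2 kcal/mol/K — synthetic, typical-IgG-order
values, not measurements). Solving for T_m rather than rescaling ΔH_m
keeps the stability curve monotone-decreasing above room temperature and
ties low 25 °C stability to a low unfolding onset, which is what makes
the LT→HT switch temperature track stability; rescaling ΔH_m instead
produces curves whose stability *rises* from 25 °C to a maximum near
45 °C, an artefact of holding a high T_m fixed for marginally stable
molecules.

Stability couples to kinetics twice. First, the equilibrium non-native
population K/(1+K) with K = exp(−ΔG_d(T)/RT) seeds the HT intermediate D
at t = 0; this dominates below ~3 kcal/mol, where the population is no
longer negligible. Second, the LT initiation constant follows a
log-linear linkage ln k_I(5 °C) = a + b·ΔG_d (b < 0; default slope −0.35
per kcal/mol anchored so that a 6 kcal/mol molecule has the mab1like
rate — a synthetic calibration). Each phase-space cell is simulated until
total dimers (NI + D2) first reach 1 % (cap: ten years; cells that never
get there are NaN), recording the LT share of aggregate mass, the
apparent rate −ln(f_monomer/100)/t₁%, and t₁%.

## Synthetic ground truth

No public mAb stability studies exist, so presets stand in for real
molecules. All numbers are invented but pinned to printed, field-typical
anchors: LT initiation E_a ≈ 18 kcal/mol (chemical modification), HT
dimerisation E_a in the 55–130 kcal/mol range (unfolding-coupled),
visible aggregation within ~2 h at 75 °C versus 1–6 months at 40 °C at
50 mg/mL, and a 36-month 5 °C total aggregate of a few tenths of a
percent. Within those anchors the HT growth constants were placed at the
low end of the activation-energy range with a large 5 °C rate constant:
that is the only region where (i) seeded non-native material aggregates
competitively at 25–35 °C, giving the phase space its steep
low-stability regime, and (ii) the D→D2 step still shapes the observable
40–75 °C kinetics enough to be identifiable from fits.

Presets: `mab1like` (baseline; slow LT dimerisation, k_NI = 0.05
M⁻¹h⁻¹, which makes k_NI identifiable through the curvature of the
40–45 °C transient), `mab3like` and `ltonly` (fast LT dimerisation,
k_NI = 2 M⁻¹h⁻¹ — the quasi-steady-state regime in which the
pseudo-first-order reduction is valid, used by the shortcut-consistency
checks), `lowstab`, `htonly`, and `blind40`. `blind40` shares every HT
parameter with `mab1like` and has the same LT initiation rate *at 40 °C*
but a higher activation energy (25 vs 18 kcal/mol), so the two molecules
produce identical 40 °C stability studies yet differ ~4-fold at 5 °C
after 36 months — the scenario in which accelerated-only screening is
blind and temperature-resolved fitting is not.

The generator simulates each condition with the reference integrator,
samples at per-temperature schedules (dense where aggregation is fast),
optionally repeats time points as replicate injections (offset by 0.001 h
so CSV keys stay unique), adds i.i.d. Gaussian noise per fraction,
clips at zero and renormalises rows to 100 %. What the generator does
*not* emulate: systematic SEC drift or column ageing, non-Gaussian
outliers, partial aggregate recovery from the column, container effects,
or any formulation chemistry — passing tests therefore demonstrate
correctness of the inference machinery under the model's own
assumptions, not robustness to real-world artefacts.

## Problem sizes and numerical choices

The dense estimation design (five temperatures 40–75 °C, three
concentrations, triplicate injections, 12-month horizon at 40/45 °C)
is the design under which noisy-data parameter recovery is tested: with
SEC noise of 0.1 % points it returns log₁₀ k_ref within ±0.1 and E_a
within ±10 % for every reaction, and the 36-month 5 °C prediction within
±15 % relative or ±0.2 % points. The 5 °C rate constant of the HT
dimerisation step is the least identifiable quantity (its per-seed ML
spread is ~0.1–0.2 log units: a 2 % error in its activation energy maps
to ~0.3 log units at the reference after back-extrapolation from
40–75 °C), so recovery at that tolerance is seed-dependent even under
this design; the prediction-relevant quantities are far more stable.
Band calibration uses 50 studies × 200 replicas; the phase-space checks
use small grids (≤ 6×4) at a 30 °C reference row. These sizes keep the
full suite near six minutes while leaving every check statistically
meaningful.

Ties and degenerate inputs: flat or decreasing aggregate series yield
k_app = 0 with a warning rather than an error; phase-space cells that
never reach 1 % dimers are NaN; zero rate constants are allowed in
parameter sets (pathway knockouts) but a reaction must have k_ref > 0 to
be *fitted* (log-space parameterisation).

## Known limitations

* Arrhenius extrapolation assumes temperature-independent activation
  energies; mechanisms with a cold-denaturation contribution to the HT
  route would violate this below ~10 °C.
* The LT pathway terminates at the dimer NI; LT trimers and
  HT monomer-addition steps (N + D) are not modelled.
* The Monte Carlo band quantifies measurement noise only, not model
  misspecification; a wrong mechanism yields a confidently wrong band.
* The 2-/3-state denaturation fit at SNR 50 has an information-limited
  ΔG_d spread of several percent on realistic titration densities;
  ensemble (bias/RMS) recovery is the guaranteed property, not a
  per-curve 5 % bound.
* The stability–kinetics linkage is a synthetic log-linear calibration;
  with real data its slope and intercept should be refitted per platform
  (`fit_linkage`).
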