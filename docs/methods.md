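# Methods

`nucfret` models the disassembly of mononucleosomes as observed by
single-molecule FRET on freely diffusing particles.  This note records the
models, the numerical choices and the limits of what the synthetic-data
tests demonstrate.

## The physical picture

A nucleosome wraps ~147 bp of DNA around a histone octamer: two H2A-H2B
dimers docked onto a (H3-H4)2 tetramer.  With a donor/acceptor pair placed
on the DNA in the dimer-binding region, burstwise FRET resolves four
species: a low-FRET open particle (LF, interdye distance ~86 A), the intact
mid-FRET nucleosome (MF, ~61 A), a transient mid-FRET state MF* (~61 A,
indistinguishable from MF by distance) and a high-FRET state HF (~46 A).
MF* and HF interconvert on tens of microseconds — faster than the ~3 ms
diffusion time, so no burst shows them separately; they appear as one
dynamic population displaced from the static FRET line.  The exchange is
the reversible opening of a dimer:tetramer interface, present in parallel
in the octasome (O_cl <-> O_op) and the hexasome (H_cl <-> H_op); slow loss
or uptake of one H2A-H2B dimer couples the two fast equilibria and makes
the apparent rates depend on total nucleosome concentration.

## Core relations

* Foerster relation `E = 1/(1 + (R/R0)^6)`; R0 = 55.6 A (Alexa488-Alexa594)
  or 52.0 A (Alexa488-Cy5), kappa^2 = 2/3, donor-only lifetime
  tau_D0 = 4.0 ns.
* Distance observables: mean interdye distance `<R_DA>` (lifetime
  analysis), FRET-averaged distance `<R_DA>_E` (intensity analysis) and
  mean-position distance `R_mp` (geometric/AV modelling) are interconverted
  with calibrated cubic polynomials
  (`<R_DA>_E = 15.3230 + 0.592830 r + 0.0017537 r^2 - 0.0000032013 r^3`);
  other coefficient sets plug into the same mechanism.
* Two-state exchange: relaxation time `t_R = 1/(k_f + k_b)`, equilibrium
  constant `K = k_f/k_b = x_open/x_closed`.

## Synthetic photon bursts

The generator emulates a confocal MFD experiment at the level the analysis
assumes, not at the level of optics:

* molecule transits: exponential burst durations (mean 3 ms, truncated to
  0.5-10 ms), exponential gaps (mean 50 ms), constant in-burst brightness
  (default 50 photons/ms).  No diffusion-profile modulation: photon
  distribution analysis operates on counts in fixed time windows, where
  profile effects average out.
* photons: emitting state from a per-burst species draw (interdye distance
  redrawn from the species' Gaussian distribution, default half-width
  sigma = 2 A) or from a continuous-time two-state trajectory for dynamic
  bursts; red-detection probability `gamma E / (gamma E + 1 - E)` plus
  crosstalk; polarization split by a per-species steady-state anisotropy;
  donor nanotimes exponential with `tau_D0 (1 - E)` folded into the
  15.625 ns excitation period (the fold makes the truncated-exponential
  likelihood exact); background 0.35 kHz per spectral channel with uniform
  nanotimes across the whole acquisition.
* donor-only molecules are emulated by tagging a fraction of bursts
  (default 10%, not printed in the source study) rather than by pulsed
  interleaved excitation; stoichiometry is computed from the tag.

Not emulated: triplet blinking, acceptor dark states, detector dead time,
IRF width.  Passing tests therefore validate the estimators against the
model they assume; they do not certify robustness to these instrumental
effects.

## Burst analysis

Bursts are maximal photon runs with inter-photon gaps < 100 us and >= 60
photons (the classic threshold criteria; values chosen to match common MFD
practice and validated against simulator ground truth).  Per burst:
background/crosstalk-corrected E (not clipped to [0,1]; negative corrected
signals only flag the record), fluorescence-weighted mean donor lifetime
(mean green nanotime minus the nanotime origin, estimated as the pooled
histogram mode when requested), steady-state anisotropy
`r = (N_par - N_perp)/(N_par + 2 N_perp)`, and stoichiometry when
acceptor-excitation counts exist.  Sub-ensemble donor decays are fitted by
maximum likelihood with 1-3 truncated exponentials plus a flat background;
the fit refuses more components than ~1000 photons each can support.

## FRET lines

Static line: for each centre distance, E and `<tau>_F` are averaged over a
Gaussian distance distribution (default linker width 6 A; 0 gives exactly
`E = 1 - tau/tau_D0`).  Because `<tau>_F = tau_D0 <q^2>/<q>` with
`q = 1 - E(R)`, broadening moves the line toward larger lifetime at fixed
E.  Dynamic line: photon-weighted mixture moments between two states; a
population between the endpoints lies right of the static line, the
burstwise signature of sub-millisecond exchange.

## Dynamic photon distribution analysis

Bursts are cut into non-overlapping windows (default 1 and 2 ms) from the
burst start; windows with < 20 photons are discarded.  The observable is
the raw red fraction after mean-background subtraction, in 40 bins on
[-0.1, 1.1].

The occupancy time T1 of one state over a window T for a stationary
two-state Markov process has two atoms (no-transition paths, weights
`p_a exp(-k_ab T)` and `p_b exp(-k_ba T)`) and a continuous density

```
f(T1) = exp(-k1 T1 - k2 T2) [ (p1 k1 + p2 k2) I0(z)
        + (p1 sqrt(k1 k2 T1/T2) + p2 sqrt(k1 k2 T2/T1)) I1(z) ],
z = 2 sqrt(k1 k2 T1 T2),  T2 = T - T1,
```

evaluated with exponentially scaled Bessel functions for numerical safety
and checked against closed-form moments (`E[x] = p_a`,
`Var[x] = 2 p_a p_b (T/k - (1 - e^{-kT})/k^2)/T^2`) and Monte-Carlo
trajectories.  The grid is adaptive (>= 240 nodes, concentrated around the
mean in the fast-exchange regime) with atom weights kept analytic.

Given a window's fluorescence count F, the red count is binomial at
p_R(E'), integrated over each species' Gaussian distance distribution
(Gauss-Hermite, 16 nodes static / 5 nodes per exchanging state) and over
the occupancy density (apparent efficiency `x E_a + (1-x) E_b`, equal
brightness assumed), then convolved with the per-channel Poisson
backgrounds (truncated at the 0.9999 quantile).  The count distribution
P(F) is taken from the observed windows (background-mean subtracted,
compressed to <= 60 support points), standard PDA practice.  Mixture split
probabilities are accumulated on a 301-point grid in p by linear
interpolation before the binomial convolution; this turns each model
evaluation into a handful of small matrix products.

Fitting minimizes Poisson-weighted chi-square jointly over all window
lengths (lmfit Levenberg-Marquardt; rates parameterized as log10).  An
identifiability guard refuses rate fits with free distances on a single
window length.  Because the millisecond windows average the microsecond
exchange almost completely, the surface has long valleys in
(distance, rate) space; when rates are free, the local fit is followed by
a coarse grid scan of the dynamic parameters (distance x both rates, all
other parameters frozen) and a final polish, keeping the better solution.

A single 1+2 ms fit of ~25k bursts determines the forward rate to roughly
10-30% (1 sigma) — the reproduction study therefore averages four
independent simulated measurements, mirroring the experimental protocol of
averaging several measurements per condition.  Recovery of the HF distance
is good to well under 1 A after averaging.

## Four-state kinetics

Steady-state populations of {O_st, O_cl, O_op, H_cl, H_op} follow detailed
balance along the reversible chain; the dimer-release step couples the
octasome and hexasome weights through the free-dimer concentration
`[D] = c_total x_H`, solved by damped fixed-point iteration to 1e-12.
Apparent exchange rates are population-weighted means of the two opening
(closing) rate constants over the closed (open) dynamic subpopulations —
with equal brightness assumed, photon and molecule weighting coincide.
Rates from the 150 mM parameter table reproduce the printed relaxation
times and equilibrium constants and give apparent rates and mean dynamic
efficiency that fall monotonically with total concentration, the
experimental signature of dimer-release coupling.  Concentration-series
fits free the two rate pairs and K_dis (log-parameterized, box-constrained
to the published bounds); salt-series fits share a single sigmoid midpoint
between the forward and backward rates, and species fractions obey
`x_MF* = (1 - x_LF - x_MF)/(1 + K)`, `x_HF = (1 - x_LF - x_MF) K/(1 + K)`
exactly.

## Geometric opening model

The DNA is an ideal left-handed superhelix (radius 41.9 A, pitch 25.9 A,
1.67 turns over 147 bp) with the dyad at sequence position -6; dye anchors
at +41 (donor) and -53 (acceptor).  One hinge per dimer:tetramer interface
sits at +/-2.6 DNA helical turns from the dyad; DNA distal to an open
interface in a hexasome continues straight along the hinge tangent with
unchanged pitch.  Opening by theta rotates the distal DNA+dimer segment
rigidly about an axis through the hinge perpendicular to the local DNA
tangent; the axis direction within that plane (its tilt) and the opening
sense are per-side calibration parameters.  A strictly horizontal axis
cannot reproduce the published opening pattern: single-side and double
opening are additive to first order and the quadratic term only increases
the distance, so no horizontal-axis parameterization makes the double
opening reach the high-FRET band at ~20 degrees while single-side opening
stays out of it — the tilted axis resolves this by letting the two sides'
large perpendicular motions cancel in the double opening.

The dye offset vectors (tangential, radial, axial in the local frame) are
effective parameters, not physical linker dimensions: together with the
axis tilts they are calibrated once so that the three theta = 0 reference
structures give 61/58/56 A (intact, alpha-hexasome, beta-hexasome) and the
opening scans show the published crossing pattern.  With the frozen
defaults: double-opening scenarios first enter the 46 +/- 1 A band at
16.5-20 degrees; single-interface curves never reach it below 90 degrees
and pass the 57 +/- 1 A band at ~13 degrees.  `calibrate_offsets` re-solves
the reference targets from any starting geometry.  R_mp values are mapped
to `<R_DA>_E` through the polynomial mechanism (the mean-distance
coefficient set by default; the calibration absorbs the residual scale
difference).

## Accessible-volume dye model

Single-radius AV: dye sphere radius R_dye on a linker of length L_link and
width w_link (Alexa: 20/4.5/1.5 A; Cy5: 22/4.5/3.5 A).  Accessible lattice
points (default spacing 0.9 A; 1.2-1.5 A in tests for speed) are found by
Dijkstra flood-fill (26-connected, Euclidean edge lengths), honouring
linker threading: path clearance uses vdW + w_link/2, dye placement uses
vdW + R_dye, and atoms within 2 A of the attachment are ignored.  Cloud
distances: R_mp between mean positions; `<R_DA>` and `<R_DA>_E` from 1e5
uniformly sampled point pairs (fixed seed).  Validated against analytic
oracles (free-space sphere, half-space hemisphere centroid 3L/8, far-field
collapse of all three observables).  Orientation effects beyond
kappa^2 = 2/3 and dye-surface sticking are out of scope.

## Problem sizes and reproducibility

All randomness flows from one master seed per run; sub-streams are derived
deterministically.  The bundled reproduction script simulates 4 x 25,000
bursts for the exchange-rate recovery and 100 replicate 12-point titration
curves; the test suite uses 3 x 25,000 bursts for the same check and
smaller streams (300-1500 bursts) for distributional comparisons.  These
sizes were chosen to keep the estimator spread a few times below the
respective reproduction tolerances.

## Known limitations

* The dynPDA brightness of exchanging states is fixed equal; unequal
  brightness is a model flag but untested.
* No pulsed interleaved excitation: stoichiometry exists only for tagged
  synthetic data.
* The geometric model is an effective idealization; its offsets are
  calibration parameters and single-side curves cross the mid-FRET band a
  few degrees earlier than the published reading (~13 vs ~15-20 degrees).
* The distance-conversion polynomial presumes dye-cloud ensembles of the
  original calibration width; synthetic spherical clouds show a ~2 A
  systematic offset, growing beyond ~70 A.
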