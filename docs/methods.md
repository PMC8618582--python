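# Methods

This note documents the model, the numerical choices and the synthetic
study conditions behind the package, and what its tests do and do not
establish.

## Chain model and units

A chromosome is a bead-spring chain, one bead per 100 kb.  Internal units
are the bead diameter d, the thermal energy kT and the picosecond; the
physical calibration (bead mass 100 amu, d = 1 nm in the integrator,
225 nm physically, 5500 ps per real hour, T = 300 K) gives a
Lennard-Jones time tau = d sqrt(m/kT) = 6.33 ps and a friction
coefficient 0.5/tau ~ 0.1 per ps.  In internal units the effective bead
mass is tau^2 = 40.1, so that tau is reproduced exactly.

Non-adjacent beads interact through the WCA excluded-volume potential
(strength U0_ev = 1 kT for all pairs — the order-kT value that also
underlies the tau estimate) and the shifted, truncated Lennard-Jones
attraction with per-pair depths U0_attr(i,j), cut at r_cut = 3 d where
the unshifted tail is 0.55% of the well depth.  Read literally, the two
branches make the pair energy discontinuous at the WCA cutoff when
U0_attr differs from U0_ev: we keep the piecewise form and use the
analytic in-branch derivatives as forces, so the measure-zero
discontinuity exerts no impulsive force.  (At the branch point itself the
force happens to be continuous, because it sits at the Lennard-Jones
minimum.)

Adjacent beads are tied by a harmonic bond of rest length d.  The bonded
interaction is a modelling choice (harmonic, stiffness 200 kT/d^2): stiff
enough to keep bond-length fluctuations below 0.1 d at kT = 1, soft
enough not to dominate the stable time step.

## Integration

Dynamics are integrated with the BAOAB Langevin scheme at kT = 1,
friction 0.1 per ps.  The default time step is 0.1 ps (~tau/63); stability
scans over 3e5-step runs showed that 0.2 ps intermittently blows up on
excluded-volume collisions while 0.1 ps is robust.  Deep attraction wells
accelerate inter-bead collisions, so when a potential field is supplied
without an explicit integrator configuration the step is scaled as
0.1 ps / sqrt(max(1, U0_max)); the 9.34 kT homopolymer globule thus runs
at ~0.033 ps.  Gaussian noise is pre-generated in chunks from a seeded
numpy generator, making every trajectory bit-reproducible on one platform.
Kinetic-energy estimates from BAOAB full-step velocities at these step
sizes read ~20% low; configurational sampling, which is what the contact
statistics use, is the quantity of interest.

## Ensemble protocol

An ensemble is produced in three phases: (1) a self-avoiding coil is
grown by chain growth (retry cap 1000 per bead, restart with an
incremented seed) inside an impenetrable spherical cage of radius 14 d;
(2) the coil is equilibrated with excluded volume only until the radius
of gyration plateaus — windowed means over 10^4 steps (5e3 in the
reduced-scale fits), stop when consecutive windows agree within 1%;
(3) attractions are switched on, the cage is removed, and after a
collapse burn-in of 4000 ps conformations are sampled every 50 ps.
Consecutive samples are correlated at this stride; for ensemble-averaged
contact maps this inflates variance but not bias, and the iterative fit
resamples every iteration.  For small chains the 1% plateau criterion is
occasionally strict relative to the natural Rg fluctuations; equilibrate
reports non-convergence with the trace rather than failing.

## Inverse potential fit

The fit starts from a uniform 1.2 kT field and iterates: sample an
ensemble (size growing from 200 to the configured maximum), build the
relative contact map (counts normalised over unmasked pairs at genomic
separation s >= 2), compare with the target by Pearson correlation over
the unmasked upper triangle, and update each unmasked pair by a fixed
step of 0.05 kT in the direction of the discrepancy, clamped at zero
(negative depths would redefine the potential).  The step is halved when
the correlation drops (damped sign update, floor at 1/16 of the initial
step); the loop stops after 3 iterations without improvement beyond 1e-3.
Centromeric and non-mappable bins are masked from comparison and update;
non-mappable attraction rows are filled with the mean of the nearest
mappable flanking rows (the single nearest row at a chain end).  One
equilibrated excluded-volume coil is shared by all iterations and fresh
noise seeds provide independent ensembles — resampling rather than
ensemble reuse.

At the recovery scale used throughout (N = 120, K = 300), the sampling
noise of two independent K = 300 ensembles from the same field limits the
map correlation to ~0.89; the fit typically reaches 0.93-0.94 against a
fixed target because the sign update also tracks the target's noise.
Full-scale chromosomes would require cluster-scale ensembles and are out
of scope.

## Damage model

IR lesions: Poisson count with mean N·alpha·D·L, uniform positions;
alpha = 8.2e-9 /Gy/bp, L = 1e5 bp, so the per-subunit probability is
8.2e-4 per Gy (0.0041 at 5 Gy) and the chr18 chain carries on average
0.074-11.2 lesions over 0.1-15 Gy.  Spontaneous lesions: independent
per-bead Bernoulli with profile Gamma_sp(j), interpreted as a probability
per chromosome per exposure snapshot (the assay time base is left
phenomenological).  The nuclease lesion sits at the bait bead with
probability 1.  Several hits on one bead collapse to a single damaged
subunit; when mechanisms coincide the origin label follows the precedence
nuclease > IR > spontaneous (coincidences are O(p^2) at the doses
considered).

Coarse breakpoint profiles are resampled to the 100-kb grid with an Akima
spline at bin centres, clipped at zero and rescaled to conserve the total;
a declared high-resolution (25-kb) interval is aggregated and spliced in
afterwards.  Gamma_sp reconstruction iterates a multiplicative update
Gamma' = Gamma·(target/simulated), clipped to [1e-8, 1], with the Pearson
stopping criterion evaluated on 1-Mb-smoothed 200-kb profiles; because
the simulated profile is linear in Gamma at D = 0, the update lands on
the target in essentially one step wherever the bait has contact support,
and loci without support stay at their prior.

## Aberration statistics

Contact-first: per cell, two independently drawn conformations and
independent damage; every contacting damaged pair converts with
probability P_c-e, symmetric and asymmetric exchanges equally likely.
Each contacting pair is an independent trial, so one lesion may in
principle join several exchanges; at the fitted P_c-e values double use
is negligible.  The HTGTS-comparable profile counts bait-involving
exchanges at the non-bait partner; all origin-pair channels are retained
in the decomposition.  The decoupled estimator evaluates the expectation
2 P_c-e q_cont(i*,j)[P_DSB + Gamma_sp(j)] directly and is the default
for population-scale numbers (the "10^8-cell" average); the full
Monte Carlo is kept for fixtures and cross-checks and agrees with the
expectation within Monte-Carlo error.

Dose response decomposes totals by channel: nuclease-spontaneous is
dose-independent, nuclease-IR linear, IR-IR quadratic.  Chi-square
goodness of fit is sum (sim-exp)^2/sim over compared bins, with the 1-Mb
window around the bait excluded (plus any declared uncertain regions);
since the simulated profile is linear in P_c-e, the grid search has the
closed-form optimum p* = sqrt(sum(e^2/g)/sum(g)), used as an internal
cross-check.

## Distance-distribution route

psi_ij(r) is histogrammed on radial bins of width 0.05 d — chosen so the
1.2 d contact radius falls on a bin edge — and normalised per chromosome
by K and by midpoint-rule shell volumes 4 pi r_mid^2 dr, which makes the
per-pair normalisation and the psi -> q_cont identity close exactly in
the same quadrature.  phi = psi·[P_DSB + Gamma_sp] and the breakpoint
frequency is the radial integral to R_cont,CA times 2 P_c-e.  With
R_cont,CA = R_cont this route coincides with the contact route to
rounding error; R_cont,CA is exposed as a parameter but has no distinct
default.

## Breakage-first kinetics

Per cell and chromosome copy, a conformation is drawn, damage sampled,
and the damaged-pair distances tracked through Langevin dynamics from 0
to t_max = 18000 ps (3.3 h), with contact checks every 5 ps (3.3 s).  A
contacting pair converts with probability V_c-e·dt per check — one
Bernoulli trial per step while in contact (rate semantics), including at
t = 0, so the contact-first mechanism is the t = 0 part of the process.
A pair whose contact episode ends without conversion is retired
(re-formed contacts neglected), lesion number is constant (no repair),
and damaged loci move like intact ones.  First-contact times are tallied
by initial-distance class ({<=1.2, 1.2-2, 2-3, 3-6, >6} d).  A `frozen`
flag skips the integration for closed-form limit checks: with static
positions the conversions per initially contacting pair are geometric,
1-(1-V dt)^(n+1).

Conformational-transition scenarios combine profiles from an original and
an altered ensemble (attractions changed only on the bait row, scale
factor supplied by the user — no canonical values exist): either a
weighted sum of two contact-first profiles with the weight fitted by
chi-square, or contact-first on the original plus breakage-first on the
altered structure.

## Synthetic study conditions

The fixture generator forward-generates everything the tests need: a
chromosome with a centromere over the first ~10% of beads, the bait at
3/4 of the chain (the chr18 proportion) and two non-mappable bins; a
truth attraction field with two diagonal blocks (1.8 and 1.5 kT) on a
1 kT background, low-frequency sinusoidal texture and 0.05 kT noise,
clipped at zero; a spontaneous profile with a smooth gradient plus a
hotspot near the bait (max ~0.025); dose 5 Gy and P_c-e = 0.003.  Scales
are N = 50/K = 120 ("tiny") and N = 120/K = 300 ("small") — sizes chosen
so the complete recovery suite runs on one CPU in minutes, with N^2 force
evaluation the limiting cost.  Dense/loose comparisons use the 9.34 kT
homopolymer globule against the self-avoiding coil on the tiny chain;
the lesion-dynamics comparisons use a 6000-ps observation window, a
15-Gy dose and a uniform 0.06 spontaneous probability so that enough
damaged pairs populate every initial-distance class, and some statistical
tests raise P_c-e above the fitted values purely to tame Poisson noise —
the scaling laws under test are independent of these scales.

What passing tests show — and do not.  The synthetic targets are
generated by the package's own forward model, so the recovery suite
establishes the correctness and invertibility of the machinery
(round-trip identifiability), not the biological adequacy of the model;
real Hi-C maps carry coverage biases, unmappable structure and
inter-chromosomal context that the generator does not emulate.  Absolute
breakpoint frequencies on the small synthetic chains are orders of
magnitude below the full-scale chromosomes simply because the chains are
shorter; ordering and scaling properties, not absolute values, are the
tested quantities at this scale.

## Known limitations

* Single chains only: no inter-chromosomal interactions, nucleolus or
  lamina, and no trans-translocations.
* No DSB repair kinetics; repair enters only implicitly through the
  fitted conversion parameters.
* The sign-update fit has no convergence guarantee and can track target
  noise; no maximum-entropy or gradient alternative is provided.
* Whether conversion trials should be per contact step or per contact
  episode is not observable from the data the model targets; per-step
  rate semantics were chosen.
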