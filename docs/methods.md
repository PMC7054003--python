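# Methods

`myovstep` models the stepping of myosin V on filamentous actin as
structurally constrained diffusion: the detached head searches for
binding sites while the two lever arms ("legs") remain connected at a
joint with a preferred inter-leg angle.  The package has three routes
to the same physics — a semi-analytical mean-field density feeding a
closed-form kinetic network, a Metropolis sampler of a discretized
two-leg chain, and an overdamped Langevin (Brownian-dynamics) engine —
so each approximation can be checked against a more microscopic route.

## Geometry

Binding sites on the actin double helix sit at
r_n = (R(cos φ_n − 1), R sin φ_n, n·Δz/2) with R = 5.5 nm,
Δz = 72/13 nm, φ_n = −12πn/13, n ∈ ℤ.  The bound head occupies n = 0;
the half-helical sites n = ±13 are at z = ±36 nm and the full repeat
n = ±26 at ±72 nm.  Each site carries a radially outward normal with
azimuth φ_n; a head can only bind a site it approaches anti-parallel
to that normal within a half-width δφ_ac (default 55.6°, a ~111° full
window).  The lattice extends to |n| ≤ 39 by default, beyond the 90 nm
maximal reach of the longest (8IQ) construct.

## Mean-field free-head density

Each leg is a semiflexible polymer of contour length L (25/35/45 nm for
the 4IQ/6IQ/8IQ constructs) and persistence length l_p = 350 nm, so the
flexibility parameter t = L/l_p ≈ 0.07–0.13 is deep in the stiff
regime.  The density of the searching head at position **r** relative
to the bound head is assembled from:

* **Leg extension.**  The stretch loss w = 1 − r/L of each leg follows
  the weakly bending normal-mode density
  f(w) = Σ_k 2(−1)^{k+1} λ_k e^{−λ_k w}, λ_k = π²k²/t
  (mean w = t/6, matching the exact worm-like chain to O(t²)).  For
  small w the series is evaluated through its Jacobi-theta dual.  This
  form was chosen over interpolation formulas with an essential zero at
  full extension because the near-extension tail controls which lattice
  sites near the maximal reach 2L are accessible, and the chain oracle
  shows the mode-sum tail is the right one.

* **Power stroke.**  The bound leg's end-to-end direction û₁ carries a
  von Mises–Fisher weight exp(𝒯 û₁·û_c), where û_c points θ_c = 65°
  from the filament axis in the x–z plane and
  𝒯 = 1 + 20ν_c/(20 + 7κν_c) (κ = L/l_p) is the power-stroke
  effectiveness (𝒯 ≈ 26.75 at ν_c = 261).  𝒯 plays the role of an
  orientational concentration: it combines the anchor-tangent
  constraint ν_c with the orientational diffusion accumulated along a
  stiff chain (for small angles 1/𝒯 ≈ 1/ν_c + κ/3).

* **Load.**  A force **F** applied at the joint adds the aligning field
  βFL **F̂** to the orientational field 𝒯û_c, giving the renormalized
  pair 𝒯′ = |𝒯û_c + βFL F̂| and û_c′ = (𝒯û_c + βFL F̂)/𝒯′.  The force
  direction convention is F̂ = (sinθ_F cosφ_F, sinθ_F sinφ_F, −cosθ_F),
  so θ_F = φ_F = 0 is a rearward pull.  β uses k_BT = 4.1 pN·nm
  (T ≈ 297 K; configurable).

* **Joint constraint.**  The angle θ_J between the two leg end-to-end
  vectors is weighted by exp{−μ_c[1 − cos(θ_J − θ_p)]}, default
  μ_c = 5 k_BT, θ_p = 83°.  A quartic variant
  μ_c[Δθ²/2 + h₃Δθ³/6 + h₄Δθ⁴/24] is available; for anharmonicities
  that do not create a spurious minimum within |Δθ| ≲ π/2 the resulting
  density is nearly indistinguishable from the cosine form (KL < 0.05).

* **Volume exclusion.**  The head–head distance r is reweighted by
  exp[−(d_V/r)⁶], with d_V = 20/27.5/35 nm per construct.  The value is
  reproduced independently by the BD route: sampling the chain with
  explicit 5 nm inter-leg bead repulsion and fitting the (d_V/r)⁶ form
  to the head-pair distance distribution returns 20.5/28.4/36.8 nm.

The density is evaluated by deterministic Gauss–Legendre quadrature
over (r₁, û₁) with the free-leg vector density and the Boltzmann
factors applied pointwise; the normalization (including exclusion)
reduces exactly to a 3-D integral over (r₁, r₂, θ_J) because every
coupling depends on the two leg vectors only through lengths and the
inter-leg angle.  Default orders (14 radial × 160 polar × 60 azimuthal
nodes) leave the dominant site densities converged to well under 1%
(doubling changes them < 0.5%); site densities are always computed by
direct quadrature at the site coordinates, never by grid interpolation.
Full 3-D grids (default 2.5 nm spacing) are for visualization and
oracle comparisons only — a 0.5 nm grid of the same extent would be
~3×10⁷ points and is unnecessary for any computed observable.

## Kinetics

Binding to site n is diffusion-limited onto a capture radius a with the
orientational window folded into the joint density:
tfp_n = [4πaD_h 𝒫(r_n, window)]⁻¹, with D_h = 5.7×10⁻⁷ cm²/s.  Sites
with window density below 10⁻¹² nm⁻³ are treated as unreachable.
Competing Poisson processes give the per-site probabilities

  P_T^n = b_n t_d1² / [tfp_n (1 + r_T t_d1)(t_d1 + t_h)],
  P_L^n = b_{−n} t_d1 / [tfp_n (1 + r_L t_d1)],

where r_T = Σ b_n/tfp_n, r_L = Σ b_{−n}/tfp_n, b_n = 1 for n > 0 and
b = 0.045 behind the bound head (the recovery stroke disfavours
backward binding after trailing detachment; mirrored for the leading
head, which keeps its ADP and needs no hydrolysis).  Trailing
detachment happens with probability g/(1+g), leading with 1/(1+g),
gating ratio g = t_d2/t_d1 = 8.  Termination is the complement, so the
five pathways sum to one exactly.  Mean binding times are
t_T = 1/r_T + t_h and t_L = 1/r_L.

Step distributions live on the half-subunit grid z_n = nΔz/2: the
head-separation distribution (gating-weighted mixture over branches,
renormalized over n > 0) is convolved with the per-branch site
distributions; the combined distribution is the gating-weighted mixture
carrying total mass 1 − P_t.  Run statistics:

  z_run = ½ Σ z_n P(z_n) / [P_t(1 − P_t)],    ⟨N_run⟩ = 1/P_t,
  t_run = [Σ-weighted (t_wait + t_T/L)] / [P_t(1 − P_t)],
  t_wait = g t_d1/(1+g).

Two printed-formula ambiguities were resolved as follows and verified
against kinetic Monte Carlo: (i) the combined distribution enters the
run length unnormalized (mass 1 − P_t), so z_run = ½⟨step⟩⟨N_run⟩;
(ii) the run-time branch sums carry the gating weights g/(1+g) and
1/(1+g), the only reading consistent with v_run = z_run/t_run and
⟨N_run⟩ = 1/P_t.  The closed-form binding times are unconditional
(they ignore the rare termination during a search); the Monte-Carlo
simulator implements the true competing-risks process, which differs
from the closed forms by O(t_diff/t_d1) ≈ 0.3% at zero load.

## Stochastic cross-validators

**Metropolis chain oracle.**  Both legs are discretized (default 14
bonds/leg) with worm-like-chain bending k_bend = l_p/ℓ per joint, the
anchor tangent constraint ½ν_c(t̂₀ − û_c)², the joint potential on the
end-to-end vectors, the (d_V/r)⁶ head repulsion, and an explicit
−β**F**·r_joint load term (no rigid-vector renormalization — the force
acts microscopically).  Bond lengths are held rigid and only pivot
rotations are proposed, because harmonic bonds make the chain slightly
extensible and put O(10⁻³) probability beyond the inextensible-theory
reach limit 2L.  Samples are deterministic per seed; an integrated
autocorrelation check warns about under-equilibrated runs.

At zero load the mean-field density agrees with the oracle to
KL ≈ 0.008–0.011 on 8 nm grids for μ_c ∈ {0, 3, 5, 12} (model densities
bin-averaged; evaluating at bin centers alone fabricates KL ≈ 0.3 from
bins straddling the reach boundary).  At 2 pN backward load the
divergence rises to ≈ 0.11: the rigid-vector load renormalization
overestimates the backward tilt of the bound leg by ~8° at βFL ≈ 10
and ignores its ~1 nm force-induced contraction, while the chain bends.
The printed closed form is kept; the discrepancy is a documented
approximation of the analytic theory, not an implementation error.

**Brownian dynamics.**  The same Hamiltonian with harmonic bonds
(25 k_BT/nm², 7 bonds/leg at the 5 nm structural granularity) is
integrated by overdamped Euler–Maruyama with analytic forces,
dt = 0.05 ns, free-draining beads at the head diffusivity.  Binding
uses the full conical acceptance criterion (angle between the free leg
and the site normal below δφ_ac), capture radius a, stochastic
hydrolysis gating, binding penalties with site blocking until the head
leaves the capture shell (approximating partially absorbing kinetics),
and bound-head detachment.  A bond-stretch monitor aborts unstable
integrations.  The global arc-swing mixing time is ~0.5 ms of
simulated time, so equilibrium ensembles are seeded from decorrelated
Metropolis configurations, and search trajectories in the test suite
use an enlarged capture radius (stated per test) to stay within CI
budgets; enlarging a erodes the separation of timescales underlying
tfp = [4πaD_h𝒫]⁻¹, which bounds how far the BD/analytic comparison can
be pushed cheaply.

## Fitting

Step-histogram fits minimize the summed KL divergence between supplied
(or synthetically generated) forward-step histograms and the model
prediction after 1 nm Gaussian localization noise and identical
binning (default 5 nm; the experimental bin width is not recoverable
from the text, so it is exposed, not hard-coded).  Empty bins receive
10⁻⁶ pseudo-mass.  The optimizer is bounded Nelder–Mead from
Latin-hypercube starts with sequential small-simplex polish restarts;
the (θ_c, θ_p) direction is a curved, shallow valley — at 500
steps/construct the per-fit scatter is several degrees and a secondary
basin ~10° away in θ_p is sometimes statistically indistinguishable,
so recovery is assessed as bias across seeds (≈1° in tests), not per
fit.  Force-response calibration solves for (b, a) — optionally 𝒯,
with (l_p, ν_c) movable along constant-𝒯 curves — matching the stall
force and zero-load run length (defaults 1.9 pN, 1.3 µm) by bounded
least squares; mutant datasets are equally weighted by default.

## What the synthetic fixtures do and do not establish

Fixture histograms are multinomial draws from the model's own step
distribution plus Gaussian localization noise.  Green recovery tests
therefore establish estimator consistency (the fitting machinery
refinds known parameters from finite data), not that the model
describes real myosin data; no experimental histograms ship with the
package.  Published observables reproduced from the fitted parameter
set alone — stall force ≈ 1.9 pN coinciding with the unit step ratio,
zero-load run length ≈ 1.3 µm, trailing binding time 1.6 → 26 ms under
load, the bimodal diffusion contour appearing only for μ_c > 0 — are
computed from scratch by `scripts/acceptance.py`.

## Known limitations

* Sub-stall regime only: no power-stroke reversal pathways, so
  behaviour above ≈ 2.5–4 pN is not described.
* The load renormalization is the printed rigid-vector approximation
  (see oracle comparison above).
* Constant bound-head detachment rate, independent of load.
* No hydrodynamic coupling, no nanoparticle-label drag, static actin.
* The forward-step width narrows with μ_c about half as fast here
  (~0.05 nm per k_BT) as the published ~0.1 nm per k_BT; the published
  closed-form density (whose appendix derivation is not part of the
  source text) evidently distributes width between sites slightly
  differently.  The 8IQ first convolved peak lands at 82.5 nm versus
  the published ≈ 78 nm for the same reason (the model weights the
  n = 15 target slightly above n = 13/14 combinations at L = 45 nm).
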