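# Methods

This note documents the models, estimators, numerical choices and
known limitations of `torves`.  Units throughout: energies kJ/mol,
angles radians, temperatures K, distances nm; k_B = 0.0083145
kJ/mol/K, so kT ≈ 2.494 kJ/mol at the default 300 K.  Time is in
arbitrary step units: the Langevin surrogate carries none of the
physical timescales of an atomistic engine, so no quantity here should
be read as a rate in nanoseconds.

## Model potentials

A landscape is a sum of inverted product-von-Mises wells on the torus
[−π, π)²,

U(z) = −Σᵢ dᵢ · exp(cᵢ [cos(Φ−Φᵢ) + cos(Ψ−Ψᵢ) − 2]),

optionally plus explicit Fourier terms, shifted so min U = 0.  The
kernel is smooth and exactly periodic, the gradient is analytic, and
an isolated well of depth d sits d below the surrounding plateau, so
barrier heights are calibrated by construction.  The default basin
layout is schematic — middle S_m = (0,0), horizontal S_h = (π,0),
vertical S_v = (0,π), corner S_c = (π,π) — and configurable; the true
basin coordinates of any particular protein system are not encoded.

Two "phantom" presets exist solely for pipeline self-consistency
tests: a resting-form-like surface (S_h deepest, amplitude 140 kJ/mol,
S_m 25 kJ/mol above it; S_v 75, S_c 85, concentration 6) and an
illuminated-form-like surface (S_m deepest, amplitude 125; S_h 123,
S_v 65, S_c 55).  They mimic the *scale* of phytochrome
photoisomerization landscapes, not their shape.

With concentration 6, the Fourier content of a well decays like the
Bessel ratio I_k(6)/I_0(6) ≈ 6·10⁻⁴ at k = 10, so an order-10 bias
basis can represent the phantom surfaces to a few tenths of a kJ/mol.

## Langevin propagator

Overdamped Euler–Maruyama with wrap-to-domain:

z ← wrap(z − βD ∇(U+V) Δt + √(2DΔt) ξ),  ξ ~ N(0, 1)².

Defaults D = 0.1 rad²/time, Δt = 0.01: per-step noise 0.045 rad and,
on the steepest phantom gradients (|∇U| ≈ 200 kJ/mol/rad), a
deterministic drift of ≈ 0.08 rad/step, keeping the discretization
bias of the stationary law well below the statistical noise of the
estimators.  A stability guard refuses parameter sets whose single-step
drift could reach π and names the largest usable Δt.  All randomness
flows through a seeded generator; equal seeds give bitwise-equal
trajectories.  The unbiased chain's stationary law is tested against
analytic two-well Boltzmann occupancies (blocked standard errors).

## VES optimisation

The bias is a real cos/sin product Fourier series of order N
((2N+1)² coefficients; N = 10 ⇒ 441).  For the uniform target the
gradient of the variational functional reduces to
∂Ω/∂α_k = −⟨f_k⟩_batch + [k = const], where the batch is all states
visited during the preceding stride (default 1000 steps), and the
constant coefficient never moves.  Updates use learning rate μ = 0.1.

Three iterate-averaging modes are implemented; the choice matters at
desk scale:

* **suffix** (default): plain SGD drives the dynamics; the reported
  bias is the running mean of the iterates from mid-run onward.
  Measured behaviour: iterates fluctuate tightly around the optimum
  (sd ≈ 0.5 kJ/mol per coefficient), and suffix averaging removes both
  that noise and the ramp pollution that a from-the-start mean decays
  only like 1/t.
* **full**: classic iterate averaging in which the running mean also
  acts on the dynamics.  At desk scale this feedback loop is weakly
  damped — the averaged coefficients oscillate around the optimum with
  errors that do not shrink monotonically over thousands of updates —
  so it is not the default here.
* **none**: the final instantaneous iterate.

After optimisation the final bias is frozen and a production phase of
equal (default) or configurable length is sampled under it.  This is a
measured necessity, not a stylistic choice: reweighting against a
still-moving bias makes the weights e^{βV_t} fluctuate exponentially in
time and collapses the effective sample size (≈17 k of 2·10⁶ samples
in a four-basin test), whereas a static production bias restores
per-bin effective counts.  The analysis then discards the optimisation
phase as burn-in.

## Reweighting and free-energy grids

Each stored sample records the bias acting at its sampling time;
weights are e^{β(V−V_max)} so the scaled maximum is exactly 1 and no
overflow occurs for arbitrarily deep biases.  A leading burn-in
fraction is masked (function default 0.02, mirroring the usual discard
of the initial weight-equilibration period; the pipeline default is
0.5 because in a short surrogate run the adaptive-bias ramp occupies
half the trajectory by design).  The 2-D estimator is a weighted
histogram on a default 100×100 periodic grid; F = −(1/β) ln p̂, deepest
finite bin pinned to 0; empty bins are flagged NaN and excluded from
all arithmetic, never replaced by a large placeholder.  Marginal
profiles integrate the Boltzmann factor over the other coordinate on
the finite bins and re-shift.

A histogram estimates the *bin-integrated* Boltzmann weight, so
validation against an analytic surface compares to the log-mean-exp of
e^{−βU} over each bin; comparing to bin-centre values would add a
discretization artifact (~0.5 kJ/mol at 50 bins on steep walls) that
is not estimator error.

Minimax path barriers between bins are computed exactly by a
Kruskal-style level sweep with union-find on the periodic 4-neighbour
lattice; NaN bins are impassable.  Tests pin this against an
independent exhaustive occupation-level/BFS oracle and, on a tiny grid,
against direct enumeration of all simple paths.

## Metastable states

High-weight samples are sieved at a free-energy cutoff: a sample is
kept if its scaled weight exceeds e^{−β·cutoff}.  The cutoff must sit
**at least ~8 kJ/mol above the shallowest basin of interest** (so the
un-sieved tail of that basin carries negligible Boltzmann mass) and
**below the surrounding barrier tops** (so basins stay disconnected).
The pipeline default of 100 kJ/mol matches the phantom presets, whose
shallowest basin lies at ≈68 kJ/mol and whose plateaus are ≥125.

Sieved samples are clustered by DBSCAN on pairwise toroidal distances
(deterministic, no cluster-count input; eps 0.5 rad, min 10 members).
Large sieves are stride-thinned to ≤4000 points before the O(n²)
distance matrix; because thinning is uniform, every state's weight
share is scaled by the same factor and relative free energies are
unaffected.  Clusters separated by a minimax barrier below a merge
threshold (default 0.5 kT) are fused into one superstate — the
operational form of treating rapidly interconverting substates as one
state.  Labels are assigned by nearest reference centroid with
conflicts going to the closer cluster and ties broken in the fixed
order S_m, S_v, S_h, S_c.

State free energies are weight shares,
F_s = −(1/β) ln(Σ_{i∈s} w_i / Σ_all w_i), shifted so the deepest state
is 0; the cross-landscape difference Δ_s = F_s^A − F_s^B is reported
per label, with labels missing on either side reported absent rather
than zero.  Note two systematic ingredients of Δ beyond well-depth
differences: basin-width (curvature) terms of order kT·ln(d₁/d₂) —
about −0.5 kJ/mol for the phantom pair — and sieve-truncation terms
when the cutoff window above a basin is small.  The statistical error
is governed by the number of independent basin visits during
production, not by the raw sample count; the pipeline therefore
defaults to a production phase (6000 strides) twice the optimisation
length (3000).

## Convergence diagnostics

Landscape checkpoints are cumulative-estimate grids at increasing
times.  The statistical distance converts each grid to p ∝ e^{−βF}
over jointly finite bins and returns the symmetrized (Jeffreys) KL
divergence ½[KL(p‖q) + KL(q‖p)] (Jensen–Shannon selectable); distances
are taken between successive checkpoints.  A run is declared converged
at the earliest checkpoint from which the sliding-window mean absolute
slope of the distance series stays below tolerance (defaults: window
3, tolerance 0.01) through the end.  Late-window FES variability is
the mean over jointly finite bins of the per-bin population standard
deviation of F across the trailing checkpoints.

Bootstrap estimation of circular observables uses the circular mean
atan2(⟨sin⟩, ⟨cos⟩) and a percentile bootstrap expressed in wrapped
deviations from the full-sample mean (seam-safe); the reported
half-width is half the percentile interval.  Coverage of the 95%
interval on von Mises data (κ = 4, n = 200, 2000 replicates) is
93–97% over 500 repetitions in the acceptance suite.  Mode counting
uses a circular histogram tripled around the seam with
`scipy.signal.find_peaks` prominence thresholds on the normalized
density scale.

## Structural observables

The toy-protein generator builds a chain of four-atom residues (N, H,
CA, O) with a separate chromophore-like residue carrying a driven
dihedral quadruple whose torsion equals the programmed series exactly
before noise; it can plant collinear donor–H–acceptor geometries,
residue contacts at stated distances and frame fractions (realized in
the first round(f·F) frames), and isotropic Gaussian jitter on a
mobile region.  It emulates the *bookkeeping* of a protein trajectory
— indices, residues, plantable geometry — not protein physics: no
excluded volume, no secondary structure, no solvent.  Passing
structural tests therefore demonstrates correctness of the estimators,
not realism of the fixture.

Kabsch superposition enforces a proper rotation (det +1) via the SVD
sign correction; fitting on collinear atom sets is refused.  RMSF
superposes all frames on the first, takes each atom's RMS deviation
from its time-mean position, and averages atoms within residues (for
isotropic jitter of σ per coordinate the expected value is σ√3).  The
hydrogen-bond criterion is geometric — d(D,A) ≤ 0.35 nm and H–D–A
angle ≤ 30° — the common convention where no single standard exists;
both parameters are exposed.  Contacts use the minimum heavy-atom pair
distance ≤ 0.35 nm with a sequence-adjacency exclusion window
(default 1).

## Energetics

τ = τ₀ e^{ΔF/kT} with τ₀ = 1 ps, a typical molecular attempt time
stated as an explicit assumption: only orders of magnitude are
meaningful.  With it, 75 kJ/mol maps to ~10 s, 100 kJ/mol to ~3·10⁵ s
and 33 kJ/mol to ~0.6 µs at 300 K.  Photon energies use
N_A h c = 119 626.57 kJ·nm/mol, giving 181.3 kJ/mol at 660 nm and
170.9 kJ/mol at 700 nm.

## Problem sizes and determinism

Default study conditions: VES order 10, μ = 0.1, stride 1000,
3000 optimisation + 6000 production strides per landscape, samples
recorded every 2 steps, 100×100 grids, burn-in 0.5.  The acceptance
script runs the four-basin recovery at 2000+2000 strides and the
variational-recovery case at order 2 with 4000 updates.  Every
stochastic component is seeded; the pipeline reproduces its outputs
bitwise under a fixed configuration, and each output file carries the
configuration hash.

## Known limitations

* The surrogate dynamics have arbitrary time units; barrier-crossing
  *times* are meaningful only through the explicit Arrhenius model.
* Only the uniform target distribution is implemented (no
  well-tempered or mixture targets, no multiple walkers).
* The FES estimator is histogram-based; no kernel or Gaussian-process
  smoothing.
* State analysis is thermodynamic (weight shares); no kinetic or
  Markov-state clustering.
* The toy-protein fixture is geometric bookkeeping only; structural
  results on it validate estimators, not biology.
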