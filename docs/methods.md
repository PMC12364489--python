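# Methods

This note documents the models, defaults, and numerical choices behind each
analysis stage, and what the synthetic study conditions do and do not
establish about real recordings.

## Spike detection and unit sorting

Extracellular SSR traces are median-centred (detection is invariant to DC
offset) and thresholded at `k · σ̂` with `σ̂ = MAD/0.6745`, the standard
robust estimate of the noise SD that is insensitive to the spikes themselves;
the default `k = 5` gives a ~10⁻⁶ per-sample false-crossing probability for
Gaussian noise.  Contiguous supra-threshold runs form candidate events timed
at their absolute extremum; the event amplitude is the peak-to-trough depth
within ±0.5 ms.  Events closer than the refractory period (default 2 ms,
matching typical olfactory sensory neuron limits and the simulator) are
merged into the larger one.  Consequence: spikes from *different* neurons
that collide within the merge window are irresolvable by design; detection
fidelity statements therefore refer to collision-free (single-unit or sparse)
activity.

Units are sorted purely by spike amplitude, as is conventional for sensilla
housing a few neurons of distinct spike sizes.  The 1-D k-means is fully
deterministic: two seedings are tried — centers at the (i+½)/k amplitude
quantiles, and farthest-first seeding, which is robust when one cluster
dominates the spike count and quantile seeding would place two centers inside
it — and the lower-SSE Lloyd solution is kept.  Labels `a, b, c…` follow
decreasing mean amplitude.  The automatic unit count maximizes the BIC of an
equal-variance 1-D Gaussian mixture evaluated at the k-means solution over
k ∈ {1, 2, 3}; the cap reflects the at-most-a-handful of neurons per
sensillum.  At cluster separations of 5 noise SD the optimal boundary still
misassigns ~0.6 % of spikes (each mean is 2.5 SD from the boundary), an
irreducible limit of amplitude-only sorting.

Responses are quantified as `Δ spikes/s = (post − pre)/window` with equal
pre/post windows (1 s for screening, 0.5 s for dose–response work) and
corrected by subtracting the solvent's Δ spikes/s measured with the same
window.  Negative corrected responses (inhibition) are retained.

## Lifetime sparseness and tuning curves

`S = (1 − (Σrᵢ/N)²/(Σrᵢ²/N)) / (1 − 1/N)` over the N per-odorant mean
responses, with negatives clipped to zero by default (`clip_negative=False`
is exposed): inhibitory responses would otherwise contribute to Σrᵢ² and
inflate apparent selectivity.  S is invariant to positive rescaling and
decreases monotonically as the profile is made more uniform.  The tuning
curve uses right-first bell ordering — strongest response centred, remaining
responses placed alternately right/left in descending order — a fixed,
deterministic convention (any symmetric alternation is equally valid; one had
to be chosen).

## Dose–response model

Three-parameter log-logistic ("log(agonist) vs response") with Hill slope
fixed at 1 and the constraints bottom ≥ 0, top ≥ bottom (enforced by fitting
the span top − bottom ≥ 0).  Doses are amounts (ng) on filter paper;
logarithms are base 10.  The fit is deterministic: `scipy.optimize.
least_squares` (trust-region reflective, tolerances 1e-12) initialized at
bottom₀ = max(0, min response), top₀ = max response, and log₁₀ED50 at the
dose whose mean response is nearest half-maximal.  A free-Hill-slope variant
and per-dose-mean fitting are exposed behind flags; with balanced replication
per-replicate and per-mean fits coincide.  ED50 is flagged unidentifiable
when the fitted curve's rise across the *observed* dose range is within twice
the residual scale — the signature of flat data, where the optimizer can park
ED50 far outside the dose range.

## Trajectory dynamicity

Inputs are unwrapped (PBC-corrected) trajectories in Å as multi-model PDB or
XYZ; a bond-length/frame-jump sanity check warns on wrapped coordinates
rather than re-implementing unwrapping.  Every frame is superposed onto the
reference frame (default: first frame, all atoms; a backbone-only fit is
available) by the Kabsch algorithm — SVD of the cross-covariance with the
determinant sign correction so only proper rotations are produced.
Superposition is idempotent and optimal in the least-squares sense; both
properties are tested, including against a brute-force rotation grid and an
independent reference rotation solver.

The explored volume of atom *i* is the volume of the 3-D convex hull (qhull)
of its positions across all frames; degenerate point sets (≤ 3 points,
collinear or coplanar) return 0 with a flag — a frozen atom explores no
volume, which is meaningful.  The per-step volume divides by the number of
frames analyzed: for a fixed sampling interval this is the average volume
explored per simulation step and lets trajectories of different lengths be
compared.  One cumulative hull per atom over the whole (concatenated)
trajectory is the default; a windowed mode (mean of per-block hulls) is
provided for long composite trajectories where a cumulative hull saturates.
Per-residue aggregation is the mean over member atoms (sum is available).

The holo/apo comparison is the per-atom ratio Rᵢ = vᵢ(holo)/vᵢ(apo),
excluding atoms with zero apo volume.  The mean over included atoms
summarizes the global effect of ligand binding (R < 1 = rigidification);
atoms with Rᵢ above a configurable threshold (default 1.5) are flagged as
mobilized regions, the pattern expected of an allosterically activated loop.

## Caste comparison and FPKM

Each EAG series (air, hexane, neocembrene, hexane, air; one series per
individual) is normalized by the mean of that individual's two air responses
— cancelling preparation and instrument gain, so the statistic is invariant
to multiplying a whole series by any constant — then log₂-transformed to
reduce heteroscedasticity.  Optionally the solvent (hexane) response is first
subtracted (off by default; non-positive values then cannot be
log-transformed and are flagged missing).  Groups are compared with Student's
t-test (pooled variance), reported together with Bartlett's equal-variance p
and per-group Shapiro–Wilk normality p so the assumption checks travel with
the result; a Welch variant is behind a flag.  FPKM is
`counts · 10⁹ / (length_bp · library_size)` with the library size defaulting
to the column total.

## Synthetic study conditions

The generators' defaults encode the study regime the analyses target:
spontaneous firing at 6.87 Hz, 0.3-s stimulus pulses, up to three units of
distinct amplitude per sensillum, a 67-odorant panel dominated by one strong
agonist (~56 Δ spikes/s) with a moderate second agonist (~25), one inhibitor
(−6.8) and a weak background capped at 7, doses of 0.01–500 ng, ED50 regimes
of 24 ng (heterologous) and 0.016 ng (native sensillum) with 9–10 replicates,
and 15-vs-15 EAG comparisons with a two-fold worker gain.  Values not fixed
by those regimes were chosen once as field-realistic and are not tuned:
replicate noise is heteroscedastic, `sd = max(1.9, 0.15·|mean|)` Δ spikes/s,
anchored at the observed scatter of weak responses; the weak-response
background of the 67-odorant panel is a fixed exponential profile
(scale 1.5 Δ spikes/s, clipped at 7) drawn from a constant internal seed, so
it is part of the package's definition rather than a per-run random
quantity.  Trajectory stand-ins use 200 atoms × 500 frames, base σ 0.5 Å
with a 20-atom loop at 2×σ, and small rigid-body jitter applied before noise
so the superposition stage is genuinely exercised; these sizes keep the whole
suite and the acceptance script in the tens of seconds while leaving
Monte-Carlo errors far below the tested effect sizes.

Spiking is homogeneous Poisson per unit with a 2-ms refractory period;
inter-spike statistics of real termite OSNs are not characterized, so Poisson
is an assumption, not a validated model.  The simulator renders each spike as
a fixed 1-ms biphasic template — real spike shapes vary within and across
units, overlap more messily, and ride on drifting baselines.  Passing tests
therefore demonstrate correctness of the *computations* (detection logic,
sorting, window arithmetic, fitting, hull volumes) under controlled
conditions, not robustness to every artifact of real recordings.  Similarly,
the fluctuation trajectories are isotropic Gaussians around a static mean
structure: they validate the explored-volume machinery and its
discrimination of mobility differences, but contain no correlated collective
motions, anisotropy, or conformational transitions of real MD.

## Known limitations

- Amplitude-only sorting cannot separate units of similar spike size and
  does not model amplitude drift or bursting; no template matching or PCA.
- Cross-unit spike collisions within the 2-ms merge window are irresolvable
  by construction.
- The dose–response module fits single-agonist curves only.
- The dynamicity module consumes trajectories; it performs no MD, docking, or
  binding-energy computation.
- FPKM is input preparation; differential-expression testing is out of scope.
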