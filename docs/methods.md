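# Methods

This note documents the models, the generative assumptions behind the
synthetic data, the numerical choices, and what the tests do and do not
demonstrate.

## Burst-level generative model (simulate)

A freely diffusing, doubly labeled dimer at ~100 pM produces well-separated
photon bursts. The simulator works at burst level, not at the level of
Brownian trajectories through a point-spread function:

- Burst start times: homogeneous Poisson process (default 10 bursts/s — a
  realistic transit rate at ~100 pM occupancy); each burst lasts a fixed
  transit time (default 2 ms).
- Burst brightness `B`: geometric with mean `burst_size_mean/2` (default
  burst_size_mean = 60 detected photons), the simplest heavy-tailed size law
  that reproduces a ≥25-photon selection regime. A log-normal alternative is
  configurable.
- Bursts are **state-pure**: one conformational state per transit.
  Within-burst interconversion (dynamic FRET) is deliberately out of scope;
  the regime modeled is the one in which the efficiency histogram shows two
  static peaks.
- Per-burst channel counts are Poisson with means
  μ_DD = B(1−E), μ_AA = Bρ (ρ = relative acceptor-excitation brightness,
  default 1), μ_FRET = BγE, plus leakage Poisson(Lk·f_DD) and direct
  excitation Poisson(Di·f_AA) added to the Dex/Aem channel. Under this
  construction the standard correction formula recovers E exactly in
  expectation, leakage/direct-excitation estimators are exact pooled ratios,
  and the 1/S-vs-E_PR regression recovers γ exactly — so parameter-recovery
  tests have sharp ground truth.
- Background: homogeneous Poisson per channel (default 300 counts/s,
  i.e. 0.3 counts/ms-bin, a typical dark+scatter level consistent with
  per-bin thresholds of 3–7 counts).
- Ground truth (burst intervals, species, true E) is carried in a sidecar
  table that analysis code never reads.

What this emulates well: shot-noise-limited efficiency histograms, species
mixtures, crosstalk distortions, titration population shifts. What it does
not emulate: diffusion-shaped burst profiles, dye blinking/bleaching,
acceptor photophysics beyond Di, inter-burst brightness correlations, and
within-burst dynamics. Passing tests therefore demonstrate correctness of
the *analysis chain* under the stated noise model, not robustness to every
instrumental artifact of real data.

## Photon processing (bursts)

- Binning at 1 ms; photon classes (D,D), (D,A), (A,A); (A,D) photons are
  FRET-insensitive under PIE and are discarded (counted for bookkeeping).
- Background per channel: iterative 5σ-clipped mean of the per-bin counts.
  A percentile-truncated mean is badly biased at dark-count rates below ~1
  count/bin (the 90th percentile of Poisson(0.3) is 1, leaving only empty
  bins), whereas sigma clipping removes the rare bright burst bins while
  keeping essentially all background mass.
- Threshold: ceil(bg + k·√bg) with k = 2, clamped into [3, 7] counts/bin —
  at realistic dark counts the clamp window is exactly the 3–7 range the
  protocol calls for.
- Burst search: maximal runs of bins with Dex-sum ≥ threshold (start/stop
  threshold crossing at bin resolution; `merge_gap` available for
  sensitivity checks, default off). Per-burst background-subtracted counts
  clamp at zero.
- Selection: background-subtracted (f_DD + f_DA) ≥ 25; stoichiometry window
  0.3–0.7 (a common ALEX choice; configurable) sorts doubly labeled bursts
  from single-label contaminants.
- Single-label **calibration** streams are searched on their own signal
  channel (f_DD for donor-only, f_AA for acceptor-only). Searching a trace
  that includes a near-background channel conditions that channel's
  in-window counts on upward background fluctuations; for the tiny leakage
  channel this selection excess is a few percent (relative) and would
  dominate the Lk error budget. Acceptor-only streams *must* be searched on
  f_AA in any case, since they have essentially no donor-excitation signal.

## Calibration (calibrate)

Pooled-count ratios (sum first, divide once) for Lk and Di: per-burst
ratio averaging carries O(1/N) Jensen bias at realistic burst sizes. γ from
the weighted linear fit of inverse apparent stoichiometry against the
crosstalk-corrected proximity ratio across ≥2 rulers with apparent-E spread
≥0.1; the fit degrades gracefully with more rulers and fails loudly on
collinear designs.

## State inference (fret_states)

Per-burst corrected efficiencies are clamped to [−0.1, 1.1] (shot-noise
overshoot retained and counted). The mixture fit is a hand-rolled 1-D EM —
kept in-package because per-iteration likelihood monotonicity is asserted
as an invariant and because a weights-only mode (fixed means/sigmas) is
needed for titrations; it is cross-checked against scikit-learn's
`GaussianMixture` in the tests. Details: ≥20 restarts (quantile-anchored
initialization plus jitter), tolerance 1e-8 on the relative log-likelihood
change, σ floor 0.01 (if the floor binds, the monotone-ascent guarantee is
void and iteration stops at the best reached point), components reported
sorted by mean. K="auto" compares K ∈ {1,2,3} by BIC.

During titrations the component means and widths are shared globally (fit
on pooled data) and only the weights move per concentration — this
stabilizes points where one population is small and matches the observed
stability of the state positions during titration. State 1 is the low-E
component by convention; `invert_states` covers label sites where the
geometric mapping is reversed (the D174C site maps low-E to state 2).

## Binding (binding)

Hyperbolic one-site isotherm with free f₀, f_max, K_D; free ligand ≈ total
ligand because the receptor is ~100 pM, far below both dissociation
constants of interest (a quadratic tight-binding form is available via
`model="quadratic"`). Weighted least squares with per-point standard errors
from a burst bootstrap; K_D uncertainty from refitting bootstrap replicates
(default 200); fold differences with pair-resampled CIs. A fit whose
plateau is statistically indistinguishable from its baseline is flagged
unreliable rather than silently reported.

**Design information limit.** At the simulated titration design (7
log-spaced points spanning 0.1×–30× K_D, ~2000 selected bursts per point,
states enriched from ~0.58 toward ~0.95) the Cramér–Rao bound on K_D is
~12.5% (1σ). Any single simulated titration therefore scatters by that much
around the truth no matter how good the estimator; accuracy checks and the
acceptance script report the median over five replicate titrations, which
isolates method bias from design-level Monte-Carlo noise. The per-run
bootstrap SE reported alongside each fit reflects the same limit.

## SAXS (saxs)

- Form factors: analytic sphere; ellipsoids and sphere dumbbells as
  cubic-lattice bead models evaluated through the Debye sum. Small systems
  (≤3·10⁵ pairs) use the exact pairwise sum (machine-precision identical to
  the naive double loop); larger systems collapse distances onto an
  8192-bin histogram whose per-bin mean distance carries the sinc
  evaluation (relative error ~1e-9 at small-angle q). Bead spacing is
  auto-chosen to cap the model at ~2000 beads.
- Simulated noise: relative σ rising linearly from 1% to 4% across the q
  grid (default 0.01–0.35 Å⁻¹, 300 points, a typical synchrotron
  configuration) plus a small additive floor (10⁻³·I(0) at the 1% level)
  representing background-subtraction noise — without the floor, σ→0 at
  form-factor zero crossings and χ² weighting becomes degenerate.
- Guinier: iteratively re-selected window growing from the lowest q while
  q·Rg ≤ 1.3 under the current estimate; weighted fit of ln I vs q²;
  positive slopes (aggregation-like) are an error, not a number.
- P(r): trapezoid discretization on 101 r-points, endpoints pinned to zero
  by construction, second-difference smoothness penalty. α="auto" uses a
  discrepancy-style rule — the strongest smoothing whose χ² stays within a
  small tolerance (5% of the minimum, or half of √(2n_q), whichever is
  larger) of the best attainable fit. An L-curve corner criterion was tried
  and rejected: its curvature maximum is unstable on wide-q curves and can
  over-smooth by orders of magnitude.
- D_max scan: one common α for all candidates (chosen on the largest
  support — per-candidate adaptation would equalize χ² across candidates
  and destroy discrimination), scored by χ²/dof + 2·(negative-mass
  fraction) + 1·(support excess, the grid fraction beyond the 99% |P| mass
  radius). Undersized supports fail on χ² or ring negative; oversized
  supports pay for their empty tail. On bodies with sharp distance-support
  edges (spheres, dumbbells) the scan recovers D_max exactly on a 10 Å
  grid; on smooth-tailed bodies (ellipsoids) it resolves D_max to about one
  10 Å grid step — an honest reflection of how weakly the scattering data
  constrain the extreme tail of P(r). Note that a 10 Å-resolution P(r)
  comparison for a small sphere (R = 10 Å) requires measuring to q·R ≈ 6;
  at q·R ≈ 3.5 the inversion is information-limited to ~2% RMS.
- Molecular weight: Porod invariant Q = ∫q²I dq with Guinier extension
  below q_min and a q⁻⁴ tail above q_max; V = 2π²I(0)/Q; MW = V/1.66 Å³/Da
  (the divisor is empirical and configurable; the MW method behind the
  study's printed masses is not specified, so no single divisor is
  privileged). A volume-of-correlation variant is provided. I(0)
  consistency between the Guinier and P(r) routes is checked and flagged
  beyond 20% (catches concentration-scaling errors). In practice P(r) is
  fitted on the small-angle region and the invariant integrated over the
  full measured range.

## FCS (fcs)

The simulator drives both detection channels with a shared symmetric
random-telegraph intensity, giving *exactly*
G(τ) − 1 = contrast·exp(−τ/τ_c) — chosen over a log-normal
(Ornstein–Uhlenbeck log-intensity) process, whose true correlation
exp(σ²ρ(τ)) − 1 deviates from a pure exponential by ~10% at contrast 0.5,
comparable to the recovery tolerances being tested. The multi-tau
correlator re-bins photons from timestamps at every stage (16 lags in
stage 0, 8 per doubling stage thereafter), so each reported lag equals the
plain binned correlator at that bin width: results are invariant to the
number of stages at overlapping lags, and a brute-force pairwise correlator
is a drop-in oracle. Decay fits offer the exponential (matching the
simulator) and a 1/(1+τ/τ_c) diffusion proxy; amplitudes consistent with
zero are flagged. Only curve-shape parameters are exposed — no biological
threshold is asserted on G_AD(τ) differences.

## Workflows, formats, configuration (io, config, workflows, cli)

Photon streams are tab-separated `timestamp_s  excitation  channel` files
with `# key=value` headers; SAXS curves are 3-column `q I σ` text with `#`
comments (a missing σ column is an error, never silently defaulted; file
reads round-trip at full float precision via `float_precision="round_trip"`).
Concentrations are always stored in molar and displayed in nM. The YAML run
configuration rejects unknown keys and round-trips losslessly. Every
workflow report embeds the fully resolved configuration and root seed; a
stage failure writes a failed report naming the stage before re-raising.
Instrument-vendor raw formats (e.g. .ptu) and a photon-HDF5 exporter are
not implemented; the plain-text format is the interchange format.

## Known limitations

- Burst search is bin-resolution (1 ms) threshold crossing, not a sliding
  window at photon resolution; sub-bin burst edges are truncated (channel-
  symmetric, hence E-neutral).
- The Gaussian mixture is an approximation to the true (binomial,
  burst-size-mixed) efficiency distribution; at strongly overlapping peaks
  this costs ~1–2 population points, within the stated tolerances.
- D_max for smooth-tailed bodies is resolved to ~one 10 Å grid step (see
  above).
- No dye photophysics beyond leakage/direct excitation/γ; no within-burst
  conformational dynamics.
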