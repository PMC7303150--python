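# Methods

## Scope and model

`stallflow` implements a quantification pipeline for *capillary stalls* —
cortical capillary segments in which blood cells show no detectable
motion — in two-photon excited fluorescence (2PEF) time-lapse stacks of
the mouse brain, together with the downstream analyses that give the
stall counts physiological meaning: line-scan red-blood-cell (RBC)
velocimetry, volumetric flow, network models of the cerebral-blood-flow
(CBF) deficit caused by occlusions, and the behavioral scores used to
relate perfusion to cognition. Because real image stacks are large and
animal-derived, every component is exercised against a synthetic-data
generator with exact ground truth; the generator is first-class, tested
code.

### The stall definition

A vessel plasma label makes lumens bright; blood cells are unlabeled and
appear as dark patches. Acquisition is modelled as 1 µm isotropic voxels
at 1 frame/s, with every capillary visible for at least 5 consecutive
frames. A segment is **stalled** when at least one dark patch is present
in every frame and no patch in the lumen moves by more than the
displacement resolution (1 µm) over the window. With a 1 µm resolution
over 5 s this bounds detectable flow at 0.2 µm/s — anything slower is
operationally a stall. The detector (`hemodyn.detect_stall_ground_truth`)
thresholds plasma voxels below 50% of the local lumen level (80th
percentile of in-lumen plasma), labels 26-connected components of at
least 6 voxels, and tracks component centroids by nearest-neighbor
matching between consecutive frames. When several patches occupy a
segment, *all* must be static for a stall call (the strictest reading);
a patch-free frame vetoes the call.

### Crowd scoring

The crowd engine reproduces the mechanics of citizen-science scoring:

- **Sensitivity estimate.** Each annotator's probability of correctly
  labelling a truly stalled item is tracked from interleaved calibration
  items with known truth, as a Laplace-smoothed true-positive rate
  ŝ = (correct on stalled + α)/(stalled seen + 2α), α = 1, so a new
  annotator starts at 0.5. Specificity is tracked symmetrically but does
  not enter the weighting.
- **Crowd confidence.** Research answers are weighted by ŝ *at answer
  time* (frozen into the record) and averaged:
  c = Σ wᵢ·1[stalled]ᵢ / Σ wᵢ ∈ [0, 1].
- **Stopping.** An item closes when the summed sensitivities of its
  answerers reach a threshold T and at least 8 answers have accrued.
  T is chosen by `calibrate_threshold`: the smallest grid value for
  which every known stall in a labelled test set scores above the 95th
  percentile of the flowing items' confidences.
- **Base-rate maintenance.** Skilled annotators see more research items
  (serving ratio steps 1:1 → 3:1 → 5:1 → 9:1 as ŝ crosses 0.6/0.8/0.95),
  so the stalled share of calibration items is re-solved per draw,
  f = q(R+1) − b·R, to hold the expected shown-stall fraction at the
  target q (default 0.25) given the research base rate b; infeasible
  combinations are clamped to [0, 1] and logged.
- **Expert triage.** After closing, items with c ≥ 0.5 (ties included)
  are reviewed in descending confidence order; only expert-confirmed
  stalls count. The reported per-stack stall fraction is exactly
  confirmed stalls ÷ total capillary segments.

### Hemodynamics

Line-scan velocimetry estimates centerline RBC speed from the streak
angle of a (time × distance) image: 128-line windows with 50% overlap
are apodized with an inscribed ellipse (making projection variance
angle-independent for structureless input), scanned over a 1° Radon
angle grid on a 2× decimated copy, then refined by bounded scalar
minimization at full resolution; speed = pitch × line rate × |tan θ*|.
A window is dropped when its variance spectrum has no dominant peak
(confidence 1 − median/max below 0.7) or when the implied slope exceeds
one image width per line (aliasing); if no window survives, the
estimate is flagged low-confidence and reported as NaN rather than a
number. Diameter is the median full width at half maximum of ≥3
profiles across the vessel, with sub-pixel edge interpolation.
Volumetric flow is F = πvr²/2; group effects are percent changes in
*medians*.

### CBF-deficit models

Two models, deliberately at different fidelity:

- **Arithmetic tiers.** Occluding a fraction p of capillaries removes
  their flow entirely and depresses downstream vessels: 2p of vessels
  at 10% of baseline (one branch downstream), 4p at 25% (two branches),
  8p at 50% (branches 3–4, pooled, assuming a branching factor of 2 and
  non-interacting stalls). Deficit = 100·[p + Σ nₖ(1 − mₖ)], giving
  19.6% at p = 2%. The tier-3/4 pooling at 16% of vessels is the unique
  resolution of the doubling pattern that reproduces that total.
- **Linear network solver.** A Poiseuille analog on the vessel graph:
  conductance r⁴/length per edge, unit pressure at surface-arteriole
  inlets, zero at terminal outlets, flow conservation at interior nodes
  (sparse Laplacian solve; residual < 1e-9 of inlet flow). Stalled edges
  get zero conductance; the deficit is the percent drop in total inlet
  flow. This is a simplification — no hematocrit partitioning,
  pulsatility, or non-Newtonian rheology — but it reproduces the
  qualitative property that the *expected* deficit exceeds the occluded
  percentage. On the layered-tree topology single stall draws are
  heavy-tailed: a stall adjacent to a penetrating arteriole starves an
  entire subtree (ratios ≫ 1) while a terminal stall is partly
  compensated by rerouting (ratio < 1), so the disproportionality
  property is asserted on the mean over ≥40 random stall configurations,
  where it holds with a comfortable margin (ratios ≈ 2–5 at p = 1–4%).

### Behavioral scores and statistics

Scores follow the standard formulas: spontaneous alternation =
100 × (distinct-arm triads)/(entries − 2); object-replacement (OR)
preference = 100 × moved-object time / total exploration (trial 2);
sociability chamber/contact fractions per session; balance-beam time
and hindpaw slips averaged over the last two of three trials (the first
is habituation; the 60 s cap is retained in the mean). Group comparison
is normality-gated: D'Agostino–Pearson per group; all normal → one-way
ANOVA with Holm–Šídák-corrected pairwise t-tests; otherwise
Kruskal–Wallis with Holm-corrected Dunn z-tests (tie-corrected,
hand-implemented). Groups of n < 8 cannot certify normality and route
to the nonparametric branch. p < 0.05 is significant, [0.05, 0.1) a
"trend". Pairs differing in one design factor get that factor's marker
(* genotype, # treatment, † diet, λ age). A two-factor interaction
(synergy) test via OLS ANOVA is exposed but optional. Under the null
the full gated pipeline's familywise error stays ≤ 0.06 at nominal
0.05 (verified over 2,000 simulations).

## The synthetic generator: what it emulates, what it does not

- **Networks** are layered random geometric graphs: a surface-arteriole
  chain feeds penetrating arterioles (PAs), each growing a
  binary-branching capillary bed (radii uniform on 1.5–4 µm, lengths
  30–60 µm, branch order +1 per generation). Stalls are Bernoulli per
  capillary at the configured rate, assigned in creation order from a
  dedicated random stream so the draw is independently reproducible;
  causes follow the configured leukocyte/platelet/RBC-only simplex;
  flowing speeds are log-normal (median 1 mm/s, σ = 0.5). Real capillary
  beds are reconvergent meshes; the tree topology is the main
  simplification and is why the network-deficit property is stated in
  expectation.
- **Stacks** paint soft-edged capsule lumens (half-maximum crossing at
  the true radius, so FWHM diameters are unbiased), 1–3 dark ellipsoidal
  patches of 6 µm per capillary, advected by the true speed with 5%
  per-frame positional jitter (without it, fast flow can alias onto
  apparent stasis at 1 frame/s — real flow decorrelates patch positions).
  Stalled patches are static, placed in the middle half of the segment,
  and carry rhodamine+hoechst (leukocyte), rhodamine-only (platelet), or
  no (RBC-only) cell-label signal. Background offsets ~10 with Gaussian
  noise σ = 2. No point-spread function, photobleaching, motion
  artifacts, or pulsatility — so passing tests demonstrate the
  *machinery* (detection, classification, aggregation) at realistic
  geometry and contrast, not robustness to real-microscope nuisances.
- **Line scans** superimpose dark Gaussian streaks (cell spacing 12 µm)
  moving at the true speed on a bright background; the aliasing regime
  caps the simulated cell count at 4000.
- **Annotators** are Bernoulli responders with fixed true
  sensitivity/specificity drawn from a Beta (optionally rescaled to
  model a competence floor). Real annotators drift, correlate, and see
  images, not labels; the simulation tests the aggregation mechanics,
  not human behavior.
- **Behavior** generators map each parameter directly onto its score's
  expectation: Beta-distributed exploration shares (concentration 50)
  around the configured preference; a Markov arm-entry chain whose
  avoid-last-two probability is the alternation propensity; log-normal
  beam times capped at 60 s; Poisson slips.
- **Pre/post flow effects** are paired per vessel (post = pre × (1 +
  effect), so the post median is the pre median scaled by the effect
  exactly), matching a repeated-measures design in which the same
  downstream arterioles are measured before and after treatment; an
  optional per-vessel between-session fluctuation can be switched on.
  An unpaired design at n = 20 and CV 0.2 would leave ≈ ±10 points of
  sampling noise on a median ratio and could not resolve a 34% effect
  to ±3; even the paired design with a 2% between-session wobble leaves
  ≈ ±2.5 points from order-statistic reshuffling around the median.

## Problem sizes and numerical choices

Stall-fraction recovery runs 3 stacks × 4,000 segments (12,000 total)
with 100 Beta(8,2) annotators; precision validation runs 20,000 segments
at a 1% stall rate with 120 annotators of competence ≥ 0.75 and ≥ 8
answers per item; composition recovery renders 500 single-capillary
stacks; velocimetry recovery uses 20 vessels × 256-line scans per
condition; behavioral recovery uses 1,000 logs. These sizes hold the
Monte-Carlo error of each recovered quantity well inside its stated
tolerance while keeping a full run in minutes on one core.

Numerical details worth knowing: constant-intensity crops normalize to
midscale 0.5 instead of dividing by zero; skeleton node clusters merge
junction voxels within 2 voxels; terminal skeleton branches shorter
than 5 µm hanging off a node are pruned as thinning artifacts, and
nodes left with two branches are dissolved (idempotent on re-run);
confidence ties at exactly 0.5 are included in expert review; the
network solver adds a unit diagonal to isolated interior nodes (they
carry no flow, their pressure is arbitrary); all randomness derives
from named, decoupled child streams of a single integer seed, so
changing one component's draw pattern never perturbs another.

## Known limitations

- The vessel-mask-to-segment path assumes a user-supplied binary mask;
  learned segmentation and motion-artifact removal are out of scope.
- The network CBF solver is linear and tree-topology by default; it
  supports arbitrary GraphML input but makes no claim of quantitative
  agreement with full CFD.
- Annotator simulation has no item-difficulty or annotator-correlation
  structure; the confidence-calibration property is tested under
  independence.
- The Radon velocimeter assumes quasi-straight streaks within a 128-line
  window; strongly pulsatile flow would need shorter windows.
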