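# stallflow

Quantification of non-flowing ("stalled") cortical capillaries and
cerebral blood flow from two-photon time-lapse imaging — rebuilt as a
tested, reusable Python pipeline and exercised end to end on a
synthetic-data generator with exact ground truth.

In mouse models of Alzheimer's disease, a small fraction of cortical
capillaries (~2%, versus ~0.5% in wild-type mice) are transiently
plugged, mostly by adhered leukocytes, and this small fraction is enough
to depress cortical blood flow by ~20%. Measuring it requires scoring
tens of thousands of capillary segments as flowing or stalled in noisy
3D time-lapse stacks — a scale reached with crowd-sourced annotation
plus statistical quality control. This package implements that whole
measurement chain for anyone who wants to study it, simulate it, or
reuse its parts:

- **`stallflow.synthgen`** — synthetic vascular networks (GraphML),
  rendered multi-channel time-lapse stacks (TIFF), line-scan space-time
  images, annotator pools, and behavioral event logs, all with known
  ground truth and seeded reproducibility.
- **`stallflow.vesselseg`** — binary vessel mask → topology-preserving
  centerline skeleton → capillary segments (paths between bifurcations,
  with spur pruning) → normalized, outlined crops for annotation.
- **`stallflow.stallcrowd`** — the crowd-scoring engine: per-annotator
  sensitivity ŝ estimated from interleaved calibration vessels
  (ŝ = (correct+1)/(seen+2)); answers weighted by ŝ at answer time and
  averaged into a crowd confidence c ∈ [0,1]; items close when
  Σŝ reaches a calibrated threshold; the shown stalled/flowing mix is
  held constant as annotators skill up; items with c ≥ 0.5 go to expert
  review in descending-confidence order.
- **`stallflow.hemodyn`** — Radon-angle line-scan velocimetry for RBC
  centerline speed v, FWHM diameter, volumetric flow **F = πvr²/2**, the
  ground-truth stall detector (<1 µm patch displacement over ≥5 s ⇒
  implied speed < 0.2 µm/s), and median-based group percent changes.
- **`stallflow.stallmetrics`** — stall prevalence per stack/group, stall
  cause from two-channel logic (rhodamine∧hoechst = leukocyte, rhodamine
  only = platelet, neither = RBC-only), and two CBF-deficit models: the
  tiered arithmetic model (occluded fraction p plus 2p/4p/8p of vessels
  at 10/25/50% of baseline flow → 19.6% deficit at p = 2%) and a linear
  Poiseuille network solver (conductance ∝ r⁴/length).
- **`stallflow.cohortstats`** — Y-maze spontaneous alternation, object-
  replacement preference, sociability fractions, balance-beam metrics,
  and normality-gated group comparison (D'Agostino–Pearson → one-way
  ANOVA + Holm–Šídák, else Kruskal–Wallis + Dunn/Holm).

## Worked example

Run the crowd pipeline on one synthetic stack and predict the blood-flow
impact of the measured stall burden:

```python
from stallflow.synthgen import generate_network, generate_players
from stallflow import stallcrowd as sc, stallmetrics as sm

graph = generate_network(
    n_penetrating=8, capillaries_per_pa=500,
    stall_rate=0.02, composition=(0.86, 0.05, 0.09), seed=11,
)
truths = [graph.graph.edges[e]["is_stalled"] for e in graph.capillary_edges()]
print(f"{len(truths)} capillaries, {sum(truths)} truly stalled "
      f"({100 * graph.true_stall_fraction():.2f}%)")

pool = generate_players(100, sensitivity_dist=(8, 2), seed=12)
res = sc.simulate_crowd(truths, pool, threshold=2.0, min_answers=8, seed=13)
calls, report = sc.expert_triage(res.calls, sc.ground_truth_oracle(res.calls))
per_stack, groups = sm.stall_fraction(calls, {0: len(truths)})
print(f"recovered stall fraction: {100 * per_stack['stall_fraction'].iloc[0]:.2f}%")
top = report["bins"][-1]
print(f"precision at confidence >0.9: {100 * top['precision']:.0f}% "
      f"({top['n_reviewed']} reviewed)")

model = sm.DeficitModel(occluded_fraction=0.02)
print(f"predicted CBF deficit at 2% stalled: {sm.arithmetic_deficit(model):.1f}%")
```

Output:

```
4000 capillaries, 74 truly stalled (1.85%)
recovered stall fraction: 1.85%
precision at confidence >0.9: 100% (22 reviewed)
predicted CBF deficit at 2% stalled: 19.6%
```

Reading it: of 4,000 capillary segments the generator stalled 74 (a
Binomial draw at the 2% rate); the simulated crowd plus expert triage
recovered exactly that fraction; every segment the crowd pushed above
0.9 confidence was a real stall; and the tiered occlusion model says a
2% stall burden costs about a fifth of cortical blood flow — which is
why so small a number matters.

The same stages are available from the shell:

```bash
stallflow synthgen --n-pa 4 --capillaries-per-pa 100 --stall-rate 0.02 \
    --seed 1 --out net.graphml
stallflow crowd --simulate --graph net.graphml --players 100 --seed 2 \
    --out calls.csv
stallflow deficit -p 0.02
stallflow run --config scenario.yaml --out results/ --seed 1
```

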