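# dartpulse

Quantification of the in-vitro response of land-snail reproductive organs to
love-dart mucous gland extracts.

Helicid snails are simultaneous hermaphrodites that stab a calcareous
"love-dart" into their mate during courtship, injecting accessory-gland
mucus into the haemolymph. In *Cornu aspersum* this mucus makes the
diverticulum (the spermatophore-receiving duct) and the copulatory canal
contract, and additionally shortens the diverticulum — changes that bias
sperm away from the sperm-digesting bursa copulatrix and so raise the dart
shooter's paternity. Whether these effects are species-specific is asked
with a cross-reactivity design: organ preparations of the focal species in
an organ bath, exposed to mucous extracts of nine donor species, with
marker-based video tracking of the organs' movements.

`dartpulse` implements that measurement and inference chain as a tested,
reusable pipeline, exercised end to end on synthetic data with known ground
truth:

* **synthetic experiment generator** (`dartpulse.simulate`) — daily trial
  designs (two focal-species positive controls bracketing up to five
  randomly ordered donor extracts, 29 days), marker trajectories with
  planted raised-cosine contraction pulses on a drifting noisy baseline,
  paired diverticulum length measurements, Brownian trait vectors on a
  tree, and rendered grayscale frame stacks;
* **marker tracking** (`dartpulse.tracking`) — Otsu dark-blob segmentation,
  sub-pixel weighted centroids, nearest-neighbour identity linking, and
  resampling onto the 5-s analysis grid;
* **contraction scoring** (`dartpulse.scoring`) — per-interval Euclidean
  displacement of a marker, and the counting rules: a threshold at 25% of
  the trial's min–max displacement range, excursions above threshold longer
  than 3 min discarded, peaks closer than 15 s merged.  A trial's score is
  the induced count (response-period minus control-period contractions),
  the intensity (maximum displacement in the trial), and a responder flag;
* **daily-control normalization** (`dartpulse.metrics`) — responses relative
  to the day's two positive controls, plus responder percentages;
* **inference layer** (`dartpulse.stats`) — a from-scratch Steel many-one
  rank test (the nonparametric analogue of Dunnett's test; tie-corrected
  rank-sum Z with family-wise adjustment via the equicorrelated
  multivariate-normal bound or joint permutation), paired Wilcoxon Z,
  Kruskal–Wallis, 2×2 chi-square on responder counts, a split-plot mixed
  ANOVA with Fisher-LSD simple effects, log-link GLMs compared by AICc, and
  one-way ANOVA;
* **shortening pipeline** (`dartpulse.shortening`) — paired six-measurement
  length records, Δmm and Δ% summaries, and the baseline-recovery check;
* **phylogenetic signal** (`dartpulse.phylo`) — Blomberg's K,

  K = (MSE₀/MSE) / [(tr V − n/(1ᵀV⁻¹1))/(n−1)],

  with V the Brownian tree covariance, and its randomization p-value from
  tip-label permutations (1000 by default).

## Worked example

```python
import dartpulse as dp

params = dp.SimulationParams(seed=1)
spec = dp.TrialSpec("demo", day=1, order_index=0, species="C_aspersum", is_control=True)
row, truth = dp.run_trial(params, spec, n_events={"control": 2, "response": 3})
print(truth.n_control, truth.n_response, row["n_control"], row["n_response"], row["induced"])
```

prints `2 3 2 3 1`: two contractions planted in the 10-min control period
and three in the 10-min response period are recovered exactly by the
detector, so the extract induced one contraction.

The full analysis is a sequence of numbered drivers:

```sh
python analysis/01_simulate_and_score.py      # 29-day experiment, both organs
python analysis/02_relative_response.py       # daily-control normalization
python analysis/03_cross_reactivity_stats.py  # Steel / Wilcoxon / KW / chi2 / GLM
python analysis/04_shortening_analysis.py     # mixed ANOVA + LSD on log-length
python analysis/05_phylosignal.py             # Blomberg's K on species traits
```

Step 01 reports, for the simulated diverticulum stream,
`control induced mean 1.72 +- 2.27 (N=58)` — the detected response of the
58 positive-control trials. Step 03 flags the extracts whose relative
response diverges from the focal control (at these defaults the two *Helix*
species and the diverticulum-less bradybaenid *F. fruticum*, with negative
Steel Z). Step 04 prints the per-extract shortening table; the strongest
extract (*E. vermiculata*) shortens the organ by `5.70 mm` = `19.69 %` of
its resting length, and the baseline-recovery ANOVA confirms the organ
regained its length between trials. All tables land under `results/`.

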