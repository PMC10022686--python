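# filotip

Quantitative analysis of protein recruitment to filopodia tips.

Filopodia are thin, finger-like actin protrusions whose distal tip
carries a protein complex built around the motor MYO10.  Deciding
whether a protein of interest is *tip-enriched* — and whether a
perturbation changes that — requires pooling hundreds of filopodia of
different lengths, plus orthogonal evidence from interactor screens and
live-cell tip dynamics.  `filotip` implements that analysis layer as a
tested, reusable pipeline:

* **Profiles → maps → enrichment.**  Tip-to-base line intensity
  profiles (bilinear sampling at 1-px arclength spacing along supplied
  paths, per-channel min–max normalization) are each reduced to **40
  bins by median** (sample *i* of *n* → bin ⌊40·i/n⌋); a condition's
  localization map is the per-bin mean over profiles, and each
  filopodium's **tip enrichment ratio** is

  $$R = \frac{\overline{I}_{\text{bins 1–6}}}{\overline{I}_{\text{bins 7–40}}}$$

  (tip window = first 6 of 40 bins ≈ first 15% of arclength).
* **Spectral-count filters.**  Putative interactors from bait-vs-control
  mass spectrometry: ≥ 2-fold enrichment over every control **and**
  more than 10 (pulldown, 2 repeats) or more than 5 (proximity
  labeling, 5 repeats) total spectral counts; volcano coordinates
  (log₂FC, −log₁₀p) and cross-screen overlaps.
* **Tip-spot tracking.**  Frame-to-frame optimal-assignment linking
  with a 1-µm maximum displacement and no gap closing (5-s frames);
  per-track duration, total distance, mean speed; per-cell summaries.
* **Statistics.**  Two-sided randomization test for differences of
  means (exact enumeration when ≤ 20,000 relabelings, otherwise 1000
  seeded permutations with add-one smoothing), Welch's t-test, Tukey
  boxplot summaries.
* **Synthetic ground truth.**  Generators for images, profiles, count
  tables and trajectories with planted signals, so every stage is
  validated end-to-end without microscope data.

See `docs/methods.md` for the full model description and design
choices.

## Worked example

The one-command demo generates synthetic data with planted truth, runs
every stage, and audits recovery:

```sh
filotip demo --seed 1 --out demo_out/
```

```json
{
  "seed": 1,
  "profiles": {
    "n_profiles": 300,
    "expected_ratio": 4.0,
    "mean_ratio": 4.002065516183781,
    "ratio_within_10pct": true,
    "ratio_gt_1_p_value": 0.000999000999000999,
    "ratio_significantly_gt_1": true
  },
  "ms_enrichment": {
    "n_planted": 10,
    "n_passing": 10,
    "planted_recovered_exactly": true
  },
  "tracking": {
    "n_ground_truth": 16,
    "n_recovered": 16,
    "identity_recovered": true,
    "mean_track_duration_s": 95.0,
    "mean_track_speed_um_per_s": 0.024938100774302533
  },
  "all_recovered": true
}
```

Reading it: 300 profiles planted with a 4:1 tip:shaft intensity step
yield a mean enrichment ratio of 4.002 (within 10% of truth, and
significantly above 1 by randomization test, p ≈ 0.001); the
twofold/>10-count filter recovers exactly the 10 proteins planted at
20-fold; and 16 simulated tip trajectories are re-linked without a
single identity error, with the correct 95-s mean duration.

The same stages are available as subcommands (`filotip simulate`,
`profiles`, `map`, `test`, `enrich`, `track`) and as a narrative
analysis sequence:

```sh
python analysis/01_simulate.py --seed 1    # synthetic inputs -> results/data/
python analysis/02_filopodia_maps.py       # 40-bin maps, ratios, randomization test
python analysis/03_ms_enrichment.py        # screen filters, volcano, overlap
python analysis/04_tracking.py             # linking, per-cell dynamics, comparison
```

For example, `02_filopodia_maps.py` prints

```
tip_enriched: n=300 filopodia, mean ratio 4.002, median 3.993 [Q1 3.932, Q3 4.075], 2 boxplot outliers
control: n=300 filopodia, mean ratio 1.001, median 1.002 [Q1 0.960, Q3 1.042], 3 boxplot outliers
randomization test (ratio, tip_enriched - control): diff = 3.001, p = 0.000999 (1000 permutations)
```

and `03_ms_enrichment.py` shows the cross-screen logic — each screen
passes its planted hits and their intersection equals the proteins
planted in both.

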