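# locogear

Decomposition of long-term free locomotor behavior into modes of motion
("gears"), for behavioral phenotyping of rodent disease models — e.g. rats
with bilateral 6-OHDA lesions of the dopaminergic midbrain, whose akinesia,
bradykinesia and hypokinesia show up as changes in the fine structure of
spontaneous open-field locomotion rather than in any single summary score.

The pipeline takes 23 h video-tracking output (x-y positions at 12.8 Hz in a
70 × 100 cm arena digitized at 320 × 435 px) and:

1. **rejects tracking artifacts** — spatial outliers outside the arena,
   resting-spot jump artifacts (every pixel "visited" twice at the pixel
   level is neglected), an 80 cm/s low-pass speed threshold for in-arena
   teleports — and linearly interpolates single missing samples;
2. **segments** the recording into rest and motion episodes by thresholding
   the 0.3 s-windowed speed *v* at a 4 cm/s noise level;
3. characterizes each episode by the base-10 logarithm of its maximal
   windowed speed, the **log max-SD** = log₁₀ max*v*. Across episodes this
   is bimodal: a slow *first gear* centered near 0.71 (≈ 5.1 cm/s) and a
   fast *second gear* near 1.24 (≈ 17.4 cm/s). A two-component Gaussian
   mixture *w*₁𝒩(μ₁, σ₁²) + *w*₂𝒩(μ₂, σ₂²) is fitted by EM to characterize
   the modes; gear *assignment* uses the fixed split at log max-SD = 1
   (10 cm/s), which stays stable when lesioning flattens the fast mode;
4. computes **six behavioral endpoints**: incidence of second-gear episodes
   (%), total covered distance (m), mean maximal speed per gear (cm/s),
   mean dwell time (s), mean spatial spread (cm), and mean track curvature —
   the percent excess of path length over the straight chord in 0.5 s
   windows — plus a binned circadian activity profile;
5. provides the **statistical layer**: Wilcoxon rank-sum comparisons with
   Benjamini–Hochberg FDR control over the 48-comparison family
   (2 groups × 6 endpoints × 4 session contrasts), and 5000-iteration
   bootstrap correlations over the 55-pair family of {SNc count, VTA count,
   laterality index, weight reduction, 6 endpoints};
6. includes **stereology arithmetic** for the accompanying cell counts:
   optical-fractionator identities (50 × 50 × 20 µm dissector = 50,000 µm³;
   150 × 150 µm grid = 22,500 µm²), group reduction percentages and the
   laterality index LI = *f* (E_LH − E_RH)/(E_LH + E_RH) ∈ [−1, 1].

Because raw tracking data of this kind is rarely shared, the package ships a
first-class synthetic-recording generator (`locogear.synth`) with per-sample
ground truth — episode ranges, gear labels, intended maximal speeds, artifact
logs and the uncorrupted path — so every stage is testable end to end.

## Worked example

```python
from locogear import run_pipeline
from locogear.synth import SynthConfig, generate_recording

cfg = SynthConfig(duration_s=3600.0, episode_rate=6.0,
                  circadian_profile=(1.0,), seed=42)
traj, truth = generate_recording(cfg)   # corrupted recording + ground truth
res = run_pipeline(traj, mixture_seed=42)

ep, m = res.endpoints, res.gear_model
print(f"detected episodes: {len(res.episodes)}")
print(f"incidence of second gear: {ep.incidence2_pct:.1f}%")
print(f"total distance: {ep.distance_m:.1f} m")
print(f"mean max speed (gear 2): {ep.mean_max_speed_cms[2]:.1f} cm/s")
print(f"mixture centers (log10 cm/s): {m.means[0]:.3f}, {m.means[1]:.3f}")
```

prints

```
detected episodes: 300
incidence of second gear: 51.7%
total distance: 23.4 m
mean max speed (gear 2): 17.8 cm/s
mixture centers (log10 cm/s): 0.706, 1.229
```

Half the episodes exceed the 10 cm/s split (the generator drew gears with
probability 0.5), the fitted mixture recovers the configured log-speed
centers 0.71 and 1.24 to within a few thousandths, and the gear-2 mean
maximal speed matches the lognormal moment implied by the fast component.
`res.provenance` reports per-step invalidation counts; the revisited-pixel
rule removes most *resting* samples (as intended — resting spots are where
jump artifacts concentrate) while motion episodes survive essentially
intact.

The same steps are available from the shell:

```sh
locogear simulate --seed 42 --out rec/
locogear preprocess --in rec/tracking.csv --out clean.csv --report report.json
locogear segment --in clean.csv --out episodes.csv
locogear decompose --episodes episodes.csv --out gears.json
locogear endpoints --traj clean.csv --episodes episodes.csv --out endpoints.json
```

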