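# dyadsync

Lag-resolved analysis of spontaneous bodily coordination between two seated
interactants — typically a child and an adult storyteller — from optical
motion-capture marker tables.

Researchers studying interpersonal coordination want to know whether, how
strongly, with what delay, and in which *morphology* two people's movements
co-occur: **symmetric** (mirror-like: both lean toward or away from each other
together) or **asymmetric** (complementary: one approaches while the other
retreats). `dyadsync` turns per-dyad torso marker trajectories into pooled,
family-wise-corrected cross-correlation curves that answer exactly that, and
ships a synthetic dyad generator with known coupling structure so every stage
of the pipeline can be validated against ground truth.

## The method

For each dyad, the four back markers of each interactant are averaged into a
torso centroid, projected onto the **proximity axis** (the line between the
two interactants' time-mean positions, oriented so that *approaching the
partner is positive for both*), differenced into a speed signal (mm/frame),
and smoothed with a causal single-pole 10 Hz low-pass filter. Coordination
between the storyteller's speed *a* and the child's speed *b* is the
uncentered product-moment coefficient

    r = Σᵢ aᵢbᵢ / √(Σᵢ aᵢ² · Σᵢ bᵢ²)

computed at lag 0 and at 15 delays of 100–1500 ms (child trailing the
storyteller), trimming the non-overlapping ends. Speed fluctuates around
zero, so no mean-centering is applied; the statistic is scale-invariant, so
units never matter. Under the approach-positive convention, r > 0 reads as
symmetric (mirror-like) coordination and r < 0 as asymmetric.

Per-lag correlations rᵢ are pooled across the G dyads of a group in Fisher
space, xᵢ = atanh(rᵢ), as the unweighted mean X with standard error
σ ≈ 1/√(Σᵢ mᵢ), where mᵢ is the number of sample pairs behind rᵢ. Confidence
bands use a two-sided normal quantile at a Bonferroni-corrected level
(default α = 0.001 over 41 comparisons, corrected p ≈ 2×10⁻⁵) and are mapped
back to the correlation scale by R = tanh(X). Contrasts — the within-dyad
pre/post-climax change and group-vs-baseline differences — are plain
differences of Fisher curves with standard errors added in quadrature.

## Worked example

Simulate a small corpus with a known mirror-like coupling (gain 0.1 at
500 ms, present only after the story climax), run the full analysis, and read
off the recovered peak:

```python
import dataclasses
from dyadsync import report, synthetic

template = dataclasses.replace(
    synthetic.DyadSimConfig(), duration_s=60.0, climax_time_s=30.0
)
cells = tuple(((a, c), 4) for a in ("3y", "6y") for c in ("PII", "PAI"))
group = synthetic.GroupSimConfig(cells=cells, template=template, base_seed=0)
_, meta_path = synthetic.simulate_group(group, "scratch/demo")

cfg = report.AnalysisConfig(
    marker_dir="scratch/demo", metadata_path=str(meta_path), out_dir="scratch/demo_out"
)
bundle = report.run(cfg)
peak = bundle.peaks.query("is_global and kind == 'max'")
print(peak[["label", "lag_ms", "R", "morphology"]].to_string(index=False))
```

prints:

```
              label  lag_ms        R morphology
             3y PAI     500 0.092388  symmetric
             3y PII     500 0.071342  symmetric
             6y PAI     500 0.084278  symmetric
             6y PII     500 0.105649  symmetric
             3y PAI     500 0.164598  symmetric
             3y PII     500 0.178956  symmetric
             6y PAI     500 0.144510  symmetric
             6y PII     500 0.155956  symmetric
        age 6y - 3y     800 0.050684  symmetric
condition PAI - PII    1300 0.040247  symmetric
```

The first four rows are the whole-session group curves, the next four the
within-dyad (post − pre) climax contrasts: every group peaks at the injected
500 ms lag with positive sign — the coupling was mirror-like — and the
contrast (R ≈ 0.16) roughly doubles the whole-session value because the
coupling is only present in the post half. It also exceeds the raw coupling
strength (theoretical ρ ≈ 0.0995 on unfiltered speeds) because the 10 Hz
filter removes more of the white coupling noise than of the smooth base
motion. The between-group contrasts (last two rows) have no injected effect;
their small maxima are sampling noise at 4 dyads per cell.

The same analysis is scripted end to end in `analysis/`
(`01_simulate_corpus.py`, `02_run_pipeline.py`, `03_validation_studies.py`),
writing tables and figures under `results/`. A `dyadsync` command-line
interface (`simulate`, `run`, `plot`, and `stage` debug subcommands) wraps
the same library calls.

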