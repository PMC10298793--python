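# slnet

Synchronization-likelihood cortical network analysis for multichannel EEG.

`slnet` is for researchers who want to characterize task-related cortical
activity as a functional network: which scalp electrodes carry mutually
synchronized signals in a given frequency band, how small-world and how
efficient the resulting network is, whether those network properties differ
between task conditions, and which channels (and underlying Brodmann areas)
distinguish one task type from another. The pipeline was built around a
comparison of equation-solving versus computer-programming tasks on the
19-electrode 10–20 montage, but every stage is generic.

## The method

1. **Connectivity — Synchronization Likelihood (SL).** Each band-filtered
   channel is delay-embedded; per reference time *i* a critical distance is
   set to the p_ref-quantile of distances to a comparison window
   w1 < |i−j| < w2, so a fraction p_ref of window points count as
   recurrences. SL(x→y) is the conditional probability that a recurrence of
   x coincides with one of y; the symmetrized index is 1 for identical
   signals and p_ref (default 0.05) for independent ones.
2. **Graphs.** The channels × channels SL matrix is thresholded at fixed
   edge density (default q = 0.2) into a binary graph, one graph per
   subject, task and band.
3. **Metrics.** Characteristic path length L, clustering coefficient C,
   small-worldness SWN = (C/C_rand)/(L/L_rand) against a seeded
   Erdős–Rényi G(n, p) null at matched density, global efficiency
   E_g = ⟨1/d_ij⟩, and per-channel nodal efficiency E_l.
4. **Statistics.** Shapiro–Wilk normality gate; two-tailed asymptotic
   Mann–Whitney U tests for all task pairs (per band and metric); Friedman
   test across the three difficulty levels of a task type.
5. **Channel clustering.** K-means (default K = 3, silhouette-guided) on
   each task's channels × stimuli nodal-efficiency table; clusters matched
   across tasks by Jaccard similarity; channels that belong to a matched
   cluster for the majority of one task type but not the other are reported
   as *differentiating elements*, annotated with Brodmann areas.

A synthetic-data module generates sessions with planted coupling modules
(shared band-limited latent sources plus independent noise), so the whole
pipeline is testable with known ground truth. See `docs/methods.md` for the
full model description and parameter rationale.

## Worked example

Simulate a session in which the programming tasks carry an extra coupled
module on channels 7, 8 and 12, then run the full pipeline on the alpha
band:

```python
from slnet import CouplingSpec, SessionSpec, PipelineConfig, run_pipeline

base = ((1, 2, 3, 4, 5, 6), (13, 14, 15, 16, 17, 18, 19))
plus = ((1, 2, 3, 4, 5, 6, 7, 8, 12), (13, 14, 15, 16, 17, 18, 19))

spec = SessionSpec(
    n_subjects=2, tasks=("ES", "EM", "EC", "PS", "PM", "PC"),
    stimuli_per_task=8, epoch_duration=2.0,
    coupling=CouplingSpec(groups=base, mixing=0.9, noise_sd=0.3,
                          band=(8.0, 12.0)),
    task_overrides={t: {"groups": plus} for t in ("PS", "PM", "PC")},
    seed=42,
)
result = run_pipeline(PipelineConfig(session=spec, bands=("alpha",), seed=42))

print(result.metrics[["subject", "task", "L", "C", "SWN", "Eg"]]
      .round(3).head(6).to_string(index=False))
print(result.differentiating.to_string(index=False))
```

Output:

```
subject task     L     C   SWN    Eg
    S01   ES 1.056 0.653 8.087 0.205
    S01   EM 1.056 0.656 7.826 0.205
    S01   EC 1.056 0.653 7.507 0.205
    S01   PS 1.306 0.644 6.390 0.243
    S01   PM 1.404 0.575 5.194 0.266
    S01   PC 1.373 0.357 3.698 0.247

 band  group task_type channel electrode brodmann
alpha      2         P    Ch07        F8       45
alpha      2         P    Ch08        T3       42
alpha      2         P    Ch12        T4       21
alpha      3         E    Ch07        F8       45
alpha      3         E    Ch08        T3       42
alpha      3         E    Ch12        T4       21
```

Reading the output: the per-subject/task graphs are strongly clustered
relative to their size-matched random nulls (SWN ≫ 1 — the planted modules
form near-cliques), and the programming tasks' extra coupling raises their
global efficiency. The differentiating-element report recovers exactly the
planted channels: Ch07/Ch08/Ch12 belong to a matched cluster in all three
programming tasks but in none of the equation tasks (group 2, type P), and
consequently sit with the unconnected channels only during equation tasks
(group 3, type E). The Brodmann column comes from the built-in
channel → electrode → area montage.

The same run is available from the shell: `slnet simulate`, `slnet sl`,
`slnet graph`, `slnet stats`, `slnet cluster`, and `slnet run config.yaml`
for the end-to-end pipeline with all tables written to an output directory.

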