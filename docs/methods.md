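# Methods

`slnet` models task-related cortical activity as a functional network over
the 19 electrodes of the 10–20 EEG montage: band-limited signals are
compared pairwise with the Synchronization Likelihood, the resulting
connectivity matrix is thresholded into a binary graph, and the graph is
summarized by small-worldness and efficiency measures that are then
compared across task conditions and clustered over channels. This note
records the model, its assumptions, the tunable parameters, and the design
choices made where the procedure was genuinely open.

## Synchronization Likelihood

For channels x and y, each series is delay-embedded
(vector *i* is (x_i, x_{i+lag}, …, x_{i+(m−1)lag})). For a reference time
*i*, the comparison window is J_i = { j : w1 < |i−j| < w2 }: the inner
radius w1 excludes autocorrelation-dominated neighbours, the outer radius
w2 keeps the comparison quasi-stationary. Independently per channel, a
critical distance ε_{k,i} is set to the p_ref-quantile of the Euclidean
distances from vector *i* to the window vectors, so that the fraction of
"recurrences" (hits H_k(i,j) = 1 when the distance is within ε) equals
p_ref by construction. The directed index

SL(x→y) = Σ_{i, j∈J_i} H_x(i,j) H_y(i,j) / Σ_{i, j∈J_i} H_x(i,j)

is the conditional probability of a y-recurrence given an x-recurrence; the
reported value is the mean of the two directions, which makes the matrix
symmetric. Identical channels score exactly 1; independent channels score
p_ref in expectation (the calibration tests verify 0.05 ± 0.01 at N = 4096);
the index is invariant to rescaling either channel, since ε is an empirical
distance quantile.

Implementation notes. ε is the k-th order statistic of the window
distances with k = round(p_ref · |J_i|) (clipped to ≥ 1), which achieves the
target recurrence fraction deterministically up to 1/|J_i| — no iterative
ε search. All channels of an epoch are embedded once and hit masks are
shared across pairs, so an epoch costs O(channels · N · window) for the
distance stage and only the final co-recurrence counts are quadratic in
channels. A channel whose window distances have zero spread (a constant
signal) admits no meaningful ε and raises `SLDegenerateError`.

Parameter recipe (`default_sl_params`). The estimator's parameters are not
universal; the defaults tie them to the analysis band at sampling rate fs:

| parameter | default | rationale |
|---|---|---|
| p_ref | 0.05 | chance level of the index; 5 % recurrence rate |
| lag | round(fs / (3·high)) | ~3 samples per period of the fastest band content |
| m | min(ceil(3·high/low) + 1, 10) | embedding spans the slowest period; capped at m_cap = 10 (the delta band's 0.01 Hz low edge would otherwise demand m ≈ 1200) |
| w1 | 2·lag·(m−1) | skip two embedding spans of serial correlation |
| w2 | w1 + round(10/p_ref) | ~10 expected recurrences per reference time |

If an epoch is too short for the recipe, m is relaxed toward 2 and then the
outer window is shortened; if nothing fits, an error is raised rather than
silently degrading.

## Graphs and metrics

Connectivity granularity. One graph per subject, task and band is built
from the *mean* SL matrix over that task's epochs; this graph provides the
global measures (SWN, E_g). The clustering stage needs per-stimulus nodal
efficiency, so there one graph is built per epoch.

Binarization. No single SL→graph rule is canonical, so the default is
proportional thresholding: the ⌊q·n(n−1)/2⌋ strongest pairs
become edges, q = 0.2 by default (34 edges on 19 nodes). Fixed density
makes graphs comparable across subjects and tasks and keeps every metric's
null at the same density. Ties at the cutoff break deterministically toward
lower channel indices; an absolute-threshold mode is provided.

Metrics, for an unweighted undirected graph with geodesics d_ij:

- L = mean of d_ij over ordered pairs; unreachable pairs are *excluded*
  from the average and the graph flagged disconnected (an edgeless graph
  raises).
- C = mean over nodes of t_i / (k_i(k_i−1)/2) (t_i triangles through i);
  degree < 2 contributes 0.
- E_g = mean of 1/d_ij with 1/∞ = 0 — finite under disconnection.
- E_l,i (nodal efficiency): Σ_{j≠i} 1/d_ij normalized either by n(n−1)
  ("global_sum", so Σ_i E_l,i = E_g exactly) or by n−1 ("per_node",
  bounded by 1). Both conventions circulate; the global_sum form bounds
  each value by 1/n ≈ 0.053 for 19 channels, while the per-node form is
  bounded by 1 and matches the 0–0.4 per-channel magnitudes typically
  reported for sparse EEG graphs of this size. Both are implemented;
  `per_node` is the default and the factor-n consistency of the two is
  tested.
- SWN = (C/C_rand)/(L/L_rand), with C_rand and L_rand the means of an
  Erdős–Rényi G(n, p) ensemble at p = the observed density (100 seeded
  draws by default), applying the identical unreachable-pair rule. Values
  slightly below 1 are reported as-is. The anchor checks: ER graphs against
  a matched null average SWN ≈ 1 (within 0.05 over 200 replicates); a ring
  lattice (n=100, k=6) rewired at p=0.1 keeps C/C_rand ≫ 1 while
  L/L_rand stays in [1, 2].

Shortest paths are computed by breadth-first search realised as repeated
boolean matrix products, which batches across a null ensemble in one numpy
call; the implementation is checked for exact agreement against a naive
BFS/triangle-enumeration oracle and against networkx.

## Statistics

Per band and metric (SWN, E_g), the unit of analysis is one value per
subject per task. A Shapiro–Wilk gate documents non-normality; pairwise
task differences use the two-tailed asymptotic Mann–Whitney U test (normal
approximation with tie and continuity corrections), reported as a symmetric
8×8 table of raw p-values — no multiple-testing correction by default,
with a Bonferroni option. Difficulty levels within a task type use the
Friedman test (df = k−1). Degenerate inputs are defined rather than left to
propagate: fully tied pooled samples give z = 0, p = 1; Friedman blocks in
which every subject ties all conditions give statistic 0, p = 1. The
calibration tests verify a 5 % ± 2 % type-I rate under a global null
(n = 16 per task, 500 replicates) and agreement of the asymptotic p with
the exact permutation p to within 0.05 at n = 4 vs 4.

## Channel clustering and differentiating elements

For each band and each of the six main tasks, channels are described by
their mean nodal efficiency per stimulus (averaged over subjects): a
19 × n_stimuli table. K-means (Euclidean, 10 restarts, seeded) clusters the
rows; K = 3 is the default, with silhouette scores over K = 2…6 and a Ward
dendrogram available for inspection. Rows are not standardized — the
efficiencies already share one scale — though a z-score option exists.
Labels are canonicalized by descending cluster mean so label identity is
reproducible.

Clusters are matched across the six tasks by greedy maximal Jaccard
similarity of member sets, anchored on the first task, ties toward the
lower cluster id, yielding K cross-task groups. Within a group, a channel
is a *differentiating element* for the programming type when it belongs to
the matched cluster in ≥ 2 of the 3 programming tasks and ≤ 1 of the 3
equation tasks (symmetrically for the equation type). The ≥2/≤1 thresholds
quantify a "majority of one type but not the other" rule and are both
configurable. Differentiating channels are reported with their electrode
name and Brodmann annotation from the montage; electrodes whose area
assignment is stated only collectively (C3/Cz/C4 → areas 1/2/5; the
occipito-temporal group → areas 18/37) or not stated at all carry candidate
sets and an `ambiguous` flag rather than a guessed single area.

## Synthetic data: what it emulates and what it does not

The generator emulates the study geometry — 19 channels at 250 Hz, five
analysis bands, 6 main tasks + 2 controls, per-subject/stimulus epochs —
with a planted-module signal model: channel groups share a band-limited
latent source (white noise filtered to the band, unit variance), weighted
by a per-channel mixing coefficient in [0,1], plus independent white noise
(noise_sd = 0.3, mixing = 0.9 by default — a strongly coupled module well
above the SL chance floor). Condition effects are planted with per-task
coupling overrides. Ground-truth labels always accompany the data, and
every epoch has its own deterministic seed stream.

Not emulated: volume conduction and common reference leakage, 1/f spectra,
ocular/muscle artifacts, non-stationarity, or oscillatory (phase-coherent)
dynamics. Passing recovery tests therefore show the pipeline's stages
compose correctly and detect planted coupling of realistic strength — not
that real EEG effects of this size would survive those confounds.

End-to-end recovery is exercised at desk scale: 2 subjects × 6 tasks ×
8 stimuli × 2-second epochs in the alpha band, base modules on channels
{1..6} and {13..19}, with the programming tasks' override adding channels
{7, 8, 12} to the first module. Over 20 seeded replicates the pipeline must
flag those channels as differentiating for the programming type in ≥ 80 %,
and flag nothing when both task types are generated identically.

## Known limitations

- The bivariate SL form is used (pairwise matrix); the fully multivariate
  SL ("channel k against all others") is not implemented.
- Nulls are G(n, p) only; degree-preserving rewiring nulls are out of scope.
- Weighted-graph metrics are not provided; binarization discards SL
  magnitude beyond rank.
- EDF files can be read (via MNE) but sessions are written as delimited
  text + JSON sidecar only.
- The delta band's 0.01 Hz low edge is handled as low-pass-only filtering;
  at 250 Hz a 0.01 Hz IIR high-pass is numerically degenerate and the
  corresponding hardware high-pass is assumed applied upstream.
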