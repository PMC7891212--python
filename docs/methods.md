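# Methods

This note documents the models, parameter choices and numerical
conventions behind `dcinet`, and what the synthetic-data experiments do
and do not establish about real recordings.

## Signal model and spectral stage

Input is a node × sample × trial array of source-space time series with
its sampling rate and epoch. The broadband stage applies a zero-phase
(forward–backward) order-4 Butterworth band-pass (default 0.1–100 Hz)
and an IIR notch (default 60 Hz, Q = 30). Reflection padding is extended
to three time constants of the low cut (capped at the record length)
because an 0.1 Hz high-pass settles over tens of seconds; on short
epochs the broadband stage can be skipped (`skip_preprocess`) when the
generator already band-limits its output.

**Symmetric orthogonalization.** Source leakage produces spurious
zero-lag correlations. We replace the node-by-time matrix X with the
closest (Frobenius) matrix Y = D·O having mutually orthogonal rows,
where O has orthonormal rows and D is diagonal. Y is found by
alternating a polar-decomposition update of O with a rescaling update of
D until the fit error stalls (tol 1e-12, ≤100 iterations). No node is
privileged; rank-deficient input is rejected with the deficient
dimension named. Trials are concatenated along time for the
decomposition — orthogonality is a property of the whole recording — and
split back afterwards.

**Bins, envelopes, AAC.** The band layout is contiguous equal-width
bins; the study layout is ten 5 Hz bins over 0.5–50.5 Hz, and the range
must divide exactly (no partial bins). Each bin is filtered zero-phase
per trial on the full epoch, the amplitude envelope is the modulus of
the analytic signal (Hilbert transform per trial — trials are not
contiguous in time), and only then is the envelope cropped to the
analysis window (default 0.8–1.3 s), keeping filter and Hilbert edge
artifacts outside the window. AAC is the Pearson correlation of two
envelopes; window samples are concatenated across trials by default
(maximizing samples per connection), with per-trial averaging available
(`trial_pooling="average"`). Between-frequency blocks are directed
low → high at this stage: entry (i, j) couples node i's low-bin envelope
to node j's high-bin envelope.

## Surrogate normalization

Each node/trial series is replaced by an IAAFT surrogate: starting from
a random shuffle, alternate (i) restoring the empirical Fourier
amplitude spectrum while keeping current phases and (ii) rank-remapping
onto the sorted original values, stopping when the relative spectral
error improves by < 1e-6 or after 100 iterations. The final step is
always the rank remap, so the surrogate's value multiset equals the
original exactly; the spectrum is preserved approximately. The s-th
surrogate of every node forms the s-th null dataset — all nodes
surrogated simultaneously, which destroys all genuine coupling while
keeping per-node spectra. Surrogates are built from the full epoch; the
connectivity pipeline is re-run per null dataset and per-connection mean
and sample sd (n−1) over the ensemble (default 100) give
z = (AAC − mean)/sd. Connections with zero null sd get z = 0 and a log
message: a connection the null cannot vary must never become a hub.
Surrogates are generated from the already-orthogonalized sources and are
not re-orthogonalized.

Calibration: on independent-noise sources (no planted coupling) pooled
z-scores are close to standard normal — the test suite checks
|mean| < 0.2, sd within [0.7, 1.3] and a 1.96-tail fraction of
0.05 ± 0.02 over ten datasets.

## Network construction

Negative z-scores are clipped to zero before thresholding: only
connections stronger than the null should form edges, and the
spanning-tree/efficiency machinery needs nonnegative weights.
Between-frequency blocks are first symmetrized by the entrywise maximum
of (i,j) and (j,i).

**OMST.** Round m extracts the maximum-weight spanning tree (Kruskal on
distances 1/w; ties broken lexicographically by node index for
determinism) over edges not retained in earlier rounds. After each round
the objective J = GE(retained)/GE(full) − Cost is evaluated, where GE is
weighted global efficiency (mean inverse shortest path length on
distances 1/w) and Cost is the retained fraction of total edge weight.
The returned network is the union over the prefix of rounds maximizing
J; rounds stop when the unused edges no longer span, and a disconnected
input falls back to the maximum spanning forest with a flag. The default
cap of 20 rounds is far above where J peaks on z-scored matrices. The
exact objective of the original orthogonal-MST formulation admits
variants; this prefix-maximization is the committed interpretation and
is verified against a brute-force oracle in the tests.

**Structural constraint and assembly.** Each thresholded matrix is
multiplied entrywise by the binary structural matrix (OMST first, then
mask — the pipeline's stated order; `mask_before_omst` flips it for
sensitivity analysis; masking can disconnect the retained graph, which
is accepted). The B within and B(B−1)/2 between matrices are placed into
the (N·B)×(N·B) supra-adjacency matrix, block (a,b) above the diagonal
and its transpose below. A within-frequency layer retaining a single
spanning tree has density (N−1)/(N(N−1)/2); at N = 246 this is 0.00813,
i.e. 0.008 at three decimals — the constant within-layer sparsity seen
at the study scale.

## Hub statistics

**Versatility** is the stationary distribution of a random walk with
teleportation on the node-layer supra graph: column-normalized
transitions, damping 0.85, teleportation 0.15, dangling node-layers
teleport uniformly, power iteration to L1 tolerance 1e-10. Scores are
aggregated by summing a node's probability over its layer replicas and
sum to 1. With one layer this is ordinary PageRank (verified against an
independent implementation to < 1e-8). Hubs are nodes with
z-standardized versatility strictly > 2 (population-sd convention,
configurable); with a couple hundred nodes the z > 2 rule captures the
fat positive tail of the centrality distribution.

**Interconnectedness and DCI.** Interconnectedness is the number of
nonzero entries in the off-diagonal blocks (a,b), a < b — each
undirected interlayer edge counted once, replica self-pairs (node i in
layer a to node i in layer b) included by default
(`count_replica_pairs=False` excludes them). DCI removes all B replicas
of a node (zeroing rows and columns) and reports the percent drop in
interconnectedness; the implementation is exactly equal to rebuilding
the network without the node (oracle-tested). Because most DCI values
are zero, the profile is scaled to unit sd *without* mean subtraction —
mean-centering would destroy the meaningful zero of a mostly-zero
metric; if all candidates tie the raw values pass through.

**Group inference.** Candidates are nodes flagged as hubs in at least
`min_subjects` subjects (default 1); a subject contributes its scaled
DCI where it detected the hub and 0 otherwise. The one-sample,
one-tailed test builds the null by sign-flipping subject values: exact
enumeration of all 2^n patterns when 2^n ≤ 4096 (p = #{null mean ≥
observed}/2^n, bounded below by 1/2^n), otherwise 5000 random flips with
the add-one estimate. Nodes that are zero in every subject get p = 1 and
a flag. Uncorrected p-values are reported. Note the calibration caveat:
raw DCI is nonnegative by construction, so a one-tailed sign-flip test
on positive-only pipeline values is anticonservative; the test's nominal
type-I error (0.05 ± 0.03 at α = 0.05, verified on 400 node-tests) holds
under the zero-symmetric null the sign-flip argument assumes. In
practice the all-or-nothing structure of hub candidacy (most subjects
contribute 0 at a non-hub) is what separates the planted connector from
bystanders.

## Synthetic data: what it emulates, what it does not

The structural generator is a stochastic block model (within-module edge
probability 4× between-module, calibrated to the requested overall
density, resampled until connected). The source generator superposes,
per node, 1/f^α-shaped Gaussian noise (α = 1) plus white noise
(sd 0.3), and for each planted coupling a sinusoidal carrier at the
bin's center frequency whose amplitude is the mix
(1−s)·own + s·shared of independent and shared positive slow modulators
(low-pass at 1 Hz, unit mean). The envelope correlation of a planted
pair therefore rises monotonically with s and vanishes at s = 0 — the
statistical structure AAC measures and nothing more. The supra fixture
plants a connector by giving one node at least twice the interlayer edge
count of the busiest other node.

Power consideration: a 0.5 s analysis window contains roughly one
independent sample of a ≤1 Hz modulator, so detection power comes from
the trial count, as in real event-related cohorts (tens of trials).
Detection-oriented tests and examples use 20 trials with oscillation
amplitude twice the noise sd; the config defaults (5 trials, amplitude
1) are a fast smoke condition under which single-pair detection is
deliberately underpowered.

Not emulated: realistic head geometry or leakage mixing (orthogonalization
is exercised, but the generator does not simulate beamformer leakage),
non-sinusoidal or bursty oscillations, phase–amplitude coupling,
between-subject anatomical variability, artifacts. Passing tests show
the pipeline recovers the coupling structure it models — not that real
MEG envelope coupling is this clean.

## Problem sizes and determinism

Tests and the acceptance script run on reduced sizes chosen to exercise
every code path: 5–12 nodes, 2–3 bins, 20–50 surrogates, 10–20 seeds per
property, with study-scale dimensions (246 nodes, 10 bins) used where
the quantity is purely structural (sparsity accounting, block counts,
supra dimension). All generators and the surrogate/permutation machinery
are reproducible from explicit seeds; independent streams are derived
via seed sequences so results do not depend on execution order.
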