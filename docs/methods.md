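# Methods

`corehub` estimates directed (effective) connectivity among channels of a
multichannel recording, identifies and classifies the network's hubs,
tracks the resulting "connective core" across conditions and time, and
relates hub dynamics to EEG microstate sequences.  This note documents
the models, the tunable parameters and the design decisions, and states
precisely what the synthetic validation does and does not demonstrate.

## Effective connectivity: normalized transfer entropy

Transfer entropy from source Y to target X over discretized signals,

    TE_{Y->X} = sum p(x_{t+1}, x_t, y_t) log2[ p(x_{t+1}|x_t, y_t) / p(x_{t+1}|x_t) ],

is estimated with plug-in (maximum-likelihood) joint histograms over
single-lag symbol triplets.  Signals are discretized per channel into
`n_bins` equal-width bins spanning the channel's own range (default 8;
the top edge maps into the last bin, a constant channel maps to the zero
symbol).  Single-lag embedding is used for both the target's past and
the source — higher-order embeddings are out of scope.

The plug-in estimate is biased upward for finite data, so the mean TE of
`n_surrogates` random permutations of the source samples (default 30,
seeded) is subtracted; permutation destroys all temporal structure while
preserving the marginal distribution.  The difference is normalized by
the target's conditional entropy H(x_{t+1}|x_t), giving the normalized
transfer entropy (NTE).  Two conventions close the definition:

* negative post-subtraction values are floored at 0, because the graph
  stages (shortest paths, betweenness) require nonnegative weights;
* a deterministic target (H = 0) gets NTE = 0 with a logged warning
  rather than a division by zero.

The connectivity matrix stores `weights[i, j] = NTE_{j->i}` — columns
send, rows receive — and serialized files state this orientation in
their header.  One set of surrogate permutations is drawn per matrix
call and shared across channel pairs; estimates are bit-reproducible
given the seed.

With 8 bins the joint histogram has 512 cells, so windows should contain
at least ~10 x bins^2 = 640 samples; shorter windows trigger a logged
warning about sparse histograms.

## Graph metrics and hub identification

NTE weights are flow-like, so edge lengths are `d = 1/w` (absent edges,
`w = 0`, become infinite); a `-log(w/max w)` alternative is available via
`distance_mapping`.  On the directed distance graph:

* **Betweenness centrality** (networkx, Brandes) with the directed
  normalization 1/((n-1)(n-2)); tied shortest paths all count.  Checked
  in the test suite against an exhaustive all-simple-paths oracle.
* **Characteristic path length** l is the mean shortest-path distance
  over ordered pairs (scipy Dijkstra).  Unreachable pairs are excluded
  from the average with the pair count adjusted (and logged) rather than
  imputed as infinity — this keeps l finite after node removals, so
  percent-impact numbers remain well defined.
* **Hub identification**: a node is a hub when the one-sided
  Mann-Whitney test of its per-window BC samples against the pooled
  samples of all remaining nodes rejects at `significance_level`
  (default 5%) in the direction "this node's BC is higher".  The test
  needs the windowed analysis: a single full-recording matrix yields one
  BC value per node and no rank test is possible.  No multiple-testing
  correction is applied by default (a Bonferroni switch exists), and the
  test direction follows the substantive meaning "statistically higher
  BC".
* **Removal impact**: 100 x (l_after - l_before)/l_before after deleting
  a node set's rows and columns, full network as benchmark.  Each set is
  evaluated independently; no additivity across sets is assumed.

## Hub typing and the connective core

For node i, the output degree OD is the sum of outgoing NTE, the input
degree ID the sum of incoming NTE, and the net entropy K = OD - ID.
K sums to exactly zero over any network (each edge feeds one OD and one
ID) — a conservation law the tests assert to 1e-9.

A hub is **divergent** (HD) when OD > (1 + threshold)·ID with threshold
0.10, **convergent** (HC) in the mirror case, **neutral** (HN)
otherwise.  The "10% higher" band is interpreted multiplicatively: it is
the only reading invariant to uniform rescaling of the weights, which
the unit-free NTE ratios require.  Boundary equality is HN ("higher" is
strict), and OD = ID = 0 (possible after flooring) is HN for lack of
imbalance evidence.  Typing applies to flagged hubs only; K is reported
for every node as a diagnostic.

Core composition is the HD/HC/HN fraction among hubs; mean K per type is
reported per recording, with an explicit "absent type" result (None)
when a type has no members — downstream group comparisons are
conditional on type presence.

## Core tracking across conditions

The connective core of a condition is the set of (node, type) pairs —
a node that stays a hub but changes type counts as a change.  For cores
A and B:

    Γ = 2 n(A ∩ B) / (n(A) + n(B))        homogeneity
    Λ = (n(A\B) + n(B\A)) / (n(A) + n(B))  heterogeneity

The complements are taken relative to the other set; this is the unique
convention under which Λ ∈ [0,1] and Γ + Λ = 1, so the two measures
partition the combined core into an invariant and a variant part.  The
transition table assigns every node that is a hub in at least one
condition a "t1 -> t2" move (NH = non-hub); fractions sum to 1 and nodes
that are hubs in neither condition are excluded.

## Windowed dynamics

Windows are `window_length_s` seconds (default 5) with `window_overlap`
(default 0.8), step = floor(length·(1-overlap)) samples, trailing
partial windows dropped.  Window w derives its surrogate stream from
seed pair (seed, w), so the windowed analysis is reproducible and
windows are mutually decorrelated.

Hub membership plays two roles.  The recording-level hub set comes from
the Mann-Whitney test over the per-window BC samples and feeds the
static analyses.  For the per-window count series, the window-local
analogue flags a node whose BC in that window exceeds the pooled BC
distribution of the whole recording (all nodes x all windows) by more
than the one-sided normal quantile of `significance_level`
(z ≈ 1.645 at 5%); flagged nodes are typed from that window's matrix.
Two simpler designs fail structurally: typing a fixed core each window
makes the per-type counts sum to a constant (perfectly complementary
series in which peaks of different types cannot co-occur), and a cut
relative to the window's own mean/SD admits a near-constant one or two
nodes regardless of how many genuinely central nodes the window has.
Judging windows against the recording-level baseline is the only
variant in which the count total tracks per-window hub richness.

A peak of a count series is a sample that exceeds mean + 1 SD of the
series (population SD) *and* is a local maximum (>= both neighbors;
endpoints compare to their single neighbor) — the conjunction honors
both the thresholding and the local-maximum triggering notions.  Peak
co-occurrence between hub types is the product-moment (phi) correlation
of the indicator series; a constant indicator yields NaN, a
distinguished "undefined" value.

## Microstates and sequence complexity

The global field power GFP_t is the spatial SD of the topography at
sample t.  Topographies at strict local GFP maxima are average-
referenced, unit-normalized and clustered by polarity-invariant modified
k-means (the de facto standard for microstate analysis): assignment by
maximal squared spatial correlation, template update by the first
principal axis of the assigned maps, convergence when the relative GEV
change drops below 1e-6 (at most 100 iterations), deterministic given
the seed.  `n_microstates` defaults to the conventional 4 (A-D).
Back-fitting labels every sample by maximal squared correlation; exact
ties — including flat, zero-variance samples — go to the lowest template
index and flat samples are flagged.  No temporal smoothing is applied by
default.  Template letters are assigned deterministically but
arbitrarily unless reference maps are supplied; canonical A-D identity
is not inferred.

Sequence irregularity uses the LZ76 exhaustive-history complexity over
the 4-letter alphabet: the number of phrases c(n) in the classic
two-pointer parse, plus the normalized form c(n)·log_4(n)/n so values
are comparable across window lengths.  The implementation is checked
exhaustively against an independent naive-substring parser for all
quaternary strings up to length 10.

Windows carrying at least one count-series peak are grouped by trigger:
a single peaking type names the group; two or more form the "common"
group.  The grouping partitions the triggered windows, and the label
subsequence of each window is scored with c and its normalized form.

## Synthetic ground truth

**Coupled VAR networks.**  x(t+1) = A x(t) + eps with A = ar_coeff·I
plus planted couplings; Gaussian noise, 500 burn-in samples, spectral
radius checked (< 1 required, generators rescale couplings below 0.95).
Linear-Gaussian dynamics make directionality unambiguous; a coupled
logistic-map generator provides a nonlinear robustness variant.

`plant_hub_network` builds recoverable source/sink structure: each
source drives ceil((n-1)/2) random targets at coupling 0.45; each sink
is driven by as many drivers at 0.25; every other node sends 3
background edges at 0.12, and with probability 0.7 a background edge
targets a source (preferential attachment).  The bias reflects what
divergent hubs are in real cortical networks — relays that are both
well reached and strongly broadcasting — and is what makes their
betweenness detectable and their removal costly.  A pure
broadcaster/collector topology instead makes the heavily driven sink
the network's dominant relay (half the network reaches it in one cheap
hop, and the bivariate estimator adds spurious out-edges from its
aggregated signal), inverting the expected removal-impact ordering.
Sinks keep a single weak dispersal edge, matching their collector role.
Default simulation: 15 nodes, T = 10,000 at 250 Hz, i.e. 40 s and 36
five-second windows — enough BC samples for the rank test at a few
seconds per run on one CPU.

**Regime switching.**  One switch (`simulate_regime_switch`) or
equal blocks under a duty-cycle pattern (`simulate_alternating`); the
state evolves continuously through switches, so a switch is purely a
change of coupling structure.  The triggered-window complexity study
switches a 72-s, 16-node recording between a quiescent background-only
regime (two blocks in three) and an engaged-core regime (2 sources plus
a relay-like sink).  The duty cycle matters twice: the quiescent
majority keeps the pooled BC baseline low, so during engaged blocks the
divergent sources and the convergent relay clear the hub cut together;
and a plateau occupying a third of a two-level series sits clearly
above the series' mean + 1 SD (at a 50% duty cycle the threshold
coincides with the plateau and strict exceedance almost never fires).
Richer regimes are counterproductive here — spreading centrality over
many hubs dilutes each one's betweenness below the pooled cut.

**Microstate EEG.**  A hidden state switches among k orthogonal,
zero-mean templates with geometric dwell times (default mean 100 ms,
floor 2 samples); each sample is the template scaled by a positive
random amplitude plus white noise at a stated SNR
(RMS signal / RMS noise).  Fast-switching episodes (default 20 ms dwell)
can be planted in chosen intervals; the complexity study plants them
inside the common-trigger windows.  The true label sequence is returned
for scoring.

**What the synthetic validation does not show.**  The generators are
linear (or logistic), stationary within regimes, artifact- and
volume-conduction-free, with orthogonal microstate topographies and
white noise.  Real EEG has correlated broadband noise, non-orthogonal
maps, volume conduction that inflates zero-lag dependence, and
nonstationarities unrelated to coupling changes.  Passing recovery tests
therefore demonstrates the correctness and calibration of the
estimators and decision rules under their own model assumptions — not
field performance on clinical recordings.

## Group-level reporting

Per-subject metrics are compared with the paired Friedman test when
every subject has every group, falling back to Kruskal-Wallis otherwise
(hub types are not always present, so complete pairing cannot be
assumed).  Post-hoc pairwise comparisons after an omnibus rejection use
two-sided rank-sum tests with Bonferroni correction; the post-hoc
procedure choice is a labeled convention, not a claim of optimality.

## Numerical conventions and edge cases

* 0·log 0 = 0 throughout; entropies are computed via `xlogy`.
* Plug-in TE is clipped at 0 against rounding noise (it is nonnegative
  analytically).
* Window step floors length·(1-overlap) with a 1e-9 guard against float
  artifacts (500 · 0.2 is not 100 in binary).
* Betweenness requires >= 3 nodes; fewer than 3 channels in a recording
  degrades the graph stage to a warning at the connectivity step.
* The average reference is an explicit, optional operation — synthetic
  fixtures are never silently re-referenced.
* Zero-phase (forward-backward) order-4 Butterworth filtering is used
  for the optional band-pass so filter delay cannot bias directionality;
  the 0.5 Hz corner rings for seconds, so scoring of filtered signals
  should discard generous edges.

## Known limitations

* Bivariate TE cannot separate direct from common-drive influence;
  heavily driven nodes acquire spurious outgoing edges.  Conditional or
  multivariate TE is explicitly out of scope.
* The histogram estimator's bias grows with n_bins^3/T; the surrogate
  subtraction removes the mean bias but not its variance.  Windows much
  shorter than ~10·bins² samples give noisy matrices.
* Hub identification needs enough windows (>= ~15-20) for useful
  Mann-Whitney power.
* EDF/BrainVision reading delegates to mne and inherits its handling of
  vendor quirks.
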