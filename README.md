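# corehub

Directed brain-network analysis from multichannel time series: estimate
effective connectivity with normalized transfer entropy, find the
network's hubs, classify them by the direction of their information
flow, and track the resulting *connective core* over conditions and
time — down to the EEG microstate sequences that accompany hub dynamics.

The toolkit is aimed at researchers working with EEG (or any
multichannel recording: EDF, BrainVision, or a plain text matrix) who
want a reproducible, seeded pipeline from raw signals to hub-level
statements, plus synthetic ground-truth generators to validate every
step.

## The model in brief

**Connectivity.**  Effective (directed) coupling from channel Y to
channel X is the normalized transfer entropy

```
TE_{Y→X} = Σ p(x_{t+1}, x_t, y_t) log₂ [ p(x_{t+1}|x_t, y_t) / p(x_{t+1}|x_t) ]

NTE_{Y→X} = ( TE_{Y→X} − ⟨TE_{Ỹ→X}⟩ ) / H(x_{t+1}|x_t)
```

with plug-in histograms over equal-width-binned signals, Ỹ a seeded
random permutation of Y (30 surrogates by default) and H the target's
conditional entropy.  NTE is bias-corrected, scale-free and nonnegative;
the N×N matrix of all pairs (columns send, rows receive) is the
directed, weighted graph everything else runs on.

**Hubs and the core.**  Edge lengths are 1/NTE.  Betweenness centrality
`BC_i = 1/((n−1)(n−2)) Σ_{k≠j≠i} #d_k^{ij}/#d_{kj}` is computed per
sliding window (5 s, 80% overlap), and a node is a **hub** when a
one-sided Mann–Whitney test says its windowed BC is higher than the
pooled rest (5%).  Each hub's net entropy `K = OD − ID` (summed outgoing
minus incoming NTE) classifies it as **divergent** (OD > 1.1·ID),
**convergent** (ID > 1.1·OD) or **neutral** — sources, sinks and
balanced relays of information flow.  The hub set is the connective
core; its preservation between conditions is measured by homogeneity
`Γ = 2n(A∩B)/(n(A)+n(B))` and heterogeneity `Λ = 1 − Γ` over
(node, type) pairs, with a full transition table (HD→HD, HN→NH, ...).
Removing a hub set and re-measuring the characteristic path length
`ℓ = mean shortest-path distance` quantifies each hub type's
contribution to network efficiency.

**Dynamics and microstates.**  Per-window hub-type counts form time
series whose peaks (mean + 1 SD, local maxima) trigger window-level
analysis; EEG topographies are segmented into 4 microstates
(polarity-invariant modified k-means on GFP peaks) and the quaternary
label sequence of each triggered window is scored with Lempel–Ziv (LZ76)
complexity.

See `docs/methods.md` for assumptions, parameter defaults, numerical
conventions and limitations.

## Worked example

Plant a 15-node coupled-autoregressive network with two information
sources and one sink, then recover them blind:

```python
import corehub as ch
from corehub.synthetic import plant_hub_network, simulate_var

spec = plant_hub_network(15, n_sources=2, n_sinks=1, seed=11)
rec = simulate_var(spec)                       # 15 x 10,000 at 250 Hz
res = ch.analyze_recording(rec, ch.AnalysisConfig(seed=11))
print(res.hubs[res.hubs.is_hub])
```

prints

```
node  is_hub      K    OD    ID hub_type
 N00    True  0.223 0.369 0.146       HD
 N01    True  0.199 0.319 0.121       HD
 N02    True -0.115 0.106 0.221       HC
```

The planted sources N00 and N01 are flagged as hubs and typed divergent
(positive net entropy K: they emit more NTE than they receive), and the
planted sink N02 is convergent (negative K).  Core composition is 67%
HD / 33% HC.  Deleting the divergent pair stretches the network's
characteristic path length by +49.6%, versus +8.8% for the convergent
hub — the sources are what hold the network's short paths together:

```python
ch.removal_impact(res.connectivity, ["N00", "N01"])   # +49.6 (%)
ch.removal_impact(res.connectivity, ["N02"])          # +8.8  (%)
```

The same stages are available from the shell:

```
corehub simulate --kind hubs --nodes 15 --seed 11 --out rec.txt
corehub hubs --input rec.txt --seed 11 --out-hubs hubs.tsv
corehub microstates --input eeg.txt --k 4 --seed 1 --out-model maps.tsv
```

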