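# flocknet

Social-network inference for RFID feeder-access experiments on wild,
PIT-tagged birds: gathering-event detection in antenna-read streams,
half-weight-index association networks, weighted assortment against
node-permutation nulls, and cross-context network-consistency tests.

## The problem

Automated feeders can impose arbitrary social structure on a wild
population: pairs of selective feeders that open only for tags ending in
an odd (respectively even) digit split the population into two random
classes and force assortment by "tag parity". Around such an experiment
sits a standard but intricate inference chain:

1. **Gathering events.** Antenna reads arrive in bursts as flocks come
   in to feed. Per location-day, a 1-D Gaussian mixture over detection
   times (order chosen by BIC) assigns each read to the event it most
   probably belongs to. Nest-box streams are grouped per box and day.
2. **Association networks.** Events form a group-by-individual matrix;
   dyadic weights are the half-weight index
   `HWI = x / (x + (yA + yB)/2) ∈ [0, 1]`.
3. **Assortment.** The weighted discrete assortativity
   `r = (Σᵢeᵢᵢ − Σᵢaᵢ²)/(1 − Σᵢaᵢ²)` (1 = perfect segregation), with an
   edge-jackknife SE and a node-permutation null that preserves network
   structure, gregariousness and type counts.
4. **Consistency.** Mantel correlations between time-windowed or
   cross-context networks (joint row/column permutation p, node-bootstrap
   CI), and MRQAP with double semi-partialing to separate the effect of
   the feeder social network from binary spatial range overlap.

A generative model of the full experiment (fission–fusion flocks driven
by a latent social-preference matrix, parity-restricted feeders, denied
reads, ephemeral patches, nest-box prospecting, slow home-range drift)
makes every stage testable end to end. See `docs/methods.md` for models
and assumptions.

## Worked example

```sh
python analysis/01_simulate.py --seed 1       # simulate the experiment
python analysis/03_assortment.py --seed 1     # Fig-2-style assortment table
```

The assortment driver simulates a desk-scale version of the experiment
(100 birds, 10/20/6-day periods), detects events, builds networks per
context and period and tests each against 1,000 node permutations. It
prints:

```
         context  period      r     se  null_lo  null_hi      p  n_nodes
selective_feeder     pre -0.012  0.026   -0.047    0.034  0.646      100
selective_feeder  during  0.597  0.015   -0.042    0.034  0.001      100
selective_feeder    post  0.034  0.029   -0.055    0.043  0.205      100
 ephemeral_patch     pre -0.029  0.043   -0.081    0.065  0.481       81
 ephemeral_patch  during  0.094  0.033   -0.064    0.045  0.003       88
        nest_box  during  0.473  0.140   -0.286    0.288  0.001       52
        nest_box    post  0.211  0.138   -0.256    0.265  0.129      66
```

Reading it: before the manipulation, feeder assortment by tag parity is
indistinguishable from the permutation null (r = −0.012 inside
[−0.047, 0.034]). During the manipulation the feeder network is strongly
assorted (r = 0.597, far above the null), and — although patches and
nest-boxes impose no access rules — both carry the segregation
(r = 0.094 and 0.473, p < 0.01): social structure created in one context
spills into others. Six days after the restriction is lifted the feeder
network is back inside the null (r = 0.034): the imposed structure
dissolves as soon as it is no longer enforced.

`python analysis/04_consistency.py` adds the windowed Mantel curves
(each window's network against the final pre-manipulation window and the
post network — similarity to the post reference rises through the
manipulation) and the cross-context Mantel/MRQAP table, where the feeder
social network has a several-fold larger coefficient than spatial range
overlap.

A `flocknet` CLI wraps the same library
(`simulate`, `detect-groups`, `build-networks`, `assort`, `compare`,
`run-all`), each output carrying a JSON provenance sidecar.

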