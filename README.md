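# paintprox

Proximity mapping for multiplexed DNA-PAINT super-resolution data.

In sequential multiplexed DNA-PAINT (adapter/eraser-based "exchange"
imaging), many protein targets are imaged one per round on the same
specimen, each round yielding a table of single-molecule localizations.
Where those targets sit relative to each other — for example, whether a
bridge-like lipid transfer protein such as VPS13B lies nearer the cis or
the trans face of the Golgi complex — is read out from inter-channel
distances at nanometer scale.  `paintprox` provides that analysis as a
reusable, tested pipeline for localization tables, together with a
synthetic-data generator with known ground truth so every stage can be
validated without microscope data.

## The statistic

For a source channel *A* and target channel *B*, the pipeline computes the
distance from **every** localization of *A* to its nearest neighbor in
*B*, discards distances of 500 nm or more (strict `<` cutoff), and
summarizes each directed pair by the **median** of the retained
distances:

```
 d_i = min_j || a_i − b_j ||,     keep d_i < c  (c = 500 nm)
 M[A→B] = median{ d_i }
```

The K×K matrix `M` over all channel pairs is the proximity heatmap; the
full distance samples behind it are exported for violin-style plots.  The
matrix is directed (`M[A→B] ≠ M[B→A]` in general, e.g. for a punctate
channel against a dense layer); an optional pooled symmetrization is
available.

Because each round is acquired separately, rounds must first be placed in
a common frame.  `paintprox` registers rounds by cross-correlating
rendered 2D histograms, with two refinements suited to multiplexed data
(different rounds image *different* structures): the shift is taken as the
correlation surface's center of symmetry rather than its raw maximum, and
shifts measured between every pair of rounds are combined by reweighted
least squares (redundant registration).

A NeNA-style estimator reports per-channel localization precision from
the distances between repeated localizations in adjacent camera frames.

## Worked example

Simulate the default multiplexed Golgi experiment (eight rounds: VPS13B
plus seven cis→trans reference markers on ring-shaped ministacks), align
the rounds, and compute the proximity matrix:

```sh
paintprox run --seed 7 --output out
```

`out/median_matrix.csv` then holds the directed median distances in nm
(rows = source channel):

```
          GM130  GRASP65  VPS13B  Giantin  GALNT2  Rab6  Golgin97  TGN46
GM130       0.0      9.7    23.1     58.1    66.0  73.6      90.8  101.6
VPS13B     27.2     30.5     0.0     33.1    42.3  46.8      65.5   74.7
TGN46     103.3    108.2    64.8     41.0    34.0  26.4      12.8    0.0
...
```

Reading the VPS13B row: its localizations sit a median of 27 nm from
GM130 and 31 nm from GRASP65 (the cis markers), ~33 nm from the medial
marker Giantin, and 65–75 nm from the trans markers Golgin97 and TGN46 —
the signature of a protein confined to the cis/medial interface.
`rank_partners(result, "VPS13B")` returns exactly this ordering.  The
run also writes `pair_distances.csv` (long-format distances behind each
matrix entry), `registration.csv` (per-round shift estimates;
sub-nanometer residuals here since the simulated stage shifts are zero),
`precision.csv` (per-channel σ; ≈5 nm, matching the simulated
localization error), `heatmap.png`, and a `manifest.json` provenance
record.

The same pipeline runs on real localization tables (CSV with `x_nm`,
`y_nm`, `frame` columns, or one HDF5 group per channel; camera-pixel
units are converted via `pixel_size`, e.g. 108 nm) with a config file:

```yaml
mode: real
input:
  path: channels.h5
  round_order: [GM130, GRASP65, VPS13B, ...]
alignment: {reference: GM130}
proximity: {cutoff: 500}
output_dir: out
```

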