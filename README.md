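# gma — Gaussian multiscale aggregation hand segmentation

Graph-based segmentation that isolates a hand (foreground object) from
arbitrary textured backgrounds, together with a synthetic
hand-over-texture database generator and a supervised F-measure
evaluation harness.

## How it works

1. The RGB image is projected onto the CIELAB a* axis (green–red
   opponent channel) and rescaled to the unit interval.
2. The pixel lattice becomes the scale-0 graph: one node per pixel with
   4-neighbourhood edges. Every node carries a *similarity function*
   φ — a unit-integral density over the a* axis (a Gaussian from the
   local neighbourhood mean/std at scale 0, a normalized mixture of the
   members at coarser scales).
3. Edge weights are the overlap ∫ min(φ_i, φ_j) of the incident
   densities (product and Bhattacharyya functionals are selectable).
4. Each scale pass walks the edges in descending-weight order and
   groups nodes whenever the pooled dispersion of the merge stays below
   the (member-count-weighted) geometric mean of the part dispersions
   plus a relaxation k. When a scale stalls, k is incremented and the
   scale retried.
5. Groups become the nodes of the next scale; structure is rebuilt by
   Delaunay triangulation over group centroids. The loop runs until
   two segments remain; the segment with the smaller border fraction is
   labeled hand.

## Package layout

| module | contents |
| --- | --- |
| `gma.graph_core` | a\*-plane conversion, scale-0 lattice graph, Delaunay restructuring |
| `gma.similarity` | similarity functions, grids, weight functionals, mixture aggregation |
| `gma.aggregation` | the multiscale engine: edge ordering, merge criterion, scale loop, hand labeling |
| `gma.synthdb` | synthetic database: hand silhouettes, 17 procedural texture families, Y-equalized + opened compositing, manifests |
| `gma.evaluation` | confusion counts, F-measure, batch per-texture reports |
| `gma.cli` | `gma segment / gendb / eval` commands, TOML/JSON run configs |

## CLI

```sh
# segment one image into a binary {0,255} mask PNG
gma segment input.png --out mask.png --trace trace.json [--config run.toml]

# generate a synthetic database (or only its manifest)
gma gendb --config db.toml --out-dir db/
gma gendb --config db.toml --manifest-only

# evaluate a segmenter over a manifest (per-texture F table)
gma eval --manifest db/manifest.csv --segmenter gma --out report.csv
gma eval --manifest db/manifest.csv --segmenter oracle --out report.csv
gma eval --manifest db/manifest.csv --segmenter external --pred-dir masks/ --out report.csv
```

Config files are TOML (JSON accepted) with `[aggregation]` and `[db]`
sections mirroring `AggregationParams` and `DbConfig`; unknown keys are
rejected. Exit code 2 from `segment` flags a degenerate one-segment
result (e.g., a constant image).

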