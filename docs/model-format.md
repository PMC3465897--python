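# Model parameter file format

A model is one UTF-8 text file. `#` starts a comment (to end of line);
blank lines are ignored; indentation is cosmetic. Two complete examples
ship with the package: `src/neurosweep/data/toy_cerebellum.txt` (3-type
toy cerebellum) and `src/neurosweep/data/minimal_two_type.txt` (smallest
useful model). `neurosweep gen-fixture` writes either to disk.

## Units

micrometres (µm) for all coordinates; somas per µm³ for cell densities;
synapses per µm³ of overlap volume for synapse densities; µm/ms for
propagation speeds; milliseconds for the resulting delays.

## Top level

```
model_space XMIN XMAX YMIN YMAX ZMIN ZMAX
master_seed INT
```

`model_space` (required) is the patch being modelled and must have
positive volume. `master_seed` (default 0) drives all randomness; two
runs of the same file are byte-identical.

## Cell types

```
cell_type NAME
    density FLOAT                                 # somas per um^3
    layer XMIN XMAX YMIN YMAX ZMIN ZMAX           # within model_space
    region NAME axonal|dendritic XMIN XMAX YMIN YMAX ZMIN ZMAX
```

`round(density × layer volume)` somas are placed uniformly in `layer`,
which must lie inside `model_space`. Each `region` line declares one
neuritic box **relative to the soma**; every instance of the type carries
the same boxes translated to its soma. Region names must be unique within
a type. Region boxes may extend beyond the model space (long fibers cross
patch boundaries).

Region names may contain `/` to form a hierarchy: a rule that names
`dend` also matches `dend/0` … `dend/7`. The octet-split operation uses
this to refine dendritic boxes without touching the rules.

## Synapse rules

```
rule PRETYPE.PREREGION -> POSTTYPE.POSTREGION
    density FLOAT                  # synapses per um^3 of overlap volume
    sign excitatory|inhibitory
    axonal_speed FLOAT             # um/ms
    dendritic_speed THRESHOLD SPEED    # repeatable
    dendritic_speed inf SPEED          # final line: covers all distances
    exclude_self true|false        # optional, default false
```

`PREREGION` must resolve to axonal region(s) of `PRETYPE`, `POSTREGION`
to dendritic region(s) of `POSTTYPE`. For every 3D overlap between a
matching axonal and dendritic box, the synapse count is Poisson with mean
`density × overlap volume`, placed uniformly inside the overlap.
`dendritic_speed` lines form a piecewise profile ordered by strictly
increasing distance thresholds; the last threshold must be `inf`.
`exclude_self true` suppresses overlaps between a cell's own regions.

## Errors

Malformed text raises a syntax error with the 1-based line number.
Semantic violations raise named errors: unknown cell-type or region
reference, polarity mismatch, negative density, duplicate name, layer
outside the model space, non-increasing speed thresholds.

## JSON form

`model_spec_to_json` / `model_spec_from_json` give a canonical JSON
serialization of the same content for machine round-tripping.
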