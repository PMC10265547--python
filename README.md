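# wmdissect

Automated virtual dissection of white-matter bundles from whole-brain
tractograms, with streamline-density mapping, test-retest reproducibility
metrics, and a synthetic phantom generator for end-to-end validation without
imaging data.

## What it does

- **Bundle registry** — a declarative, YAML-serializable dissection protocol.
  The built-in default registry defines 68 bundles (15 bilateral association
  families, 8 commissural bundles including the corpus callosum in 7
  segments, 12 bilateral projection families, 3 bilateral cerebellar
  families). Each definition lists include VOIs (all must be intersected),
  exclude VOIs (any hit rejects), optional endpoint VOIs (streamlines must
  terminate inside), filter parameters, and a minimum-streamline failure
  threshold (default 10, applied both after selection and after the first
  filtering step).
- **VOI materialization** — parcellation labels (symbolic names or raw ids),
  world-space boxes, midsagittal slabs, and 6-connected dilations, all
  rendered as binary masks on the parcellation's grid.
- **Dissection engine** — streamline selection by arc-length resampling
  (default step: half the smallest voxel dimension), length filtering,
  medoid-distance outlier rejection, moving-average smoothing, and per-stage
  counts with failure flagging.
- **Maps** — streamline-density maps (one count per streamline per traversed
  voxel), binary masks, and voxel-wise heat maps of summed replicate masks.
- **Metrics** — Dice, density-weighted Dice, density correlation, volume
  overlap/overreach, bundle adjacency (mm), two-way random absolute-agreement
  single-measure ICC with 95% confidence bounds, and descriptive summaries
  (median / sample stdev / IQR / min, maximum absolute inter-session
  difference).
- **Phantoms** — miniature parcellations plus geometric bundles (straight,
  arc, helix, commissural arch centerlines with Gaussian radial jitter),
  distractor streamlines, test-retest session pairs, and an "atlas" phantom
  binding the full symbolic region vocabulary of the default registry.

All computation happens in world RAS+ millimetres; TCK/TRK/NIfTI quirks are
confined to the I/O layer (backed by nibabel).

## CLI

```bash
# generate a demo phantom scene (parcellation, tractogram, truth, registry)
wmdissect phantom --out scene/ --seed 3

# dissect a whole-brain tractogram into bundles
wmdissect dissect --tractogram scene/whole_brain.tck \
    --parcellation scene/parcellation.nii.gz --labels scene/labels.json \
    --registry scene/registry.yaml --out run1/

# per-bundle similarity table between two dissections (long-format CSV)
wmdissect compare --a run1/ --b run2/ --out similarity.csv

# heat map of summed binary masks across replicate runs
wmdissect heatmap run1/ run2/ run3/ --out heat/

# reliability of a per-bundle score table (items x sessions CSV)
wmdissect icc --ratings scores.csv
```

Omitting `--registry` uses the built-in 68-bundle protocol; its label-based
VOIs use a documented symbolic vocabulary that resolves against the atlas
phantom's label table, and real atlas label ids can be substituted via
`label_ids` in a user-supplied registry file.

## Layout

- `src/wmdissect/registry.py` — bundle definitions, schema, default protocol
- `src/wmdissect/io.py` — TCK/TRK/NIfTI I/O, world/voxel coordinate contract
- `src/wmdissect/voi.py` — VOI mask materialization
- `src/wmdissect/dissect.py` — selection, filtering, smoothing, failure rule
- `src/wmdissect/maps.py` — density maps, binary masks, heat maps
- `src/wmdissect/metrics.py` — similarity and reliability metrics
- `src/wmdissect/phantom.py` — synthetic scenes and test-retest replication
- `src/wmdissect/cli.py` — CLI subcommands, run planning, manifests
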