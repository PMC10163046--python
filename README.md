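# ncplink

Tools for linking species to Nature's Contributions to People (NCPs,
a.k.a. ecosystem services) and mapping them spatially:

* **NCP catalog** (`ncplink.catalog`) — NCP definitions with category
  (material / non-material / regulating), per-lineage applicability
  (tracheophytes, vertebrates) and sign permissions. A built-in 17-NCP
  catalog ships with the package (`load_catalog("builtin")`).
* **Relationship table** (`ncplink.table`) — a species × NCP matrix of
  signed values {+1, 0, −1} with two NA flavours (no information vs. not
  applicable), validation, per-species score summaries, per-NCP sign
  counts, species filtering (minimum occurrences, alien exclusion),
  synonym merging and top-species ranking.
* **Attribution** (`ncplink.attribution`) — rules that turn evidence into
  cell values: membership lists (+1/−1 for members, 0 otherwise),
  third-quartile thresholding of reference counts (strictly above Q3 →
  +1), and policy-based merging of heterogeneous evidence records.
* **Spatial index** (`ncplink.spatial`) — rasterize point occurrences
  onto a regular grid and compute, per pixel and NCP category,
  `index = mean(per-species category score) × pixel area [km²]`, with
  optional boundary clipping of border pixels. Output as CSV or ESRI
  ASCII raster.
* **Synthetic data** (`ncplink.synth`) — seeded generators for
  relationship tables (with exact ground-truth tallies), occurrence
  grids with controlled richness, and heavy-tailed reference counts;
  plus a full-scale preset table (2066 species, 208 missing cells).

## CLI

The `ncplink` entry point mirrors the pipeline stages:

```bash
# generate a synthetic relationship table and validate it
ncplink simulate table --n-tracheophytes 50 --n-vertebrates 20 --seed 1 --out table.csv
ncplink validate --table table.csv --catalog builtin

# per-(group, NCP) summary counts and top-scored species
ncplink summarize --table table.csv --out-dir out/ --group-by subgroup --top-n 5

# merge evidence and quartile-thresholded reference counts into cell values
ncplink attribute --evidence evidence.csv --counts scientific_interest=counts.csv --out cells.csv

# per-pixel NCP index maps (one per category) with a run manifest
ncplink simulate occurrences --table table.csv --nrows 4 --ncols 4 --out occ.csv
ncplink map --table table.csv --occurrences occ.csv --out-dir maps/ \
        --cell-size 1 --ncols 4 --nrows 4 --format csv
```

Every command accepts `--config config.yaml`; explicit flags override
config values. Exit codes: 0 success, 1 validation/attribution failure,
2 usage error.

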