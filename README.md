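# histotex

Texture-based classification of normal vs. fibrotic liver histology across
three color spaces (grey scale, RGB, HSI) and three image resolutions
(full, half, quarter).

The pipeline:

1. **Images** — 24-bit RGB rasters (BMP/PNG), 680×512 at full resolution;
   half/quarter resolutions by block-mean averaging. Each image is split
   into 4 equal non-overlapping ROIs (2×2 grid after trimming a border
   margin). A synthetic trichrome-like liver generator (`synthetic_data`)
   produces labeled cohorts (5 control + 7 fibrosis images → 20 + 28 ROIs)
   so everything runs without external data.
2. **Color spaces** — luminance grey (BT.601 weights), separated R/G/B
   channels, and H/S/I channels; each layer is analyzed as an independent
   grey-scale image.
3. **Normalization** — every channel ROI is clipped to μ ± 3σ of its own
   values and quantized to 7 bits (integers 1–128), removing brightness
   dependence.
4. **Texture engines** — co-occurrence matrix at d=1, θ=0° (11 Haralick
   features); run-length matrices in 4 directions (5 features each);
   orthonormal Haar wavelet subband energies E_1..E_5.
5. **Feature selection** — parameters pooled per scheme (channel-prefixed
   columns), ranked by the two-class Fisher coefficient
   (m₁−m₂)²/(v₁+v₂); the top 3 become the classification features.
6. **Classification** — unsupervised 2-cluster k-means on standardized
   features (optional leave-one-out 1-NN); per-group percentage error
   = 100 × misclassified / group size.

## CLI

```bash
# synthetic labeled dataset (writes PNGs + manifest.csv)
histotex generate --seed 0 --out data/

# feature table of one grid cell
histotex features --data data/ --resolution quarter --scheme RGB --method COM --out feats.csv

# full grid: 3 schemes x 3 resolutions x 3 methods -> errors.csv + selected_features.csv
histotex run --data data/ --out results/
histotex run --seed 0 --out results/            # synthetic cohort generated on the fly

# bar-chart panels of the error table
histotex plot --errors results/errors.csv --out errors.png
```

Useful flags on `run`: `--resolutions full,half,quarter`,
`--schemes greylevel,RGB,HSI`, `--methods COM,RLM,WT`,
`--classifier {kmeans,1nn-loo}`, `--margin 0.05`, `--seed N`.

## Library use

```python
import histotex as ht

config = ht.SyntheticConfig(master_seed=0)
result = ht.run_experiment(config=config, seed=0)
print(result.errors)     # scheme / resolution / method / group / percent_error
print(result.features)   # top-3 Fisher-selected features per grid cell
```
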