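# radrep

Test–retest repeatability analysis of PET radiomics features on synthetic
cohorts.

A PET acquisition can be split into two statistically equivalent but
independent halves (in the clinic: reconstructing odd- and even-time-stamp
list-mode events separately). Features extracted from both halves of the same
scan then measure each feature's intrinsic repeatability without a second
scan. `radrep` implements that whole analysis as a reusable pipeline:

1. **phantom simulation** (`radrep.phantom`) — brain-like activity maps with
   textured spherical tumors (tumor-to-background contrast ≥ 1.6), Gaussian
   PSF blur, Poisson counting noise, and an exact event split via
   Bernoulli-½ thinning, which yields two independent Poisson half-count
   images; multi-group cohorts with per-group tumor volume and texture
   distributions.
2. **segmentation** (`radrep.segmentation`) — SUV normalization, a 30-mm
   background reference sphere, tumor auto-contouring at a
   tumor-to-brain-ratio threshold of 1.6, and a series of spherical VOIs
   (10–40 mm) centered on the uptake maximum. Masks are defined once on a
   reference image and reused voxel-for-voxel on both halves.
3. **image filters** (`radrep.filters`) — 13 filtered variants per image: all
   8 single-level undecimated coif1 wavelet decompositions (LLL…HHH) and 5
   scale-normalized Laplacian-of-Gaussian scales (sigma 1–5 mm).
4. **feature bank** (`radrep.features`) — 93 features per variant (18
   first-order + 24 GLCM + 14 GLDM + 16 GLRLM + 16 GLSZM + 5 NGTDM), i.e.
   1,302 features per VOI over the 14 variants. Intensities are discretized
   with a fixed bin width of 0.15; no voxel resampling; no shape features
   (VOI geometry is identical across a pair by construction).
5. **repeatability** (`radrep.icc`) — per-feature two-way absolute-agreement
   single-measure ICC with exact F-based 95% CI, classified into
   repeatable / moderately repeatable / not repeatable CI bands, summarized
   per family, filter, VOI size and genotype group.
6. **clustering** (`radrep.cluster`) — z-scored Ward clustering of subjects
   on the repeatable-feature subset, genotype purity with a permutation null.

## CLI

```sh
radrep simulate --config cohort.yaml --out sim/ --seed 1   # images + manifest
radrep segment  --image sim/images/sub-000_test.nii.gz --out seg/
radrep filter   --image sim/images/sub-000_test.nii.gz --out variants/
radrep extract  --image ... --mask seg/tumor.nii.gz --out features.csv
radrep icc      --test tumor_test.csv --retest tumor_retest.csv --out icc.csv
radrep cluster  --features ... --icc icc.csv --labels labels.csv --out out/
radrep run      --config cohort.yaml --out run/ --seed 1   # everything
```

`run` writes `cohort.csv`, per-VOI tidy feature tables, per-VOI ICC tables,
`repeatability_summary.json`, cluster assignments/composition, and a
`manifest.json`; rerunning with the same config and seed reproduces all CSV
outputs bitwise. See `examples/cohort.yaml` for a config template; any field
of `radrep.pipeline.PipelineConfig` can be set there.

## Library example

```python
from radrep import (PhantomSpec, simulate_pair, sphere_mask,
                    variant_feature_vector, icc_a1)

spec = PhantomSpec(tumor_radius=14.0, texture_amplitude=0.25)
_, test, retest = simulate_pair(spec, seed=1)
voi = sphere_mask(test, spec.tumor_center, 20.0)
features_test = variant_feature_vector(test, voi)     # 1,302 named features
features_retest = variant_feature_vector(retest, voi)
```
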