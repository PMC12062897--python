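# findwormz

Automated fluorescence quantification of *Caenorhabditis elegans* from
paired brightfield/fluorescence micrographs.

Manually tracing each worm in ImageJ limits the sample size of *C. elegans*
fluorescent-reporter experiments. `findwormz` automates that step for
images in which the worms have been gently pushed apart so that no two
animals touch: it segments each worm from the **brightfield** channel,
transfers the per-worm pixel masks to the **fluorescence** channel, and
reports background-subtracted intensity statistics per animal, plus a
color-coded overlay image for visual quality control. It is aimed at bench
scientists running reporter screens (e.g. transcriptional mCherry/GFP
fusions) who want per-worm numbers out of a folder of image pairs with a
single command.

## The method

For each field of view the brightfield image is prepared by percentile
contrast stretching, division by a wide-Gaussian estimate of the
illumination field, and a slight Gaussian blur (worms are transparent, so
transmitted light leaves light and dark patches inside one animal; the blur
evens these out). The prepared image is thresholded by Otsu's criterion,
small holes are filled and specks removed, and connected components are
labeled. Each object is scored for its **worminess**

    W = P / (4 * sqrt(A))

where *P* is the object's perimeter (Crofton estimate) and *A* its pixel
area. *W* is scale-invariant: an ideal circle scores the minimum
sqrt(pi)/2 ≈ 0.89, a square scores 1.0, and elongated objects score higher.
Adult worms fall in the default acceptance band **[1.5, 2.1]**; round
debris and ragged artifacts fall outside it and are discarded, after which
a minimum-area filter removes anything too small to be a worm at the
working magnification.

The surviving masks are applied to the *raw* fluorescence image. For each
worm the mean and standard deviation of fluorescence, area, perimeter and
worminess are recorded. One background level is estimated per image as the
mean fluorescence over every pixel **not** detected as foreground at the
thresholding stage — including debris that the shape filter later rejects —
so junk on the slide can never contaminate the background; this background
is subtracted from each worm's mean.

The package also ships a synthetic-plate generator that renders ground-truth
brightfield/fluorescence pairs (curved dark tubes with planted per-worm
fluorescence means, round debris, specks, illumination ramp, sensor noise),
so the entire pipeline is testable offline against known answers.

## Worked example

Generate a four-condition synthetic experiment and quantify it:

```sh
findwormz synth --out plates --n-images 4 --n-worms 10 --seed 1
findwormz run --input plates --output results --key plates/key.csv
```

which prints

```
wrote 4 synthetic plate pair(s) to plates
processed 4 image(s), 0 failed; 40 worms kept, 8 removed by worminess, 0 by size
```

The 8 rejected objects are the planted round debris (worminess ≈ 0.89,
below the 1.5 bound). `results/measurements.csv` holds one row per kept
worm:

```
pair_id,worm_number,condition,mean_fl,sd_fl,area,perimeter,worminess,background_fl,mean_fl_bgsub,...
plate01,1,cond_a,3866.37,659.98,1441.0,274.75,1.809,1000.63,2865.73,...
plate01,2,cond_a,3900.34,628.43,2056.0,287.07,1.583,1000.63,2899.70,...
```

`worm_number` matches the number drawn on `results/plate01_overlay.png`,
so any mis-identified object can be spotted and its row dropped.
`mean_fl_bgsub` is the worm's mean fluorescence minus the per-image
background (here ≈ 1000.6, the planted level was 1000): plate01's worms
were planted at mean 4000, and the recovered background-subtracted means
cluster at ≈ 2900 ± noise, i.e. 4000 − 1000 with a small shrinkage from
mask-edge pixels. `results/backgrounds.csv` lists the per-image background
and the number of pixels it was averaged over, and each overlay has a JSON
sidecar mapping worm numbers to centroids and colors.

For real data, point `--input` at a folder of `*_BF.tif` / `*_Fl.tif`
pairs (patterns configurable) with an optional `key.csv` mapping filename
stems to condition labels. All tunables — worminess band, minimum area,
blur width, threshold mode, polarity — are CLI flags or YAML config keys;
see `findwormz run --help`.

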