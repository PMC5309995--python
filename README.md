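# nucleotool

Continuous nucleosome-occupancy analysis from mapped sequencing fragments:
windowed occupancy tracks, replicate statistics, stable/fuzzy region
calling, differential occupancy, nucleosome-repeat-length (NRL) estimation
from phasograms, feature-aligned aggregate profiles and k-means cluster
maps. A built-in simulator generates fragment data with known ground truth
so the whole pipeline is testable without external downloads.

All coordinates are BED-style 0-based half-open. Readers accept plain or
gzip-compressed files interchangeably (content sniffing); writers compress
when the output path ends in `.gz`.

## Library layout

| module | purpose |
| --- | --- |
| `nucleotool.fragments` | BED I/O, strand extension of single-end reads, paired-end mate merging, chromosome splitting, fragment-length estimation by strand cross-correlation |
| `nucleotool.occupancy` | fragment coverage → windowed `.occ` tracks, depth normalization `O_N = <O_R> / (nuc_size · N_R / chr_length)`, region extraction, methylation-call conversion |
| `nucleotool.replicates` | per-window replicate mean / SD / SE, relative error, stable (`rel_err < 0.2`) vs fuzzy (`rel_err > 2`) calls |
| `nucleotool.differential` | relative occupancy change `O_diff = 2(O_1 − O_2)/(O_1 + O_2)`, gained/lost region reporting |
| `nucleotool.nrl` | start-to-start phasogram, Savitzky-Golay peak detection, NRL as slope of peak position vs peak index |
| `nucleotool.aggregate` | feature-aligned profile matrices, high-occupancy artifact filtering, gap-aware aggregate profiles, smoothing, derivatives |
| `nucleotool.clustermap` | row sorting (mean signal / external score), seeded k-means, order transfer between conditions, per-cluster BED export, heatmaps |
| `nucleotool.simulate` | regular nucleosome-array fragments (known NRL) and replicate scenarios with planted stable/fuzzy/gained/lost regions |

## CLI

A typical workflow, end to end on simulated data:

```bash
# simulate fragments from a regular array (NRL 190, jitter 20 bp)
nucleotool simulate --nrl 190 --jitter 20 --fragments 50000 --seed 1 --out sim.bed.gz

# split mixed-chromosome input, make 100-bp occupancy tracks
nucleotool split-chrom reads.bed.gz chroms/
nucleotool occupancy --window 100 --normalize chroms/chr1.bed chr1.occ.gz

# single-end preprocessing
nucleotool fraglen --max-shift 400 chroms/chr1.bed
nucleotool extend-se --length 147 chroms/chr1.bed chr1.frags.bed.gz
nucleotool extend-pe pairs.bed frags.bed.gz

# replicate averaging and stable/fuzzy calls
nucleotool average --out mean.occ --stats-out stats.tsv rep1.occ rep2.occ rep3.occ
nucleotool stable-regions --stable-max 0.2 --fuzzy-min 2 --err sd \
    --out regions.tsv rep1.occ rep2.occ rep3.occ

# differential occupancy between two conditions
nucleotool compare --signal occupancy --threshold 0.99 esc.tsv mef.tsv \
    --out-gained gained.tsv --out-lost lost.tsv

# NRL estimation
nucleotool nrl --delta 1000 --out phasogram.tsv sim.bed.gz
nucleotool nrl-fit phasogram.tsv --out fit.json --plot nrl.png

# aggregate profiles and cluster maps around features
nucleotool aggregate --flank 50000 --window 100 --max-fold 10 \
    trackdir/ features.bed --out-profile agg.tsv --out-matrix matrix.tsv.gz
nucleotool clustermap --k 5 --subregion -500 500 --seed 17 matrix.tsv.gz \
    --features features.bed --out-order order.tsv --out-heatmap hm.png
nucleotool clustermap --apply-order order.tsv matrix2.tsv.gz --out-heatmap hm2.png

# methylation calls (chrom, pos, fraction TSV) to a density track
nucleotool meth-track --threshold 0.5 --window 100 calls.tsv meth.occ
```

Occupancy files are two tab-separated columns (window start, value); the
chromosome name defaults to the file stem (`chr1.occ.gz` → `chr1`).

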