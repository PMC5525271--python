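# photosrna

Small-RNA and degradome analysis for de-etiolating seedling time courses.

When a dark-grown seedling first sees light (photomorphogenesis), small
regulatory RNAs — miRNAs, phased siRNAs (phasiRNAs) and other siRNAs —
tune the transcriptome by guiding cleavage of their target mRNAs.
`photosrna` implements the computational toolchain such a study needs,
end to end and fully testable offline:

* **PHAS/TAS locus detection** — a sliding-window scan scoring 21-nt
  phasing registers with a hypergeometric tail probability
  P(X ≥ k | N, K, n), where n is the number of distinct (5′ start, strand)
  alignment positions in a 251-nt window and k the number on the
  best-supported register (minus-strand starts offset +2 nt for the dicing
  overhang).
* **Degradome (PARE) cleavage calling** — Allen-style complementarity
  scoring (mismatch 1, G:U 0.5, doubled at sRNA positions 2–13), category
  assignment of the 5′-end peak opposite sRNA positions 10–11, an
  empirical p-value from dinucleotide-preserving sRNA shuffles, and the
  validity filter category ≤ 2 ∧ p ≤ 0.05 ∧ ≥ 5 site reads.
* **Quantification and classification** — family-weighted exact-match
  counting, RPM normalization by mapped 20–24-nt totals, the
  expressed-sRNA criterion (≥ 5 reads in ≥ 1 time point for every
  replicate) and per-time-point Welch t-tests against darkness for light
  regulation.
* **Comparative statistics** — two-sample Kolmogorov–Smirnov determinant
  analysis of sRNA-to-target ratios, fold-change t-tests, a Fisher exact
  test for transposable-element targeting enrichment, and seeded k-means
  clustering of light-response log2FC profiles.
* **Synthetic data** — a deterministic generator of transcriptomes with
  planted target sites, phased loci, three-replicate time-course counts
  and degradome profiles, with complete ground-truth tables.

The high-level API is statsmodels-style: build a model from data, call
`fit()`, get a Results object with a `summary()` table
(`PhasingScan`, `DegradomeTargeting`, `LightResponseModel`).

## Worked example

```python
from photosrna.degradome import DegradomeParams
from photosrna.models import DegradomeTargeting, PhasingScan
from photosrna.synthetic_data import (
    SimulationConfig, simulate_world, simulate_degradome,
)

cfg = SimulationConfig(seed=42, n_transcripts=12, n_mirnas=6, n_phas_loci=2,
                       cluster_archetype_sizes={"I": 1, "II": 2, "III": 2})
world = simulate_world(cfg)

print(PhasingScan(world.phas_alignments, world.phas_references).fit()
      .summary().to_string(index=False))

profiles = simulate_degradome(cfg, world)["light"]
print(DegradomeTargeting(world.srnas, world.transcripts, profiles,
                         DegradomeParams(n_shuffles=100, seed=42)).fit()
      .summary().head(6).to_string(index=False))
```

prints

```
   locus  start  end trigger  n  k      p_value
synPHAS1      1  377       . 17 17 1.982805e-26
synPHAS2      1  377       . 18 18 2.861781e-28
    srna transcript  site  score  site_reads     site_rpm  category        p  valid
syn-miR1      synT1   262    0.0           9  9230.769231         0 0.009901   True
syn-miR2      synT2   290    0.0          13 13333.333333         0 0.009901   True
syn-miR3      synT3   267    0.0          13 13333.333333         0 0.009901   True
syn-miR4      synT4    49    0.0          17 17435.897436         0 0.009901   True
syn-miR5      synT5   125    0.0          6   6153.846154         0 0.009901   True
syn-miR6      synT6   183    0.0          13 13333.333333         0 0.009901   True
```

Both planted phased loci are recovered with every distinct alignment in
register (n = k) at vanishing p-values, and each planted cleavage event is
called valid: a perfect-complement site (score 0), a unique degradome
maximum at the expected cleavage coordinate (category 0), and the smallest
p reachable with 100 shuffles, 1/101 ≈ 0.0099.

A thin CLI mirrors the pipeline stages:

```bash
photosrna simulate --seed 4 --out-dir world/
photosrna phasing --alignments world/phas_alignments.tsv \
                  --references world/transcriptome.fasta --out loci.gff3
photosrna degradome --srnas world/srna_catalog.fasta \
                    --transcripts world/transcriptome.fasta \
                    --profiles world/degradome_light.tsv --out calls.tsv
photosrna cluster --log2fc fc.tsv --k 3 --out clusters.tsv
```

## Reference tables

`photosrna/data/` ships two small reference tables transcribed from a
published de-etiolation profiling study: twelve expressed PHAS/TAS loci
with their (n, k, p) statistics — used to calibrate the phasing-statistic
convention (see `docs/methods.md` for the calibration and its residual) —
and 66 light-regulated miRNA log2FC profiles with their I/II/III cluster
labels, the worked example for `cluster_profiles`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the whole pipeline from scratch on freshly simulated inputs —
phasing scan, degradome target calling, light-response classification and
clustering of the packaged reference profiles — and writes the results
JSON.

See `docs/methods.md` for the models, parameter defaults, numerical
choices and known limitations.
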