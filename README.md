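# mitoscreen

Tools for evaluating punctate protein-occupancy signal in ChIP-seq data
aligned to a single circular contig (e.g. the mitochondrial genome), built
around the observation that true occupancy shows a strand-asymmetric
read-end pattern while common artifacts (such as D-loop enrichment) are
strand-symmetric however strong they appear.

The package provides, end to end:

- **`mitoscreen.simulate`** — synthetic circular genomes, planted motifs /
  truth sites, and simulated ChIP and control reads with the asymmetric
  (occupancy) and symmetric (artifact) signatures, written as
  FASTA/SAM/BED.
- **`mitoscreen.mappability`** — k-mer self-mapping mappability tracks
  (default k=36) under unique-alignment semantics, with optional mismatch
  tolerance, reverse-complement counting and origin-wrapping k-mers.
- **`mitoscreen.tracks`** — strand-specific coverage and base-resolution
  5'-end count tracks from SAM/BAM, with paired-end duplicate collapsing
  and single-end retain-all rules, serialized as bedGraph pairs.
- **`mitoscreen.screen`** — candidate region calling over a median
  background, strand cross-correlation asymmetry scoring, and
  classification into `occupancy_like` / `artifact_like` / `ambiguous` /
  `masked` with a configurable artifact mask (e.g. the control region).
- **`mitoscreen.model`** — a base-resolution sequence-to-profile neural
  network (dilated residual CNN; multinomial profile NLL + log-total-counts
  MSE losses; GC-matched non-peak sampling, jitter and reverse-complement
  augmentation; contig-grouped cross-validation), implemented in pure
  numpy with explicit gradients, plus tiled forward/RC-averaged prediction
  around the circle and a corroboration score against observed calls.
- **`mitoscreen.evidence`** — cross-dataset aggregation into evidence
  tiers (orthogonal reagent replication, same-reagent replication,
  single-dataset, discordance) and hierarchical clustering of profiles.
- **`mitoscreen.cli` / `mitoscreen.pipeline`** — a `mitoscreen` command
  wiring everything together with JSON configs, checksummed manifests and
  circular/linear strand plots.

## CLI

```bash
mitoscreen config-dump              # print all pipeline defaults as JSON
mitoscreen demo --seed 1 --out out/demo
mitoscreen simulate --length 16569 --n-reads 20000 --seed 1 --out-prefix out/sim
mitoscreen mappability --fasta out/sim.fa --k 36 --circular --out out/map.bedGraph
mitoscreen tracks --alignments out/sim.sam --out-prefix out/tracks
mitoscreen screen --alignments out/sim.sam --fasta out/sim.fa \
    --mask 16024:1122 --out-prefix out/screen
mitoscreen run --config myrun.json --out out/run
```

`mitoscreen run` executes simulate → mappability → tracks → screen →
model → evidence and writes a `manifest.json` with a SHA-256 checksum per
output; re-running with the same config and seed reproduces all
non-training outputs byte-for-byte.

Real data enter through the same interfaces: alignments as SAM/BAM on a
single circular contig (the reference pipeline aligned 36-mers with
unique-mapping settings; this package consumes alignments as given and
does no re-alignment or MAPQ filtering), peak lists as BED, masks as
interval lists.

## Conventions

All coordinates are 0-based, half-open and modular; origin-spanning
features are canonical `(start, length)` pairs with `start` inside the
contig. The minus-strand 5' end is the rightmost aligned base. Every
source of randomness flows from an explicit seed through
`numpy.random.default_rng`; no global RNG state is used.
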