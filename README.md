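# methsig

Prioritizing differential DNA-methylation events by the regulatory and
conformational context of their genomic neighbourhood.

## The problem

High-throughput methylation assays (BeadChip arrays, bisulfite sequencing)
routinely yield thousands of differentially methylated CpG sites (DMS)
between two sample groups, most of them in poorly annotated regions.  Which
of them matter?  `methsig` ranks DMS under the hypothesis that a methylation
change is more likely to have functional, transcription-level consequences
when it falls on a genomic substrate enriched in cis-regulatory and
structure-forming elements, rather than in a featureless "desert".

For each DMS *x<sub>i</sub>* the package examines a fixed window (default
100 nt, ±50 around the CpG cytosine) and measures a set of attributes
*a<sub>j</sub>*:

* **G4** — canonical G-quadruplex-forming sequences (four runs of ≥3 G
  separated by loops of 1–7 nt, both strands);
* **Pals** — palindromes (exact reverse-complement arms ≥6 nt, loop ≤10 nt);
* **TFBS** — transcription-factor binding sites from JASPAR-style position
  frequency matrices, scanned as log-odds PWMs at a relative-score
  threshold;
* **cTFBS** — overlaps with a conserved-TFBS interval track;
* **splicing** — a logical joining tentative donor/acceptor splice sites
  (Shapiro–Senapathy percentile score ≥80) with known alternative-splicing
  event overlaps;
* **shape** — a logical that is positive when methylating the central CpG
  significantly alters at least one predicted DNA-shape profile (minor
  groove width, roll, propeller twist, helix twist; pentamer-table decoding,
  Wilcoxon p < 0.05).

Each attribute is mapped onto [0, 1] (counts min-max normalized across the
dataset, logicals kept as 0/1), giving the signature matrix *A′* with
entries *a′<sub>ij</sub>*.  The **genomic index** of a site is the weighted
sum

&nbsp;&nbsp;&nbsp;&nbsp;idx<sub>i</sub> = Σ<sub>j</sub> w<sub>j</sub> a′<sub>ij</sub>,

with unit weights by default (so idx ∈ [0, 6] over the six standard
attributes).  Sites are ranked by descending index; higher values flag
methylation changes sitting on element-rich substrate.

The package also covers the surrounding workflow: BED/TSV loading, β/M
value conversions, read-depth filtering of bisulfite counts, Welch/Mann-
Whitney differential filtering with Benjamini–Hochberg FDR (defaults
|Δβ| ≥ 0.3, p < 0.01, FDR < 0.01), group-level enrichment reports, and an
association test between the genomic index and differential gene
expression.  A seeded synthetic-data module generates genomes, beta
matrices and feature-planted windows so every stage is testable offline.

## Worked example

Rank 100 synthetic sites, half with planted regulatory elements:

```python
import numpy as np
from methsig import fetch_windows, PentamerShapeTable
from methsig.pipeline import build_ranking, extract_features
from methsig.regulatory import pfm_to_pwm
from methsig.simulate import (SimulationConfig, fixture_pfm, make_genome,
                              make_tracks, plant_features)

cfg = SimulationConfig(seed=42, n_sites=100, genome_length=20_000)
genome, sites = make_genome(cfg)
classes = {s.site_id: ("enriched" if i < 50 else "desert")
           for i, s in enumerate(sites)}
genome, truth = plant_features(genome, sites, classes, cfg)
ctfbs, altspl = make_tracks(sites, classes, cfg)

windows = fetch_windows(genome, sites, offset=50)
feats = extract_features(windows, [pfm_to_pwm(fixture_pfm())], ctfbs, altspl,
                         shape_table=PentamerShapeTable.synthetic(seed=0))
matrix, ranked = build_ranking(feats)
for r in ranked[:5]:
    print(f"rank {r.rank}: {r.site_id}  genomic_index = {r.genomic_index:.3f}")
```

prints

```
rank 1: site00015  genomic_index = 5.100
rank 2: site00049  genomic_index = 4.600
rank 3: site00003  genomic_index = 4.300
rank 4: site00007  genomic_index = 4.300
rank 5: site00014  genomic_index = 4.300
```

All five top-ranked sites are from the element-enriched class; the class
means in this run are 3.89 (enriched) versus 0.90 (desert).  The index is
dataset-relative (min-max mapping), so compare values within a run, not
across runs, unless fixed bounds are configured.

The same workflow is available from the shell:

```bash
methsig simulate --seed 3 --n-sites 200 --outdir fixtures/
methsig preprocess --beta-matrix fixtures/beta_matrix.tsv \
    --groups fixtures/groups.tsv --sites fixtures/site_coords.tsv \
    --out dms.bed
methsig features --dms dms.bed --genome fixtures/genome.fa --out features.tsv
methsig rank --features features.tsv --out ranked.tsv
```

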