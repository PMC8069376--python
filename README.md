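# capturesim

In silico hybridization-capture (CaptureSeq-style) marker-gene profiling of
microbial communities — probe design, three-arm sequencing simulation, read
classification, targeted OTU assembly, and diversity analytics, with full
ground truth at every step.

## The problem

Profiling a microbial community with "universal" PCR of a taxonomic marker
(16S rRNA, *cpn60*, ITS) is cheap and deep but biased: primers miss taxa,
high-GC templates amplify poorly, and no single amplicon spans Bacteria,
Archaea and Eukarya at once. Shotgun metagenomics is unbiased but wasteful —
in soil, well under 0.1% of shotgun reads touch a given marker gene, so
reaching adequate marker coverage is expensive. Hybridization capture is the
middle road: tiled oligonucleotide baits complementary to every known marker
sequence pull marker-bearing DNA fragments out of a sheared total-DNA
library before sequencing, enriching the target thousands-fold without PCR
on the marker itself, and recovering all three domains in one library.

`capturesim` implements that entire computational workflow as a simulator
plus analysis toolkit, built around the chaperonin-60 (*cpn60*) marker: the
type I chaperonin of Bacteria and organelles and the type II
(thermosome/CCT) of Archaea and the eukaryotic cytosol, whose 549–567 bp
universal target (UT) region serves as a pan-domain barcode. Everything runs
at desk scale on synthetic communities with known composition, so every
claim about the method is checkable against ground truth.

## What is in the box

| module            | contents |
|-------------------|----------|
| `marker_db`       | `MarkerRecord`/`MarkerDB` (sequence + taxonomy + UT interval), cluster count tables, FASTA/TSV I/O |
| `probe_design`    | 120-nt baits tiled every 60 nt (50% overlap), 3′ end-anchoring, ambiguity filtering, dedup, coverage reports |
| `community_sim`   | marker families from a common ancestor at controlled identity, host genomes at target GC, even-mock and spike-in community designs |
| `capture_sim`     | shearing, a probabilistic hybridization-capture model, GC-biased PCR, paired 2×250 read simulation with substitution errors |
| `profiler`        | k-mer-seeded local alignment of read pairs to the reference set → taxonomic cluster counts, hypergeometric down-sampling |
| `otu_assembly`    | per-cluster de Bruijn (k=31) unitig assembly, contig identity to truth, 220-nt sub-OTU (ASV) calling |
| `diversity_quant` | rarefied Chao1 / Shannon / Simpson / Good's coverage, Bray–Curtis, PCoA, average-linkage clustering, spike-recovery statistics |
| `bench` + CLI     | one-command three-arm benchmarks (`zymo_even`, `spike_series`, `soil_like`) with TSV + markdown reports |

The capture model maps the best ungapped probe–fragment overlap identity
*I* (≥ 40 nt) to a capture probability

```
P(capture) = p_bg                                           I < I_min
           = p_bg + (p_on − p_bg) · (I − I_min)/(1 − I_min)  otherwise
```

with defaults `p_on = 0.95`, `p_bg = 1e-4`, `I_min = 0.55` — an off-target
floor of one fragment in ten thousand and near-certain capture of perfect
duplexes. The amplicon arm weights UT templates by
`(1 + e(GC))^cycles` with `e(GC) = e0·(1 − b·max(0, GC − 0.5))`, i.e. a
compounding efficiency penalty above 50% GC over 40 cycles.

## Worked example

```bash
capturesim bench --preset zymo_even --seed 7 --pairs 5000 --fragments 50000 --out bench_out
```

simulates an even ten-member mock community (eight bacteria at 12% each,
two eukaryotes at 2% each, each marker embedded in a 40 kb host genome),
runs the capture, shotgun and amplicon arms, maps every read pair back to
the reference set, assembles each capture-arm cluster, and writes
`bench_out/report.md`, which contains (seed 7, sizes as above):

```
## Marker read fractions per arm

          zymo_even
capture      0.9998
shotgun      0.0456
amplicon     1.0000

- capture enrichment, sample `zymo_even`: log10 fold = 4.63

## Even-community composition (bacterial clusters)

- mean bacterial proportion, capture arm: 12.5%
- mean bacterial proportion, shotgun arm: 12.5%
- mean bacterial proportion, amplicon arm: 12.5%
```

Reading: shotgun reads hit the marker ~5% of the time (the host genomes are
~30× the marker length; real genomes are far larger still), capture lifts
that to ~99.98% — a fold-change of the marker:background ratio of about four
orders of magnitude — and all three arms see the eight bacterial clusters
at a mean relative abundance of 12.5%, the design value. The accompanying
`assembly_report.tsv` lists one contig per member, each ≥ 99% identical to
its source marker and longer than the UT alone, because captured fragments
drag flanking sequence along.

The same machinery is exposed as a library:

```python
from capturesim.bench import zymo_community
from capturesim import design_array, build_libraries, build_index, profile_sample

db, sample = zymo_community(seed=7)
probes = design_array(db)                      # 120/60 tiling
bundle = build_libraries(sample, db, probes, seed=7)
result = profile_sample(bundle.capture, build_index(db))
print(result.column)                           # mapped pairs per cluster
```

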