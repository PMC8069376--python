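# Methods

This note documents the models behind `capturesim`, the parameters that
matter, the numerical choices, and what the synthetic benchmarks do and do
not establish about real data.

## Marker reference model

A marker database is a set of chaperonin-style reference sequences, each
with a taxon label, a domain of life, a chaperonin type (I for
Bacteria/organelles, II for Archaea and the eukaryotic cytosol), and a
universal-target (UT) interval — the 549–567 nt region addressed by
universal primers and used as the coordinate anchor for sub-OTU calling.
Coordinates are 0-based half-open throughout; 1-based descriptions such as
"nucleotides 1–220" translate to the slice `[0, 220)` at the reporting
boundary. Metadata travels as a fixed-header TSV beside a plain FASTA; `N`
is legal in references but never in probes.

One taxonomic cluster corresponds to one reference record. Whether a
real-world cluster might merge near-identical references is left open;
merging would only relabel columns of the count table and none of the
statistics downstream depend on it.

## Synthetic data: what it emulates, what it does not

`community_sim` manufactures ground truth at three levels.

**Marker families.** Records derive from one seeded random ancestor by
point substitution: exactly `round((1 − identity) · L)` positions are
changed, so identity to the ancestor is exact by construction (verified
against an alignment oracle in tests). There are no indels — this keeps
identity arithmetic and read/reference coordinate mapping exact, and it is
the reason several components (capture identity, sOTU trimming) can use
ungapped logic safely. Replacement bases are tilted toward a per-record
target GC; with a 0.5-GC ancestor and a substitution budget of
`1 − identity`, the attainable GC shift is about `±(1 − identity)/2`, so
extreme GC values are expressed at the genome level (host genome
composition) rather than inside the marker itself.

**Host genomes.** A marker is embedded verbatim at a recorded position in
random sequence generated at a target GC (realized GC within ±2% for
≥10 kb). Genomes default to 40 kb — roughly 100× smaller than real
bacterial genomes. This is the central desk-scale compression: marker
density per genome (~3.5%) is correspondingly inflated, so simulated
shotgun on-target fractions (~5%) sit far above the <0.1% seen in real
soil shotgun data. Comparisons *between* arms (enrichment folds, effort
ratios) remain meaningful because all arms share the same compression;
absolute on-target fractions do not transfer to real data.

**Communities.** The even mock community holds eight bacterial members at
12% mass each and two eukaryotic members at 2% each (sums to 1; enforced
to 1e-9). The spike-in series holds 20 UT-only plasmid members at
10⁸/10⁷/10⁶/0 copies each across four samples, in a constant carrier
background. Copy numbers convert to shearing weights as
copies × fragment-bearing length; mass fractions are used directly. The
carrier totals 2.8×10¹⁵ weight units — the ~2500:1 carrier:plasmid mass
ratio implied by ~0.4 ng of plasmid spiked into hundreds of ng of carrier —
and is represented by five 50 kb genomes, two of which carry an endogenous
marker (a seed-associated bacterium and fungus analogue). These endogenous
markers matter quantitatively: they are captured at on-target efficiency
and, at a ~0.4% carrier density, dominate the captured background, which
keeps the spiked panel a minority of the captured pool (~12% at the high
level) — the regime in which read counts stay proportional to input copies
across levels. The nanogram↔copy conversion itself is not modeled; copies
are exposed directly.

## The three sequencing arms

**Shearing.** Fragment sources are drawn by weight, lengths are
Normal(500, 150) truncated at 50 nt and clipped to the source, start
positions uniform. Two allocation schemes exist: `proportional` (one
simulated fragment = one molecule, weight 1 — the default) and `uniform`
(the fragment budget is split evenly across sources and each fragment
carries weight `w_source/n_source`). The uniform scheme is importance
sampling for long-tailed designs like the spike series, where a
proportional pool of feasible size would contain only a handful of plasmid
fragments at the low spike level and molecule-count Poisson noise — an
artifact of simulating ~10⁵ fragments where a real library has ~10⁹ —
would swamp the statistics being measured.

**Hybridization capture.** Each fragment's capture probability follows a
piecewise-linear ramp in its best probe identity *I*:
`p_bg` for `I < 0.55`, rising linearly to `p_on = 0.95` at `I = 1`, with
`p_bg = 1e-4`. Identity is the **ungapped overlap identity** of the best
probe placement: candidate placements (diagonals) come from 11-mer seeds
shared between fragment and probe (both strands, two seed hits on the same
diagonal required), and each placement is scored as matching bases over
the geometric probe/fragment overlap, which must span ≥ 40 nt. Ungapped
identity is the deliberate choice here: gapped edit-distance identity
between *unrelated* 120 nt sequences is ~0.55–0.65 — at or above the
capture threshold — which would erase the off-target floor entirely,
whereas ungapped identity of random pairs is ~0.3 and of true homologs
(substitution-only world) exact. It also matches the physics: a capture
duplex pays for bulges, and base-pairing fraction is the quantity the
threshold describes. Capture is drawn per molecule: a fragment of weight
*w* stands for `round(w/q)` molecules (*q* the smallest fragment weight)
and is thinned with a Binomial draw, which reduces to the per-fragment
Bernoulli draw whenever all weights are equal.

Two enrichment regimes follow from one parameterization. The
marker:non-marker *ratio* fold-change is ≈ `p_on/p_bg` ≈ 10^3.98 whenever
markers are rare pre-capture — the 3–4-orders-of-magnitude regime measured
by locus-specific quantification. The on-target *read fraction* after
capture depends additionally on how much background mass survives the
floor; with a realistically heavy carrier it lands at tens of percent.
Both regimes coexist in one simulation, as they do in the real experiment.

A known limitation: placements are discovered by exact 11-mer seeds, so
fragments whose best probe identity is below ~0.65 are usually *not found*
and fall to the floor, even though the ramp assigns them a small positive
capture probability. The ramp itself is exposed analytically
(`HybridizationModel.capture_probability`) for reasoning about permissive
capture of diverged, database-absent sequences; in-pipeline discovery of
such fragments is seed-limited. No pairwise statistic at 120 nt scale can
simultaneously give random pairs the floor and 59%-identity homologs a
reliable signal.

**Amplicon arm.** UT templates (members by copy number, endogenous
background markers by genome copies) are weighted by
`(1 + e(GC))^cycles`, `e(GC) = e0·(1 − b·max(0, GC − 0.5))`, defaults
`e0 = 0.95`, `b = 0.8`, 40 cycles — computed in log space and normalized.
Only the direction of GC bias is anchored in observation; the linear
penalty form and its slope are modeling choices.

**Read simulation.** 2×250 paired reads: mate 1 from the fragment 5′ end,
mate 2 reverse-complemented from the 3′ end, truncated at fragment
boundaries; i.i.d. substitutions at 0.005/base (no indels, no quality
model — qualities are constant 'I'). Read ids carry the true source.

## Read classification

The profiler assigns read pairs to taxonomic clusters with a seeded local
aligner: a complete 11-mer index over both strands of every reference
proposes candidates by joint mate votes (query k-mers sampled every 4 nt
in the batch path); candidates are aligned with edlib (infix mode), and
the pair goes to the single record maximizing summed mate score —
requiring both mates on the same record, identity ≥ 0.7 over ≥ 50 nt,
ties broken by lexicographically smallest record id. Multi-mapping pairs
are thus assigned, not fractionally split. Scores follow the fixed scheme
match +2, mismatch −3, gap open −5, gap extend −2; the single-pair API
computes them exactly from the alignment CIGAR, while the batch path
derives score and identity from edit distance alone under a
substitution-dominant assumption (exact for gap-free alignments, which is
the overwhelming case in this simulator). Tests hold the seeded mapper to
≥ 99% agreement with an exhaustive Smith–Waterman oracle over all
references. Down-sampling of count columns is multivariate hypergeometric
(without replacement), exact in total, seeded.

## OTU assembly and sub-OTU calling

Per-cluster read bins are assembled with a minimal de Bruijn unitig
builder: k = 31 counting over both mates and their reverse complements,
k-mers below count 2 dropped, maximal unambiguous paths emitted longest
first, strand duplicates collapsed, contigs under 200 nt discarded.
Branches are resolved by dominance: at a fork, the heaviest edge is
followed when it outweighs every alternative ≥ 10-fold — recurring
sequencing-error k-mers sit far below true coverage and would otherwise
fragment contigs at high depth — while balanced forks (genuine haplotype
splits) terminate the unitig. This is a deliberate simplification of a
full assembler — no graph phasing beyond that rule — adequate at low
error rates; planted-truth tests require ≥ 99% identity over ≥ 95% of a
500–1500 nt reference at 30× error-free coverage, and unrelated haplotype
pairs in one bin must come out as separate contigs.

Sub-OTUs (ASVs) are 220 nt windows anchored at the UT start: reads are
placed on the bin's reference by best-strand infix alignment (offsets are
exact in a substitution-only world), reverse-orientation reads are
reverse-complemented, reads not covering the full window are discarded,
and exact variants are collapsed. Denoising is the minimal analogue of
model-based error correction: a variant within 1 mismatch of an accepted
variant at least 10× more abundant is absorbed into it; survivors below
`min_count = 2` or 0.1% of the bin are dropped. Exact-collapse plus floors
alone is not sufficient — at 1000 reads × 0.5%/base, recurring identical
single-error reads exceed any fixed count floor — while equal-abundance
single-nucleotide variants are never merged, preserving
single-nucleotide resolution. A eukaryote whose UT contains a 64 nt
insertion at position 165 is carried as a test fixture: assembly must
reconstruct the insertion and the ASV window contains its start.

## Diversity and recovery statistics

Alpha diversity is computed on bootstrap rarefactions (default depths
250–2750 step 250, 100 replicates; benchmarks use 25 replicates to keep
runtimes short) with QIIME-1 conventions: bias-corrected Chao1
`S + F1(F1−1)/(2(F2+1))`, Shannon in bits (base configurable), Simpson as
`1 − Σp²`, Good's coverage `1 − F1/N`. Coverage-vs-effort curves rescale
mapped depth by each method's on-target fraction, so methods are compared
at total sequencing cost. Beta diversity is Bray–Curtis
(`1 − 2Σmin/(Σx+Σy)` on counts) with classical-scaling PCoA — negative
eigenvalues are zeroed and their magnitude reported, no Cailliez
correction — and deterministic average-linkage clustering exported as
Newick. Spike recovery reports per-member Pearson r² of mapped counts
against true copies across levels (undefined under zero variance →
missing), pooled Spearman ρ over all member×level pairs, and expresses
marker:reference enrichment as a **ratio of log10 copy numbers**
(7.58/5.56 = 1.36), matching the printed convention of the quantification
tables. Significance testing between diversity metric groups
(Kruskal–Wallis, Levene) is delegated to scipy.stats.

## Benchmarks and problem sizes

The three presets run community → probes → three arms → profiling →
analysis from one seed; all randomness flows from config seeds and a rerun
is byte-identical. Default budgets are 5×10⁴ read pairs and 2×10⁵
fragments per arm; the test suite uses smaller sizes (4–10×10³ pairs) and
the spike-recovery check uses the full 5×10⁵ pairs per sample over
10⁵ uniformly-allocated fragments. The soil-like preset holds 500 taxa
with log-uniform abundances over four orders of magnitude, Bacteria
dominant with trace Archaea and Eukarya; its exact proportions are fixture
choices. With 40 kb hosts the capture arm reaches a given Good's coverage
at roughly 1/20 the total sequencing effort of the shotgun arm; on real
genomes the gap would be far larger.

## What passing tests establish

Passing tests show the pipeline's internal consistency against known
truth under the stated generative model: substitution-only evolution,
uniform fragmentation, error-free coordinates, no chimeras, no quality
artifacts, compressed genome sizes. They do not establish performance on
real libraries — adapter content, indels, PCR duplicates, hybridization
kinetics, and reference incompleteness are all outside the model.
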