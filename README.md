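# ugdr

Detection of recombined regions, loss of heterozygosity (LOH) and
chromosomal copy-number changes in yeast genomes of ploidy 1n–4n, from a
comparison of allele ratios and read-depth coverage between a parent (or
reference strain) and a potentially recombined strain.

## Who this is for

Yeast geneticists mapping recombination in hybrids and polyploids —
meiotic tetrads, return-to-growth (RTG) mother/daughter pairs, or two
phylogenetically close clinical strains — without needing a merged parental
reference genome or strain-specific hard coding. The inputs are the
standard outputs of a short-read alignment + variant-calling pipeline
(BWA → SAMtools/Picard → FreeBayes, plus GATK DepthOfCoverage): one VCF and
one per-base depth-of-coverage table per strain.

## The method

At a biallelic marker with `a` alternate copies among `p` homologs, the
allele ratio

```
Ratio = AO / DP
```

(alternate observations over total depth, the analogue of a B-allele
frequency) is expected at the ratio-group center `a/p`. The centers are
ploidy dependent: `{0, 1}` for haploids, `{0, 0.5, 1}` for diploids,
`{0, 0.33, 0.67, 1}` for triploids, `{0, 0.25, 0.5, 0.75, 1}` for
tetraploids. An observed ratio is assigned to the unique center within
±θ, where θ = 0.04 — half the distance between the closest adjacent
centers across ploidies (0.25 vs 0.33, 0.67 vs 0.75) — and ambiguous
ratios are discarded. Markers first pass quality filters: DP ≥ 20, site
QUAL > 200, and AO > 20 at 80× coverage (rescaled to the sample's own mean
depth; all cutoffs user-adjustable).

Each parent marker is paired with the recombinant strain and labelled:

* **invariant** — same center in both strains (gray in the profile plot);
* **LOH_0 / LOH_1** — center moved to 0 / 1 (red / blue). A marker absent
  from the recombinant VCF but covered with ≥ 20 reads there is imputed as
  ratio 0, since variant callers are silent at homozygous-reference sites;
* **het_change** — a different heterozygous center of the same ploidy,
  e.g. 0.33 → 0.67 (black);
* **ploidy-change candidate** — a center only explicable by gaining or
  losing one homolog (e.g. 0.33 → 0.25 with a coverage gain), confirmed or
  demoted by the normalized depth of coverage.

Recombined regions are runs of at least 4 adjacent ratio-variant markers,
tolerating at most 2 consecutive invariant markers between a pair of
variant ones. In parallel, the **normalized depth of coverage** (NDoC) —
recombinant ÷ parent per-base depth averaged in 1-kb windows — flags
potential deletions (NDoC < 0.5, orange dots) and insertions (NDoC > 1.5,
green dots) and arbitrates the ploidy-change candidates. The result is a
per-chromosome recombination profile plot and a set of plain TSV tables.

A synthetic-data module generates matched parent/recombinant VCF +
coverage fixtures with plantable LOH, heterozygous-recombination,
chromosome gain/loss and segmental-duplication events
(AO ~ Binomial(DP, a/t), DP ~ Poisson coverage), and four-spore tetrads
with crossovers and gene conversions, so the whole pipeline is testable
without any sequencing data.

## Worked example

Simulate a triploid strain with a planted interstitial LOH on chrI and a
whole-chromosome gain of chrIII, then analyse it:

```
$ printf 'kind\tchrom\tstart\tend\nLOH_0\tchrI\t40000\t80000\nchrom_gain\tchrIII\t1\t100000\n' > events.tsv
$ ugdr simulate --ploidy 3 --seed 42 --events events.tsv --out sim/
simulated 900 parent / 827 recombinant markers into sim
$ ugdr run --parent sim/parent.vcf --sample sim/recomb.vcf \
           --parent-doc sim/parent.doc --sample-doc sim/recomb.doc \
           --ploidy 3 --out out/
830 parent markers kept, 477 calls, 2 recombined regions
$ cat out/regions_of_recombination.txt
chrom	start	end	n_variant_alleles	event_type	mean_ndoc
chrI	45309	77378	35	LOH_0	1.000885005225788
chrIII	1384	99225	61	chrom_gain	1.334542080686493
```

Both planted events are recovered: the chrI region is an LOH toward the
reference allele (35 markers whose ratio fell from 0.33 to 0) with neutral
coverage (NDoC ≈ 1.00), and the chrIII region is a chromosome gain — the
marker ratios moved off the triploid centers while the NDoC rose to
≈ 4/3, the expected value for a 3n → 4n chromosome. `out/` also contains
the parental/recombined alleles files, the variant and invariant alleles
files, the per-window NDoC table (`sample_normalized1KB.txt`), the profile
plot (`sample_profile.svg`) and a `manifest.json` recording the resolved
parameters.

The same analysis is available as a library:

```python
from ugdr import SimulationConfig, simulate_pair, run_in_memory

pair = simulate_pair(SimulationConfig(seed=42, ploidy=3))
result = run_in_memory(pair.parent_records, pair.recomb_records,
                       pair.parent_coverage, pair.recomb_coverage,
                       pair.config.layout, ploidy=3)
print(result.regions)
```

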