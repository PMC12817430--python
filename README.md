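# seedtrace

Identify direct-seeded plant populations and their seed provenance from
diploid SNP genotypes.

Restoration projects frequently sow commercial seed mixtures; when the seed
comes from a foreign evolutionary lineage, or from a single bottlenecked seed
lot distributed across many sites, the resulting populations carry genomic
signatures that distinguish them from natural ones.  `seedtrace` implements a
sequential genomic decision pipeline:

1. **QC** — site and individual filter cascade on VCF input (minor allele
   count, genotype/site depth, allele balance, mapping-quality ratio,
   quality/depth, missingness) plus greedy LD thinning (one SNP per window),
   and genotyping error rates from technical replicate pairs.
2. **Ancestry** — a binomial-mixture admixture model fitted by EM (Q and P
   matrices), masked cross-validation for choosing the number of lineages
   (ESUs), Hungarian alignment of restarts, and per-individual lineage
   assignment with an admixture flag (foreign ancestry ≥ 10% by default).
3. **Statistics** — per-individual observed heterozygosity and inbreeding
   F = (O−E)/(N−E) with lineage-specific allele frequencies, pairwise F_ST
   (Weir–Cockerham 1984 default, Hudson alternative), and identity-by-state
   dissimilarity.
4. **Clustering** — neighbor-joining trees, and a quantitative star-cluster
   detector: populations sharing a homogeneous seed lot show near-zero
   mutual F_ST and high cross-population nearest-neighbor mixing.
5. **Classification** — decision rules per population: a single seed source
   whose nearest natural, non-admixed reference population lies more than
   100 km away (or whose lineage does not occur in the region) is
   allochthonous seeding; admixture involving an allochthonous lineage is
   admixed seeding; a shared homogeneous autochthonous source is homogeneous
   seeding; everything else (including admixture among local lineages) is
   natural.

A Balding–Nichols simulator (`seedtrace.simulate`) generates georeferenced
multi-lineage scenarios with known truth — lineage drift, shared seed lots
with founder bottlenecks, admixed populations, missing data, and
error-injected technical replicates — so the full pipeline is testable
without any external data.  A packaged evidence table
(`seedtrace/data/swiss_evidence.tsv`, 31 populations) drives the
classification summary end of the pipeline.

## CLI

```bash
seedtrace simulate --config scenario.yaml --seed 7 --out sim/
seedtrace qc --vcf sim/genotypes.vcf --thin-bp 5000 --out filtered.vcf
seedtrace admix --vcf filtered.vcf --k 1..6 --restarts 20 --seed 7 --out adm/
seedtrace stats --vcf filtered.vcf --groups groups.tsv --out stats/
seedtrace cluster --dist stats/ibs_dissimilarity.tsv --out tree.nwk
seedtrace errors --vcf sim/genotypes.vcf --replicates sim/replicates.vcf
seedtrace classify --out summary.tsv        # packaged evidence table
seedtrace run-all --config scenario.yaml --seed 7 --k 3 --out run/
```

`run-all` writes every intermediate (filtered VCF, Q/P matrices, F_ST matrix,
diversity table, Newick tree, source-group report, classification and
summary tables) under `--out`, and is deterministic given `--seed`.

## Layout

- `src/seedtrace/simulate.py` — structured-population simulator with truth
- `src/seedtrace/genotype_io.py` — VCF I/O, QC cascade, LD thinning, replicate error rates
- `src/seedtrace/popstats.py` — H_o, inbreeding F, F_ST, IBS dissimilarity
- `src/seedtrace/ancestry.py` — admixture EM, cross-validation, alignment, assignment
- `src/seedtrace/clustering.py` — neighbor joining, star-cluster detection
- `src/seedtrace/classify.py` — decision rules, summary, packaged evidence table
- `src/seedtrace/pipeline.py`, `cli.py` — orchestration and `seedtrace` CLI
- `tests/` — unit, property and acceptance tests (`tests/test_acceptance.py`)
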