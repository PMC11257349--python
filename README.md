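# neowscan

Detection of sex-chromosome–autosome fusions in ZW taxa from population
short-read resequencing data, with optional Hi-C evidence and a simulator
with known fusion truth.

## The problem

In female-heterogametic (ZW) groups such as butterflies and moths, females
lack crossing over, so a chromosome that fuses to the W becomes a
female-limited, non-recombining neo-sex chromosome.  Such fusions are easy
to miss: W chromosomes rarely assemble well, and the fused autosome still
looks diploid in both sexes.  But population data from both sexes carry
clear signatures.  For a W-fused autosome:

* each female carries one fused and one ordinary haplotype, so at sites
  where the fused haplotype carries a derived mutation **all females are
  heterozygous and all males homozygous**;
* female heterozygosity is elevated along the whole chromosome;
* between-population FST computed **in females only** drops (females of
  different species share the fused haplotype), while male FST is normal;
* where the fused haplotype has degenerated beyond mappability, female
  depth falls toward half and heterozygosity vanishes;
* a female Hi-C library shows excess contacts between the fused
  chromosomes on exactly one haplotype; a male (ZZ) library shows none.

`neowscan` computes each signature from a VCF plus a sample sheet, tests a
genealogical prediction (a female-specific haplotype clade at candidate
SNPs) with a self-contained local-tree construction, assigns unplaced
scaffolds to the W from sex-stratified depth, scores Hi-C contact
enrichment, and integrates everything into per-chromosome calls:
`no_fusion`, `sex_linked_undetermined`, `W_fused` or `Z_fused` (the last
two require Hi-C).  A full description of the model and estimators —
Hudson-style windowed FST = 1 − π_within/d_xy, per-individual
heterozygosity proportion, the Hardy–Weinberg exact QC test, the
median-rate Hi-C enrichment score — is in [docs/methods.md](docs/methods.md).

Because real fusions come without ground truth, the package includes a
first-class simulator (`neowscan.synthetic_data`) that generates genotypes,
depths, phased haplotypes and Hi-C contacts under the ZW inheritance model
(achiasmatic females, matrilineal fused haplotype, mutation accumulation,
segmental mapping dropout, hemizygous dosage) with every truth label
recorded, so the whole pipeline is validated end to end at desk scale.

## Worked example

Simulate a two-species clade (10 females + 10 males per species, five 2-Mb
autosomes, one W-autosome fusion on chr4) and scan it:

```python
import neowscan as nw

ds = nw.simulate_dataset(nw.SimConfig(seed=1))
lengths = {c: ds.config.chrom_length(c) for c in ds.config.chrom_names}
res = nw.scan_for_fusions(ds.table, ds.sheet, ds.config.fused_clade, lengths)

for call in res.calls:
    print(call.chromosome, call.verdict, call.evidence.flags)
```

prints

```
chr1 no_fusion {'het_excess_vs_males': False, 'het_excess_vs_autosomes': False, 'fst_reduction_female': False, 'depth_reduction_female': False, 'clade_fraction': False}
chr2 no_fusion {'het_excess_vs_males': False, 'het_excess_vs_autosomes': False, 'fst_reduction_female': False, 'depth_reduction_female': False, 'clade_fraction': False}
chr3 no_fusion {'het_excess_vs_males': False, 'het_excess_vs_autosomes': False, 'fst_reduction_female': False, 'depth_reduction_female': False, 'clade_fraction': False}
chr4 sex_linked_undetermined {'het_excess_vs_males': True, 'het_excess_vs_autosomes': True, 'fst_reduction_female': True, 'depth_reduction_female': False, 'clade_fraction': True}
chr5 no_fusion {'het_excess_vs_males': False, 'het_excess_vs_autosomes': False, 'fst_reduction_female': False, 'depth_reduction_female': False, 'clade_fraction': False}
```

Only the truly fused chromosome is flagged: its females are significantly
more heterozygous than males and than females on every other autosome, the
female between-species FST is depressed relative to the genome, and ~100%
of candidate sites show the female-specific haplotype clade.  The verdict
stays `sex_linked_undetermined` because resequencing alone cannot tell a W
fusion from a Z fusion; adding simulated female and male Hi-C matrices
(`simulate_hic_female` / `simulate_hic_male`, where only the female carries
the junction) upgrades the call to `W_fused`.

The same steps are available from a shell:

```
neowscan simulate --seed 1 --out-dir sim/ --hic
neowscan classify --vcf sim/genotypes.vcf --samples sim/samples.tsv \
    --clade sp1,sp2 --chrom-lengths lengths.tsv \
    --hic-female sim/hic_female --hic-male sim/hic_male --out calls.tsv
```

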