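# mitodui

Comparative analysis of **doubly uniparentally inherited (DUI) bivalve
mitochondrial genomes** — the female-transmitted (F) and male-transmitted (M)
mtDNA lineages found in freshwater mussels and a few other bivalves.

In a DUI species the two gender-associated mitogenomes coexist in one animal
and can diverge by 40% or more in nucleotide sequence.  Characterising such a
pair is a standard workflow with many moving parts; `mitodui` implements all
of them as a library:

* **Genome architecture** — circular-genome model with 0-based half-open
  coordinates and origin-wrapping features; gene inventory, overlapping gene
  pairs, unassigned (intergenic) regions, start/stop-codon classes
  (conventional ATG/ATA/ATT vs alternative ATC/TTG/GTG), a six-frame ORF
  scan, and the male *cox2* 3′ extension statistic.
* **Composition** — AT%/GC%, strand skews (AT skew = (A−T)/(A+T),
  GC skew = (G−C)/(G+C)), per-partition tables (whole genome, rRNAs, protein
  genes by codon position, tRNAs, control region), codon usage with RSCU.
* **Divergence** — peptide-guided codon alignment (Needleman–Wunsch,
  BLOSUM62, affine 10/1, retro-aligned onto codons), p-distances with
  site-bootstrap standard errors, and Nei–Gojobori (1986) Ka/Ks with
  Jukes–Cantor correction: per-codon synonymous-site fractions averaged over
  both sequences, observed differences averaged with equal weight over all
  minimal-substitution pathways avoiding stop codons, ω = Ka/Ks.
  Concatenation with codon-position masking and partition maps.
* **Coding potential** — Fickett's TESTCODE statistic with the published
  lookup tables and weights (coding ≥ 0.95, noncoding ≤ 0.74), for the
  gender-specific FORF/MORF open reading frames.
* **Control region** — tandem-repeat detection (self-match seed-and-extend),
  stem-loop potential by Nussinov base-pair maximisation, and ranking of
  unassigned regions by the three CR criteria: length, AT enrichment, and a
  repeat whose unit folds into a hairpin.
* **Gene order** — signed circular permutations, canonicalised at *cox1*;
  breakpoint distance; clade-diagnostic (synapomorphic) adjacencies.
* **Light phylogenetics** — Saitou–Nei neighbor joining, monophyly checks,
  newick I/O; used to verify the reciprocal monophyly of F and M clades on
  distance matrices.
* **Synthetic data** — a seeded generator for annotated circular genomes
  with planted composition, skews, repeats and control regions, plus a
  proposal/acceptance codon-evolution process with controllable ω.  A
  packaged F-like/M-like fixture pair conditioned on the published
  *Solenaia carinatus* architecture ships with the package.

## Worked example

```python
from mitodui.data import solenaia_fixture_pair
from mitodui.genome import cox2_extension, gene_overlaps, intergenic_regions
from mitodui.divergence import gene_divergence
from mitodui.repeats import control_region_candidates

f, m = solenaia_fixture_pair()          # the packaged synthetic F/M pair

len(intergenic_regions(f)), len(intergenic_regions(m))   # (27, 23)
len(gene_overlaps(f)), len(gene_overlaps(m))             # (2, 6)
cox2_extension(f, m)                                     # (543, 0.797...)

for r in gene_divergence(f, m, labels=["cox1", "rrnS"]):
    print(r.gene, round(r.pd_nt, 3), r.omega)
# cox1 0.404 0.3238...
# rrnS 0.291 None

top = control_region_candidates(f)[0]
top.region.flank_upstream, top.region.flank_downstream   # ('nad5', 'trnQ')
top.repeats[0].period, round(top.repeats[0].copies)      # (101, 8)
```

Reading the numbers: the male genome's *cox2* is 543 bp (79.7%) longer than
the female's — the characteristic M-genome extension; *cox1* differs at
40.4% of aligned nucleotide sites with Ka/Ks ≈ 0.32 (strong purifying
selection despite the huge divergence); and the female control region is the
1049 bp *nad5*–*trnQ* unassigned region carrying an 8 × 101 bp tandem array
whose unit folds into a stem-loop.

The `examples/` directory has one narrative script per capability
(architecture, composition-free divergence table, control-region scan,
gene-order synapomorphies, simulation/recovery); each prints its results
with a line on what they mean.  A thin CLI wraps the same library:

```bash
mitodui report --out report/          # full bundle on the packaged pair
mitodui stats path/to/genome.gb       # one-genome architecture
mitodui cr-scan genome.fasta          # control-region ranking
```

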