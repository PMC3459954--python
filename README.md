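# hapresolve

Character-based evaluation of DNA barcode markers against morphological
species, for multi-marker surveys of low-variation taxa such as deep-sea
octocorals.

## The problem

Mitochondrial markers evolve slowly in octocorals, so a single "barcode"
locus rarely separates all morphological species: distinct morphospecies
can share a haplotype, and one species can carry several. Distance
thresholds then mislead, and the informative question becomes a
*character-based* one — for a given marker, or combination of markers, is
every haplotype observed in a species exclusive to that species?

`hapresolve` implements that evaluation as a reusable pipeline:

1. **Haplotype collapsing.** Within each aligned marker, specimens with
   column-for-column identical sequences form one haplotype; a single
   nucleotide difference *or a gap difference* separates haplotypes.
   Unalignable or ambiguous columns are masked out first.
2. **Combination haplotypes.** Mitochondrial markers are one linked locus,
   so per-specimen codes are combined across markers: two specimens share a
   combination haplotype iff they match in *every* marker (tuple equality).
   This is the finest partition the marker set supports.
3. **Resolution scoring.** A species *S* is **fully resolved** by a marker
   subset iff every haplotype observed in *S* occurs in no specimen of any
   other taxon in the dataset — other genera included, since haplotype
   sharing across genus boundaries is real in these markers. Reported per
   single marker and per subset, with the percentage of the focal genus's
   morphospecies resolved.
4. **Distances.** Uncorrected p-distances under pairwise deletion
   (p = differing sites / sites where both sequences have an unambiguous
   base), summarized as min–max ranges at the intraspecific, interspecific
   (within genus) and intergeneric levels, plus a cryptic-species screen:
   any species whose maximum intraspecific p exceeds 0.5% is flagged.
5. **Ranges.** Per-haplotype depth extremes, 100 m depth-bin occupancy,
   site/region sets, and maximum great-circle span — quantifying how
   coarser markers inflate apparent species ranges.

A seeded synthetic-data generator emulates the whole data-generating
process (genus backbones, species divergence, intraspecific variants,
verbatim haplotype sharing across congeners, clade-specific indels), so
every stage is testable against planted ground truth.

## Worked example

The package ships a reference dataset: haplotype codes for 54 North
Pacific primnoid octocoral colonies — 39 *Narella* spanning 12
morphospecies, plus 15 colonies of five other genera — across the five
mitochondrial markers NCR1, ND6, ND2, COI+ and MutS.

```python
import hapresolve as hr

records, codes = hr.reference_dataset()
assigns = {m: hr.combination_from_codes(codes[[m]], marker_set=(m,))
           for m in codes.columns}
subsets = [(m,) for m in codes.columns] + [
    tuple(codes.columns), ("COI+", "MutS"), ("COI+", "MutS", "ND2")]
report = hr.resolution_summary(assigns, subsets, records,
                               focal_genus="Narella")
print(report.to_frame().to_string())
```

prints

```
                   NCR1 ND6 ND2 COI+ MutS NCR1+ND6+ND2+COI++MutS COI++MutS COI++MutS+ND2
analyzed_length
n_haplotypes         13  15  15   18   20                     27        24            26
n_haplotypes_focal    8   7   9   10   11                     17        14            16
n_species_resolved    2   3   4    6    6                     10         9            10
n_species_total      12  12  12   12   12                     12        12            12
pct_resolved         17  25  33   50   50                     83        75            83
```

Reading the columns: the least variable marker (NCR1) yields only 13
haplotypes across all 54 colonies and fully resolves just 2 of the 12
focal morphospecies (17%) — it cannot even separate some genera. The full
five-marker combination yields 27 combination haplotypes (17 within
*Narella*) and resolves 10 of 12 morphospecies (83%). The two-marker
"extended barcode" COI+ + MutS reaches 9 species (75%); adding ND2
recovers the tenth. The two species that remain unresolved share a
combination haplotype with each other:

```python
full = report["NCR1+ND6+ND2+COI++MutS"]
print(dict(full.unresolved))
# {'Narella arbuscula': ('Narella sp. cf. macrocalyx',),
#  'Narella sp. cf. macrocalyx': ('Narella arbuscula',)}
```

## Command line

```sh
resolve fixture -o out/                 # write the reference table as TSV
resolve run --mode codes --specimens out/reference_haplotypes.tsv \
    --focal-genus Narella -o results/   # full analysis from coded haplotypes
resolve simulate --seed 3 -o sim/       # synthetic FASTAs + metadata
resolve run --mode sequences --specimens sim/specimens.tsv \
    --marker NCR1=sim/NCR1.fasta --mask NCR1=50-75 ... -o simres/
```

`run` writes a per-specimen haplotype table, a marker summary table
(TSV), and a machine-readable `report.json`; sequences mode adds distance
summaries and cryptic-species flags. See `docs/methods.md` for the model,
conventions and parameter defaults.

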