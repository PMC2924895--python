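# ofrbarcode

Species discrimination from DNA-barcode loci (COI, matK, rbcL, ITS, or any
short marker) using **Oligonucleotide Frequency Ranges (OFR)**, together
with the three classical comparator criteria — uncorrected *p*-distance,
Euclidean distance of k-mer frequencies, and simple diagnostic characters —
plus an indel Type I/II risk analysis, a mini-barcode trimming scan, and a
seeded synthetic-data generator.  It is aimed at barcoding and molecular
taxonomy workflows where species must be told apart from a few hundred
nucleotides of sequence per specimen.

## The method

For every accession *j* of species *i* the frequency of each di- or
trinucleotide *XX*/*XXX* is counted with a single-nucleotide sliding window
and normalised by the window count: F(XX) = count/(n−1), F(XXX) =
count/(n−2), with *n* the sequence length.  Each species is then summarised
by the **range** [Min, Max] of each oligonucleotide's frequency across its
accessions (at least two accessions per species are required).  Two species
A and B are **resolved** when at least one oligonucleotide satisfies

    max( Min_B − Max_A , Min_A − Max_B ) ≥ t ,   t = 1 / (a − k + 1)

where *a* is the dataset's average ungapped sequence length, so t = 1/(a−1)
for dinucleotides and 1/(a−2) for trinucleotides — the frequency resolution
of a single window.  Pairwise outcomes fill a symmetric 0/1 ("binomial")
matrix, scored as percent species resolution (a species counts as resolved
when it separates from every other evaluable species; a per-pair score is
also available).

The comparators follow the standard barcoding-gap and character
definitions: a species passes the distance criterion when its minimum
interspecific distance strictly exceeds its maximum intraspecific distance
(*p*-distance with pairwise deletion, or Euclidean distance
D = sqrt(Σ (F1 − F2)²) over all 4^k oligonucleotides); a pair passes the
character criterion when one species has a *simple pure* character (a state
fixed in it and absent from the other).

Because t depends on *a*, indels shift the effective stringency: sequences
shorter than *a* face a too-weak threshold (false positives, Type I) and
longer ones a too-strict threshold (false negatives, Type II).  The
`robustness` module bounds the minimal indel length that can flip a pair
and applies the length-asymmetry rule (D_s > D_l → Type I, D_l > D_s →
Type II).

## Worked example

Simulate a small benchmark (6 species × 4 accessions, 600 nt, intraspecific
divergence 0.01, interspecific 0.08) and run the pipeline:

```sh
$ ofr simulate --n-species 6 --accessions 4 --inter-div 0.08 \
      --intra-div 0.01 --seed 42 -o demo
wrote 24 records (6 species) to demo/simulated.fasta

$ ofr matrix demo/simulated.fasta --k 2 -o demo_matrix
percent_resolution (species): 100.0

$ ofr compare demo/simulated.fasta -o demo_compare
p_distance: 100.0
euclid_di: 100.0
euclid_tri: 100.0
characters: 100.0
ofr_di: 100.0
ofr_tri: 100.0
```

`percent_resolution (species): 100.0` means every species' dinucleotide
frequency ranges are separated from every other species' by at least
t = 1/599 for at least one dinucleotide; the `compare` block shows all six
criteria agreeing at this divergence.  The written artifacts include the
0/1 matrix (`resolution_matrix.tsv`), per-pair evidence with the
discriminating oligonucleotides and their gaps
(`resolution_evidence.json`), and a `provenance.json` with the exact
parameters.  A mini-barcode scan (`ofr scan demo/simulated.fasta --end 3p`)
reports the shortest average length that keeps the maximum resolution.

The same operations are available as a library:

```python
from ofrbarcode import SimSpec, generate_dataset, resolution_matrix, percent_resolution

ds, truth = generate_dataset(SimSpec(n_species=6, accessions_per_species=4,
                                     inter_div=0.08, intra_div=0.01, seed=42))
rm = resolution_matrix(ds, k=2)
print(percent_resolution(rm, mode="species"))   # 100.0
```

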