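# rimkit

Computational toolkit for the RimB/RimK ribosome-modification pathway in
bacteria. RimK, an ATP-Grasp ligase, adds α-linked glutamate residues to
the C-terminus of ribosomal protein RpsF (S6) and synthesises free
poly-α-L-glutamate; RimB, a rare bacterial retropepsin-like aspartic
endopeptidase, removes those glutamates and recognises nothing but the
poly-Glu motif itself. `rimkit` is aimed at microbiologists and
bioinformaticians asking which proteins and genomes carry such motifs,
which engineered substrates RimB will cleave, and how rimB / rimK / rimBK
(hybrid) gene arrangements distribute across bacterial genomes.

## What it computes

* **Poly-Glu census** (`rimkit.polyglu`) — all maximal runs of ≥ 5
  consecutive E residues per protein, with C-terminal status, plus the
  nested rim-bearing vs rim-lacking genome partition.
* **Cleavability prediction** (`rimkit.cleavage`) — RimB cleaves a tail
  when it contains ≥ 6 contiguous glutamates, or ≥ 5 when the run includes
  the terminal genetically encoded glutamate. An ordinal rate class
  (NIL … EQUIVALENT) is assigned from run length, calibrated on the
  packaged 26-construct substrate panel.
* **Rim-gene classification** (`rimkit.rimclass`) — reciprocal-best-hit
  presence calls (E ≤ 1e-9, exact reciprocity) from 12-column tabular
  search output, assembly-quality filtering (reference/representative,
  ≤ 15 contigs, ≥ 500 CDSs), arrangement classes, and mobile-genetic-
  element proximity within a 5-gene window.
* **Supermatrix** (`rimkit.supermatrix`) — concatenation of seven marker
  alignments (AtpD, DhaE, GuaA, GyrB, RecA, RpoB, RpoD) with all-gap
  blocks for missing markers, deletion of columns with > 50% gaps, and
  iTOL colour-strip annotation export.
* **Mass ladders** (`rimkit.msladder`) — detection of poly-Glu polymer
  series in deconvoluted +1 peak lists: peaks spaced by one Glu residue,
  m/z = n·129.04259 + 18.01056 + 1.00728 + k·21.98194 for k sodium
  adducts, matched within a ppm tolerance.
* **Synthetic data** (`rimkit.synthetic`) — seeded generators for every
  input format with planted, machine-readable ground truth.

See `docs/methods.md` for the model details and design choices.

## Worked example

Simulate a 15-accession universe with planted rim arrangements and 30%
decoy hits, classify it, and summarise:

```sh
$ rimkit simulate universe --seed 3 --out-dir uni --decoy-rate 0.3 --mge-fraction 0.4
wrote 5 files to uni (15 accessions)
$ rimkit classify-rim --meta uni/metadata.tsv --forward uni/forward_hits.tsv \
      --reverse uni/reverse_hits.tsv --gene-order uni/gene_order.tsv --out profiles.tsv
10/15 accessions rim-bearing -> profiles.tsv
$ rimkit partition --profiles profiles.tsv --out partition.tsv
arrangement_class  count  percent
        rimB+rimK      5     50.0
        rimK only      3     30.0
       rimBK only      2     20.0
```

Ten of the fifteen accessions carry at least one rim gene; percentages are
over rim-bearing accessions only and match the planted mix exactly, since
decoys are built to fail the presence criterion. Ladder detection on a
simulated polymer spectrum (chains of 5–28 glutamates plus 30 noise peaks):

```sh
$ rimkit simulate ladder --seed 4 --n-max 28 --noise-peaks 30 --out-dir lad
wrote lad/peaks.csv (54 peaks)
$ rimkit ladder --peaks lad/peaks.csv --out series.tsv
max_n=28 over 1 series -> series.tsv
```

The detector assigns the 24 ladder peaks to chain lengths 5–28 and ignores
all 30 decoys: the longest polymer contains 28 glutamate units. Cleavage
prediction on the packaged substrate panel:

```sh
$ rimkit predict-cleavage --out cleavage.tsv
21/26 constructs cleavable -> cleavage.tsv
$ head -3 cleavage.tsv
name	encoded_suffix	added_tail	observed_rate	cleavable	longest_run	boundary	rate_class
RpsF-10Glu	DNADE	EEEEEEEEEE	EQUIVALENT	True	11	True	EQUIVALENT
RpsF-10Asp	DNADE	DDDDDDDDDD	NIL	False	1	True	NIL
```

The all-glutamate reference tail (an 11-residue run through the encoded
terminus) is cleaved at the reference rate; the all-aspartate tail is not
recognised at all.

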