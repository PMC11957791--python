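# Methods

## Scope and model

`rimkit` implements the desk-scale computational arm of a study of RimB, a
bacterial retropepsin-like aspartic endopeptidase that removes glutamate
residues from the polyglutamylated C-terminus of ribosomal protein RpsF and
stimulates free poly-α-L-glutamate synthesis by the ligase RimK. Five
analyses are covered: a poly-Glu run census over proteomes, a rule-based
cleavability predictor for engineered C-terminal tails, reciprocal-best-hit
classification of rim-gene arrangements across genome accessions,
concatenated marker supermatrix construction for phylogenomics, and poly-Glu
mass-ladder detection in deconvoluted single-charge peak lists. Sequence
search, alignment and tree inference are external tools whose outputs this
package consumes; wet-lab assays and structure prediction are out of scope.

## Poly-Glu run census (`polyglu`)

A qualifying motif is a *maximal* run of consecutive E residues of length at
least `min_len` (default 5). Coordinates are 1-based inclusive; a run is
C-terminal when its last residue is the protein's last. `X`, gap characters
(`-`, `.`) and `*` break runs — an ambiguous position never extends a motif
— and any other non-amino-acid character is rejected. Counting is at the
protein level, independent of the coding sequence. Because a protein can
carry several runs, per-genome statistics report both the run count and the
count of distinct proteins with runs. The nested partition report
conditions each percentage on its parent branch (rim-bearing or
rim-lacking → has a poly-E gene → has a C-terminal poly-E gene) and rounds
to one decimal; empty branches are flagged rather than reporting 0/0.

## Cleavability rules (`cleavage`)

Cleavage of a tail construct is predicted when

* any maximal E-run reaches **6** residues, or
* a maximal E-run of **5** contains the last genetically encoded residue,
  that residue itself being E (the "boundary rule").

Aspartate never counts toward a run, and the prediction is a function of
the tail region only — carrier-protein identity is irrelevant. Internal
runs (not reaching the C-terminus) use the same 6-residue threshold, since
an internal octa-glutamate linker is an experimentally confirmed substrate.

The relative *rate* is an ordinal (NIL < VERY_SLOW < SLOW < REDUCED <
EQUIVALENT). The default heuristic maps the longest eligible run L to:
L ≥ 11 on the unmodified reference suffix (`DNADE`) → EQUIVALENT; L ≥ 8 →
REDUCED; L ≥ 6 → SLOW; boundary-rule-only constructs → VERY_SLOW. Observed
rates are only approximately proportional to run length, so the packaged
substrate panel (26 constructs) ships an observed-rate column used as a
per-construct calibration overlay; the overlay changes the ordinal class
for six constructs but never the binary call. The heuristic (overrides
excluded) is monotone: extending an eligible run by one E never lowers the
class. Where the panel lists no encoded suffix for a construct the boundary
rule is inert, which is the conservative reading.

## Rim-gene classification (`rimclass`)

Accessions are screened with three queries (RimB, RimK, the RimBK hybrid)
against pre-computed forward and reverse hit tables in the 12-column
tabular search format. Assembly-quality filter: reference/representative
flag set, ≤ 15 contigs, ≥ 500 CDSs (both thresholds inclusive). A query is
present in an accession iff the top forward hit (maximum bitscore, ties by
minimum E-value then lexicographic subject id — the search literature is
silent on ties, so a deterministic rule is imposed) has E ≤ 1e-9
(inclusive) and is reciprocal, i.e. the subject's top reverse hit is the
exact original query protein. A missing reverse entry counts as
non-reciprocal and is logged. Presence is per accession, ignoring copy
number.

Hybrid resolution: when the RimB- and RimK-query top hits of an accession
resolve to one and the same subject, both passing the E-value threshold,
and that subject's reverse top hit is one of the three rim queries, the
accession is called RimBK-positive and separate B/K presences are
suppressed — a single hybrid gene must not be double-counted as rimB+rimK.
The family-reciprocity condition exists because without it two unrelated
decoy hits landing on the same subject could fabricate a hybrid call.
Thresholding alone is monotone in `e_max`; the hybrid overlay can in
principle reclassify a borderline accession when the ceiling is raised,
which is the intended semantics (the evidence changed).

The presence pattern maps deterministically onto eight arrangement classes;
accessions with all three queries present fall under `Others`. Partition
percentages are computed over rim-bearing accessions only. MGE proximity is
ordinal: a rim gene is linked when an MGE-flagged gene lies within 5 gene
indices on the same replicon (strand and physical distance ignored).

## Supermatrix (`supermatrix`)

Seven marker proteins (AtpD, DhaE, GuaA, GyrB, RecA, RpoB, RpoD) are
concatenated per accession in a fixed order. An accession missing a marker
receives an all-gap block of that marker's width rather than being dropped;
missing-marker gaps count as gaps in filtering. Columns whose gap fraction
strictly exceeds 0.5 are deleted (exactly 50% is kept); the operation is
idempotent and invariant under row permutation, and a partition log tracks
per-marker column ranges through filtering. Alignment ('.' normalised to
'-') and tree inference are delegated to external tools; the module also
validates Newick leaf names and writes the two iTOL colour-strip rings
(taxonomic group, rim class) with a stable category → colour mapping.

## Mass ladders (`msladder`)

A poly-Glu n-mer is n residues plus one water; the singly protonated ion
with k sodium substitutions has

    m/z = n·129.04259 + 18.01056 + 1.00728 + k·21.98194   (monoisotopic)

so consecutive chain lengths are spaced one Glu residue (129 Da nominal)
apart and each Na-for-H substitution adds 21.98194 Da. An average-mass
table (residue 129.1155) is available for instruments reporting average
masses of long polymers; monoisotopic is the default since the source
spectra come from a lock-mass-calibrated Q-TOF. Detection matches each
chain length (up to 60) at each sodium count (up to 3) to the closest peak
within a ppm tolerance (default 20 ppm, a conservative figure for that
instrument class), then lets candidate series claim peaks greedily —
longest series first, total matched intensity as tie-break — so each peak
supports at most one series. Series shorter than 3 assignments are
discarded; gaps within a series are tolerated. Only relative intensities
are used, so detection is invariant under uniform intensity scaling.

## Synthetic data (`synthetic`)

The generators emulate the pipeline's input formats with planted,
machine-readable truth; one integer seed determines every byte of output.

* **Proteomes** — backgrounds are drawn uniformly from the 19 non-E
  residues, so planted runs are the only runs and recovery can be asserted
  exactly. Terminal runs end at the final residue; internal runs are
  inserted strictly inside the background so both flanks are non-E.
* **Rim universes** — each accession gets one of seven arrangement classes;
  planted best hits have E ≤ 1e-9 with matching reciprocal reverse rows,
  hybrid accessions route the RimB- and RimK-query best hits onto the
  single hybrid gene, and decoys are constructed to fail the presence
  criterion (E > 1e-9, or reciprocity broken), with bitscores low enough
  never to displace a planted top hit. MGE flags are planted near a
  configurable fraction of rim genes; truth records the realised linkage
  (a flag planted for one rim gene can fall within another's window).
* **Ladders** — peaks sit at theoretical polymer m/z jittered uniformly
  within a stated ppm, with exponentially decaying intensities and a
  constant attenuation per sodium series; noise peaks are kept ≥ 50 ppm
  from every theoretical ladder mass (chain lengths to 60, sodium counts
  to 3) so planted truth stays recoverable by a correct detector.

None of the generators simulate sequence evolution, realistic alignment
scores, isotope envelopes or instrument baselines; passing recovery tests
therefore demonstrates correctness of the bookkeeping and decision rules,
not robustness to real-data artefacts such as compositionally biased
proteomes or overlapping polymer series.

## Test problem sizes

The recovery suites run 10 simulated universes of 200 accessions at decoy
rate 0.5, 100 noisy ladder simulations (50 decoy peaks, jitter half the
matching tolerance, chain lengths 20–36), 100 proteome round-trips, 1000
random sequences against a brute-force run enumerator, and 100 random
alignments for filter invariants — sizes chosen so the full suite runs in
seconds while exercising every decision boundary (thresholds are tested on
both sides: contigs 15/16, CDS 500/499, E 1e-9/1e-8, gap 0.50/0.51, MGE
distance 5/6, run length 5/6 internal and 4/5 boundary).

## Known limitations

* Ordinal rate classes beyond the calibration panel extrapolate a
  heuristic; only the binary cleavability call is claimed for new tails.
* The reciprocity test requires the exact query protein as the reverse top
  hit; gene-family-level reciprocity would be more permissive.
* The ladder detector assumes deconvoluted, singly charged peak lists; it
  does not handle charge-state mixtures or isotope clusters.
* Genome-scale census percentages depend on external genome downloads and
  are not reproduced here; the census and partition operations are instead
  validated on synthetic truth.
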