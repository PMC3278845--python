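# Methods

This note documents the models, numerical choices and limitations of
`dinucpred` at the level a user needs to interpret its outputs.

## Contact definition and dinucleotide sites

A *contact* is any protein-residue atom strictly closer than 3.5 Å to any
atom of an RNA dinucleotide site. The inequality is strict: an atom pair
at exactly 3.5 Å does not count. All atoms present in the input file
participate, including hydrogens when a structure provides them;
detection is implemented with KD-trees and is verified in the test suite
against a brute-force all-pairs scan, so any spatial-indexing
acceleration is behaviourally invisible.

Dinucleotide sites are *overlapping*: every consecutive nucleotide pair
(step 1, 5′→3′) is a site, giving L−1 sites for an unbroken chain of
length L and covering all 16 ordered classes AA…UU. The overlap has one
important consequence: a residue touching a single interior nucleotide
contacts *both* sites that contain it, so one physical contact can light
two profile columns. A pair of nucleotides only forms a site when the
chain is continuous there — O3′(i)–P(i+1) below 2.0 Å, or, when those
atoms are absent, consecutive author residue numbers — which prevents
phantom sites across crystallographic gaps.

Structure input is PDB text (read via Biopython): first model only,
highest-occupancy alternate location (ties resolved by label order),
MSE read as MET, solvent skipped, and chains that are neither protein
nor RNA (e.g. DNA) excluded with a warning. Chain type is decided by
majority over polymer residue names.

## Accessible surface area

The random-docking null needs absolute ASA per residue and per
nucleotide, computed on each chain *isolated* from its complex. ASA is
computed by Shrake–Rupley sampling: 960 deterministic golden-spiral
points per atom on the solvent-extended sphere of radius r + 1.4 Å,
heavy atoms only, with element radii C 1.87, N 1.65, O 1.40, S 1.85,
P 1.90 Å. A point is buried if it falls inside any neighbouring atom's
extended sphere; the exposed fraction times 4π(r + probe)² is the atom's
area, summed per residue.

Because a fixed point set is direction-dependent, coordinates are first
rotated into a principal-axes frame derived from the atom cloud (axis
signs fixed by the third moment of the projections). This makes the
sampled areas equivariant under rigid motion — the same chain translated
or rotated yields identical ASA to machine precision — at no accuracy
cost. Sampling error at 960 points is well under 1% against dense
Monte-Carlo surface integration on overlapping-sphere fixtures; the
isolated-sphere case is exact by construction.

## Random-docking expectation and signed χ²

For one complex with N observed residue–site contact pairs, the expected
count for amino-acid type i and dinucleotide class j is

    E_ij = N · ASA(i) · ASA(j) / Σ_k Σ_l ASA(k) · ASA(l)

where ASA(i) is the summed ASA of all residues of type i in the complex
and ASA(j) the summed ASA of all sites of class j. The allocation
conserves N exactly (the denominator factorises, so Σ E_ij = N to
floating-point precision). Observed counts are at residue–site pair
granularity: a residue touching two distinct GA sites counts twice (a
binary per-residue-per-class mode is available).

Observed and expected matrices are summed over all complexes *first*
(each complex weighted equally), then each cell is scored with

    χ²_ij = sign(O_ij − E_ij) · (O_ij − E_ij)² / E_ij

and a p-value from the χ²(1) survival function of the unsigned
statistic; direction is carried entirely by the sign. Cells with
E < 1e-9: the statistic is 0 (p = 1) when O = 0, and NaN (undefined,
written as NA) when O > 0 — no infinities are produced.

## Sequence features

Per residue, a window of n neighbours per side (n ∈ [0, 8], window
length 2n + 1) concatenates per-position blocks:

* **21-bit one-hot** — 20 amino-acid bits plus a terminal bit for window
  positions beyond the sequence ends;
* **PSSM** — the 20 PSI-BLAST log-odds of that position, passed through
  the logistic function 1/(1+e^(−x)) by default so they lie in (0,1)
  alongside the binary features (raw and ÷10 scalings are available);
  out-of-range positions contribute zero rows.

Optionally one 20-vector of global amino-acid composition (fractions,
summing to 1) is appended. Feature dimension is
(2n+1)·(21·sparse + 20·pssm) + 20·gac, constant across proteins under
one configuration. PSSM files are the standard blastpgp ASCII layout;
column order is taken from the file header and remapped internally to
the fixed alphabet ACDEFGHIKLMNPQRSTVWY.

## Network, training and cross-validation

The predictor is a fully connected three-layer network: logistic hidden
layer (default 10 units) and 16 independent logistic outputs — the
targets are multilabel (a residue may contact several classes), so no
softmax. Training is online (per-pattern) backpropagation on squared
error; weight initialisation is uniform(−0.1, 0.1) and pattern order is
reshuffled every epoch, all from one seeded generator, so training is
bit-reproducible. After each epoch the mean squared error on a held-out
stop set is evaluated; training halts when it has not improved for
`patience` consecutive epochs (or at `max_epochs`) and the weights of
the best stop-set epoch are returned. Defaults: learning rate 0.05,
patience 10, max 500 epochs. All residues are training patterns with no
class re-balancing by default; a seeded negative-subsampling option
exists for speed.

On the small synthetic benchmarks in the test suite, a higher learning
rate (0.2) with a longer patience (25–50) is used: with rare positives,
squared-error descent at rate 0.05 improves the stop error so slowly
that patience-10 stopping can trigger before any class separation has
emerged. These are experiment settings, not package defaults.

Cross-validation is five-fold at the *protein* level: folds partition
the proteins; in cycle c, fold c is scored, fold (c+1) mod 5 drives
early stopping, and the remaining three train. Every protein is scored
exactly once, by a model that never saw it; per-class AUC is computed on
the pooled out-of-fold scores. Per-RNA-functional-class training
(viral/mRNA/tRNA/rRNA) runs one such cross-validation per class,
skipping classes with fewer than 5 proteins, with per-class
hyper-parameter overrides recorded in the report.

## Evaluation

AUC uses the Mann–Whitney rank statistic with midranks for tied scores,
which equals the trapezoidal area under the ROC curve; operating points
treat score ≥ cutoff as positive, and the peak-F point maximises F1 with
ties broken toward the higher cutoff. The precision calibration is the
raw step function cutoff → TP/(TP+FP) among predictions at or above the
cutoff, per class, computed on out-of-fold predictions only; no
smoothing or monotonic regression is applied, and classes without
positives are reported unavailable rather than extrapolated.

## Fragment pairs

For fragment lengths L (protein, ≥1) and M (RNA, ≥2), all stride-1
window combinations are generated — (n−L+1)·(m−M+1) per chain pair — and
labelled 1 when any inter-fragment atom pair is strictly within 3.5 Å.
Features are the residue model's 16 scores for each fragment residue
followed by the fragment's M−1-dinucleotide composition (16 fractions
summing to 1), giving 16·L + 16 values. The pair classifier is the same
network machinery with one output; cross-validation folds are assigned
per *complex*, because pair-level folds would put near-duplicate sliding
windows on both sides of a split. Defaults L = M = 5. Negatives vastly
outnumber positives; seeded negative subsampling is available but off by
default.

## Synthetic data

The generator emulates exactly what the pipeline consumes, not
biophysics. Chains are laid out along parallel axes 25 Å apart: three
pseudo-atoms per residue (CA, CB, CG), four per nucleotide (P, C1′, N1,
O3′) with O3′–P spacing 1.2 Å so chain-continuity checks pass. A contact
is realised by pulling a residue's CG atom to 3.2 Å (configurable,
always < 3.5) from the C1′ of the chosen site's 5′ nucleotide; the
geometry guarantees that exactly that nucleotide is touched, and the
ground-truth profile is recorded by an independent brute-force recount
of the generated coordinates.

Two planting modes:

* **stochastic** — every residue contacts a uniformly chosen site with
  probability `background_contact_rate` (default 0.05); residues named
  in `planted_pairs` additionally contact a site of the planted class
  with probability min(0.95, background · odds). Odds of 1 reduce to
  background. Because of site overlap, planting class b1b2 also enriches
  the planted residue's row at classes X+b1 — expected, and excluded
  from the "non-planted background" when tests compare planted versus
  chance cells.
* **identity rule** — a map residue-letter → class; rule residues always
  contact, others never. Each rule dinucleotide b1b2 is embedded in the
  RNA as the triplet b2-b1-b2 and the contact aimed at the embedded
  occurrence, so the overlap-coupled second label (b2b1) is also a pure
  function of the rule class and the target stays deterministic — the
  basis of the end-to-end learning checks.

PSSM files carry +4 on each residue's own column plus integer Gaussian
noise (sd 1), mimicking the self-conservation of real profiles, in
genuine blastpgp layout with the native ARNDCQEGHILKMFPSTWYV column
order so the reader's remapping is exercised. One global seed fans out
to per-complex streams; identical configurations produce byte-identical
directories.

What the synthetic data does *not* model: real side-chain chemistry and
packing, base pairing and RNA secondary structure, evolutionary
correlation between neighbouring PSSM rows, and realistic contact
densities (real interfaces put ~2% of residues in contact with a given
dinucleotide class; the generator's rates are chosen for statistical
power at small n). Passing tests therefore demonstrate correctness of
the machinery and recoverability of planted signal — not the accuracy
attainable on curated complex sets, which requires real structures and
PSSMs from a sequence database search.

## Problem sizes

The bundled checks run on one CPU in a few minutes total: preference
recovery uses 16 replicates of 10 complexes (~300 residues each
dataset); the learning checks use 20 complexes (~600 residues) for the
five-fold run plus five permuted-label controls; the fragment classifier
uses 10 units of 100 pairs. These sizes give comfortable statistical
margins for every asserted bound while staying small enough to iterate
on.

## Known limitations

* PDB input only; mmCIF and assembly reconstruction are out of scope.
* PSI-BLAST itself is not run; PSSMs are consumed, not produced.
* The ASA radius table covers C/N/O/S/P; structures with other
  heteroatoms in polymer chains need radii added before ASA is computed.
* The χ² statistic treats cells independently (one degree of freedom
  each); no multiple-testing correction is applied to the 320 p-values.
* Per-complex equal weighting of the pooled statistics is a choice;
  size-weighted pooling would emphasise large complexes.
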