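# Methods

This note records the models, conventions and design choices behind
`ehmine`, in the order the pipeline runs them.

## Sequence database

Proteomes are PROKKA/Prodigal-style `.faa` files: the header splits at the
first whitespace into id and free-text annotation; a trailing `*`
(translated stop) is stripped, an internal `*` is rejected as an
annotation fault, and `X` is accepted as an unknown residue.  A compiled
database preserves source order and enforces globally unique ids.  One
annotation string is stored per product; when PROKKA and Prodigal
disagree, reconciling them is the caller's job (an optional
`id<TAB>annotation` sidecar overrides header descriptions).

## Alignment engine

Pairwise global alignment is a three-state affine-gap dynamic programme
(Gotoh) over BLOSUM62 with gap open 11 and extend 1, the common protein
default.  A gap run of length *g* costs `open + (g−1)·extend`,
and transitions between the two gap states are allowed, so the optimum
equals the best score over *all* alignment strings (this is also the
universe the test oracle enumerates).  `X` scores 0 against everything,
making ambiguity scoring-neutral.  Ties are broken deterministically:
match/mismatch over gap-in-second-sequence over gap-in-first.  Because
co-optimal alignments are tie-broken asymmetrically, the identity matrix
orients every pair by id before aligning, which makes it exactly
permutation-equivariant.

Percent identity is `100 × identical columns / columns with ≥ 1 residue`
— the gap-inclusive convention suited to clustering, where terminal
truncations should register as dissimilarity; the stricter gap-free
denominator is available behind a flag (`gap_free=True`).

The multiple alignment is center-star progressive: the center maximises
summed pairwise identity, others are merged under "once a gap, always a
gap".  This is a deliberate stand-in for a production MSA tool — adequate
for bootstrap column resampling at desk scale, not for publication-grade
alignments of distant homologs.

## Mining

Two candidate routes, mirroring practice:

* **Text mining** — plain case-insensitive substring match (default
  keyword `"epoxide hydrolase"`), no stemming; monotone in the keyword
  set.
* **Domain scan** — per-family PSSMs built from bundled seed alignments
  (columns with > 50 % gaps dropped; pseudocount 0.5; flat background
  0.05, matching the synthetic residue composition).  A scan reports the
  best ungapped window; a hit requires the profile's threshold, defined
  as the 99th percentile of best-window scores over 1000 length-preserving
  shuffles of the *pooled* seed residues (fixed calibration seed 1982).
  Pooling makes each decoy several profile-lengths long so the null is a
  max-over-windows statistic like a real scan; calibrating on single-seed
  shuffles (one window each) was observed to let ~78 % of full-length
  random proteins through.  With the pooled null the false-hit rate is
  near the nominal 1 % per profile, and the handful of background
  proteins that do pass are rejected downstream for lacking catalytic
  machinery.

The Pfam accessions (PF06441, PF07858) are provenance labels only; no
downloaded HMMs are involved, and full profile-HMM scoring is out of
scope.

## Classification

Candidate residues are never pattern-matched blindly: the candidate is
globally aligned to its best-identity reference and the reference's
annotated catalytic positions are read through the alignment, the way the
field reports positions in reference numbering.  The family decision tree
is, first match wins:

1. complete LEH Asp-Arg-Asp triad → `LEH`;
2. missing nucleophile Asp → `rejected` (not a bona fide EH);
3. D-R-x-x-R-x-x-x-R from the nucleophile → `dehalogenase_like`;
4. complete α/β triad (nucleophile Asp, base His, Tyr, acid Asp/Glu at
   either charge-relay anchor, variant A checked first) →
   `abEH_Nterm`/`abEH_core` by the N-terminal-domain call;
5. otherwise `rejected`.

The LEH hypothesis competes only when the candidate's evidence points at
that family — an LEH domain hit, or identity to the LEH references at
least that to the α/β references.  Without this gate a short LEH
reference can anchor a chance-complete D/R/D onto the arginine-rich motif
region of a dehalogenase-like sequence.  The H-G-X-P X-class (aromatic
{F, W, Y}; H excluded as ambiguous) and the post-Asp aromatic are
advisory evidence only, since genuine EHs with aliphatic X residues are
documented.  The dehalogenase motif is checked only when a nucleophile
position maps and is Asp.

The N-terminal-domain call requires both signals: length at least 100
residues above the median of the core (domain-less) references *and* an
EH-N profile hit in the first half of the sequence.

LEH selectivity residues are read at ReLEH-equivalent positions
80/114/116: V@80 or F@114 flags an (R,R)-leaning enzyme, Y@80 or V@116 an
(S,S)-leaning one; the wild-type I/L/I flags neither.  All user-facing
positions are 1-based; internal indices are 0-based.

The shipped reference set consists of synthetic scaffolds carrying the
documented roles (file names and docstrings say so); users substitute
real enzymes through the same YAML + FASTA schema.  Reference scaffolds
carry an acid at *both* charge-relay anchors so they can anchor candidates
of either variant.

## Phylogrouping

Identity → distance (`d = 1 − pid/100`) → neighbor joining with the
Q-criterion.  NJ is deterministic: ties are broken by the
lexicographically smallest pair of cluster labels (a cluster is labelled
by its smallest leaf id) and negative branch lengths clamp to zero.
Supports come from column-bootstrap over the family MSA (default 500
replicates): each replicate re-derives identities, distances and an NJ
tree; an internal edge's support is the percentage of replicates
containing its bipartition.  LEH and α/β enzymes are analysed in separate
trees, and `--strip-nterm` removes detected EH-N domains before the α/β
tree so grouping reflects the shared hydrolase core.

A candidate inherits group label L iff the smallest supported
(≥ `min_support`, default 50 %) clade containing it and at least one
reference contains references of label L only; both sides of each
supported bipartition count as clades on the unrooted tree, and
equal-sized candidates are ordered deterministically.  Mixed or
reference-free clades leave the candidate `ungrouped`.

Neighbor joining replaces maximum-likelihood estimation deliberately: the
purpose here is group assignment relative to labelled references, for
which NJ on identity distances is exact in the additive regime and cheap
to bootstrap; ML tree estimation is out of scope.

## Biotransformation analytics

Integrals convert to concentrations through an OLS line fitted to the
external-standard series (5 points in routine use; ≥ 2 distinct
concentrations required).  Concentrations below the intercept clamp to
zero with a warning — negative controls can legitimately out-measure
trace product, so this is not an error.  Conversion is
`100 × max(product − background, 0) / s₀` (s₀ default 10 mM), capped at
100 with a warning; the no-enzyme control subtraction is the single
background correction applied.  Enantiomeric excess uses calibrated
concentrations (identical to raw areas for same-analyte enantiomers under
equal response); an exact tie reports e.e. 0, "racemic".  Replicates are
summarised as mean and sample (n−1) SD — appropriate for duplicates and
triplicates — flagged above 7 percentage points, the usual reporting
bound for such assays.  The stereochemical call applies only to
mono-stereocentre benzylic epoxides: different substrate/product
configurations mean inversion, hence attack at the benzylic carbon;
identical means retention, hence terminal attack; meso or unresolved
inputs return `n/a`.

## Synthetic data

Each enzyme family descends from a fixed consensus (derived once from
hard-coded seeds): LEH (149 aa, ReLEH-style numbering: Arg99-Asp101-Asp132
triad, water-positioning Tyr53/Asn55, selectivity I80/L114/I116), two
distinct α/β cores (300 aa — one for the EH-N-bearing lineage, one for
the core-only lineage, echoing the observation that the two groups differ
throughout the hydrolase domain), a dehalogenase-like core (25 % diverged
from the core-only consensus, hydrophilic H-G-X-P and the triple-arginine
motif planted — dehalogenases are close relatives of EHs), and a distant
second LEH lineage (30 % diverged).  The EH-N block adds 120 residues
plus a 4-residue linker, within the 100–150-residue surplus that
distinguishes the N-terminal-domain group.  Scaffolds diverge from their
consensus by 8 % i.i.d. substitutions at unprotected sites — no indels —
so every manifest claim is checkable by direct string inspection and
alignment anchoring is exercised without gap placement ambiguity.
Backgrounds are residue-i.i.d. (uniform over the 20 amino acids, matching
the profile background); realism is not the generator's objective,
unambiguous truth is.

Defaults model the study conditions at desk scale: 500 gene products
(10 LEH, 20 + 20 α/β with/without EH-N, 10 decoys, 440 background),
mutation rate 0, annotation noise 0, background lengths ~N(320, 80²)
truncated at 60, seed 1982.  Chromatogram tables emit the exact CSV the
reducer consumes, with integrals `slope·conc + intercept + N(0, σ)`.

What passing tests therefore show: the rules and reductions are
implemented correctly and are robust to substitution noise with conserved
catalytic sites.  What they do not show: recall on real proteomes with
indels, domain shuffling, fragmentary gene calls or divergent homologs
below the profile threshold — the generator does not model those.

Because planted LEH candidates and the primary LEH references radiate
star-like from one consensus, their within-family grouping can resolve
ambiguously (a candidate may attach next to the distant-lineage pair);
the well-separated α/β groups assign cleanly.  This mirrors real LEH
practice, where new enzymes are described by nearest characterised
relatives rather than firm group membership.

## Numerical and testing choices

Scores are small-integer sums in floats, so exact equality comparisons in
the traceback are safe.  The alignment oracle in the tests is a memoised
recursion over the three column types — independent of the vectorised
implementation — itself validated against literal enumeration of all
alignment strings for lengths ≤ 5; random test pairs draw lengths 1–12,
where full enumeration would be infeasible.  NJ is cross-checked against
an independent library implementation on additive fixtures, and against
an exhaustive least-squares topology search for up to six taxa.
Pipeline runs derive all stage seeds from the single config seed
(proteome = seed, α/β bootstrap = seed+1, LEH bootstrap = seed+2,
chromatograms = seed+3), giving byte-identical reruns.  Test and
acceptance problem sizes (500-product proteomes, 10-seed sweeps, 25–500
bootstrap replicates) were chosen as the smallest sizes at which the
measured properties are stable.
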