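# Methods

## Codon substitution model

The engine implements a Goldman–Yang-style codon model over the 61
sense codons of the standard genetic code.  For codons i ≠ j differing
at exactly one nucleotide position,

    q_ij ∝ π_j · κ^[transition] · ω^[nonsynonymous],

with all multi-nucleotide changes forbidden.  π is estimated from the
data; the default is F3x4 (products of position-specific nucleotide
frequencies renormalised over sense codons, 9 free parameters), with
F1x4 (3) and empirical codon frequencies (60) available.  The chain is
time-reversible; transition probabilities come from the
eigendecomposition of the π-symmetrised generator, with
scaling-and-squaring (`scipy.linalg.expm`) as a fallback when the
symmetrised matrix is not numerically symmetric (e.g. after frequency
flooring).  Zero entries of π are floored at 1e-10 and renormalised,
with a warning.

### Site-class mixtures and rate scaling

Site models mix ω classes: M0 (single ω), M1a (p0 with ω0 ≤ 1, p1 with
ω = 1), M2a (M1a plus p2 with ω2 ≥ 1).  Branch-site model A has the
standard four classes 0/1/2a/2b; classes 2a/2b use ω2 on foreground
branches only and the background behaviour of classes 0/1 elsewhere,
with proportions p2a = (1−p0−p1)·p0/(p0+p1) and p2b analogous.  The
null variant fixes ω2 = 1.

All classes of a mixture share **one** scale factor: the expected
substitution rate averaged over classes under their *background* ω.
Branch lengths are therefore expected substitutions per codon averaged
over site classes, and a foreground class with ω2 > 1 adds
substitutions on foreground branches instead of merely recomposing
them.  (Scaling each class to rate 1 individually was evaluated and
rejected: it removes most of the branch-site signal, because a
foreground ω2 then changes only the synonymous/nonsynonymous mix at
constant total rate.)  The standalone single-matrix constructor
`build_codon_rate_matrix` is scaled to mean rate 1, which coincides
with the mixture convention for M0.

Gaps, stop codons and codons containing IUPAC ambiguity codes are
treated as fully missing (all-ones partials).  Likelihoods use
Felsenstein pruning over site patterns (columns compressed with
multiplicity weights) with per-node rescaling against underflow.

### GTR+Γ

Nucleotide likelihoods (contig placement) use GTR with a discrete
gamma: 4 equal-probability categories by default, category rates equal
to the conditional means of the Gamma(α, α) slices, normalised to mean
exactly 1.  No invariant-sites category is included: topology inference
is out of scope and placement is insensitive to it at the divergences
simulated here.

## Fitting

`CodonModel(...).fit()` maximises the likelihood by L-BFGS-B on
transformed parameters (log κ with κ ∈ [0.01, 100]; log ω with
ω0 ∈ [1e-4, 1] and ω2 ∈ [1, 50]; additive-log-ratio proportions bounded
at ±15).  Default starting points sit in the purifying regime
(κ = 2, ω0 ≈ 0.15, p0 ≈ 0.7); `restarts` adds seeded jittered starts,
so fits are bit-for-bit reproducible given (input, seed).

Branch lengths are estimated under M0 by coordinate ascent: alternating
L-BFGS-B updates of (κ, ω) with per-branch Brent optimisation on cached
up/down pruning messages (messages refreshed every six edges and every
sweep), iterated until the round-to-round log-likelihood gain drops
below 1e-3.  Mixture models then hold those branch lengths fixed —
tractable at desk scale and standard practice for branch-site
screening; `branch_lengths="fixed"` instead uses the input tree's
lengths.  Branch lengths are counted in k (the AIC parameter count)
since they are estimated from the data, alongside frequency parameters,
κ, and the model's free mixture parameters (M0: 1, M1a: 2, M2a: 4,
model A: 4, model A null: 3); M2a and model A thus add exactly 2 free
parameters over M1a, and the model A vs M1a LRT uses df = 2 (the null
variant vs model A uses df = 1).

Nested fits warm-start from the enclosing null (model A and M2a from
M1a with the foreground proportion pushed to ~0), which enforces the
nesting chain lnL(M1a) ≤ lnL(M2a), lnL(M1a) ≤ lnL(model A) up to
optimiser tolerance and roughly halves fitting time.
`rank_hypotheses` fits M0 once, reuses its branch lengths for all
models, and sorts by AIC with ties broken by fewer foreground branches
then name; the best row is flagged decisive when the runner-up's ΔAIC
exceeds 10 (configurable).

## Contig annotation

* **Homology extraction** — exact 12-mer seeds nominate reference
  sequences; candidates are scored by affine local alignment
  (match +1, mismatch −2, gap open −5, extend −2; biopython
  `PairwiseAligner`); the longest matching contig region is kept when
  strictly longer than `min_len` (default 50 bp; 500 bp for screens of
  day-sampled transcriptome collections).  Both strands are searched;
  coordinates are 1-based inclusive on the forward contig with a
  strand flag.
* **Profile alignment** — the matched segment is aligned to the frozen
  columns of the reference alignment by affine-gap dynamic programming
  against position-specific nucleotide frequencies (expected
  match/mismatch score per column; gap open −4, extend −1; free
  leading/trailing reference columns).  Query-only insertions are
  discarded (counted and reported) so every query occupies exactly the
  reference columns and placements are comparable across contigs.  A
  query with > 80% of its bases in insertions is reported unalignable.
* **Placement** — instead of re-inferring a full tree per contig, the
  query is attached by a pendant edge to the midpoint of every branch
  of the fixed reference topology; the pendant length is optimised by
  Brent under GTR+Γ using cached pruning messages.  This preserves
  exactly the nesting information a per-contig tree would give, at a
  small fraction of the cost.  The likelihood weight ratio (lwr) of the
  best branch is its softmax weight over all branches (of the two
  equivalent edges at a rooted root, one is scored).
* **Assignment** — "clearly nested within a lineage" is operationalised
  as: the best branch lies strictly inside the lineage's clade (the
  stem branch does not count) **and** lwr ≥ 0.8 (configurable).
  Raising the threshold can only shrink the assigned set.
* **rpm** — counts/total-alignable × 1e6 per contig; lineage abundance
  is the sum over its contigs; unassigned rpm is kept in its own bucket
  so per-sample totals are conserved exactly.

## Residue diagnostics

Queries are aligned to the reference protein globally (BLOSUM62, gap
open −11, extend −1) and every requested reference position is mapped
to the aligned query residue (or gap), positions 1-based on the
ungapped reference.  Position 780 is classified — serine:
C4/CAM-associated; alanine: non-CCM-like; anything else or a gap:
other.  The other recurrently substituted positions (531, 572, 665,
761) are reported descriptively only, since they are illustrative
rather than diagnostic.  Alignments with < 30% identity are flagged as
unreliable numbering.  The reference sequence is always a user input;
packaged tests use a synthetic stand-in, not the real protein.

## Synthetic data: what it emulates and what it does not

Every generator is a pure function of (arguments, seed).

* **Trees** — random topologies grown by splitting a uniformly chosen
  pendant edge; branch lengths iid Uniform(0.02, 0.3) by default, a
  range typical of within-family gene trees at codon scale.
* **Codon alignments** — root codons from π, then per-branch
  class-conditional transitions; per-site true class labels are
  returned so recovery tests can close the simulate→fit loop.  No
  indels are simulated (columns are alignment-free); real alignments
  add alignment error that these tests do not probe.
* **Reference panels** — a lineage backbone (default divergence 0.4
  expected substitutions/site between lineages) with small subtrees
  (0.06 within) hanging under each lineage ancestor, evolved under
  GTR+Γ; lineage clades are monophyletic by construction.
* **Diel experiments** — the default planted design is the qualitative
  day/night × watering structure of the motivating system: one gene
  lineage dominant in well-watered day samples (C4-like) and one
  induced at night under drought (CAM-like), with the remaining
  lineages at low constant abundance; numeric values follow the
  published per-sample rpm of the PEPC lineages.  Contigs are fragments
  of lineage source sequences (uniform start; clamped-normal length
  400 ± 150, minimum 200 bp, matching assembler minimum contig
  lengths) with 2% point mutations; read counts are multinomial with a
  1e6 library so expected lineage rpm equals the design cell.  Real
  data add chimeric contigs, multi-mapping reads and library-size
  variation that the generator does not emulate; passing tests
  demonstrate correctness of the pipeline's arithmetic and placement,
  not robustness to assembler artefacts.

## Study conditions used by tests and the acceptance script

The statistical acceptance tests use: null calibration — 200 datasets
of 300 codons on an 8-taxon tree simulated under M1a (p0 = 0.65,
ω0 = 0.15), foreground hypothesis = two internal clade-stem branches,
rejection threshold α = 0.05; power — 50 datasets of 500 codons with
ω2 = 2 planted on those two branches (p2 = 0.2, ω0 = 0.1); fraction
recovery — 20 datasets of 600 codons on a 12-taxon tree with three
foreground branches, planted fraction 0.107 at ω2 = 1.35; annotation —
100 queries evolved 0.05–0.2 substitutions/site from panel members.
`scripts/acceptance.py` recomputes the same quantities at reduced
replicate counts (60 null, 25 power, 10 recovery, 50 queries) so a
single run stays fast; its `--seed` drives every random stream.

## Known limitations

* Branch-site fits on short foreground branches are weakly identified
  (ω2 often hits its bounds under the null); the LRT remains
  calibrated because the statistic, not ω2, is thresholded.
* Standard errors are not reported; uncertainty is assessed by LRT and
  AIC comparisons only.
* The placement lwr is computed over branch argmax scores, not a full
  integration over attachment positions within each branch.
* Bayes-empirical-Bayes identification of individual selected sites is
  not implemented.
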