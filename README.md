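# ccmphylo

Molecular-evolution toolkit for multigene families co-opted into
carbon-concentrating photosynthesis (C4 and CAM), built around the
phospho*enol*pyruvate carboxylase (PEPC) gene family as the motivating
system.  It answers three questions that recur whenever a
photosynthetic pathway is assembled from existing genes:

1. **Which branches of the gene tree evolved adaptively?**
   Site and branch-site codon models (dN/dS): M0, the nearly neutral
   model M1a, the positive-selection model M2a, and branch-site model A
   with a-priori *foreground* branch sets, compared by likelihood-ratio
   tests and ranked by AIC = 2k − 2 ln L.
2. **Which gene lineage does each transcriptome contig belong to, and
   how strongly is it expressed?**  Homology extraction (longest local
   match > 50 bp, both strands), alignment to a frozen reference
   profile, maximum-likelihood placement on a reference tree under
   GTR+Γ, assignment to a gene lineage when the contig is clearly
   nested inside the lineage's clade, and transcript abundance in
   reads per million of alignable reads (rpm) summed per lineage.
3. **Does a protein carry the diagnostic C4/CAM residue?**  Queries are
   mapped onto a reference PEPC numbering by global protein alignment;
   serine at the position homologous to reference position 780 marks
   C4/CAM-associated enzyme forms, the ancestral alanine marks
   non-CCM forms.

A forward simulator (`ccmphylo.simulate`) generates every input the
pipeline consumes — labelled trees, codon alignments under any of the
model families, reference panels with nested monophyletic gene
lineages, and day/night × watering-regime expression experiments with a
planted rpm design — so the whole pipeline is testable end to end with
no external data.

## The model at the core

Codon substitution follows a Goldman–Yang-style Markov process over the
61 sense codons: q_ij = π_j · κ^[transition] · ω^[nonsynonymous] for
single-nucleotide changes, 0 otherwise.  Site classes mix several ω
values; branch-site model A lets a fraction of sites switch to ω2 ≥ 1
on foreground branches only:

| class | proportion | background ω | foreground ω |
|-------|-----------|--------------|--------------|
| 0     | p0        | ω0 < 1       | ω0           |
| 1     | p1        | 1            | 1            |
| 2a    | (1−p0−p1)·p0/(p0+p1) | ω0 | ω2 ≥ 1    |
| 2b    | (1−p0−p1)·p1/(p0+p1) | 1  | ω2 ≥ 1    |

Likelihoods are computed by Felsenstein pruning with per-node rescaling
and site-pattern compression; model A is tested against M1a by an LRT
with two degrees of freedom, and alternative foreground hypotheses are
ranked by AIC.

## Worked example

```python
import numpy as np
import ccmphylo as cp
from ccmphylo.models import CodonModel, likelihood_ratio_test

# simulate a gene tree and an alignment with positive selection on two
# internal branches (omega2 = 2 on 20% of sites)
tree = cp.simulate_tree(8, seed=1)
fg_tree = tree.with_foreground(branches=["n1", "n3"])
params = cp.CodonModelParams(kappa=2.0, omega=1.0, pi=np.full(61, 1/61))
mix = cp.SiteClassMixture.model_a(0.5, 0.3, 0.1, 2.0)
aln, _ = cp.simulate_codon_alignment(fg_tree, mix, params, 500, seed=101)

m0  = CodonModel(aln, tree, model="M0").fit(seed=0)
m1a = CodonModel(aln, tree, model="M1a").fit(seed=0, m0_result=m0)
ma  = CodonModel(aln, fg_tree, model="modelA").fit(seed=0, m0_result=m0,
                                                   warm_start=m1a)
print(f"lnL(M1a) = {m1a.llf:.2f}   lnL(model A) = {ma.llf:.2f}")
print(likelihood_ratio_test(m1a, ma, df=2))
print(f"foreground site fraction = "
      f"{cp.foreground_site_fraction(ma):.3f}, omega2 = {ma.omegas['w2']:.2f}")
```

Output:

```
lnL(M1a) = -6409.72   lnL(model A) = -6404.45
LRTResult(statistic=10.537852559087696, pvalue=0.005149136338954198, df=2)
foreground site fraction = 0.144, omega2 = 1.52
```

The LRT rejects the nearly neutral model (χ² = 10.5, df = 2,
p ≈ 0.005) and the fitted model attributes ~14% of sites to the
foreground classes with ω2 ≈ 1.5 — close to the planted 20% at ω2 = 2.
`ma.summary()` prints the full estimate table; `cp.rank_hypotheses`
fits a list of foreground hypotheses and returns the AIC ranking.

A command-line interface mirrors the library:
`ccmphylo fit|rank|annotate|rpm|residues|simulate --help`.

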