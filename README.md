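# parevol

Molecular-evolution analyses for heterochronous virus sequence data: temporal
signal, episodic selection, functional divergence, residue coevolution and
ribosome-binding-motif characterization — with seeded synthetic-data
generators so every stage can be exercised and validated without sequence
downloads.

## Who this is for

Virologists and molecular evolutionists studying how related viral lineages
(for example, the three picobirnavirus species, whose RdRp segments appear to
descend from distinct reovirus-like and partitivirus-like ancestors) acquired
similar phenotypes in parallel. The package re-implements, as a tested
library, the inference chain such a study needs:

1. **Temporal signal** (`parevol.temporal_signal`) — root-to-tip regression
   (rate = slope, tMRCA = x-intercept) with an analytic optimal-root search,
   and BETS: the Bayes factor between a model given real sampling dates
   (heterochronous) and one with dates constrained equal (isochronous),
   log *M* estimated by path sampling (PS) and stepping-stone (SS) sampling
   from power-posterior ladders, with block-bootstrap Monte-Carlo errors.
2. **Adaptive divergence** (`parevol.epoch_divergence`) — a time tree is cut
   into 50-year epochs; the HKY transition/transversion ratio κ_n is fitted
   jointly per epoch by maximum likelihood; episodic positive selection is
   tested with the branch-site codon models A (ω₂ ≥ 1 on pre-specified
   foreground branches) vs A₁ (ω₂ = 1), compared by a χ²₁ LRT; the
   adaptive-divergence statistic per window is AD = Σω₂ / κ_n, the sum of
   statistically supported foreground dN/dS divided by the epoch's mutational
   transition bias.
3. **Functional divergence** (`parevol.functional_divergence`) — type I
   (covarion-like rate shifts between two clusters; Gamma-Poisson mixture
   over Fitch substitution counts, coefficient θ_I) and type II
   ("constant-but-different": sites conserved within clusters but fixed for
   residues of different physicochemical class, coefficient θ_II), each with
   site posteriors Q_k and a flagging cutoff (default Q_k > 0.98).
4. **Coevolution** (`parevol.coevolution`) — after a physicochemical alphabet
   reduction, column pairs whose states co-segregate on the tree (agreement
   of maximal-monophyletic-block signatures) are tested by tip permutation,
   clustered, and summarized into intra-/inter-domain interaction weights
   (direct plus indirect through shared cluster members).
5. **Shine-Dalgarno-like motifs** (`parevol.sd_motifs`) — 5′UTR/intergenic
   extraction, scanning for the canonical AGGAGGU (U ≡ T) or the degenerate
   core xGGxGGx at a 5 ± 2 nt spacer before the ATG, per-position Shannon
   entropy (stability), logo matrices and metadata cross-tabulations.
6. **Synthetic data** (`parevol.synthetic_data`) — seeded generators for
   dated coalescent/birth-death trees, HKY alignments with epoch-varying κ,
   GY94 codon alignments with branch-site ω classes, two-cluster protein
   alignments with planted θ fractions, planted coevolving column pairs and
   UTR sets with planted SD motifs, each with a truth envelope.

## Worked example

```python
from parevol import synthetic_data as syn
from parevol.temporal_signal import bets_compare, fit_root_to_tip

# Bayes-factor arithmetic on published log marginal likelihoods
# (RdRp segment, strict clock, path sampling)
comp = bets_compare(176_580.2855, 176_878.692, convention="table1")
print(f"BF = {comp.bayes_factor:.4f}  favored: {comp.favored_model}")

# root-to-tip regression on a simulated dated tree with distance noise
tt = syn.simulate_timed_tree(n_taxa=20, seed=11, sampling_window=100, pop_size=40)
dt = syn.as_divergence_tree(tt, rate=1e-3, noise_sd=0.004, seed=11)
fit = fit_root_to_tip(dt, rooting="best-r2")
print(f"rate = {fit.substitution_rate:.3e} subs/site/year")
print(f"tMRCA = {fit.tmrca:.1f}  R^2 = {fit.r_squared:.3f}")
```

prints

```
BF = 298.4065  favored: heterochronous
rate = 9.420e-04 subs/site/year
tMRCA = 1790.1  R^2 = 0.981
```

The Bayes factor of 298.4 reproduces the published table entry for the RdRp
strict-clock comparison and, being far above the decision threshold of 3,
supports the heterochronous model — the sequences carry usable temporal
signal. The regression recovers the simulated clock rate of 10⁻³
substitutions/site/year to within the injected noise, and the x-intercept
dates the root.

A command-line interface mirrors the library:

```bash
parevol rtt --tree tree.nwk --rooting best-r2 --out results/
parevol bets --het trace_het.tsv --iso trace_iso.tsv --convention table1
parevol adaptive-div --tree t.nwk --codon-aln cds.fasta --dna-aln nt.fasta \
    --foreground branches.txt --windows 50 --epochs 3
parevol fundiv --aln prot.fasta --tree t.nwk --cluster1 ids1.txt \
    --cluster2 ids2.txt --type I --qk-cutoff 0.98
parevol coevo --aln prot.fasta --tree t.nwk --domains domains.tsv \
    --perms 1000 --alpha 0.05 --seed 7
parevol sdscan --fasta segments.fasta --orfs orfs.tsv --spacer 5 --tol 2
parevol simulate codon --seed 1 --out sim/
```

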