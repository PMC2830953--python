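# phyloselect

Selective-pressure analysis of protein-coding gene families, built for
molecular evolutionists who want the full pipeline — data-quality gating,
long-branch-attraction diagnosis, codon-model selection inference, and
disease-site annotation — as one tested, scriptable Python package.

## The science

The rate ratio ω = dN/dS of non-synonymous to synonymous substitution
measures selective pressure on a protein-coding gene: ω < 1 is purifying
selection, ω ≈ 1 neutrality, and ω > 1 positive (Darwinian) selection.
Because selection acts episodically — on a few codons, sometimes only on
particular lineages — `phyloselect` fits the standard ladder of codon
site-class mixtures (M0, M1, M2, M3 k=2/3, M7 beta, M8, M8a) and the
branch-site models A, A-null and B on a 61-state Goldman–Yang-style
substitution model, compares nested pairs by likelihood-ratio test
(2ΔlnL against χ² at the registered degrees of freedom), and identifies
selected sites by naive and Bayes empirical Bayes posteriors.

Selection inference is only as good as the data behind it, so the
pipeline gates on quality first: a sum-of-pairs randomization z-score for
the alignment, per-taxon composition chi-square screens, and quartet
likelihood mapping for phylogenetic signal (category 1/2/3).  Topological
conflict between gene and species trees is diagnosed with nodal-distance
RMSD and the Shimodaira–Hasegawa test, and long-branch attraction is
tested with the slow-fast method: strip the fastest of 8 site-rate
categories, re-infer the tree, and ask whether agreement with the species
phylogeny returns.  Finally, positively selected sites are mapped to a
reference sequence and tested for proximity to disease-implicated
residues by a uniform-placement randomization test.

See `docs/methods.md` for models, assumptions and numerical choices.

## Worked example

Simulate 500 codons for 10 mammals under M8 (90% of sites with ω drawn
from beta(0.4, 0.6), 10% at ω = 4), then test for positive selection:

```python
from phyloselect import (CodonModelSpec, SimulationRecipe, fit_model,
                         mammal_tree, run_lrt, simulate_codon_alignment,
                         site_posteriors)

tree = mammal_tree().prune_to(
    ["Human", "Chimp", "Macaque", "Mouse", "Rat", "GuineaPig", "Rabbit",
     "Dog", "Cow", "Opossum"])
truth = {"kappa": 2.0, "p0": 0.9, "p": 0.4, "q": 0.6, "omega_s": 4.0}
aln, _ = simulate_codon_alignment(SimulationRecipe(
    tree=tree, model=CodonModelSpec("M8"), params=truth, n_sites=500, seed=11))

m7 = fit_model(aln, tree, CodonModelSpec("M7"), branch_lengths="given")
m8 = fit_model(aln, tree, CodonModelSpec("M8"), branch_lengths="given")
print(run_lrt(m7, m8))
print(site_posteriors(m8, aln, method="BEB").n_calls())
```

Output (`examples/04_site_selection.py` prints the full walk-through):

```
M7: lnL = -5936.17   M8: lnL = -5878.55
M8 estimates: p0=0.930 p=0.513 q=0.752 omega_s=4.48 (truth: p0=0.9, omega_s=4)
M7 vs M8 LRT: 2dlnL = 115.25, df = 2, p = 9.43e-26 -> positive selection
BEB positively selected sites: 26>0.50  17>0.95  12>0.99
```

The LRT statistic 115.25 on 2 degrees of freedom decisively rejects the
no-selection beta model; the recovered mixture (93% beta-distributed
sites, a selected class at ω ≈ 4.5) matches the generating values, and
26 sites exceed the 0.50 posterior call threshold.

The other `examples/` scripts cover the quality screens, gene-vs-species
tree comparison, the slow-fast LBA scan, branch-site analysis on the
rodent stem (2% of sites at foreground ω ≈ 73 recovered with
p ≈ 3e-10), and the disease-proximity test.

A thin CLI mirrors the stages (`phyloselect quality|tree|compare|lba|
select|annotate|simulate|run`); `phyloselect run --config gene.yaml
--outdir out/` executes the whole per-gene workflow and writes the TSV
report bundle.

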