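# cactakit

Annotation and comparative dynamics of **CACTA-superfamily TIR transposons**,
built for highly repetitive nonautonomous families of the kind found in plant
genomes: hundreds to thousands of short (300–450 bp) copies with unusually
long terminal inverted repeats (TIRs), conserved `5'-CACTA ... TAGTG-3'`
termini, and AT-rich 3-bp target site duplications (TSDs).

Given two (or more) assemblies of closely related genomes, the pipeline

1. **discovers** family members structurally (termini + TIR + TSD validation)
   and by homology to a seed library (score > 250, hit length > 50 bp),
   classifying copies as complete or truncated;
2. **profiles insertion-site bias** — per-position nucleotide frequencies over
   the TSD and ±200 bp of flanking sequence, with GC summaries and a logo
   count-matrix export;
3. **maps chromosomal density** in 100-kb windows and tests centromere
   depletion with a Welch t-test;
4. **clusters** complete elements into subfamilies with the greedy multi-round
   85/85 rule (≥85% identity over ≥85% of the query's length);
5. **calls insertion polymorphisms** between assemblies by anchoring each
   element's 100-bp flanks in the other genome (present / absent / ambiguous,
   with uniqueness and repeat filters);
6. **dates activity** with a transposon molecular clock: orthologous element
   pairs shared by both genomes give a mean Kimura two-parameter distance
   K̄, the known split time *T* calibrates the substitution rate

   r = K̄ / (2T),    and any element divergence *k* converts to an age  t = k / (2r);

   per-subfamily all-pairs divergence histograms and neighbor-joining trees
   summarize amplification history.

Real assemblies are never required: `cactakit.simulate` generates a pair of
genomes diverged from a common ancestor with planted elements and a complete
ground-truth registry (coordinates, TSDs, subfamily labels, shared/specific
status, gene context), so every stage is verifiable end to end.

## Worked example

```python
from cactakit.simulate import SimulationConfig, simulate_pair
from cactakit.discovery import annotate
from cactakit.profile import extract_site_context, build_pfm, site_bias_report
from cactakit.seqcore import gc_fraction
from cactakit.dating import calibrate_rate

cfg = SimulationConfig(seed=7, chrom_length=500_000, elements_per_subfamily=30,
                       n_truncated=20, n_polymorphic_a=10, n_polymorphic_b=10)
sim = simulate_pair(cfg)

ann = annotate(sim.genome_a, sim.library, genome_id="A")
print(ann.summary)
# {'genome': 'A', 'n_total': 150, 'n_complete': 130, 'n_truncated': 20,
#  'masked_bp': 55669, 'masked_fraction': 0.0527...}

complete = [e for e in ann.elements if e.complete]
ctx, _ = extract_site_context(complete, sim.genome_a)
rep = site_bias_report(build_pfm(ctx), gc_fraction("".join(sim.genome_a.values())))
print(f"TSD GC {rep.tsd_gc_mean:.3f} < flank GC {rep.flank_gc_mean:.3f} "
      f"< genome GC {rep.genome_gc:.3f}")
# TSD GC 0.151 < flank GC 0.281 < genome GC 0.354

cal = calibrate_rate([0.0146], 110_000)   # mean ortholog K over a 110-kyr split
print(f"r = {cal.r:.3g} subs/site/yr")
# r = 6.64e-08 subs/site/yr
```

The discovery summary says 130 of the 150 annotated copies retain both
termini, a ≥50-bp TIR and identical 3-bp flanks (complete), covering ~5.3% of
the simulated assembly.  The GC ordering — TSD far below flanks, flanks below
genome — is the signature of AT-preferring insertion.  The last two lines are
the clock calibration: a mean ortholog divergence of 0.0146 substitutions/site
across a 0.11-My split implies ~6.6 × 10⁻⁸ substitutions/site/year.

The same stages are available as a CLI
(`cactakit simulate | discover | profile | density | cluster | polymorph |
date | genic | run-all`); `cactakit run-all --seed 7 --out outdir` writes every
stage's TSV/GFF3/BED/Newick output plus a consolidated `report.json`.

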