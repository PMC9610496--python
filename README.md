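# rnpfootprint

Survivorship footprinting of extracellular nonvesicular RNA.

## The problem

Secreted ribonucleases of the RNase A superfamily cleave single-stranded RNA
on the 3′ side of pyrimidine residues (C, U). RNA inside extracellular
vesicles (EVs) is shielded by the lipid bilayer, but nonvesicular RNA —
carried by extracellular particles such as exomeres (~35 nm) and supermeres
— is exposed. Only the intervals physically covered by bound protein
complexes survive digestion: the extracellular nonvesicular RNAome is shaped
by survivorship bias. A surviving fragment is predictable from the cleavage
chemistry: a protected interval `[a, b)` on a transcript yields the fragment

```
start = (nearest pyrimidine strictly upstream of a) + 1        (or 0)
end   = (nearest pyrimidine at or downstream of b) + 1         (or L)
```

because the cut falls 3′ of the pyrimidine and the cut base stays on the
upstream product. The classic example is the Sm heptamer ring on the
oligo(U) Sm site of the U2 snRNA, whose footprint circulates as the fragment
annotated as miR-1246; looser factors (SF3B1 on the branch site loop,
SNRPA1 on stem loop IV) add footprints in some particle classes only.

`rnpfootprint` turns that reasoning into a testable pipeline for
computational biologists working on extracellular RNA fragmentomics:

- **core** — the cleavage rule, eligible-site logic and protected-fragment
  prediction, with BED6/FASTA interchange;
- **synth** — seeded generators: per-molecule stochastic digestion (each
  eligible site cut with probability `q`), compartment read simulation
  (CELL / EV / EXOMERE / SUPERMERE) producing FASTQ + ground-truth BED, and
  a spectral-count table generator with per-class effects;
- **readproc** — adapter trimming, exhaustive sense-strand alignment against
  small transcript references (SAM output), per-transcript counts and RPM;
- **profiles** — coverage pileups (depth / 5′ / 3′ tracks, bedGraph export),
  footprint calling, terminus-pyrimidine statistics, fold changes;
- **compare** — classification of a profile into `uniform` (EV/cell-like),
  `multi_footprint` (exomere-like) or `core_only` (supermere-like), and
  rank-correlation profile similarity;
- **proteomics** — spectral-count normalization (`log2(raw/total·10⁴ + 1)`),
  size–count Spearman correlation (exact permutation p for n ≤ 10), Wilcoxon
  matched-pairs signed-rank test (exact for n ≤ 25 via the conditional
  rank-sum distribution), and two-way ANOVA (protein × class) with
  per-protein Tukey HSD comparisons.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (all outputs under `results/`):

```
python analysis/01_simulate.py
python analysis/02_process_reads.py
python analysis/03_footprints_and_classes.py
python analysis/04_proteomics_stats.py
```

`01` builds a 199-nt synthetic U2-like reference carrying an Sm-like core
interval and two peripheral intervals, simulates 20,000 reads per
compartment at cleavage probability q = 0.9, and a 200-protein
spectral-count table with a 25-protein "ribosomal" group enriched 2× in the
exomere class. `03` then prints, for that simulation:

```
CELL       label=uniform          breadth=0.980 in_core=0.218 concordant={'core': 0, 'peripheral': 0} pyrimidine_3p=0.273
EV         label=uniform          breadth=0.985 in_core=0.199 concordant={'core': 0, 'peripheral': 0} pyrimidine_3p=0.268
EXOMERE    label=multi_footprint  breadth=0.583 in_core=0.332 concordant={'core': 1, 'peripheral': 2} pyrimidine_3p=1.000
SUPERMERE  label=core_only        breadth=0.266 in_core=0.911 concordant={'core': 1, 'peripheral': 0} pyrimidine_3p=1.000
similarity to CELL: EV         rho=0.427
similarity to CELL: EXOMERE    rho=0.597
similarity to CELL: SUPERMERE  rho=0.303
```

Reading this: the undigested compartments cover the whole transcript
(breadth ≈ 0.98, classified `uniform`) and their read 3′ ends land on
pyrimidines at roughly the transcript's pyrimidine content (0.27); the
digested compartments end almost exclusively on pyrimidines (1.000, the
cleavage chemistry read directly off the reads), the exomere-like sample
shows the core plus both peripheral footprints, and the supermere-like
sample shows only the core footprint with 91% of its coverage inside the
predicted core fragment. `04` prints the matching proteomics readout — a
positive size–count correlation within the enriched group
(`rho=0.642 p=5.5e-04`, exomere class) and a one-sided-extreme paired
signed-rank test (`W+=325 p=6.0e-08 n=25`: every group protein higher in
the exomere class).

A thin CLI exposes the same steps (`rnpfoot simulate / process / classify /
proteomics-stats ...`).

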