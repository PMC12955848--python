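# codonfold

Design mRNA coding sequences (CDSs) that are simultaneously **structurally
stable** and **well adapted to the host's codon usage**.

A protein of `l` residues admits up to `6^l` synonymous CDSs, and the two
standard quality measures pull in opposite directions: the minimum free
energy (MFE) of the most stable secondary structure rewards GC-rich,
pairing-prone sequences, while the codon adaptation index (CAI) — the
geometric mean of per-codon relative adaptiveness `w` — rewards the host's
preferred codons.  `codonfold` searches the *joint* space of synonymous
sequences and pseudoknot-free structures exactly, minimizing

```
mu * MFE  -  kappa * l * log(CAI)        with  l*log(CAI) = sum_codons ln w
```

which covers both common scalarizations: `MFE - lambda * l*log(CAI)`
(`mu=1, kappa=lambda`, `lambda >= 0`) and `lambda*MFE - (1-lambda) *
l*log(CAI)` (`lambda` in `[0,1]`).  On top of the single-`lambda` solver it
enumerates the **supported Pareto front** of (MFE, CAI) trade-offs
automatically by weighted-sum recursion.

## How it works

* **Codon lattice** — all synonymous CDSs are encoded as paths of a layered
  graph with at most 6 codon-prefix states per nucleotide position; the
  prefix-trie transitions preserve the intra-codon dependencies of the
  6-codon amino acids (Leu, Arg, Ser), and each codon's `-ln w` is charged
  once on its third-position edge.
* **Joint dynamic program** — a span-based Zuker-style DP over pairs of
  lattice states finds the exact optimum in `O(L^3)` time and `O(L^2)`
  space for `L = 3l` (bounded lattice width).  An optional beam width `b`
  keeps only the `b` best pairing states per right endpoint for a fast,
  feasible approximation.
* **Energy models** — base-pair maximization (`nussinov`) for exact
  desk-scale validation, and a Turner-2004-derived nearest-neighbor model
  (stacking + loop tables + affine multiloop + terminal-AU penalty) for
  realistic energies.  See `docs/methods.md` for the exact parameter
  surface.
* **Brute-force oracles** — tiny-instance enumeration of all CDSs and all
  structures backs every DP with an independent ground truth in the tests.

## Worked example

```
$ printf '>P1\nMDEKRHGGFLSW\n' > p1.fasta
$ codonfold single --protein p1.fasta --formulation derna --lam 0.8 --out-prefix p1_out
P1: mfe=-18.70 cai=0.8697 objective=-14.6250 -> p1_out.fasta, p1_out.tsv

$ cat p1_out.fasta
>P1
AUGGACGAGAAGCGCCACGGGGGCUUCUUGUCCUGG
..(((((((((((.((....)))))))))))))...
```

At `lambda = 0.8` the designed 36-nt CDS folds into a 13-pair helix at
−18.7 kcal/mol while keeping CAI = 0.870 under the embedded human usage
table; the reported objective is `0.8*(-18.7) - 0.2*(-1.675) = -14.625`.

Pareto mode explores the whole trade-off:

```
$ printf '>demo\nMFLSKW\n' > demo.fasta
$ codonfold pareto --protein demo.fasta --model nussinov --out-prefix front
demo: 2 distinct Pareto-optimal CDSs out of 3 solver outputs -> front.front.tsv

$ cut -f1,2,4,5 front.front.tsv
lambda       cds                 mfe      cai
0.999999000  AUGUUUCUGAGCAAGUGG  -6.0000  0.976494
0.000001000  AUGUUCCUGAGCAAGUGG  -5.0000  1.000000
```

The stable end gains one base pair (nussinov units) by spending CAI; the
adapted end uses every preferred codon (CAI = 1).  Per-point MFE%/CAI%
columns rescale each measure to 0–100% across the front (100% = best).

The same API is available from Python:

```python
import codonfold as cf
w = cf.relative_adaptiveness(cf.embedded_human_usage())
front = cf.pareto_front("MFLSKW", w, cf.nussinov_model())
for p in front.points:
    print(p.cds, p.mfe, round(p.cai, 4))
```

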