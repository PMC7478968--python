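# crispr-e

Gene essentiality testing from CRISPR/Cas9 clone genotyping: indel
calling, reading-frame classification, and exact frameshift-depletion
statistics.

## The problem

Classical essentiality assays (knockout by homologous recombination,
transposon mutagenesis) rely on negative selection: when no knockout is
recovered, there is usually no proof that the gene was ever hit. A
positive-evidence alternative is to target the gene's open reading frame
with sgRNA/Cas9 in a population of haploid cells, pick surviving clones,
and Sanger-sequence the target region of each clone. Error-prone NHEJ
repair leaves insertions and deletions at the cut site whose net length
`n` falls into three residue classes mod 3:

- **3n (in-frame)** — the downstream reading frame is preserved; the
  protein keeps or loses a few residues and often remains functional;
- **3n+1 and 3n+2 (frameshift)** — the downstream protein is scrambled
  and the gene is inactivated.

If the gene is dispensable, surviving clones carry both classes. If the
gene is **essential**, every frameshift lineage dies during clonal
growth: the surviving clones carry *only* in-frame alleles, and those
in-frame alleles are the positive proof that Cas9 did cut the locus.

## The statistic

Assume editing events fall into the three residue classes uniformly, so
a frameshift occurs with theoretical frequency `f_exp = 2/3` (the
default; it is a parameter, because real sgRNA-specific indel spectra
can be biased). Among `k` independent edited events with `x` frameshift
events:

- `P(all in-frame) = (1 - f_exp)^k = (1/3)^k` — the exact null
  probability of observing zero frameshifts in a neutral gene;
- `P(X <= x)`, `X ~ Binomial(k, f_exp)` — the one-sided exact tail for a
  frameshift *deficit*;
- the **essentiality score** `E = (x/k) / f_exp` with an exact
  Clopper–Pearson interval on `x/k` scaled by `1/f_exp`:
  `E > 1` — losing the gene is beneficial; `E = 1` — neutral;
  `0 < E < 1` — deleterious; `E = 0` — essential.

Clones with byte-identical edit signatures are collapsed into one
independent editing event before computing `k` (identical clones are
progeny of a single cut-and-repair outcome); editing and inactivation
*efficiencies* are reported over sequenced clones, and both denominators
appear explicitly in every report.

## Worked example

The package ships the clone compositions of five single-gene
*Dictyostelium discoideum* experiments as programmatically built
fixtures (`crispre.datasets`), including the essential dynein light
intermediate chain gene Dync1li1. Write one to disk and genotype it:

```python
from crispre import datasets
exp = datasets.dync1li1_combined()
datasets.write_experiment(exp, "demo/dync1li1")
```

```
$ crispr-e call --reference demo/dync1li1/reference.fasta \
    --orf-start 12 --orf-end 171 --guide ATGGTATCTCCCCTAATCAT \
    --clones demo/dync1li1/clones.fasta \
    --status demo/dync1li1/status.tsv --out-dir demo/out
CRISPR-E report (schema 1.0)
clones: 21 total = 0 failed + 21 sequenced (3 WT + 18 edited)
independent editing events: 18
event classes: in_frame=18, frameshift_plus1=0, frameshift_plus2=0
editing efficiency (edited clones / sequenced clones): 85.7% (18 out of 21)
inactivation efficiency (frameshift clones / sequenced clones): 0.0% (0 out of 21)
class fractions over events: in-frame 100%, 3n+1 0%, 3n+2 0%
k = 18 independent edited events, x = 0 frameshift
P(all in-frame | neutral) = (1 - 0.6667)^18 = 2.581e-09
one-sided exact frameshift-deficit P = 2.581e-09
E = 0 [95% CI 0-0.278]
verdict: essential
```

Reading it: 18 of 21 clones were edited (85.7% on-target efficiency), so
Cas9 demonstrably cut the locus — yet not one surviving allele is a
frameshift. Under the neutral null that outcome has probability
(1/3)^18 ≈ 2.6 × 10⁻⁹; the essentiality score is E = 0 with an exact
95% upper bound of 0.28, so the gene is called essential.

The same pipeline is available as a library (`call_experiment`,
`collapse_identical_clones`, `essentiality_from_summary`), and
pre-called variant tables (TSV: `clone_id, kind, position, ref_allele,
alt_allele`, 0-based positions) can substitute for clone FASTA via
`--variants`, bypassing alignment.

Other subcommands: `crispr-e stats --k 18 --x 0` (bare-count mode with
`--f-exp`, `--confidence`, `--alpha`), `crispr-e simulate` (synthetic
clone sets with configurable indel spectra, sibling-clone rate,
sequencing failures and frameshift survival `s`; seeded and
byte-reproducible), `crispr-e report` (re-render saved JSON).

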