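# Methods

## Model and procedure

The package genotypes clonal Sanger amplicons of a Cas9-targeted ORF
region and quantifies essentiality from the selective absence of
frameshift alleles among surviving clones.

**Target location.** The 20-nt protospacer is matched exactly (no
mismatches) on both strands of the reference amplicon; it must occur
once, immediately 5′ of a PAM matching `NGG` (the pattern is
configurable, e.g. for non-SpCas9 dialects). The blunt cut is placed
3 bp 5′ of the PAM, between protospacer bases 17 and 18 — the standard
SpCas9 convention, adopted here as a documented assumption since cut
positions are otherwise only known from where indels cluster.
Coordinates are 0-based, half-open, on the reference plus strand;
minus-strand hits are reflected into plus coordinates.

**Allele calling.** Each clone is aligned globally to the reference
(affine gaps; default match +2, mismatch −3, gap open −6, gap extend −1
in the convention where a length-L gap scores `open + (L−1)·extend`;
end gaps are penalized because the clone is a full-length amplicon).
The defaults were chosen so that a >20-nt deletion is recovered as a
single gap rather than a run of mismatches. Clones below a 60%
identity floor (or outside 1.5× length bounds) are degraded to
`failed_sequencing` rather than aborting the experiment. Gap runs
become single insertion/deletion edits, mismatch columns single-base
substitutions; indels are left-normalized (VCF-style, bounded by the
preceding edit) so that sibling-clone detection is byte-exact
regardless of where the aligner happened to place a gap in a repeat.

**Frame classification.** Only edits intersecting the analysis window
(default ±30 nt around the cut; edits spanning the boundary count in
full) contribute. The frame class is the non-negative residue of the
net indel length mod 3; substitutions never change frame.
Substitution-only alleles are edited and in-frame. Clones whose edits
all fall outside the window are classified WT-at-target and flagged —
distant edits are more plausibly PCR/sequencing artifacts, and the
essentiality argument concerns the targeted region only. The ±30
default comfortably covers the largest deletions seen in the packaged
clone sets (22 bp).

**Translation and stop gains.** In-frame alleles are re-translated
from the ORF start to one codon past the window (or past the furthest
edit); a stop codon appearing there that is absent from the reference
translation is flagged `stop_gain` — such alleles still count as
in-frame in the class tallies but are reported separately, since an
in-frame allele with a premature stop can inactivate the gene without
shifting frame. Frameshift alleles are translated to the first
downstream stop.

**Independent events.** Clones with identical in-window edit
signatures are collapsed into one independent editing event (siblings
of one cut-and-repair outcome that separated after editing). WT clones
never merge with edited ones. Efficiencies (editing = edited/sequenced,
inactivation = frameshift/sequenced) use clone-level counts over
successfully sequenced clones; class fractions and the E score use
event-level counts. Both denominators are printed because they answer
different questions (how well the guide works vs what the surviving
allele spectrum is).

## Statistics

With `k` independent edited events, `x` of them frameshift, and
theoretical frameshift frequency `f_exp` (default 2/3, i.e. residues
uniform over {0,1,2}):

- `P(all in-frame) = (1 − f_exp)^k`. Note the formula is followed as
  written; the decimals sometimes quoted alongside it elsewhere
  ((1/3)^4 as 0.005, (1/3)^7 as 0.00018) are inconsistent with the
  formula itself ((1/3)^4 = 1/81 ≈ 0.0123, (1/3)^7 = 1/2187 ≈ 0.00046)
  and are not used as oracles anywhere.
- Frameshift-deficit test: exact binomial tail `P(X ≤ x)`,
  `X ~ Binom(k, f_exp)` (scipy `binomtest`), one-sided by default to
  match the directional natural-selection argument; a two-sided
  alternative is available via a flag.
- `E = (x/k)/f_exp`, with a Clopper–Pearson interval on `x/k`
  (statsmodels `proportion_confint(method="beta")`) scaled by
  `1/f_exp`. Exact intervals are the default because every realistic
  clone count here is small (k ≤ 21); no asymptotic interval is
  offered. Verdict bands: `E = 0` essential (equivalently `x = 0`),
  `0 < E < 1` deleterious, `E = 1` neutral, `E > 1` beneficial to lose.
- Planning aid: the smallest k with `(1 − f_exp)^k ≤ α` (3 at α=0.05,
  5 at α=0.01).

`f_exp` is configurable because sgRNA-specific repair spectra are known
to be biased; it can be estimated from a non-essential control gene.
Consequently the test is most reliable for calling essential genes
(`x = 0` is robust to moderate spectrum bias), less so for grading the
essentiality of non-essential ones.

## Synthetic data generator

`crispre.simulate` emulates the clone-picking design: per clone, a
sequencing failure (probability `p_fail`), a sibling of an earlier
surviving event (`p_duplicate`, copying the parent's exact edits), or a
fresh outcome — unedited with probability `1 − p_edit`, otherwise one
draw from a deletion/insertion/substitution-only mixture centered at
the cut site. Frameshift outcomes survive with probability
`frameshift_survival` (s); rejected outcomes are resampled as surviving
lineages, keeping the picked clone count fixed (clone-level survival,
not population dynamics). Defaults model a typical single-gene
experiment: 12 clones, `p_edit` 0.7, `p_fail` 0.1, `p_duplicate` 0.15,
mixture weights 0.55/0.30/0.15.

Indel sizes default to capped geometric distributions (deletions:
p = 0.20, cap 30 nt; insertions: p = 0.30, cap 12 nt), chosen to span
the −22…+12 nt range of the packaged real clone sets; explicit
size-weight maps can be substituted — a uniform {1..6} spectrum puts
exactly 2/3 of its mass on non-multiples of 3 and is used in the
calibration tests. Substitution-only alleles draw 1–3 substituted bases
within ±2 nt of the cut. With a fixed seed, the FASTA, truth table and
echoed config are byte-identical across runs.

What the generator does **not** emulate: microhomology-mediated repair
(real deletion endpoints are sequence-dependent), chromatogram noise
and mixed traces, biased sgRNA-specific spectra, or population drift
during growth. Passing pipeline-vs-truth tests therefore demonstrates
correctness of the calling and statistics on clean clonal outcomes,
not robustness to base-calling artifacts (unalignable-clone handling
covers the gross failure mode only).

**Parameter recovery.** Under a frame-uniform spectrum, the surviving
frameshift frequency is `(2/3)s / ((2/3)s + 1/3)`, so the analytic
score is `E_true = 1` at s=1, `0.75` at s=0.5, `0` at s=0; the general
closed form uses the configured spectrum's frameshift mass. The
recovery study (100 seeded replicates per s, 120 clones, `p_edit` 0.8,
k ≥ 50 edited clones each) runs the full FASTA-alignment pipeline and
checks that the exact CI covers `E_true` in ≥ 90 of 100 replicates.
Recovery is computed at the clone level with collapsing disabled and
`p_duplicate = 0`: with no sibling clones every clone is an independent
event, whereas signature collapsing would wrongly merge coincidentally
identical independent outcomes (small indels have a small outcome
space), biasing k downward at large clone counts. The pipeline default
for real data remains collapsing on, where clone counts are small and
identical sequences are overwhelmingly siblings.

## Packaged fixtures

The five single-gene clone sets (grlB, grlC, KIF1A, fAR1, Dync1li1
with two guides singly and combined) are rebuilt programmatically from
their per-clone edit compositions. Reference amplicons are synthetic —
deterministic sequences with the guide embedded on a codon boundary,
an AGG PAM and a stop-free ORF — because no accessions exist for the
original amplicons; where an individual indel's exact size or position
was not published (fAR1, the combined Dync1li1 set), synthetic values
consistent with the published class tallies are used, and docstrings
say so. One ambiguity is resolved explicitly: the grlB set has six
failed clones but only five are named; the unlisted clone B8 is taken
as the sixth.

## Numerical and design choices

- Alignment ties are resolved deterministically (first optimal
  alignment of the aligner's fixed enumeration order); left
  normalization makes the extracted edits canonical regardless of the
  tie chosen, which is what event collapsing and the round-trip
  invariant rely on.
- Degenerate inputs: zero sequenced clones is an error for
  efficiencies; zero edited events makes E undefined (reported as
  "essentiality untestable" with exit status 0 and a warning, since an
  all-WT clone set is an editing failure, not evidence).
- The multinomial null over the three residue classes reduces to the
  binomial on (frameshift vs not); tests verify the binomial tail
  against full 3^k enumeration for k ≤ 8.
- Problem sizes in the validation suite (3000 simulated clones for
  truth agreement, 100 replicates × 120 clones for recovery, 10^4
  draws for interval coverage) keep the whole study at desk scale —
  a few tens of seconds on one CPU.

## Known limitations

- Single-site, single-gene analysis; no multi-gene screening
  corrections (a wrapper applying Benjamini–Hochberg across genes
  would be straightforward but is out of scope).
- Haploid logic: each clone is one allele. Diploid phasing and mixed
  Sanger traces (TIDE/ICE-style deconvolution) are out of scope.
- Exact-match guide location only; no on-target efficiency prediction
  or off-target enumeration.
- `E` inherits any bias in `f_exp`; interpretation bands are sharp at
  the point estimate, so the reported CI should accompany any verdict
  other than `essential`.
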