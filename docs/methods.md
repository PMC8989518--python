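# Methods

## Positional PAS-motif enrichment

The core statistic is the per-offset density of polyadenylation-signal
hexamers around RBP binding sites. Each site contributes one window of
2F nucleotides (F = 100 by default) centred on its *anchor* — the 5′ end of
the binding interval in RNA orientation: the BED `start` for plus-strand
sites, `end − 1` for minus-strand sites. Windows on the minus strand are the
reverse complement of the genomic sequence, so offset *o* always reads the
transcript base *o* nt downstream of the anchor; a polyadenylation-signal
analysis is only meaningful in transcript orientation, which is why strand
`.` in the input BED is a hard error rather than a default.

Within each window every exact occurrence of every motif in the set
(default: AATAAA, ATTAAA, AAATAA, ATAAAA, ATAAAT) is counted at its start
offset; occurrences may overlap and one offset may emit several motifs
(the counts are summed, not collapsed). `N` bases match nothing. Matching is
sense-strand-only within the oriented window, since the PAS is a sense
element. The density at offset *o* is total matches at *o* divided by the
number of windows; offsets within motif-length−1 of the window's downstream
edge cannot host a full motif and report 0. Sites whose window would cross a
contig boundary are dropped and counted (`n_dropped`), not zero-padded, to
avoid edge-biased densities.

Under an i.i.d. uniform background each eligible offset has expected density
5·4⁻⁶ ≈ 0.0012207 (linearity over the five hexamers); the test suite checks
the implementation against this closed form at 3 binomial standard errors,
and against a naive per-position re-scanner exactly.

**Smoothing** is a centred moving average, default window w = 11 nt, odd w
required; at the profile edges the window truncates to the offsets that
exist. The choice is deliberately the simplest defensible smoother; w is
exposed as a flag. Ties in the smoothed argmax resolve to the smallest
offset, deterministically.

**Permutation null.** Each null replicate circularly rotates every window's
sequence by an independent uniform shift and re-aggregates; this preserves
each window's length and base composition while destroying positional
structure. With n_perm replicates (default 1000, minimum 100),
z(o) = (observed(o) − mean_null(o)) / sd_null(o), with sd computed across
replicates (ddof = 1) and z set to 0 where sd = 0. The null is seeded and
bit-reproducible.

**Cross-factor profiles** count a query factor's anchor positions at each
relative offset from the anchor sites, same contig and same strand only,
offsets in the anchor's RNA orientation (minus-strand anchors:
offset = anchor − query), normalised by the number of anchor sites exactly
as the motif profile is. On dense site sets the density at a planted offset
can exceed the planted contribution slightly, because unrelated same-strand
sites occasionally fall inside an anchor's window; the end-to-end demo
therefore checks the peak offset exactly and the peak density as ≥ 1.

## Splice-event filter and dPPAU

Differential splice events are kept iff FDR < 0.05 (strict) and the
junction-read rule for their class holds: A3SS/A5SS need
IJC₁ + IJC₂ + SJC ≥ 10; SE, MXE and RI need SJC ≥ 10, or one inclusion
count ≥ 10 with the other ≥ 5. One rule implementation serves SE/MXE/RI;
MXE's extra junction pairs are collapsed into the two IJC columns by the
table schema (a documented simplification). The filter is deterministic and
idempotent.

dPPAU is the mean proximal polyA-usage (percent) over condition samples
minus the mean over controls — group means, not per-pair differences.
Positive dPPAU means increased proximal-site usage in the condition. Events
are classified at strict thresholds: proximal-up = #{dPPAU > t},
proximal-down = #{dPPAU < −t}, t ∈ {0, 20}; counts are monotonically
non-increasing in t by construction.

## BioID shortlisting

The t-test runs on log2-transformed LFQ intensities (standard for LFQ;
intensity 0 is missing and is dropped, never imputed). It is the
pooled-variance Student's form, not Welch. Degenerate cases are pinned:
fewer than two non-missing values in either group → p undefined (and the p
filter fails); zero pooled variance with differing means → p = 0; identical
constant groups → p = 1. No multiple-testing correction is applied — the
procedure is a raw p < 0.05 filter by design. The four filters
(peptides > 4, coverage > 20%, p < 0.05, log2FC > 1) are conjunctive and
strict at their boundaries, so relaxing any one can only grow the shortlist.

## Fold-change concordance

Genes are intersected by id and kept if significant in both tables
(`mode=both`, the default and the conservative reading) or in at least one
(`mode=either`). Pearson r, its p-value, and the OLS slope/intercept of b's
log2FC on a's come from `scipy.stats.linregress`. Fewer than three surviving
genes is an error stating the count.

## Synthetic data: what it emulates, and what it does not

Each generator is a pure function of its parameters and a seed; a master
seed derives per-stage seeds through numpy's `SeedSequence([master,
stage_index])`, so one flag reproduces a whole run and adding a stage never
perturbs the others. The defaults are the pipeline's study conditions:

| generator | defaults | emulates |
|---|---|---|
| `gen_genome` | 100 kb, uniform base probabilities | an unstructured background genome |
| `gen_sites` | 500 sites, length 20, F = 100, strands Bernoulli(0.5) | CLIP binding intervals, placed so no window is dropped |
| `plant_pas` | AATAAA at round(Normal(+20, 5)) nt downstream, planting probability 0.5 | a PAS positioned after the binding site in a fraction of transcripts |
| `shift_sites` | +7 nt downstream in RNA orientation | a co-binding 3′-processing factor at a controlled offset |
| `gen_splice_events` | 500 rows over branch-pinned templates | an rMATS-style table whose kept set is known by construction |
| `gen_ppau` | 2000 events, 5 samples/group, baseline 50%, effect ±30, 20% shifted, noise sd 2 | QAPA-style PPAU tables at mouse-cohort scale |
| `gen_quant` | 600 proteins, 25 interactors, 3 reps/group, effect 3 log2 units, sd 0.2 | MaxQuant-style LFQ with clean planted interactors |
| `gen_fc_pair` | 2000 genes, bivariate normal, r = 0.30 | paired differential tables with a chosen correlation |

Offsets are planted in RNA orientation deliberately, to exercise the
strand/reverse-complement logic — the most error-prone contract in the
package. Plant offsets that would leave the window are redrawn (at most 100
attempts). PPAU values are clipped to [0, 100]; at the default baseline and
noise clipping is rare. With 500 sites on 100 kb, independently planted
motifs can occasionally overwrite one another; peak-recovery statistics are
insensitive to this, and tests that assert per-site exactness use spaced,
collision-free site layouts.

What the generators do **not** model — and hence what passing tests do not
demonstrate about real data: CLIP peak-width and sequence-composition
structure, transcriptome annotation and 3′-UTR geometry, compositional
coupling between proximal and distal usage, MS missingness that depends on
intensity, and correlated significance between fold-change tables (the
generated p-values are uniformly significant so the correlation estimate is
exercised in isolation).

## Pipeline, problem sizes and determinism

The `demo` orchestrator runs simulate → profile → cobind → splice-filter →
apa → bioid → concord with one seed and writes per-stage planted-vs-recovered
checks; any failure makes the exit status non-zero. Every output file starts
with a `# config_hash=… seed=…` comment so runs are attributable; reruns with
the same configuration are byte-identical. Configuration is a flat YAML
mapping; CLI flags override the file, the file overrides the defaults, and
the defaults are exactly the analysis parameters above.

The shipped problem sizes (500 sites × 200-nt windows × 1000 permutations;
2000 sites for the analytic background; 2000 events/genes for the table
stages) were chosen so the planted effects are recovered with wide margins —
e.g. the planted-peak z exceeds 20 against a threshold of 5, and the dPPAU
noise sd of 2 puts the effect 8 standard errors from the t = 20 boundary —
while a full demo completes in seconds. Stochastic checks (background
density within 3 SE, correlation within ±0.05) hold for typical seeds but
are, by nature, ~2–3σ statements per run.

## Known limitations

- Whether the original CLIP analyses oriented flanks by strand or used
  plus-strand genomic sequence throughout is not documented upstream; this
  package orients by strand (the biologically meaningful choice for a PAS
  analysis), which may shift minus-strand details relative to analyses that
  did not.
- The upstream smoother settings are likewise unreported; the moving average
  here is a simple, documented stand-in and the window is a flag.
- The splice filter treats MXE through two IJC columns; tables with richer
  junction structure must be collapsed before input.
- `read_genome` loads contigs into memory (no FASTA indexing); genome-scale
  inputs work but are not the target. BigBed/BAM inputs are out of scope.
- The shortlist implements exactly the four stated filters; any further
  confidence ranking among passing proteins is left to the user.
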