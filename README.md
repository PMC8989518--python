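# apakit

Tools for screening RNA-binding proteins (RBPs) for a role in mRNA
polyadenylation. The package implements the computational chain used to
identify such regulators from public data: positional enrichment of
polyadenylation-signal (PAS) hexamers around CLIP binding sites, cross-factor
binding profiles, splice-event junction filtering, classification of
alternative-polyadenylation shifts, proximity-labelling (BioID) interactor
shortlisting, and fold-change concordance between knockdown/knockout
experiments — plus synthetic-data generators with known ground truth so the
whole pipeline can be exercised and validated end to end without any
downloads.

## What it computes

**Positional PAS-motif profile.** For each strand-aware binding site the
100-nt flanking window around the site's transcriptional start (its 5′ end in
RNA orientation; minus-strand windows are reverse-complemented so increasing
offset always means downstream on the transcript) is scanned for the five
consensus PAS hexamers

```
AATAAA, ATTAAA, AAATAA, ATAAAA, ATAAAT
```

counting every exact, possibly overlapping occurrence. The per-offset density
is

&nbsp;&nbsp;&nbsp;&nbsp;d(o) = (number of motif starts at offset *o*, summed over sites) / (number of sites),

smoothed with a centred moving average (default window 11 nt). Significance
comes from a permutation null: each window's sequence is circularly rotated by
an independent uniform shift (preserving its base composition), densities are
re-aggregated *n*<sub>perm</sub> times, and z(o) = (d(o) − mean<sub>null</sub>) / sd<sub>null</sub>.
Under an i.i.d. uniform background the expected density per eligible offset is
5·4⁻⁶ ≈ 0.00122, which the package's tests verify analytically.

**Cross-factor binding profile.** The same positional normalisation applied
to a second factor's binding starts relative to the anchors (same contig, same
strand, offsets in the anchor's RNA orientation) — e.g. a 3′-end-processing
factor around an SR-protein's sites.

**Splice-event filter.** Differential splice events (rMATS-style tables) are
kept iff FDR < 0.05 and, for A3SS/A5SS, the junction reads sum to ≥ 10; for
SE/MXE/RI, the skipping count SJC ≥ 10 or one inclusion count ≥ 10 with the
other ≥ 5. Kept events are tallied per class.

**dPPAU classification.** For each APA event, dPPAU = mean proximal polyA-site
usage (PPAU, percent) in condition − mean in control; events are counted as
proximal-up (dPPAU > t) or proximal-down (dPPAU < −t) at the strict thresholds
t = 0 and t = 20.

**BioID shortlist.** Proteins pass iff all four strict filters hold: > 4 razor
+ unique peptides, > 20% sequence coverage, p < 0.05 (two-sided pooled-variance
Student's t on log2 LFQ intensities versus the free-ligase control; zeros are
missing) and log2 fold change > 1.

**Fold-change concordance.** Genes significant (p < 0.05) in both differential
tables (or in either, by flag) are compared by Pearson correlation with an
ordinary-least-squares regression line.

## Worked example

Plant AATAAA hexamers downstream of synthetic binding sites (normal offsets,
mean +20 nt, sd 5 nt, planting probability 0.5) and recover the offset:

```python
from apakit import synthetic, extract_flanks, permutation_z, smooth_profile

genome = synthetic.gen_genome(100_000, seed=synthetic.stage_seed(17, "genome"))
sites = synthetic.gen_sites(genome, 500, flank=100, site_len=20,
                            seed=synthetic.stage_seed(17, "sites"))
planted, truth = synthetic.plant_pas(genome, sites, offset_mean=20,
                                     offset_sd=5.0, planting_prob=0.5,
                                     seed=synthetic.stage_seed(17, "pas"))
windows, n_dropped = extract_flanks(sites, planted, 100)
prof = smooth_profile(permutation_z(windows, n_perm=1000, seed=11), 11)
print(f"planted sites: {len(truth.planted_site_ids)}/{len(sites)}")
print(f"smoothed peak: offset {prof.argmax_offset():+d} nt, z = {prof.z.max():.1f}")
print(f"density at peak: {prof.density_at(prof.argmax_offset()):.4f} motifs/site")
```

prints

```
planted sites: 238/500
smoothed peak: offset +20 nt, z = 21.9
density at peak: 0.0660 motifs/site
```

i.e. with roughly half the sites carrying a planted signal the smoothed
density peaks exactly at the planted mean offset, 22 standard deviations above
the rotation null, at 0.066 motif starts per site (~54× the 0.00122 uniform
background).

The same analysis, and every other stage, is available from the shell:

```bash
apakit demo --seed 17 --outdir demo_out
```

simulates every input, runs profile → cobind → splice-filter → apa → bioid →
concord, writes all outputs (TSV with a config-hash/seed header) and a
`report.tsv` comparing planted against recovered values per stage; it exits
non-zero if any recovery check fails. Individual stages: `apakit simulate`,
`apakit profile`, `apakit cobind`, `apakit splice-filter`, `apakit apa`,
`apakit bioid`, `apakit concord` (see `--help` for flags).

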