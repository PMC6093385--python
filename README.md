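# seedrd

Transcript-degradation analysis for mRNA stored in dry seeds, from
whole-molecule cDNA coverage profiles.

Dry-stored seeds cannot repair their molecules; stored mRNA slowly breaks by
random strand fission, and the damage is measurable long before seeds start
dying.  With poly(A) selection and oligo(dT)-primed whole-molecule cDNA
sequencing, only the 3'-terminal fragment of a broken transcript becomes a
read, so fragmentation shows up as read depth that rises from the 5' to the
3' end.  `seedrd` quantifies that signature and is aimed at anyone comparing
transcript integrity between sample cohorts (e.g. young vs aged seed lots)
from long-read cDNA alignments.

## The statistics

Per sample, depth along each transcript is normalized to 0–100 (maximum over
the full transcript), then averaged within a cohort.  Over the central
window W = [⌈0.25 L⌉, ⌊0.75 L⌋] (transcript ends are unreliable):

```
RD_ref   = Σ_{b∈W} (100 − d̄_ref(b))        / (L·100)   # young cohort vs intact
RD_delta = Σ_{b∈W} (d̄_ref(b) − d̄_aged(b)) / (L·100)   # aged vs young
```

Both are ~0 for intact transcripts and approach 0.5 for fully degraded
windows.  Each transcript lands in a region of the (RD_delta, RD_ref)
plane — A (intact; box calibrated on intact spike-in controls), A′
(intact-ish), B (degraded only during storage), C (early + progressive),
D (early then stable) — with strict rectangular boundaries.

Around the statistics the package provides:

- a random strand-fission simulator (per-bond break probability λ, oligo(dT)
  or random-hexamer chemistry, spike-ins, depth noise) with the closed-form
  coverage oracle `P(cover x) = (1−λ)^(L−x)` and a λ-recovery estimator;
- per-base depth from SAM/BAM or samtools-depth-style TSV;
- the transcript-curation cascade (present in all samples → >75% reference
  coverage → max depth ≥20 in every sample);
- the qPCR ΔCt integrity assay (ΔCt = Ct(3′) − Ct(5′) amplicon), primer
  efficiency from dilution series, and the closed-form link
  `ΔCt = (s₃−s₅)·ln(1−λ)/ln E` for 3'-anchored libraries;
- a `seedrd` CLI (`simulate`, `depth`, `filter`, `rd`, `classify`, `qpcr`,
  `report`, `run`) driven by one YAML config and one seed.

## Worked example

A simulated two-cohort study (60 transcripts plus 8 intact spike-ins,
2 cohorts × 5 replicates, λ_early = 2×10⁻⁴, λ_aging = 1.5×10⁻³, 8 000
reads per sample):

```python
from seedrd import fission_study

study = fission_study(0, n_transcripts=60, reads_per_sample=8000)
for r in study.cascade.reports:
    print(f"{r.stage}: {r.n_input} -> {r.n_output}")
s = study.length_stratification()
print(f"mean RD_delta  >2500 bp: {s['mean_rd_delta_long']:.3f}"
      f"   <1200 bp: {s['mean_rd_delta_short']:.3f}")
print(f"Spearman(length, RD_delta) = {s['spearman_length_rd_delta']:.2f}")
print(study.rd_table.groupby("region").size().to_string())
```

prints

```
presence: 68 -> 68
coverage: 68 -> 68
depth: 68 -> 45
mean RD_delta  >2500 bp: 0.295   <1200 bp: 0.183
Spearman(length, RD_delta) = 0.76
region
A                8
A'               1
B               27
unclassified     9
```

Reading: all simulated transcripts are present everywhere, but low-abundance
ones fail the depth≥20 stage (68 → 45).  Long transcripts accumulate more
storage degradation than short ones (RD_delta 0.295 vs 0.183, Spearman
0.76 with length), the 8 spike-in controls all land in region A (the box is
derived from them), and most curated transcripts fall in region B —
intact when young, degraded after storage — the expected signature of
random fission at an aging-driven rate.

The qPCR side of the same model, for end amplicons 1 300 bp apart on a
1 500-bp transcript with efficiency E = 2:

```python
from seedrd import AmpliconAssay, expected_delta_ct
assay = AmpliconAssay("tx", (51, 150), (1351, 1450), efficiency=2.0)
expected_delta_ct(assay, 1500, 2e-4,   "polyA_oligodT")  # -> -0.38 cycles
expected_delta_ct(assay, 1500, 1.7e-3, "polyA_oligodT")  # -> -3.19 cycles
expected_delta_ct(assay, 1500, 1.7e-3, "total_hexamer")  # -> 0.0
```

The aged cohort's 5' amplicon template is ~7× rarer, costing ~2.8 cycles of
ΔCt in 3'-anchored libraries, while the random-hexamer total-RNA library is
blind to fragmentation position — the contrast that distinguishes strand
fission from, e.g., base oxidation.

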