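# nucfish

A quantification pipeline for **amplified nuclear RNA FISH** experiments —
the kind of assay in which isolated nuclei are hybridized with exon- and
intron-targeting probes, the signal is exponentially amplified over several
probe-binding rounds, and nuclei are then imaged and/or flow-sorted by
transcriptional activity of a single gene.

It is written for microscopists and genomicists who need to turn raw
multi-channel image stacks, flow-event tables and qPCR fold-enrichment
tables into per-cell transcription-site counts, amplification rates, sorting
statistics and chromatin-accessibility contrasts, with every step testable
against simulated ground truth.

## What it computes

- **Spot calling.** Diffraction-limited puncta are detected per z-plane as
  local maxima of a Laplacian-of-Gaussian band-pass response and refined by
  least-squares fitting of an isotropic 2D Gaussian
  `I(x, y) = b + A exp(−((x−x₀)² + (y−y₀)²) / 2σ²)`
  on the plane where the response peaks, giving subpixel centers,
  amplitudes, widths and local backgrounds.
- **Transcription-site calling.** A transcription site is an exon-probe spot
  colocalized with an intron-probe spot inside the same nucleus. Matching is
  greedy nearest-neighbour within a lateral window of 2.5 px (360 nm at
  144 nm/px), with optional mutual-nearest-neighbour confirmation, followed
  by per-cell counting and signal-to-noise summaries.
- **Amplification kinetics.** Per-round spot intensities are summarized by
  their median and fitted by OLS of log₂ intensity against round number; the
  slope gives the fold per round `f = 2^slope` and the binding efficiency
  `f / 2` relative to theoretical doubling.
- **Sorting gates.** Flow events are assigned to ordered half-open gates
  (G1 < G2 < G3) on log₁₀ fluorescence; per-gate means are correlated
  (Pearson) with qPCR-measured intron abundance.
- **Chromatin accessibility.** Target-gene fold enrichment (FE) is
  normalized to the per-replicate mean FE of three control-gene amplicons
  (U_mean): `RQ = 2^−(FE_target − U_mean)`, log-transformed as
  `log₁₀(RQ + 10⁻¹⁰)`, and compared between gates by a paired t-test on
  per-replicate means.

A seeded synthetic-data module generates image stacks, flow events and FE
tables with full ground truth, so every stage is validated end to end.

## Worked example

```python
import nucfish as nf

# simulate a small field of nuclei and call transcription sites
cfg = nf.SceneConfig(n_nuclei=6, seed=42)
stack, mask, truth = nf.generate_scene(cfg)
lm = nf.LabelMask(mask)
exon = nf.assign_spots_to_nuclei(nf.call_spots(stack, "exon"), lm)
intron = nf.assign_spots_to_nuclei(nf.call_spots(stack, "intron"), lm)
sites = nf.call_txn_sites(exon, intron, nf.MatchParams(radius_px=2.5))
counts = nf.per_cell_counts(sites, lm)
print(f"exon spots: {len(exon)}, intron spots: {len(intron)}")
print(f"transcription sites: {len(sites)} (truth: {len(truth.sites)})")
print(f"sites per nucleus: {counts['count'].tolist()}")

# amplification kinetics
series, _ = nf.generate_amplification_series(
    nf.AmplificationConfig(binding_efficiency=0.871, seed=42))
fit = nf.fit_fold_per_round(series)
print(f"fold per round: {fit.fold_per_round:.3f} "
      f"(efficiency {100*fit.efficiency:.1f}%, R^2 {fit.fit_r2:.4f})")

# accessibility contrast between low and high expression gates
fe = nf.generate_fe_table(effect_size=1.0, n_replicates=6, seed=42)
tests = nf.compare_gates(nf.compute_rq_table(fe), pairs=[("G1", "G3")])
row = tests.iloc[0]
print(f"G1 vs G3: mean logRQ shift {row['mean_difference']:.3f}, "
      f"t = {row['t']:.2f}, p = {row['p']:.2e}")
```

prints

```
exon spots: 94, intron spots: 4
transcription sites: 4 (truth: 4)
sites per nucleus: [0, 0, 3, 1, 0, 0]
fold per round: 1.743 (efficiency 87.1%, R^2 0.9999)
G1 vs G3: mean logRQ shift 0.611, t = 31.92, p = 5.67e-07
```

All 4 simulated transcription sites are recovered among ~100 single-RNA
exon spots; a series generated at 87.1% binding efficiency is fitted back to
a 1.743-fold amplification per round; and nuclei sorted into the
high-expression gate show a significantly higher log-accessibility than the
low gate (the positive logRQ shift means the target locus is more open).

The same stages are available from the shell:

```bash
nucfish simulate --out-dir run/ --seed 1
nucfish txnsites --stack run/stack.tiff --mask run/mask.tiff --out-dir run/sites
nucfish all --out-dir run_all/ --seed 1   # every stage on simulated data
```

Each subcommand writes CSV tables with a `#`-prefixed metadata header and a
JSON run manifest; reruns with the same seed are byte-identical.

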