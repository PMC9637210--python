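# fretfish

Tools for **FRET-FISH**: measuring local chromatin compaction at chosen
genomic loci by combining DNA-FISH oligo probes with Förster resonance
energy transfer (FRET) read-outs.

A FRET-FISH probe tiles a target locus with 60-nt primary oligos whose
detection oligos carry alternating donor (D) and acceptor (A)
fluorophores (e.g. Cy3/Cy5, Förster radius R₀ = 52 Å). When the
underlying chromatin fibre is compact, many D–A dye pairs sit within
R₀ and sensitized acceptor emission appears under donor excitation.
The per-locus compaction read-out is the **FRET-FISH score**

    Score = 100 · I_FRET / (I_FRET + I_D)    [%]

where I_FRET is the intensity in the FRET channel (donor excitation,
acceptor emission) at the acceptor dot and I_D the donor-channel
intensity at the donor dot. Higher scores mean more compact chromatin.
An orthogonal lifetime read-out uses donor quenching: FLIM decays are
fitted with multi-exponential models and the efficiency is
E = 1 − τ_DA/τ_D with the unquenched donor lifetime τ_D held fixed.

The package is aimed at microscopy groups running oligo-FISH compaction
assays and at anyone who wants a fully testable, simulation-backed
re-implementation of the computational pipeline:

| module                 | what it does |
|------------------------|--------------|
| `fretfish.probe_design`| sliding-window oligo enumeration, GC / homopolymer filters, homology penalties, best-window selection under dye group/spacing layouts (G1-S50 … G4-S300), assembly of designs 1–3 with adapters and AATTA/TAATT stabilization tails |
| `fretfish.imaging`     | nucleus segmentation (2D max-projection Otsu + watershed, or 3D), 3D dot detection, bead-based channel-shift correction, donor–acceptor pairing (7 px / 1.9 µm radius), lamina distances, quartile layers, Hoechst cell-cycle gating |
| `fretfish.scoring`     | FRET scores, D-only/A-only crosstalk baselines, KDE mode splitting of bimodal score distributions, rank-test comparisons, ATAC-seq window-count concordance |
| `fretfish.flim`        | Poisson-MLE multi-exponential tail fits, intensity/amplitude-weighted average lifetimes, IRF-convolved two-component donor model, FRET efficiency |
| `fretfish.simdata`     | synthetic genomes, 3D multi-channel stacks with a Förster-law forward model (crosstalk, bleed-through, Poisson noise), photon decays, coverage tracks — all with ground truth |

## Worked example

Design a probe for a 20 kb region and fit a simulated donor decay:

```sh
$ fretfish simulate --preset probe --seed 1 --out-dir demo
$ fretfish design --region-fasta demo/region.fa --design 3 --out-prefix demo/probe
designed 259 oligos, span 16895 nt, min gap 5 nt, total penalty 0.0
  fasta: demo/probe.fa
  bed: demo/probe.bed
  tsv: demo/probe.tsv

$ fretfish simulate --preset flim --seed 1 --out-dir demo
$ fretfish flim --decay demo/decay.csv --out demo/fit.json
tau [2.9806] ns (avg int 2.981, amp 2.981)
```

The design line says the probe holds 259 oligos (alternating donor and
acceptor roles) spanning 16 895 nt of the target, with at least 5 nt
between consecutive target sequences and zero accumulated homology
penalty. The decay was simulated at the 1000-photon budget with a
3.057 ns generating lifetime; the single-signal tail fit returns
2.98 ns, within the shot-noise scatter expected at that photon count.

The imaging side runs the same way from Python:

```python
from fretfish import imaging, scoring, simdata

cfg = simdata.SimImagingConfig(n_nuclei=50, w_compact=0.5, seed=0)
stacks, truth, _ = simdata.gen_image_dataset(cfg)
nuclei = imaging.segment_nuclei(stacks[0])
donors = imaging.detect_dots(stacks[0], "donor", nuclei)
acceptors = imaging.detect_dots(stacks[0], "acceptor", nuclei)
pairs, _ = imaging.pair_dots(donors, acceptors, max_separation_px=7.0)
for p in pairs:
    imaging.measure_fret_intensity(p, stacks[0]["fret"], stacks[0]["donor"])
scores = [scoring.fret_score(p.i_fret, p.i_donor) for p in pairs]
split = scoring.split_modes(scores) if len(scores) >= 30 else None
```

With a half-compact mixture the score distribution is bimodal (modes
near 18% and 63% under the default crosstalk/bleed-through of 5%) and
`split_modes` recovers the compact fraction from the high-mode weight.

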