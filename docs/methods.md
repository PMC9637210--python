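# Methods

This note documents the models, estimators and defaults behind
`fretfish`, and what the synthetic-data generators do and do not
emulate.

## Probe design

Candidates are every length-`l` window (default 60 nt) of the target
sequence in 1-nt steps. A candidate is *bad* when it contains N, its
longest homopolymer run exceeds 6 (runs of exactly 6 are allowed), or
its GC fraction falls outside the inclusive band [0.35, 0.80] — the
permissive reading of the 35–80% filter. Homology penalties are the sum
of external hit scores per oligo (BLASTn outfmt-6 `bitscore`), with the
oligo's trivial self-hit excluded by default. For self-contained tests
the package ships an exhaustive ungapped identity scan
(`homology_oracle`) that reports every genome offset matching at
≥ 80% identity; it is meant for kilobase-scale synthetic genomes, not
as a BLAST replacement. The production command line is

```
blastn -query Oligos_list.fa -db whole_genome.fa -out homologies.txt \
       -evalue 10 -word_size 11 -gapopen 15 -gapextend 10 -penalty -3
```

Good oligos whose left and right neighbours are both bad are removed
before window selection; an isolated good window inside a masked or
low-complexity block is most often a filtering artifact.

**Window selection.** The dye layout defines an ideal start grid:
`n_total` slots in alternating donor/acceptor groups of `group_size`,
with gaps `spacing_same_dye` within a group and `spacing_between_dyes`
between groups (presets G1-S50 … G4-S300; the default layout is the
dense design used on ~20 kb targets — 260 oligos, single-oligo groups,
5-nt gaps). Every window offset of the target is scored: each slot
snaps to the good candidate within ± l/2 nt minimizing its contribution
`penalty + λ·|deviation|` (λ = 1 penalty-unit per nt, configurable),
subject to a 5-nt minimum gap to the previous oligo; slots with no
usable candidate leave their group incomplete, allowed up to
`incomplete_group_tolerance` groups (default 10). The returned window
is lexicographically best: fewest missing slots, then smallest total
objective, ties to the smallest start coordinate. The tolerance default
is not cosmetic: a single 7-mer homopolymer poisons ~60 consecutive
candidate starts, so on random sequence a zero-tolerance grid is almost
never satisfiable at dense spacing.

**Assembly.** Design 1 is `L + T + R` with 20-nt orthogonal adapters
per dye role (L*/R* detection oligos are adapter reverse complements).
Design 2 adds the 5′ TAATT and 3′ AATTA stabilization strings to the
primary oligos; the two strings are mutual reverse complements, so the
3′ tail of one oligo anneals to the 5′ tail of the next, holding
neighbouring dyes in proximity. Design 3 keeps design-1 primaries and
puts the same tails on the detection oligos (5′ of L*, 3′ of R*). The
stabilization strings are the explicit 5-nt sequences; coordinates are
0-based half-open internally, 1-based inclusive in FASTA headers, BED
native. Probes are designed on the + strand of the provided sequence.

## Imaging

Stacks are (z, y, x) per channel with default voxel size
(0.3, 0.2714, 0.2714) µm — the lateral pitch at which the 7-px pairing
radius equals 1.9 µm. 2D segmentation thresholds the axial
max-projection with Otsu's criterion (replacing interactive threshold
tuning), splits touching nuclei by a distance-transform watershed and
drops objects below 50 µm². 3D mode thresholds the volume directly.

Dot detection band-passes each channel (difference of Gaussians,
σ = 1–3 px), finds 3D local maxima inside each nucleus, ranks by
filtered amplitude and keeps the top `expected_per_nucleus` (default 2,
one per homologue) whose amplitude exceeds 8 robust-noise units
(median ± MAD of the filtered image); centroids are intensity-weighted
over a 5-voxel window. The quality cutoff sits between the brightest
noise excursions observed in pure-background fields (≈ 7 units) and
the dimmest genuine dots at the default photon budgets (≳ 12 units).

Channel shift is estimated from bead fields: upsampled phase
cross-correlation initializes the translation, matched bead centroids
(assignment within 3 px) refine it as the mean displacement; at least
3 matched beads are required and the RMS residual is reported.

**Pairing** solves, per nucleus, the assignment that first maximizes
the number of donor–acceptor pairs within the 7-px radius and then
minimizes their total 3D distance (a large-constant cost in a linear
assignment makes the objective exactly lexicographic). A greedy
mutual-nearest-neighbour matcher was considered but rejected because it
is not guaranteed to reach the minimum-total-distance matching the test
oracle enumerates; on well-separated FISH dots the two coincide.

The intensity statistic read at a dot is the raw voxel value at the
(rounded) dot position minus the median of a surrounding box shell
(inner half-width 2, outer 4 voxels), clipped at zero. `i_fret` is read
in the FRET channel at the acceptor dot, `i_donor` in the donor channel
at the donor dot.

Normalized lamina distance is the anisotropy-aware Euclidean distance
transform of the 3D nucleus mask at the dot, divided by the nucleus'
maximum interior depth (0 at the edge, 1 at the deepest point).
Quartile layers follow the empirical distance distribution — layer 1
outermost — with boundary ties resolved by stable input order; this is
the dot-quantile definition, not equal-volume shells (an
`equal-volume` interpretation would need mask geometry, not just dot
distances, and is deliberately not the default).

Cell-cycle gating assumes a bimodal integrated DNA-stain (Hoechst)
distribution: a Gaussian KDE on log intensity locates the valley
between the two dominant modes (2N vs 4N); a 2-component Gaussian
mixture is the fallback when no interior valley exists, and clearly
unimodal inputs are flagged unknown rather than force-split. Within
G1, the top quartile is Hoechst-high; by default all remaining G1 cells
are Hoechst-low (a bottom-quartile definition is selectable). Mitotic
cells are only ever accepted from user-supplied annotations.

## Scoring

The score of a pair is 100·I_FRET/(I_FRET + I_D); pairs with zero total
intensity are dropped with a warning. No crosstalk correction is
subtracted from test scores — donor-only and acceptor-only control
hybridizations quantify the baseline instead (median/IQR, mutual
homogeneity by rank test). Under the simulator's emission model a
bleed-through fraction β with no FRET gives the closed-form baseline
score 100·β/(1+β), which the pipeline reproduces.

Bimodal score distributions are split at the density minimum between
the two dominant KDE maxima (Silverman bandwidth; a second-derivative
"inflection" mode is available behind a flag). Modes below 5% of the
peak density are ignored; with fewer than two prominent modes the
distribution is declared unimodal and no high fraction is reported.
Group comparisons use the two-sided Wilcoxon rank-sum test plus a
Hodges–Lehmann median shift. ATAC-seq concordance counts reads whose
5′ start falls inside the probe's first-to-last-oligo window (so
overlapping windows never double-count a read) and reports Spearman
and Pearson coefficients of per-locus mean score vs window count; the
expected sign is negative (accessible chromatin is less compact).
Per-locus summaries pool scores per dot across replicates.

## FLIM

Tail fits model the bins after the histogram peak (plus one IRF width)
as a sum of exponentials with constant background and maximize the
Poisson likelihood (photon counts are Poisson; a least-squares
objective is available for comparison) with 5 seeded Nelder–Mead
restarts in log-parameters. Component intensities are
I[k] = A[k]·τ[k]/Δt; the intensity-weighted average lifetime
Στ I/ΣI is the mean photon arrival time and the amplitude-weighted
average Στ A/ΣA the mean decay time; the former never falls below the
latter. The FRET donor model convolves a shiftable, background-padded
IRF with a fixed-τ_D + free-τ_DA two-component decay on the histogram
grid; τ_DA is constrained to [2Δt, τ_D] (negative efficiency is
unphysical), and efficiency is reported as NA when the quenched
fraction vanishes. Repetition-period wrap-around is ignored — a fair
approximation for lifetimes ≤ 4 ns at 78 MHz excitation.

Two-component fits with lifetime ratio below ~1.5 at kilophoton budgets
are flagged as weakly identifiable; at 10⁵ photons a τ = (1, 4) ns
pair is recovered within 5%.

## Synthetic data

The imaging simulator is the minimal generative model that reproduces
the assay's observable structure, not photorealistic optics. Nuclei are
ellipsoids (default semi-axes 2×5×5 µm) on a grid, 16 per stack, with
DNA-stain density proportional to DNA content (2N/4N mixture, 30% 4N)
and an optional condensation factor emulating drug-induced compaction.
Each nucleus carries 2 dot pairs; the donor–acceptor separation r (Å)
follows a two-state mixture — compact 49 ± 3 Å, open 75 ± 3 Å — mapped
to efficiency by the Förster relation E = 1/(1+(r/R₀)⁶) with R₀ = 52 Å
(Cy3/Cy5; 60 Å fits the AF488/AF594 pair), so the states sit at
E ≈ 0.59 and E ≈ 0.11. Dye-orientation effects are folded into R₀.
Channel photon yields per dot: donor (1−E)·N_D, FRET
E·N_D + β·(1−E)·N_D + α·N_A, acceptor N_A, with crosstalk α (direct
acceptor excitation) and bleed-through β (donor emission in the FRET
band) both defaulting to 0.05 as single scalar fractions. Dots are
rendered as 3D Gaussian PSFs (σ = 1×1.3×1.3 px); Poisson noise plus
Gaussian read noise is applied per voxel. Both paired dots share one
spatial position: the Å-scale separation is far below voxel size, so it
affects photon physics only.

Decay histograms sample arrival times from the amplitude-weighted
exponential mixture, jitter them with a Gaussian IRF, and bin at
0.05 ns over a fixed 25 ns acquisition window (extended if a photon
arrives later); the fixed window matters, because truncating the
histogram at the last observed photon lets the fitted background
absorb tail photons and biases lifetimes low at kilophoton budgets.
ATAC-like tracks draw per-locus Poisson read counts whose expectation
decays exponentially with the locus' compaction parameter (coupling 2,
log-normal noise CV 20%), with uniform read starts in the window.

What passing simulation tests does **not** show: robustness to optical
aberrations, spectral unmixing errors, hybridization-efficiency
variation along the probe, segmentation of crowded/overlapping tissue
nuclei, or chromatin polymer behaviour between the two probed states.
The two-state separation mixture is the simplest generator of the
bimodal scores the assay reads out; real loci sample a continuum.

## Problem sizes and determinism

All generators and fits are deterministic given a seed; exports are
byte-identical for identical inputs. The test suite runs at desk scale:
20 kb design regions, 200-candidate windowing oracles, 32–200 nuclei
per imaging condition (a 5-point compaction sweep uses 200 nuclei per
point), 10-seed lifetime panels at the 1000-photon budget and 20
donor-model round-trips at 10⁵ photons, and 50-seed ATAC sign checks.
The acceptance script derives every stream from its `--seed` argument.

## Known limitations

- The homology oracle is ungapped; indel-containing cross-hybridization
  is only caught by external BLASTn.
- Window selection snaps slots greedily left-to-right within a window;
  a globally optimal slot assignment (dynamic programming over slot ×
  candidate) could differ when penalties are strongly anti-correlated
  with grid deviation.
- The KDE valley threshold is bandwidth-dependent for weakly separated
  modes; fractions within ±0.05 of truth should only be expected for
  mode separations well above the bandwidth.
- `fit_fret_donor` treats the IRF as known up to shift and additive
  background; a badly wrong IRF width biases τ_DA.
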