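"""Synthetic fixtures with ground truth for every pipeline stage.

Generates (a) random genomes with optionally planted duplications for
probe-design and homology tests, (b) multi-channel 3D image stacks in
which each nucleus carries diffraction-limited donor/acceptor dot pairs
whose FRET efficiency follows the Förster relation
E(r) = 1 / (1 + (r/R0)^6) on a two-state (compact/open) separation
mixture, with crosstalk, bleed-through and Poisson noise, (c) photon
decay histograms from exponential mixtures convolved with a Gaussian
IRF, and (d) ATAC-like coverage tracks inversely coupled to a per-locus
compaction parameter.  All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .flim import DecayHistogram
from .imaging import ImageStack
from .probe_design import GenomicInterval

__all__ = [
    "SimImagingConfig",
    "forster_efficiency",
    "gen_genome",
    "gen_image_dataset",
    "gen_decay",
    "gen_atac",
]


def forster_efficiency(r: np.ndarray | float, r0: float) -> np.ndarray | float:
    """Förster transfer efficiency E = 1/(1 + (r/R0)^6); r, R0 in Å."""
    return 1.0 / (1.0 + (np.asarray(r, dtype=float) / r0) ** 6)


# ---------------------------------------------------------------------------
# genomes


def gen_genome(
    length: int,
    gc_target: float = 0.5,
    planted_repeats: list[tuple[int, int, int]] | None = None,
    seed: int = 0,
) -> tuple[str, dict]:
    """Seeded i.i.d. genome at a target GC, with optional planted
    duplications.

    ``planted_repeats`` is a list of (src_start, repeat_length, dst_start)
    segment copies; truth records their coordinates.  Same seed, same
    bytes.
    """
    if length < 1000:
        raise ValueError("genome length must be >= 1 kb")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_target) / 2, gc_target / 2, gc_target / 2, (1 - gc_target) / 2])
    seq = rng.choice(np.array(list("ACGT")), size=length, p=p)
    repeats = []
    for src, rep_len, dst in planted_repeats or []:
        if rep_len > length or src + rep_len > length or dst + rep_len > length:
            raise ValueError("planted repeat exceeds genome bounds")
        seq[dst : dst + rep_len] = seq[src : src + rep_len]
        repeats.append({"src_start": src, "length": rep_len, "dst_start": dst})
    return "".join(seq), {"seed": seed, "gc_target": gc_target, "repeats": repeats}


# ---------------------------------------------------------------------------
# imaging


@dataclass
class SimImagingConfig:
    """Study conditions for the imaging simulator.

    The donor–acceptor separation r (Å) follows a two-state mixture:
    a compact state near ``r_compact`` and an open state near
    ``r_open``; with the Cy3/Cy5 Förster radius of 52 Å the defaults
    give E ≈ 0.59 (compact) and E ≈ 0.11 (open).  Crosstalk alpha is
    direct acceptor excitation at the donor line; bleed-through beta is
    donor emission leaking into the FRET detection band.
    """

    n_nuclei: int = 50
    nucleus_radii_um: tuple[float, float, float] = (2.0, 5.0, 5.0)  # (z, y, x) semi-axes
    voxel_size: tuple[float, float, float] = (0.3, 1.9 / 7, 1.9 / 7)
    dots_per_nucleus: int = 2
    w_compact: float = 0.5
    r_compact: float = 49.0  # Å
    r_open: float = 75.0  # Å
    r_sigma: float = 3.0  # Å jitter within a state
    r0: float = 52.0  # Å (Cy3/Cy5); 60 Å for AF488/AF594
    alpha: float = 0.05  # acceptor crosstalk
    beta: float = 0.05  # donor bleed-through
    donor_photons: float = 2000.0
    acceptor_photons: float = 2000.0
    dna_photons_per_voxel: float = 30.0
    condensation_factor: float = 1.0  # raises DNA-stain density (drug emulation)
    psf_sigma_px: tuple[float, float, float] = (1.0, 1.3, 1.3)
    read_noise: float = 2.0
    background: float = 10.0
    frac_4n: float = 0.3  # fraction of non-G1 (4N) nuclei
    nuclei_per_stack: int = 16
    stack_z: int = 20
    seed: int = 0


def _render_spot(img: np.ndarray, pos: np.ndarray, photons: float, sigma: np.ndarray) -> None:
    """Splat a 3D Gaussian of given photon mass onto img (in place)."""
    half = np.ceil(4 * sigma).astype(int)
    lo = np.maximum(np.round(pos).astype(int) - half, 0)
    hi = np.minimum(np.round(pos).astype(int) + half + 1, img.shape)
    if (lo >= hi).any():
        return
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    g = np.ones(grids[0].shape)
    for gr, p, s in zip(grids, pos, sigma):
        g = g * np.exp(-((gr - p) ** 2) / (2 * s**2))
    g /= g.sum()
    img[tuple(slice(l, h) for l, h in zip(lo, hi))] += photons * g


def gen_image_dataset(config: SimImagingConfig) -> tuple[list[ImageStack], pd.DataFrame, pd.DataFrame]:
    """Render multi-channel stacks with ground truth.

    Per dot pair with separation r and efficiency E = E(r; R0), expected
    photon yields are: donor channel (1−E)·N_D; FRET channel
    E·N_D + β·(1−E)·N_D + α·N_A; acceptor channel N_A — so donor plus
    transferred photons conserve N_D before noise.  Nuclei are ellipsoids
    whose DNA-stain density scales with DNA content (2N/4N) and the
    condensation factor.  Returns (stacks, truth_dots, truth_nuclei).
    """
    rng = np.random.default_rng(config.seed)
    dz, dy, dx = config.voxel_size
    rz = config.nucleus_radii_um[0] / dz
    ry = config.nucleus_radii_um[1] / dy
    rx = config.nucleus_radii_um[2] / dx

    grid = int(np.ceil(np.sqrt(config.nuclei_per_stack)))
    pitch_y = int(np.ceil(2.4 * ry))
    pitch_x = int(np.ceil(2.4 * rx))
    shape = (config.stack_z, grid * pitch_y, grid * pitch_x)

    stacks: list[ImageStack] = []
    dot_rows: list[dict] = []
    nuc_rows: list[dict] = []
    remaining = config.n_nuclei
    stack_idx = 0
    global_label = 0
    sigma = np.asarray(config.psf_sigma_px)

    while remaining > 0:
        n_here = min(remaining, config.nuclei_per_stack)
        chans = {c: np.zeros(shape) for c in ("dna", "donor", "acceptor", "fret")}
        for k in range(n_here):
            global_label += 1
            cy = (k // grid + 0.5) * pitch_y
            cx = (k % grid + 0.5) * pitch_x
            cz = shape[0] / 2
            zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
            ell = ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1
            is_4n = rng.random() < config.frac_4n
            content = 2.0 if is_4n else 1.0
            density = config.dna_photons_per_voxel * content * config.condensation_factor
            chans["dna"][ell] += density
            nuc_rows.append(
                dict(
                    stack=stack_idx,
                    nucleus_label=k + 1,
                    global_label=global_label,
                    center_z=cz,
                    center_y=cy,
                    center_x=cx,
                    dna_content="4N" if is_4n else "2N",
                    cycle_truth="nonG1" if is_4n else "G1",
                )
            )
            for _ in range(config.dots_per_nucleus):
                # place the dot well inside the nucleus
                while True:
                    off = rng.uniform(-0.6, 0.6, size=3)
                    pos = np.array([cz + off[0] * rz, cy + off[1] * ry, cx + off[2] * rx])
                    if ((off**2).sum()) <= 0.36:
                        break
                compact = rng.random() < config.w_compact
                r = rng.normal(config.r_compact if compact else config.r_open, config.r_sigma)
                r = max(r, 1.0)
                E = float(forster_efficiency(r, config.r0))
                n_d = config.donor_photons
                n_a = config.acceptor_photons
                donor_ph = (1 - E) * n_d
                fret_ph = E * n_d + config.beta * (1 - E) * n_d + config.alpha * n_a
                _render_spot(chans["donor"], pos, donor_ph, sigma)
                _render_spot(chans["acceptor"], pos, n_a, sigma)
                _render_spot(chans["fret"], pos, fret_ph, sigma)
                dot_rows.append(
                    dict(
                        stack=stack_idx,
                        nucleus_label=k + 1,
                        global_label=global_label,
                        z=pos[0],
                        y=pos[1],
                        x=pos[2],
                        r_angstrom=r,
                        true_E=E,
                        state="compact" if compact else "open",
                        donor_photons=donor_ph,
                        fret_photons=fret_ph,
                        acceptor_photons=n_a,
                    )
                )
        for c, img in chans.items():
            noisy = rng.poisson(img + config.background).astype(float)
            noisy += rng.normal(0, config.read_noise, size=img.shape)
            chans[c] = np.clip(noisy, 0, None)
        stacks.append(ImageStack(channels=chans, voxel_size=config.voxel_size))
        remaining -= n_here
        stack_idx += 1

    return stacks, pd.DataFrame(dot_rows), pd.DataFrame(nuc_rows)


# ---------------------------------------------------------------------------
# decays


def gen_decay(
    taus: list[float] | float,
    amplitudes: list[float] | float = 1.0,
    photons: int = 1000,
    irf_sigma: float = 0.0,
    t0: float = 0.0,
    bin_width: float = 0.05,
    window_ns: float = 25.0,
    seed: int = 0,
) -> DecayHistogram:
    """Sample a photon decay histogram from an exponential mixture.

    Arrival times are exponential with component lifetimes ``taus`` (ns),
    mixed in proportion amplitude×tau (each component's photon yield),
    jittered by a Gaussian IRF of width ``irf_sigma`` and offset ``t0``.
    Bins are uniform ``bin_width`` ns from 0 over a fixed acquisition
    window of ``window_ns`` (as in a TCSPC detection window; extended if
    a photon arrives later) and cover every sample — negative jittered
    arrivals clip into the first bin — so counts sum to ``photons``
    exactly.
    """
    taus = np.atleast_1d(np.asarray(taus, dtype=float))
    amps = np.broadcast_to(np.atleast_1d(np.asarray(amplitudes, dtype=float)), taus.shape)
    if (taus <= 0).any():
        raise ValueError("lifetimes must be positive")
    if photons < 100:
        raise ValueError("need at least 100 photons")
    rng = np.random.default_rng(seed)
    weights = amps * taus
    weights = weights / weights.sum()
    comp = rng.choice(len(taus), size=photons, p=weights)
    arrival = rng.exponential(taus[comp]) + t0
    if irf_sigma > 0:
        arrival = arrival + rng.normal(0, irf_sigma, size=photons)
    arrival = np.clip(arrival, 0, None)
    n_bins = int(np.ceil(max(window_ns, arrival.max() + bin_width) / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(arrival, bins=edges)
    centers = edges[:-1] + bin_width / 2
    irf = None
    if irf_sigma > 0:
        irf = np.exp(-((centers - t0) ** 2) / (2 * irf_sigma**2))
        irf = irf / irf.sum()
    return DecayHistogram(bin_centers=centers, counts=counts, irf=irf)


# ---------------------------------------------------------------------------
# coverage


def gen_atac(
    loci: pd.DataFrame,
    coupling: float = 2.0,
    baseline_reads: int = 1000,
    noise_cv: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ATAC-like read starts inversely coupled to compaction.

    ``loci`` needs columns (locus, chrom, start, end, compaction) with
    compaction in [0, 1].  Expected reads per locus decay exponentially
    with compaction (rate ``coupling``), with multiplicative log-normal
    noise of the given CV; read 5' starts are uniform in the window.
    Returns (read_starts with columns chrom/pos, truth per locus).
    """
    required = {"locus", "chrom", "start", "end", "compaction"}
    if not required <= set(loci.columns):
        raise ValueError(f"loci table needs columns {sorted(required)}")
    if len(loci) < 3:
        raise ValueError("need at least 3 loci")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log(1 + noise_cv**2))
    rows = []
    truth = []
    for r in loci.itertuples(index=False):
        mean = baseline_reads * np.exp(-coupling * r.compaction)
        if noise_cv > 0:
            mean = mean * rng.lognormal(-(sigma**2) / 2, sigma)
        n = int(rng.poisson(mean))
        starts = rng.integers(r.start, r.end, size=n)
        rows.append(pd.DataFrame({"chrom": r.chrom, "pos": np.sort(starts)}))
        truth.append(dict(locus=r.locus, compaction=r.compaction, expected_reads=mean, n_reads=n))
    return pd.concat(rows, ignore_index=True), pd.DataFrame(truth)


def write_bedgraph(read_starts: pd.DataFrame, path: str | Path) -> Path:
    """Write per-base read-start counts as a bedGraph track."""
    path = Path(path)
    with open(path, "w") as fh:
        for chrom, g in read_starts.groupby("chrom"):
            pos, counts = np.unique(g["pos"].to_numpy(), return_counts=True)
            for p, c in zip(pos, counts):
                fh.write(f"{chrom}\t{p}\t{p + 1}\t{c}\n")
    return path


def config_to_json(config, path: str | Path) -> Path:
    """Serialize a generator config next to its outputs."""
    import json

    path = Path(path)
    path.write_text(json.dumps(asdict(config), indent=2, default=list))
    return path
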