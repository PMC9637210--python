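"""From multi-channel 3D stacks to per-nucleus dot tables.

Covers nucleus segmentation (2D max-projection threshold + watershed, or
3D), diffraction-limited dot detection, bead-based channel-shift
estimation, donor–acceptor dot pairing, FRET-channel intensity read-out,
normalized lamina distances, radial layer assignment, DNA-content
cell-cycle gating, and 3D inter-locus distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.spatial.distance import cdist
from skimage import feature, filters, measure, morphology, segmentation
from skimage.registration import phase_cross_correlation

__all__ = [
    "ImageStack",
    "NucleusRecord",
    "Dot",
    "DotPair",
    "ChannelShift",
    "segment_nuclei",
    "detect_dots",
    "estimate_channel_shift",
    "pair_dots",
    "measure_fret_intensity",
    "normalized_lamina_distance",
    "assign_layers",
    "classify_cell_cycle",
    "distance_3d",
    "nuclear_intensity",
    "dots_to_frame",
    "pairs_to_frame",
]


@dataclass
class ImageStack:
    """Multi-channel 3D stack; all channels share shape and voxel size.

    ``channels`` maps labels like ``dna``/``donor``/``acceptor``/``fret``
    to (z, y, x) arrays.  Default voxel size mirrors a typical widefield
    FISH acquisition: 0.3 µm focal-plane spacing, ~0.27 µm lateral pitch
    (at which a 7-px radius equals 1.9 µm).
    """

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float] = (0.3, 1.9 / 7, 1.9 / 7)
    deconvolved: bool = False

    def __post_init__(self) -> None:
        shapes = {ch: a.shape for ch, a in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")

    def __getitem__(self, channel: str) -> np.ndarray:
        if channel not in self.channels:
            raise KeyError(f"channel {channel!r} absent (have {sorted(self.channels)})")
        return self.channels[channel]

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape


@dataclass
class NucleusRecord:
    label: int
    mask: np.ndarray  # boolean, 2D or 3D
    area_2d: float = 0.0
    volume: int = 0
    hoechst_total: float = 0.0
    cycle_class: str = "unknown"  # G1 | nonG1 | M | unknown
    hoechst_subclass: str = "NA"  # high | low | NA
    bbox: tuple | None = None


@dataclass
class Dot:
    position: tuple[float, float, float]  # (z, y, x) px, sub-voxel
    channel: str
    intensity: float
    nucleus_label: int
    quality: float = 0.0


@dataclass
class DotPair:
    donor: Dot
    acceptor: Dot
    separation_px: float
    i_fret: float = np.nan
    i_donor: float = np.nan


@dataclass
class ChannelShift:
    translation: tuple[float, float, float]  # (dz, dy, dx) px
    residual: float
    n_beads: int = 0


# ---------------------------------------------------------------------------
# segmentation


def segment_nuclei(
    stack: ImageStack,
    mode: Literal["2d", "3d"] = "2d",
    min_area_um2: float = 50.0,
    dna_channel: str = "dna",
) -> list[NucleusRecord]:
    """Segment nuclei from the DNA-stain channel.

    2d mode thresholds the axial max-intensity projection with an
    inter-class-variance (Otsu) threshold, separates touching nuclei by a
    distance-transform watershed, and discards objects below
    ``min_area_um2``.  3d mode thresholds the full volume and labels in
    3D.  Blank images yield an empty list.
    """
    dna = stack[dna_channel].astype(float)
    dz, dy, dx = stack.voxel_size

    if mode == "2d":
        proj = dna.max(axis=0)
        if proj.max() <= 0 or np.allclose(proj, proj.flat[0]):
            return []
        thr = filters.threshold_otsu(proj)
        fg = proj > thr
        fg = morphology.remove_small_objects(fg, max_size=max(0, int(min_area_um2 / (dy * dx)) - 1))
        if not fg.any():
            return []
        dist = ndimage.distance_transform_edt(fg)
        # watershed seeded at smoothed distance maxima splits touching nuclei
        smooth = ndimage.gaussian_filter(dist, sigma=3)
        peaks = feature.peak_local_max(smooth, min_distance=7, labels=fg, exclude_border=False)
        markers = np.zeros_like(fg, dtype=int)
        for i, (y, x) in enumerate(peaks, start=1):
            markers[y, x] = i
        if markers.max() == 0:
            labels = measure.label(fg)
        else:
            labels = segmentation.watershed(-smooth, markers, mask=fg)
    else:
        if dna.max() <= 0 or np.allclose(dna, dna.flat[0]):
            return []
        thr = filters.threshold_otsu(dna)
        fg = dna > thr
        fg = morphology.remove_small_objects(fg, max_size=max(0, int(min_area_um2 / (dy * dx)) - 1))
        labels = measure.label(fg)

    records = []
    dense = 0
    for region in measure.regionprops(labels):
        if mode == "2d" and region.area * dy * dx < min_area_um2:
            continue
        dense += 1
        mask = labels == region.label
        if mode == "2d":
            hoechst = float(dna.sum(axis=0)[mask].sum())
            area = region.area * dy * dx
            volume = 0
        else:
            hoechst = float(dna[mask].sum())
            area = mask.any(axis=0).sum() * dy * dx
            volume = int(region.area)
        records.append(
            NucleusRecord(
                label=dense,
                mask=mask,
                area_2d=area,
                volume=volume,
                hoechst_total=hoechst,
                bbox=region.bbox,
            )
        )
    return records


# ---------------------------------------------------------------------------
# dot detection


def _subvoxel_centroid(img: np.ndarray, peak: tuple[int, ...], radius: int = 2) -> np.ndarray:
    """Intensity-weighted centroid in a small window around a peak."""
    slices = tuple(
        slice(max(0, p - radius), min(s, p + radius + 1)) for p, s in zip(peak, img.shape)
    )
    window = np.clip(img[slices], 0, None)
    if window.sum() <= 0:
        return np.asarray(peak, dtype=float)
    grids = np.meshgrid(*[np.arange(s.start, s.stop) for s in slices], indexing="ij")
    return np.array([(g * window).sum() / window.sum() for g in grids])


def detect_dots(
    stack: ImageStack,
    channel: str,
    nuclei: Sequence[NucleusRecord],
    expected_per_nucleus: int = 2,
    low_sigma: float = 1.0,
    high_sigma: float = 3.0,
    quality_threshold: float = 8.0,
) -> list[Dot]:
    """Detect the most intense diffraction-limited dots per nucleus.

    Band-pass (difference-of-Gaussians) filter, 3D local maxima inside
    each nucleus mask, ranked by filtered intensity; the top
    ``expected_per_nucleus`` peaks exceeding ``quality_threshold`` (in
    robust-noise units of the filtered image) are kept, with intensity-
    weighted sub-voxel centroids.
    """
    img = stack[channel].astype(float)
    band = filters.difference_of_gaussians(img, low_sigma, high_sigma)
    noise = 1.4826 * np.median(np.abs(band - np.median(band)))
    noise = max(noise, 1e-12)

    dots: list[Dot] = []
    for nuc in nuclei:
        mask3d = np.broadcast_to(nuc.mask, img.shape) if nuc.mask.ndim == 2 else nuc.mask
        coords = feature.peak_local_max(
            band, min_distance=2, labels=mask3d.astype(int), exclude_border=False
        )
        if coords.size == 0:
            continue
        values = band[tuple(coords.T)]
        order = np.argsort(values)[::-1]
        kept = 0
        for idx in order:
            if kept >= expected_per_nucleus:
                break
            q = values[idx] / noise
            if q < quality_threshold:
                break
            peak = tuple(int(v) for v in coords[idx])
            pos = _subvoxel_centroid(band, peak)
            dots.append(
                Dot(
                    position=tuple(pos),
                    channel=channel,
                    intensity=float(img[peak]),
                    nucleus_label=nuc.label,
                    quality=float(q),
                )
            )
            kept += 1
    return dots


# ---------------------------------------------------------------------------
# channel shift


def estimate_channel_shift(
    bead_stack_a: np.ndarray,
    bead_stack_b: np.ndarray,
    min_beads: int = 3,
) -> ChannelShift:
    """Rigid translation between two bead channels.

    Phase cross-correlation gives an initial sub-pixel shift; bead
    centroids matched under that shift then refine the translation as the
    mean displacement, with the RMS residual reported.
    """
    a = np.asarray(bead_stack_a, dtype=float)
    b = np.asarray(bead_stack_b, dtype=float)
    shift0, _, _ = phase_cross_correlation(a, b, upsample_factor=20)

    def _beads(img: np.ndarray) -> np.ndarray:
        band = filters.difference_of_gaussians(img, 1.0, 3.0)
        thr = band.mean() + 4 * band.std()
        coords = feature.peak_local_max(band, min_distance=3, threshold_abs=thr)
        return np.array([_subvoxel_centroid(band, tuple(c)) for c in coords]) if len(coords) else np.empty((0, img.ndim))

    pa, pb = _beads(a), _beads(b)
    if len(pa) < min_beads or len(pb) < min_beads:
        raise ValueError(f"fewer than {min_beads} beads detectable in both channels")
    # match b beads (shift-corrected) to nearest a bead
    d = cdist(pa, pb + shift0)
    rows, cols = optimize.linear_sum_assignment(d)
    good = d[rows, cols] < 3.0
    if good.sum() < min_beads:
        raise ValueError(f"fewer than {min_beads} matched beads (got {int(good.sum())})")
    disp = pa[rows[good]] - pb[cols[good]]
    translation = disp.mean(axis=0)
    residual = float(np.sqrt(((disp - translation) ** 2).sum(axis=1).mean()))
    return ChannelShift(translation=tuple(translation), residual=residual, n_beads=int(good.sum()))


def apply_shift(dots: Sequence[Dot], shift: ChannelShift) -> list[Dot]:
    """Return dots translated into the reference channel's frame."""
    t = np.asarray(shift.translation)
    return [
        Dot(tuple(np.asarray(d.position) + t), d.channel, d.intensity, d.nucleus_label, d.quality)
        for d in dots
    ]


# ---------------------------------------------------------------------------
# pairing


def pair_dots(
    donor_dots: Sequence[Dot],
    acceptor_dots: Sequence[Dot],
    max_separation_px: float = 7.0,
) -> tuple[list[DotPair], list[Dot]]:
    """Match donor and acceptor dots within each nucleus.

    Solves, per nucleus, the assignment that first maximizes the number
    of pairs within ``max_separation_px`` (3D Euclidean, in px) and then
    minimizes their total distance; each dot joins at most one pair.
    Returns (pairs, unmatched_dots).
    """
    pairs: list[DotPair] = []
    unmatched: list[Dot] = []
    labels = sorted({d.nucleus_label for d in donor_dots} | {d.nucleus_label for d in acceptor_dots})
    for lab in labels:
        dd = [d for d in donor_dots if d.nucleus_label == lab]
        aa = [d for d in acceptor_dots if d.nucleus_label == lab]
        if not dd or not aa:
            unmatched.extend(dd + aa)
            continue
        dist = cdist([d.position for d in dd], [a.position for a in aa])
        # large-constant cost makes the assignment lexicographic:
        # max feasible pairs first, then min total distance
        big = max_separation_px * (len(dd) + len(aa) + 1)
        cost = np.where(dist <= max_separation_px, dist, big)
        rows, cols = optimize.linear_sum_assignment(cost)
        used_d, used_a = set(), set()
        for r, c in zip(rows, cols):
            if dist[r, c] <= max_separation_px:
                pairs.append(DotPair(donor=dd[r], acceptor=aa[c], separation_px=float(dist[r, c])))
                used_d.add(r)
                used_a.add(c)
        unmatched.extend(d for i, d in enumerate(dd) if i not in used_d)
        unmatched.extend(a for i, a in enumerate(aa) if i not in used_a)
    return pairs, unmatched


# ---------------------------------------------------------------------------
# intensity read-outs


def _local_intensity(img: np.ndarray, position: Sequence[float], inner: int = 2, outer: int = 4) -> float:
    """Background-subtracted peak value at a dot: voxel value minus the
    median of a surrounding shell (box annulus inner<r<=outer), clipped
    at zero."""
    pos = tuple(int(round(p)) for p in position)
    if any(p < 0 or p >= s for p, s in zip(pos, img.shape)):
        raise ValueError(f"dot position {pos} outside stack bounds {img.shape}")
    out_sl = tuple(slice(max(0, p - outer), min(s, p + outer + 1)) for p, s in zip(pos, img.shape))
    box = img[out_sl].copy()
    # carve out the inner box to leave the shell
    in_sl = tuple(
        slice(max(0, p - inner) - o.start, min(s, p + inner + 1) - o.start)
        for p, s, o in zip(pos, img.shape, out_sl)
    )
    mask = np.ones(box.shape, dtype=bool)
    mask[in_sl] = False
    background = float(np.median(box[mask])) if mask.any() else 0.0
    return max(0.0, float(img[pos]) - background)


def measure_fret_intensity(pair: DotPair, fret_img: np.ndarray, donor_img: np.ndarray) -> DotPair:
    """Read the sensitized-emission signal of a pair.

    ``i_fret`` is the background-subtracted intensity in the FRET channel
    (donor excitation, acceptor emission) at the acceptor dot position;
    ``i_donor`` likewise in the donor channel at the donor dot.
    """
    pair.i_fret = _local_intensity(fret_img, pair.acceptor.position)
    pair.i_donor = _local_intensity(donor_img, pair.donor.position)
    return pair


# ---------------------------------------------------------------------------
# radial geometry


def normalized_lamina_distance(
    position: Sequence[float],
    nucleus_mask_3d: np.ndarray,
    voxel_size: tuple[float, float, float] = (0.3, 1.9 / 7, 1.9 / 7),
) -> float:
    """Normalized 3D distance of a dot to the nuclear edge: 0 at the
    boundary, 1 at the deepest interior point of that nucleus.  Distances
    honour anisotropic voxel size (µm)."""
    pos = tuple(int(round(p)) for p in position)
    if not nucleus_mask_3d[pos]:
        raise ValueError(f"dot at {pos} lies outside the nucleus mask")
    edt = ndimage.distance_transform_edt(nucleus_mask_3d, sampling=voxel_size)
    return float(edt[pos] / edt.max())


def assign_layers(distances: Sequence[float]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assign dots to four concentric nuclear layers by quartiles of
    their normalized lamina distances.

    Layer 1 is the outermost (smallest distances), layer 4 the innermost.
    Returns (labels in 1..4, per-layer fractions, quartile cut-points).
    Ties at quartile boundaries are resolved by stable input order; a
    fully degenerate (all-equal) input collapses to layer 1 with a
    warning.
    """
    d = np.asarray(distances, dtype=float)
    if len(d) < 4:
        raise ValueError("need at least 4 distances for quartile layers")
    if not np.isfinite(d).all():
        raise ValueError("distances must be finite")
    cuts = np.quantile(d, [0.25, 0.5, 0.75])
    if np.ptp(d) == 0:
        warnings.warn("all lamina distances identical; assigning every dot to layer 1")
        labels = np.ones(len(d), dtype=int)
        frac = np.array([1.0, 0.0, 0.0, 0.0])
        return labels, frac, cuts
    order = np.argsort(d, kind="stable")
    labels = np.empty(len(d), dtype=int)
    labels[order] = 1 + (4 * np.arange(len(d))) // len(d)
    frac = np.bincount(labels, minlength=5)[1:] / len(d)
    return labels, frac, cuts


# ---------------------------------------------------------------------------
# cell-cycle gating


def classify_cell_cycle(
    nuclei: Sequence[NucleusRecord],
    hoechst_low_definition: Literal["remaining", "bottom_quartile"] = "remaining",
) -> list[NucleusRecord]:
    """Gate nuclei into G1 vs non-G1 from integrated DNA-stain intensity.

    The nuclear Hoechst total is bimodal in a cycling population (2N G1
    peak, 4N G2/M peak).  A kernel-density estimate on log intensity
    locates the valley between the two dominant modes; if no valley is
    found, a 2-component Gaussian mixture supplies the threshold; if the
    distribution is effectively unimodal, every nucleus is flagged
    unknown.  Within G1, the top quartile becomes Hoechst-high; the rest
    are Hoechst-low ("remaining" definition) or only the bottom quartile
    is low ("bottom_quartile").
    """
    if len(nuclei) < 2:
        raise ValueError("need at least 2 nuclei to gate the cell cycle")
    totals = np.array([n.hoechst_total for n in nuclei], dtype=float)
    if np.ptp(totals) == 0 or (totals <= 0).any():
        warnings.warn("degenerate DNA-content distribution; cell cycle unknown")
        for n in nuclei:
            n.cycle_class = "unknown"
            n.hoechst_subclass = "NA"
        return list(nuclei)

    logt = np.log(totals)
    threshold = _bimodal_threshold(logt)
    if threshold is None:
        warnings.warn("DNA-content distribution not bimodal; cell cycle unknown")
        for n in nuclei:
            n.cycle_class = "unknown"
            n.hoechst_subclass = "NA"
        return list(nuclei)

    g1_totals = totals[logt < threshold]
    q75 = np.quantile(g1_totals, 0.75) if len(g1_totals) else np.inf
    q25 = np.quantile(g1_totals, 0.25) if len(g1_totals) else -np.inf
    for n, lt in zip(nuclei, logt):
        if lt >= threshold:
            n.cycle_class = "nonG1"
            n.hoechst_subclass = "NA"
        else:
            n.cycle_class = "G1"
            if n.hoechst_total > q75:
                n.hoechst_subclass = "high"
            elif hoechst_low_definition == "bottom_quartile":
                n.hoechst_subclass = "low" if n.hoechst_total <= q25 else "NA"
            else:
                n.hoechst_subclass = "low"
    return list(nuclei)


def _bimodal_threshold(values: np.ndarray) -> float | None:
    """Valley between the two dominant KDE modes; GMM fallback."""
    from scipy.stats import gaussian_kde

    kde = gaussian_kde(values)
    grid = np.linspace(values.min(), values.max(), 512)
    dens = kde(grid)
    maxima = [
        i for i in range(1, len(grid) - 1) if dens[i] >= dens[i - 1] and dens[i] > dens[i + 1]
    ]
    if len(maxima) >= 2:
        top2 = sorted(sorted(maxima, key=lambda i: dens[i], reverse=True)[:2])
        lo, hi = top2
        valley = lo + int(np.argmin(dens[lo : hi + 1]))
        return float(grid[valley])
    # GMM fallback: threshold where the two component posteriors cross
    from sklearn.mixture import GaussianMixture

    gmm = GaussianMixture(n_components=2, random_state=0, n_init=3).fit(values.reshape(-1, 1))
    means = np.sort(gmm.means_.ravel())
    if (means[1] - means[0]) < 1.5 * np.sqrt(gmm.covariances_.ravel()).mean():
        return None  # components overlap too much: effectively unimodal
    grid = np.linspace(means[0], means[1], 256)
    post = gmm.predict_proba(grid.reshape(-1, 1))
    hi_comp = int(np.argmax(gmm.means_.ravel()))
    cross = int(np.argmin(np.abs(post[:, hi_comp] - 0.5)))
    return float(grid[cross])


# ---------------------------------------------------------------------------
# misc


def distance_3d(p1: Sequence[float], p2: Sequence[float]) -> float:
    """3D Euclidean distance between two points (same physical frame)."""
    a, b = np.asarray(p1, float), np.asarray(p2, float)
    return float(np.sqrt(((a - b) ** 2).sum()))


def nuclear_intensity(
    stack: ImageStack,
    channel: str,
    nuclei: Sequence[NucleusRecord],
    statistic: Literal["total", "mean"] = "mean",
    background: float = 0.0,
) -> pd.Series:
    """Per-nucleus intensity statistic over the mask voxels (2D masks
    integrate the axial sum projection)."""
    img = stack[channel].astype(float) - background
    values = {}
    for nuc in nuclei:
        if not nuc.mask.any():
            raise ValueError(f"nucleus {nuc.label} has an empty mask")
        plane = img.sum(axis=0) if nuc.mask.ndim == 2 else img
        vals = plane[nuc.mask]
        values[nuc.label] = float(vals.sum() if statistic == "total" else vals.mean())
    return pd.Series(values, name=f"{channel}_{statistic}")


def dots_to_frame(dots: Sequence[Dot]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                nucleus_label=d.nucleus_label,
                channel=d.channel,
                z=d.position[0],
                y=d.position[1],
                x=d.position[2],
                intensity=d.intensity,
                quality=d.quality,
            )
            for d in dots
        ]
    )


def pairs_to_frame(pairs: Sequence[DotPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                nucleus_label=p.donor.nucleus_label,
                donor_z=p.donor.position[0],
                donor_y=p.donor.position[1],
                donor_x=p.donor.position[2],
                acceptor_z=p.acceptor.position[0],
                acceptor_y=p.acceptor.position[1],
                acceptor_x=p.acceptor.position[2],
                separation_px=p.separation_px,
                i_fret=p.i_fret,
                i_donor=p.i_donor,
            )
            for p in pairs
        ]
    )
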