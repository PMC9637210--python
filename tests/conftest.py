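import numpy as np
import pytest

from fretfish import imaging, simdata


@pytest.fixture(scope="session")
def small_imaging_dataset():
    """One rendered 32-nucleus dataset shared by imaging-level tests."""
    cfg = simdata.SimImagingConfig(n_nuclei=32, seed=3)
    stacks, truth_dots, truth_nuclei = simdata.gen_image_dataset(cfg)
    return cfg, stacks, truth_dots, truth_nuclei


def run_fret_pipeline(stacks, pair_radius_px: float = 7.0, expected_dots: int = 2):
    """Segment, detect, pair and measure every stack; returns pairs with
    i_fret / i_donor populated, tagged with their stack index."""
    all_pairs = []
    for si, st in enumerate(stacks):
        nuclei = imaging.segment_nuclei(st)
        dd = imaging.detect_dots(st, "donor", nuclei, expected_per_nucleus=expected_dots)
        aa = imaging.detect_dots(st, "acceptor", nuclei, expected_per_nucleus=expected_dots)
        pairs, _ = imaging.pair_dots(dd, aa, max_separation_px=pair_radius_px)
        for p in pairs:
            imaging.measure_fret_intensity(p, st["fret"], st["donor"])
        all_pairs.append((si, nuclei, pairs))
    return all_pairs


def brute_force_pairing(donors, acceptors, max_sep):
    """Exhaustive pairing oracle: maximize pair count within max_sep,
    then minimize total 3D distance, over all injective matchings."""
    import itertools

    from fretfish.imaging import distance_3d

    best = None
    nd, na = len(donors), len(acceptors)
    k = min(nd, na)
    for d_idx in itertools.permutations(range(nd), k):
        for a_idx in itertools.combinations(range(na), k):
            pairs = []
            total = 0.0
            for di, ai in zip(d_idx, a_idx):
                dist = distance_3d(donors[di].position, acceptors[ai].position)
                if dist <= max_sep:
                    pairs.append((di, ai))
                    total += dist
            key = (-len(pairs), total)
            if best is None or key < best[0]:
                best = (key, set(pairs))
    return best[1] if best else set()


def make_bead_stack(positions, shape=(20, 64, 64), photons=5000.0, rng=None):
    """Render Gaussian beads at the given (z, y, x) positions."""
    img = np.zeros(shape)
    for pos in positions:
        simdata._render_spot(img, np.asarray(pos, float), photons, np.array([1.0, 1.3, 1.3]))
    if rng is not None:
        img = rng.poisson(img + 5.0).astype(float)
    return img
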