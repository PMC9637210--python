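"""FRET-FISH scores and compaction-state statistics.

The score of a donor–acceptor dot pair is the sensitized-emission
fraction, Score = 100 · I_FRET / (I_FRET + I_D), where I_FRET is the
acceptor-channel intensity under donor excitation and I_D the
donor-channel intensity.  Higher scores mean more compact chromatin.
This module also provides the donor-only / acceptor-only crosstalk
baselines, kernel-density splitting of bimodal score distributions,
rank-test group comparisons, and the concordance of mean scores with
ATAC-seq accessibility over the probe windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .probe_design import GenomicInterval

__all__ = [
    "ModeSplit",
    "AtacComparison",
    "fret_score",
    "score_pairs",
    "crosstalk_baseline",
    "split_modes",
    "compare_conditions",
    "atac_window_counts",
    "correlate_score_vs_atac",
]


@dataclass
class ModeSplit:
    threshold: float
    frac_low: float
    frac_high: float
    bandwidth: float
    is_bimodal: bool
    mode_locations: tuple[float, ...] = ()


@dataclass
class AtacComparison:
    table: pd.DataFrame  # columns: locus, chrom, start, end, atac_count, mean_score
    scc: float = np.nan
    pcc: float = np.nan
    scc_p: float = np.nan
    pcc_p: float = np.nan

    @property
    def inverse(self) -> bool:
        """True when accessibility falls as the FRET score rises."""
        return bool(np.isfinite(self.scc) and self.scc < 0)


def fret_score(i_fret: float, i_donor: float) -> float:
    """Sensitized-emission FRET score in percent.

    100 · I_FRET / (I_FRET + I_D).  Undefined (NaN, with a warning) when
    both intensities are zero; invariant under joint intensity scaling.
    """
    if i_fret < 0 or i_donor < 0:
        raise ValueError("intensities must be nonnegative")
    total = i_fret + i_donor
    if total == 0:
        warnings.warn("i_fret + i_donor == 0; score undefined, record dropped")
        return float("nan")
    return 100.0 * i_fret / total


def score_pairs(pairs_df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized scores for a pairs table (columns i_fret, i_donor);
    pairs with zero total intensity are dropped with a warning."""
    df = pairs_df.copy()
    total = df["i_fret"] + df["i_donor"]
    dead = total == 0
    if dead.any():
        warnings.warn(f"dropping {int(dead.sum())} pairs with zero total intensity")
        df = df[~dead]
        total = total[~dead]
    df["score_pct"] = 100.0 * df["i_fret"] / total
    return df


def crosstalk_baseline(
    scores_donor_only: Sequence[float],
    scores_acceptor_only: Sequence[float],
    scores_test: Sequence[float] | None = None,
) -> dict:
    """Summarize donor-only / acceptor-only control scores.

    Controls are samples hybridized with only one primary-oligo species,
    so any apparent FRET there comes from crosstalk (direct acceptor
    excitation) or bleed-through (donor emission in the FRET band).  No
    correction is subtracted from test scores; the summary just reports
    the control medians/IQRs, whether the two controls are mutually
    homogeneous (rank test), and, when test scores are given, whether
    they exceed the pooled baseline.
    """
    d = np.asarray(scores_donor_only, dtype=float)
    a = np.asarray(scores_acceptor_only, dtype=float)
    if len(d) == 0 or len(a) == 0:
        raise ValueError("both control conditions must be non-empty")

    def _summ(x: np.ndarray) -> dict:
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        return dict(median=float(med), iqr=float(q3 - q1), n=len(x))

    out = {"donor_only": _summ(d), "acceptor_only": _summ(a)}
    if np.array_equal(np.sort(d), np.sort(a)):
        out["homogeneous_controls"] = True
    else:
        p_dn_vs_ac = stats.mannwhitneyu(d, a, alternative="two-sided").pvalue
        out["homogeneous_controls"] = bool(p_dn_vs_ac > 0.05)
        out["controls_p"] = float(p_dn_vs_ac)
    if scores_test is not None:
        t = np.asarray(scores_test, dtype=float)
        pooled = np.concatenate([d, a])
        res = stats.mannwhitneyu(t, pooled, alternative="greater")
        out["test"] = _summ(t)
        out["test_exceeds_baseline"] = bool(res.pvalue < 0.05)
        out["test_p"] = float(res.pvalue)
    return out


def split_modes(
    scores: Sequence[float],
    bandwidth: float | str = "silverman",
    grid_size: int = 512,
    min_rel_prominence: float = 0.05,
    method: str = "valley",
) -> ModeSplit:
    """Split a bimodal score distribution at the point between its modes.

    A Gaussian KDE (Silverman bandwidth by default) is evaluated on a
    grid; the threshold is the density minimum between the two dominant
    maxima ("valley", default) or the second-derivative zero-crossing
    between them ("inflection").  Fractions are the empirical proportions
    below/above the threshold.  With fewer than two sufficiently
    prominent modes the distribution is declared unimodal.
    """
    x = np.asarray(scores, dtype=float)
    if len(x) < 30:
        raise ValueError(f"need >=30 scores to split modes (got {len(x)})")
    kde = stats.gaussian_kde(x, bw_method=bandwidth if isinstance(bandwidth, str) else None)
    if not isinstance(bandwidth, str):
        kde.set_bandwidth(bandwidth / x.std(ddof=1))
    bw = float(kde.factor * x.std(ddof=1))
    pad = 3 * bw
    grid = np.linspace(x.min() - pad, x.max() + pad, grid_size)
    dens = kde(grid)

    maxima = [
        i
        for i in range(1, grid_size - 1)
        if dens[i] >= dens[i - 1] and dens[i] > dens[i + 1]
    ]
    prominent = [i for i in maxima if dens[i] >= min_rel_prominence * dens.max()]
    if len(prominent) < 2:
        return ModeSplit(
            threshold=float("nan"),
            frac_low=1.0,
            frac_high=float("nan"),
            bandwidth=bw,
            is_bimodal=False,
            mode_locations=tuple(float(grid[i]) for i in prominent),
        )
    top2 = sorted(sorted(prominent, key=lambda i: dens[i], reverse=True)[:2])
    lo, hi = top2
    if method == "inflection":
        d2 = np.gradient(np.gradient(dens, grid), grid)
        seg = d2[lo : hi + 1]
        crossings = np.nonzero(np.diff(np.sign(seg)))[0]
        idx = lo + int(crossings[len(crossings) // 2]) if len(crossings) else lo + int(np.argmin(dens[lo : hi + 1]))
    else:
        idx = lo + int(np.argmin(dens[lo : hi + 1]))
    threshold = float(grid[idx])
    frac_high = float((x > threshold).mean())
    return ModeSplit(
        threshold=threshold,
        frac_low=1.0 - frac_high,
        frac_high=frac_high,
        bandwidth=bw,
        is_bimodal=True,
        mode_locations=(float(grid[lo]), float(grid[hi])),
    )


def compare_conditions(scores_a: Sequence[float], scores_b: Sequence[float]) -> dict:
    """Two-sided rank-sum comparison of two score groups.

    Returns the Wilcoxon rank-sum (Mann–Whitney) p-value and the
    Hodges–Lehmann median shift (median of all pairwise b−a differences).
    Groups smaller than 3 give p = NaN with a warning.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    shift = float(np.median(b[None, :] - a[:, None]))
    if min(len(a), len(b)) < 3:
        warnings.warn("group smaller than 3; p-value not reported")
        return {"p_value": float("nan"), "median_shift": shift, "n_a": len(a), "n_b": len(b)}
    p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return {"p_value": p, "median_shift": shift, "n_a": len(a), "n_b": len(b)}


def atac_window_counts(
    windows: Sequence[GenomicInterval],
    read_starts: pd.DataFrame,
) -> np.ndarray:
    """Count reads per probe window.

    ``read_starts`` has columns (chrom, pos) giving each read's 5' start;
    a read contributes to the window containing its start, so no read is
    counted twice by overlapping windows.  Windows on chromosomes absent
    from the track count 0 with a warning.
    """
    if not {"chrom", "pos"} <= set(read_starts.columns):
        raise ValueError("read_starts needs columns 'chrom' and 'pos'")
    counts = np.zeros(len(windows), dtype=int)
    by_chrom = {c: np.sort(g["pos"].to_numpy()) for c, g in read_starts.groupby("chrom")}
    for i, w in enumerate(windows):
        pos = by_chrom.get(w.chrom)
        if pos is None:
            warnings.warn(f"no coverage on {w.chrom}; window counts 0")
            continue
        counts[i] = int(np.searchsorted(pos, w.end) - np.searchsorted(pos, w.start))
    return counts


def read_bedgraph_starts(path) -> pd.DataFrame:
    """Expand a bedGraph of per-base read-start counts into a read-start
    table (chrom, pos) usable by :func:`atac_window_counts`."""
    bg = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "count"])
    rows = []
    for r in bg.itertuples(index=False):
        for p in range(int(r.start), int(r.end)):
            if r.count > 0:
                rows.extend([(r.chrom, p)] * int(r.count))
    return pd.DataFrame(rows, columns=["chrom", "pos"])


def correlate_score_vs_atac(comparison: AtacComparison) -> AtacComparison:
    """Spearman and Pearson correlation of per-locus mean FRET score
    against ATAC window read count.  A negative sign is the expected
    direction: accessible chromatin is less compact."""
    df = comparison.table
    if len(df) < 3:
        raise ValueError("need >=3 loci to correlate")
    score = df["mean_score"].to_numpy(dtype=float)
    count = df["atac_count"].to_numpy(dtype=float)
    if np.ptp(score) == 0 or np.ptp(count) == 0:
        warnings.warn("constant vector; correlations undefined")
        comparison.scc = comparison.pcc = float("nan")
        return comparison
    scc = stats.spearmanr(score, count)
    pcc = stats.pearsonr(score, count)
    comparison.scc, comparison.scc_p = float(scc.statistic), float(scc.pvalue)
    comparison.pcc, comparison.pcc_p = float(pcc.statistic), float(pcc.pvalue)
    return comparison
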