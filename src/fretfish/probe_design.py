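"""Design of FRET-FISH oligo probes.

A FRET-FISH probe tiles a genomic target with 60-nt primary oligos whose
detection oligos carry alternating FRET donor (D) and acceptor (A) dyes.
Candidate oligos are enumerated with a 1-nt sliding window, filtered on
composition (GC content, homopolymer runs), penalized by genome-wide
homology, and the probe is placed at the window of the target that
minimizes total penalty while honouring the requested dye layout
(group size and inter-oligo spacings).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "OligoCandidate",
    "DesignParams",
    "ProbeOligo",
    "ProbeSet",
    "HomologyHit",
    "LAYOUT_PRESETS",
    "DEFAULT_ADAPTERS",
    "SS_5P",
    "SS_3P",
    "enumerate_oligos",
    "composition_filter",
    "aggregate_homology",
    "homology_oracle",
    "select_best_window",
    "assemble_oligos",
    "design_probe",
    "export_probe",
    "import_probe",
    "read_blast_hits",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Stabilization strings appended at the 5' / 3' ends in designs 2 and 3.
#: They are mutual reverse complements, so the 3' tail of one oligo can
#: base-pair with the 5' tail of the next one along the target.
SS_5P = "TAATT"
SS_3P = "AATTA"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open, 0-based genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class OligoCandidate:
    """One sliding-window oligo with its composition and homology penalties."""

    target_seq: str
    interval: GenomicInterval
    gc_fraction: float
    max_run: int
    homology_penalty: float = 0.0
    quality: str = "good"

    @property
    def oligo_id(self) -> str:
        return f"oligo_{self.interval.start}"


@dataclass
class DesignParams:
    """Tunable probe-design parameters.

    Spacings are gaps in nt between the 3' end of one target sequence
    and the 5' start of the next.  The default layout is the dense
    alternating-oligo design used for ~20 kb targets: single-oligo dye
    groups at the minimum 5-nt gap.
    """

    l: int = 60
    n_total: int = 260
    group_size: int = 1
    spacing_same_dye: int = 5
    spacing_between_dyes: int = 5
    min_gap: int = 5
    gc_low: float = 0.35
    gc_high: float = 0.80
    max_run_allowed: int = 6
    incomplete_group_tolerance: int = 10
    snap_tolerance: int | None = None  # defaults to l // 2
    lambda_spacing: float = 1.0  # penalty units per nt of grid deviation

    def __post_init__(self) -> None:
        if not self.gc_low < self.gc_high:
            raise ValueError("gc_low must be < gc_high")
        if self.min_gap < 0:
            raise ValueError("min_gap must be >= 0")

    @property
    def snap_tol(self) -> int:
        return self.l // 2 if self.snap_tolerance is None else self.snap_tolerance

    @classmethod
    def from_file(cls, path: "str | Path") -> "DesignParams":
        """Load parameters from a YAML or JSON config file; unset keys
        keep their defaults."""
        import json

        import yaml

        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown design parameters: {sorted(unknown)}")
        return cls(**data)


#: Layout presets named G<group>S<spacing>: groups of 1/2/4 same-dye
#: oligos with 50/150/300-nt gaps between consecutive oligos.
LAYOUT_PRESETS: dict[str, dict[str, int]] = {
    "G1S50": dict(group_size=1, spacing_same_dye=50, spacing_between_dyes=50),
    "G1S150": dict(group_size=1, spacing_same_dye=150, spacing_between_dyes=150),
    "G2S50": dict(group_size=2, spacing_same_dye=50, spacing_between_dyes=50),
    "G2S300": dict(group_size=2, spacing_same_dye=300, spacing_between_dyes=300),
    "G4S50": dict(group_size=4, spacing_same_dye=50, spacing_between_dyes=50),
    "G4S300": dict(group_size=4, spacing_same_dye=300, spacing_between_dyes=300),
}

#: 20-nt orthogonal adapter pairs per dye role (L, R).  These are
#: synthetic orthogonal sequences in the style of barcoded FISH adapter
#: libraries; real designs substitute their own validated pairs.
DEFAULT_ADAPTERS: dict[str, tuple[str, str]] = {
    "donor": ("GTTCAGCGTACCAGATCGTT", "CATCGATCCTAGGTTGACCA"),
    "acceptor": ("TGACCTTCGAGGTACTGCAT", "ACGGATGTTCACGCTAGATC"),
}


@dataclass
class ProbeOligo:
    """An assembled probe oligo: target sequence plus adapters (and,
    depending on the design variant, stabilization tails)."""

    candidate: OligoCandidate
    dye_role: str  # "donor" | "acceptor"
    left_adapter: str = ""
    right_adapter: str = ""
    lss: str | None = None
    rss: str | None = None
    full_seq: str = ""


@dataclass
class ProbeSet:
    """An ordered probe: oligos with dye roles, plus detection oligos."""

    name: str
    design_variant: str = "design1"
    layout: str = "custom"
    oligos: list[ProbeOligo] = field(default_factory=list)
    detection_oligos: list[dict] = field(default_factory=list)
    total_penalty: float = float("nan")
    objective: float = float("nan")

    @property
    def span(self) -> int:
        if not self.oligos:
            return 0
        return self.oligos[-1].candidate.interval.end - self.oligos[0].candidate.interval.start

    def intervals(self) -> list[GenomicInterval]:
        return [o.candidate.interval for o in self.oligos]

    def min_gap(self) -> int:
        """Smallest gap in nt between consecutive oligo target intervals."""
        iv = self.intervals()
        if len(iv) < 2:
            raise ValueError("need at least two oligos to compute gaps")
        return min(b.start - a.end for a, b in zip(iv, iv[1:]))


@dataclass(frozen=True)
class HomologyHit:
    """One homology hit of an oligo against the reference genome."""

    query_id: str
    score: float
    is_self: bool = False

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("hit score must be >= 0")


# ---------------------------------------------------------------------------
# candidate enumeration and filtering


def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def _max_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def enumerate_oligos(seq: str, l: int, chrom: str = "region") -> list[OligoCandidate]:
    """Enumerate all length-``l`` windows of ``seq`` in 1-nt steps.

    Returns ``len(seq) - l + 1`` candidates in genomic order (empty, with
    a warning, when the sequence is shorter than ``l``).  Windows
    containing N are marked bad immediately.
    """
    if l < 1:
        raise ValueError("oligo length must be >= 1")
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains invalid characters: {sorted(bad)}")
    if len(seq) < l:
        warnings.warn(f"sequence of length {len(seq)} shorter than oligo length {l}; no candidates")
        return []
    out = []
    for start in range(len(seq) - l + 1):
        sub = seq[start : start + l]
        out.append(
            OligoCandidate(
                target_seq=sub,
                interval=GenomicInterval(chrom, start, start + l),
                gc_fraction=_gc_fraction(sub),
                max_run=_max_run(sub),
                quality="bad" if "N" in sub else "good",
            )
        )
    return out


def composition_filter(cands: Sequence[OligoCandidate], params: DesignParams) -> list[OligoCandidate]:
    """Mark candidates bad when GC is outside [gc_low, gc_high] (inclusive
    bounds) or the longest homopolymer run exceeds ``max_run_allowed``.
    Pure relabelling; idempotent."""
    out = []
    for c in cands:
        bad = (
            "N" in c.target_seq
            or c.max_run > params.max_run_allowed
            or not (params.gc_low <= c.gc_fraction <= params.gc_high)
        )
        out.append(replace(c, quality="bad" if bad else "good"))
    return out


def aggregate_homology(
    cands: Sequence[OligoCandidate],
    hits: Iterable[HomologyHit],
    exclude_self: bool = True,
) -> list[OligoCandidate]:
    """Sum homology hit scores per oligo into ``homology_penalty``.

    Every oligo trivially matches its own genomic locus, so self-hits are
    excluded by default.  Hits naming an unknown oligo id raise.
    """
    by_id = {c.oligo_id: 0.0 for c in cands}
    for h in hits:
        if h.query_id not in by_id:
            raise KeyError(f"homology hit references unknown oligo id {h.query_id!r}")
        if exclude_self and h.is_self:
            continue
        by_id[h.query_id] += h.score
    return [replace(c, homology_penalty=by_id[c.oligo_id]) for c in cands]


def homology_oracle(
    cands: Sequence[OligoCandidate],
    genome_seq: str,
    min_identity: float = 0.8,
) -> list[HomologyHit]:
    """Exhaustive ungapped homology search of each candidate against a
    genome sequence.

    Reports every genome offset where the oligo aligns at >= ``min_identity``
    fraction of matching bases, scoring each hit by the number of matched
    bases.  A hit at the candidate's own coordinate is flagged ``is_self``.
    Deterministic; intended for the small synthetic genomes used in
    testing — production designs run BLASTn and feed the tabular output
    through :func:`read_blast_hits`.
    """
    genome = np.frombuffer(genome_seq.upper().encode(), dtype="S1")
    hits: list[HomologyHit] = []
    for c in cands:
        oligo = np.frombuffer(c.target_seq.encode(), dtype="S1")
        l = len(oligo)
        if len(genome) < l:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(genome, l)
        matches = (windows == oligo).sum(axis=1)
        min_matches = int(np.ceil(min_identity * l))
        for pos in np.nonzero(matches >= min_matches)[0]:
            hits.append(
                HomologyHit(
                    query_id=c.oligo_id,
                    score=float(matches[pos]),
                    is_self=(int(pos) == c.interval.start),
                )
            )
    return hits


def read_blast_hits(
    path: str | Path,
    cands: Sequence[OligoCandidate] | None = None,
) -> list[HomologyHit]:
    """Read a BLAST outfmt-6-like tabular file into homology hits.

    Only ``qseqid`` (col 1) and ``bitscore`` (col 12) are consumed.  A hit
    is flagged self when its subject coordinates cover the oligo's own
    locus with 100% identity (best-effort; requires standard columns).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 12:
        raise ValueError("expected >=12 tab-separated columns (BLAST outfmt 6)")
    known = {c.oligo_id for c in cands} if cands is not None else None
    hits = []
    for row in df.itertuples(index=False):
        qid = str(row[0])
        if known is not None and qid not in known:
            raise KeyError(f"BLAST hit references unknown oligo id {qid!r}")
        is_self = float(row[2]) == 100.0 and qid.startswith("oligo_") and str(row[1]) == qid
        hits.append(HomologyHit(query_id=qid, score=float(row[11]), is_self=is_self))
    return hits


# ---------------------------------------------------------------------------
# window selection


def _drop_isolated_good(quality: np.ndarray) -> np.ndarray:
    """Good oligos flanked by bad neighbours on both sides are demoted;
    they cannot anchor a reliable stretch of the probe."""
    good = quality.copy()
    n = len(good)
    for i in range(n):
        if not good[i]:
            continue
        left_bad = i == 0 or not good[i - 1]
        right_bad = i == n - 1 or not good[i + 1]
        if left_bad and right_bad:
            good[i] = False
    return good


def _ideal_offsets(params: DesignParams) -> tuple[np.ndarray, list[str]]:
    """Ideal start offsets (relative to window start) and dye roles for
    each of the n_total probe slots under the requested layout."""
    starts = [0]
    roles = ["donor"]
    for i in range(1, params.n_total):
        same_group = (i % params.group_size) != 0
        gap = params.spacing_same_dye if same_group else params.spacing_between_dyes
        starts.append(starts[-1] + params.l + gap)
        group_index = i // params.group_size
        roles.append("donor" if group_index % 2 == 0 else "acceptor")
    return np.asarray(starts), roles


def select_best_window(
    cands: Sequence[OligoCandidate],
    params: DesignParams,
    name: str = "probe",
    layout: str = "custom",
) -> ProbeSet:
    """Place the probe at the window minimizing total penalty.

    Every window start offset is tried.  Within a window each ideal grid
    slot snaps to the nearest good candidate within ±l/2 nt, subject to a
    minimum ``min_gap`` between consecutive target sequences; slots with
    no usable candidate leave their group incomplete.  The objective is
    the sum of per-oligo penalties plus ``lambda_spacing`` per nt of
    deviation from the ideal grid; ties go to the smallest start.
    """
    if not cands:
        raise ValueError("no candidates supplied")
    quality = np.array([c.quality == "good" for c in cands])
    usable = _drop_isolated_good(quality)
    if not usable.any():
        raise ValueError("no good oligo candidates after filtering")
    good_starts = np.array([c.interval.start for i, c in enumerate(cands) if usable[i]])
    good_pen = np.array([c.homology_penalty for i, c in enumerate(cands) if usable[i]])
    ideal, roles = _ideal_offsets(params)
    span = ideal[-1] + params.l
    seq_len = cands[-1].interval.end
    if span > seq_len:
        raise ValueError(
            f"layout span {span} nt exceeds target length {seq_len} nt "
            f"(first unsatisfiable constraint: total span; reduce n_total or spacings)"
        )
    tol = params.snap_tol
    max_missing = params.incomplete_group_tolerance * params.group_size

    best: tuple[float, int, list[int]] | None = None
    for offset in range(seq_len - span + 1):
        targets = ideal + offset
        chosen: list[int] = []
        deviation = 0.0
        penalty = 0.0
        missing = 0
        prev_end = -np.inf
        ok = True
        for t in targets:
            lo = max(t - tol, prev_end + params.min_gap)
            hi = t + tol
            i0 = np.searchsorted(good_starts, lo, side="left")
            i1 = np.searchsorted(good_starts, hi, side="right")
            if i0 >= i1:
                missing += 1
                if missing > max_missing:
                    ok = False
                    break
                chosen.append(-1)
                continue
            window_pos = good_starts[i0:i1]
            # per-slot objective contribution; ties to smaller deviation, then start
            dev = np.abs(window_pos - t)
            contrib = good_pen[i0:i1] + params.lambda_spacing * dev
            j = i0 + int(np.lexsort((window_pos, dev, contrib))[0])
            chosen.append(j)
            deviation += abs(int(good_starts[j]) - int(t))
            penalty += good_pen[j]
            prev_end = good_starts[j] + params.l
        if not ok:
            continue
        # lexicographic: fill as many slots as possible, then minimize
        # penalty + lambda * grid deviation; ties to smallest offset
        objective = penalty + params.lambda_spacing * deviation
        key = (missing, objective)
        if best is None or key < best[0]:
            best = (key, offset, chosen)

    if best is None:
        n_good = int(usable.sum())
        raise ValueError(
            "no feasible window: could not fill the oligo grid "
            f"({n_good} usable candidates for {params.n_total} slots; "
            "first unsatisfiable constraint: slot occupancy within snap tolerance)"
        )
    (_, objective), offset, chosen = best
    idx_map = np.nonzero(usable)[0]
    oligos = []
    for slot, j in enumerate(chosen):
        if j < 0:
            continue
        cand = cands[int(idx_map[j])]
        oligos.append(ProbeOligo(candidate=cand, dye_role=roles[slot]))
    total_penalty = sum(o.candidate.homology_penalty for o in oligos)
    return ProbeSet(
        name=name,
        layout=layout,
        oligos=oligos,
        total_penalty=total_penalty,
        objective=objective,
    )


# ---------------------------------------------------------------------------
# assembly and export


def _check_adapters(adapters: Mapping[str, tuple[str, str]]) -> None:
    seqs = []
    for role, (left, right) in adapters.items():
        for ad in (left, right):
            if len(ad) != 20:
                raise ValueError(f"{role} adapter {ad!r} is {len(ad)} nt; adapters must be 20 nt")
            seqs.append(ad)
    # orthogonality: warn on any shared >=15-nt exact substring
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            a, b = seqs[i], seqs[j]
            if any(a[k : k + 15] in b for k in range(len(a) - 14)):
                warnings.warn(f"adapters {a} and {b} share a >=15-nt substring; not orthogonal")


def assemble_oligos(
    probe: ProbeSet,
    adapters: Mapping[str, tuple[str, str]] | None = None,
    variant: str = "design1",
) -> ProbeSet:
    """Assemble full oligo sequences for one of the three design variants.

    design1: ``L + T + R``.  design2: the primary oligos additionally
    carry the 5' (TAATT) and 3' (AATTA) stabilization tails, which are
    mutual reverse complements so neighbouring oligos can anneal.
    design3: primaries identical to design1; the stabilization tails go
    on the detection oligos instead (5' of L*, 3' of R*).
    """
    if variant not in ("design1", "design2", "design3"):
        raise ValueError(f"unknown design variant {variant!r}")
    adapters = dict(adapters or DEFAULT_ADAPTERS)
    _check_adapters(adapters)

    oligos = []
    for o in probe.oligos:
        left, right = adapters[o.dye_role]
        lss = SS_5P if variant == "design2" else None
        rss = SS_3P if variant == "design2" else None
        core = left + o.candidate.target_seq + right
        full = (lss or "") + core + (rss or "")
        oligos.append(
            replace(o, left_adapter=left, right_adapter=right, lss=lss, rss=rss, full_seq=full)
        )

    detection = []
    for role, (left, right) in adapters.items():
        l_det = revcomp(left)
        r_det = revcomp(right)
        if variant == "design3":
            l_det = SS_5P + l_det
            r_det = r_det + SS_3P
        detection.append({"dye_role": role, "side": "L*", "sequence": l_det, "stabilized": variant == "design3"})
        detection.append({"dye_role": role, "side": "R*", "sequence": r_det, "stabilized": variant == "design3"})

    return replace(probe, design_variant=variant, oligos=oligos, detection_oligos=detection)


def design_probe(
    seq: str,
    params: DesignParams | None = None,
    hits: Iterable[HomologyHit] | None = None,
    variant: str = "design1",
    layout: str = "custom",
    adapters: Mapping[str, tuple[str, str]] | None = None,
    name: str = "probe",
    chrom: str = "region",
) -> ProbeSet:
    """Full pipeline: enumerate, filter, penalize, select window, assemble."""
    params = params or DesignParams()
    if layout in LAYOUT_PRESETS:
        params = replace(params, **LAYOUT_PRESETS[layout])
    cands = enumerate_oligos(seq, params.l, chrom=chrom)
    cands = composition_filter(cands, params)
    cands = aggregate_homology(cands, hits or [])
    probe = select_best_window(cands, params, name=name, layout=layout)
    return assemble_oligos(probe, adapters=adapters, variant=variant)


def export_probe(probe: ProbeSet, prefix: str | Path) -> dict[str, Path]:
    """Write FASTA (full sequences), BED (target intervals, 0-based
    half-open) and a TSV probe table; returns the written paths."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    fasta = prefix.with_suffix(".fa")
    bed = prefix.with_suffix(".bed")
    tsv = prefix.with_suffix(".tsv")

    records = []
    rows = []
    for i, o in enumerate(probe.oligos):
        iv = o.candidate.interval
        oid = f"{probe.name}_{i:04d}_{o.dye_role}"
        # FASTA header display coordinates are 1-based inclusive
        desc = f"{iv.chrom}:{iv.start + 1}-{iv.end} {o.dye_role} {probe.design_variant}"
        records.append(SeqRecord(Seq(o.full_seq), id=oid, description=desc))
        rows.append(
            dict(
                name=oid,
                chrom=iv.chrom,
                start=iv.start,
                end=iv.end,
                dye_role=o.dye_role,
                gc=o.candidate.gc_fraction,
                max_run=o.candidate.max_run,
                penalty=o.candidate.homology_penalty,
                full_seq=o.full_seq,
            )
        )
    SeqIO.write(records, fasta, "fasta")
    df = pd.DataFrame(rows)
    df[["chrom", "start", "end", "name"]].to_csv(bed, sep="\t", header=False, index=False)
    meta = f"# name={probe.name} variant={probe.design_variant} layout={probe.layout}\n"
    with open(tsv, "w") as fh:
        fh.write(meta)
        df.to_csv(fh, sep="\t", index=False)
    return {"fasta": fasta, "bed": bed, "tsv": tsv}


def import_probe(tsv_path: str | Path) -> ProbeSet:
    """Re-read a probe TSV written by :func:`export_probe`."""
    tsv_path = Path(tsv_path)
    with open(tsv_path) as fh:
        header = fh.readline().strip()
    meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
    df = pd.read_csv(tsv_path, sep="\t", comment="#")
    oligos = []
    for row in df.itertuples(index=False):
        cand = OligoCandidate(
            target_seq="",  # recovered below from the full sequence
            interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
            gc_fraction=float(row.gc),
            max_run=int(row.max_run),
            homology_penalty=float(row.penalty),
        )
        o = ProbeOligo(candidate=cand, dye_role=row.dye_role, full_seq=row.full_seq)
        oligos.append(o)
    probe = ProbeSet(name=meta["name"], design_variant=meta["variant"], layout=meta["layout"], oligos=oligos)
    # recover target sequences by stripping adapters/tails
    l = len(oligos[0].candidate.interval) if oligos else 0
    for o in probe.oligos:
        full = o.full_seq
        if probe.design_variant == "design2":
            full = full[len(SS_5P) : len(full) - len(SS_3P)]
        o.candidate.target_seq = full[20 : 20 + l]
        o.left_adapter = full[:20]
        o.right_adapter = full[20 + l :]
        if probe.design_variant == "design2":
            o.lss, o.rss = SS_5P, SS_3P
    return probe
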