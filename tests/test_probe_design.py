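"""Probe design: enumeration, filters, homology, window selection, assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fretfish import probe_design as pdm
from fretfish.probe_design import (
    DesignParams,
    GenomicInterval,
    HomologyHit,
    OligoCandidate,
    aggregate_homology,
    assemble_oligos,
    composition_filter,
    design_probe,
    enumerate_oligos,
    export_probe,
    homology_oracle,
    import_probe,
    revcomp,
    select_best_window,
)
from fretfish.simdata import gen_genome


def random_seq(n, seed=0, gc=0.5):
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


# ---------------------------------------------------------------------------
# enumeration


@pytest.mark.parametrize(
    "seq_len,l,expected",
    [(60, 60, 1), (62, 60, 3), (59, 60, 0), (100, 1, 100)],
)
def test_enumeration_count(seq_len, l, expected):
    seq = random_seq(seq_len)
    if expected == 0:
        with pytest.warns(UserWarning):
            cands = enumerate_oligos(seq, l)
    else:
        cands = enumerate_oligos(seq, l)
    assert len(cands) == expected
    assert [c.interval.start for c in cands] == list(range(expected))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(seq_len=st.integers(1, 200), l=st.integers(1, 80))
def test_enumeration_count_property(seq_len, l):
    seq = random_seq(seq_len, seed=seq_len * 81 + l)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cands = enumerate_oligos(seq, l)
    assert len(cands) == max(0, seq_len - l + 1)


def test_n_containing_windows_marked_bad():
    seq = "A" * 30 + "N" + "C" * 30  # only windows spanning index 30 touch the N
    cands = enumerate_oligos(seq, 10)
    for c in cands:
        expect_bad = c.interval.start <= 30 < c.interval.end
        assert (c.quality == "bad") == expect_bad


# ---------------------------------------------------------------------------
# composition filter


def _mk60(seq):
    assert len(seq) == 60
    return enumerate_oligos(seq, 60)[0]


@pytest.mark.parametrize(
    "seq,expected",
    [
        # run of 7 identical bases: rejected (more than 6 repetitive nt)
        ("AAAAAAA" + random_seq(53, seed=1, gc=0.6), "bad"),
        # run of exactly 6: allowed
        ("AAAAAA" + random_seq(54, seed=2, gc=0.6), "good"),
        # GC 34% (below): bad; GC exactly 35%: good (inclusive bound)
        ("GC" * 10 + "AT" * 20, "bad"),  # 20/60 = 33%
        ("GCG" * 7 + "AT" * 19 + "A", "good"),  # 21/60 = 35%
        # interior of the allowed region
        (("GCAT" * 15), "good"),
    ],
)
def test_composition_filter_cases(seq, expected):
    params = DesignParams()
    cand = composition_filter([_mk60(seq)], params)[0]
    assert cand.quality == expected


def test_composition_filter_boundaries_and_idempotence():
    params = DesignParams()
    # GC exactly 80% = 48/60 is allowed, 49/60 is not
    ok = _mk60("GC" * 24 + "AT" * 6)  # 48/60 GC = 80%
    too_high = _mk60("GC" * 24 + "G" + "AT" * 5 + "A")  # 49/60 GC
    cands = composition_filter([ok], params)
    assert abs(ok.gc_fraction - 0.80) < 1e-9
    assert cands[0].quality == "good"
    assert too_high.gc_fraction > 0.80
    assert composition_filter([too_high], params)[0].quality == "bad"
    once = composition_filter([ok, too_high], params)
    twice = composition_filter(once, params)
    assert [c.quality for c in once] == [c.quality for c in twice]


# ---------------------------------------------------------------------------
# homology


def test_homology_penalty_summation():
    cands = enumerate_oligos(random_seq(61, seed=3), 60)
    hits = [
        HomologyHit("oligo_0", 30.0),
        HomologyHit("oligo_0", 40.0),
    ]
    out = aggregate_homology(cands, hits)
    assert out[0].homology_penalty == 70.0
    assert out[1].homology_penalty == 0.0


def test_homology_unknown_id_raises():
    cands = enumerate_oligos(random_seq(60, seed=3), 60)
    with pytest.raises(KeyError, match="oligo_999"):
        aggregate_homology(cands, [HomologyHit("oligo_999", 1.0)])


def test_self_hit_excluded():
    genome = random_seq(1000, seed=4)
    oligo = genome[100:160]
    cand = OligoCandidate(
        target_seq=oligo,
        interval=GenomicInterval("g", 100, 160),
        gc_fraction=0.5,
        max_run=2,
    )
    hits = homology_oracle([cand], genome, min_identity=0.9)
    # oligo occurs exactly once: only the self hit
    assert len(hits) == 1 and hits[0].is_self
    out = aggregate_homology([cand], hits, exclude_self=True)
    assert out[0].homology_penalty == 0.0
    out = aggregate_homology([cand], hits, exclude_self=False)
    assert out[0].homology_penalty == 60.0


def test_oracle_finds_planted_duplicate():
    genome, truth = gen_genome(2000, seed=5, planted_repeats=[(200, 60, 1200)])
    oligo = genome[200:260]
    cand = OligoCandidate(
        target_seq=oligo, interval=GenomicInterval("g", 200, 260), gc_fraction=0.5, max_run=2
    )
    hits = homology_oracle([cand], genome, min_identity=0.95)
    positions = sorted((h.is_self) for h in hits)
    assert len(hits) == 2
    assert sum(h.is_self for h in hits) == 1


def test_oracle_no_hits_for_unrelated_sequence():
    genome = random_seq(1000, seed=6)
    oligo = random_seq(60, seed=77)
    cand = OligoCandidate(
        target_seq=oligo, interval=GenomicInterval("other", 0, 60), gc_fraction=0.5, max_run=2
    )
    # exhaustive sliding-identity scan: no window of an unrelated 1 kb
    # sequence matches a random 60-mer at 80% identity
    assert homology_oracle([cand], genome, min_identity=0.8) == []


def test_oracle_exact_identity_single_hit():
    oligo = random_seq(60, seed=8)
    cand = OligoCandidate(
        target_seq=oligo, interval=GenomicInterval("g", 0, 60), gc_fraction=0.5, max_run=2
    )
    hits = homology_oracle([cand], oligo, min_identity=1.0)
    assert len(hits) == 1 and hits[0].score == 60.0


# ---------------------------------------------------------------------------
# window selection


def brute_force_best_window(cands, params):
    """Independent re-enumeration: all offsets, per-slot snap minimizing
    penalty + lambda*|deviation| with plain Python loops."""
    good = []
    quality = [c.quality == "good" for c in cands]
    for i, c in enumerate(cands):
        if not quality[i]:
            continue
        left_bad = i == 0 or not quality[i - 1]
        right_bad = i == len(cands) - 1 or not quality[i + 1]
        if left_bad and right_bad:
            continue
        good.append(c)
    ideal, _roles = pdm._ideal_offsets(params)
    span = int(ideal[-1]) + params.l
    seq_len = cands[-1].interval.end
    tol = params.snap_tol
    best = None
    for offset in range(seq_len - span + 1):
        prev_end = -(10**9)
        total = 0.0
        missing = 0
        feasible = True
        for t in ideal + offset:
            options = [
                c
                for c in good
                if abs(c.interval.start - t) <= tol and c.interval.start >= prev_end + params.min_gap
            ]
            if not options:
                missing += 1
                if missing > params.incomplete_group_tolerance * params.group_size:
                    feasible = False
                    break
                continue
            pick = min(
                options,
                key=lambda c: (
                    c.homology_penalty + params.lambda_spacing * abs(c.interval.start - t),
                    abs(c.interval.start - t),
                    c.interval.start,
                ),
            )
            total += pick.homology_penalty + params.lambda_spacing * abs(pick.interval.start - t)
            prev_end = pick.interval.start + params.l
        if feasible and (best is None or (missing, total) < best):
            best = (missing, total)
    return best


def _toy_candidates(seed=9, n=150, l=10):
    seq = random_seq(n + l - 1, seed=seed)
    params = DesignParams(
        l=l, n_total=6, group_size=1, spacing_same_dye=8, spacing_between_dyes=8,
        min_gap=2, incomplete_group_tolerance=0,
    )
    cands = enumerate_oligos(seq, l)
    rng = np.random.default_rng(seed)
    out = []
    for c in cands:
        from dataclasses import replace

        q = "bad" if rng.random() < 0.15 else "good"
        out.append(replace(c, quality=q, homology_penalty=float(rng.integers(0, 50))))
    return out, params


def test_select_matches_bruteforce_on_small_instance():
    cands, params = _toy_candidates()
    assert len(cands) <= 200
    probe = select_best_window(cands, params)
    oracle = brute_force_best_window(cands, params)
    assert oracle is not None
    missing, total = oracle
    assert probe.objective == pytest.approx(total)
    assert len(probe.oligos) == params.n_total - missing


def test_unique_feasible_window_is_returned():
    # one good stretch only: oligos must come from it
    l, gap = 10, 5
    n_slots = 3
    seq = random_seq(200, seed=11)
    params = DesignParams(
        l=l, n_total=n_slots, group_size=1, spacing_same_dye=gap, spacing_between_dyes=gap,
        min_gap=gap, incomplete_group_tolerance=0, snap_tolerance=0,
    )
    cands = enumerate_oligos(seq, l)
    from dataclasses import replace

    # good candidates only at grid positions 50/65/80 and their right
    # neighbours (which carry a penalty), so the window at offset 50 with
    # zero total penalty is the unique optimum
    grid = [50, 50 + l + gap, 50 + 2 * (l + gap)]
    goods = {g: 0.0 for g in grid} | {g + 1: 5.0 for g in grid}
    cands = [
        replace(
            c,
            quality="good" if c.interval.start in goods else "bad",
            homology_penalty=goods.get(c.interval.start, 0.0),
        )
        for c in cands
    ]
    probe = select_best_window(cands, params)
    assert [o.candidate.interval.start for o in probe.oligos] == grid
    assert probe.total_penalty == 0.0


def test_isolated_good_oligo_removed():
    cands, params = _toy_candidates(seed=12)
    from dataclasses import replace

    # make candidate 40 good but flanked by bad neighbours
    cands[39] = replace(cands[39], quality="bad")
    cands[40] = replace(cands[40], quality="good", homology_penalty=0.0)
    cands[41] = replace(cands[41], quality="bad")
    probe = select_best_window(cands, params)
    starts = [o.candidate.interval.start for o in probe.oligos]
    assert cands[40].interval.start not in starts


def test_infeasible_constraints_error():
    cands, params = _toy_candidates()
    params.n_total = 100  # span far exceeds the sequence
    with pytest.raises(ValueError, match="span"):
        select_best_window(cands, params)


def test_design_pipeline_respects_all_filters():
    seq, _ = gen_genome(20_000, seed=1)
    params = DesignParams()
    probe = design_probe(seq, params=params, variant="design1")
    assert probe.min_gap() >= params.min_gap
    for o in probe.oligos:
        assert len(o.candidate.target_seq) == params.l
        assert params.gc_low <= o.candidate.gc_fraction <= params.gc_high
        assert o.candidate.max_run <= params.max_run_allowed
    donors = sum(o.dye_role == "donor" for o in probe.oligos)
    acceptors = len(probe.oligos) - donors
    assert abs(donors - acceptors) <= params.group_size


# ---------------------------------------------------------------------------
# assembly


@pytest.fixture
def assembled_probes():
    seq, _ = gen_genome(3000, seed=13)
    params = DesignParams(n_total=20)
    out = {}
    for variant in ("design1", "design2", "design3"):
        out[variant] = design_probe(seq, params=params, variant=variant)
    return out


def test_design1_full_length(assembled_probes):
    for o in assembled_probes["design1"].oligos:
        assert len(o.full_seq) == 100  # 20 + 60 + 20


def test_design2_stabilization_tails_anneal(assembled_probes):
    probe = assembled_probes["design2"]
    for o in probe.oligos:
        assert o.full_seq.startswith("TAATT") and o.full_seq.endswith("AATTA")
    for a, b in zip(probe.oligos, probe.oligos[1:]):
        # 3' tail of one oligo base-pairs with the 5' tail of the next
        assert revcomp(a.full_seq[-5:]) == b.full_seq[:5]


def test_design3_primaries_match_design1(assembled_probes):
    p1 = assembled_probes["design1"]
    p3 = assembled_probes["design3"]
    assert [o.full_seq for o in p1.oligos] == [o.full_seq for o in p3.oligos]
    det3 = {(d["dye_role"], d["side"]): d["sequence"] for d in p3.detection_oligos}
    det1 = {(d["dye_role"], d["side"]): d["sequence"] for d in p1.detection_oligos}
    for key, seq3 in det3.items():
        if key[1] == "L*":
            assert seq3 == "TAATT" + det1[key]
        else:
            assert seq3 == det1[key] + "AATTA"


def test_detection_oligos_are_adapter_revcomps(assembled_probes):
    probe = assembled_probes["design1"]
    roles = {o.dye_role: o for o in probe.oligos}
    for d in probe.detection_oligos:
        adapter = roles[d["dye_role"]].left_adapter if d["side"] == "L*" else roles[d["dye_role"]].right_adapter
        assert d["sequence"] == revcomp(adapter)


def test_bad_adapter_length_rejected(assembled_probes):
    probe = assembled_probes["design1"]
    with pytest.raises(ValueError, match="20 nt"):
        assemble_oligos(probe, adapters={"donor": ("ACGT", "A" * 20), "acceptor": ("C" * 20, "G" * 20)})


# ---------------------------------------------------------------------------
# export round trip


def test_export_roundtrip(tmp_path, assembled_probes):
    probe = assembled_probes["design2"]
    paths = export_probe(probe, tmp_path / "probe")
    back = import_probe(paths["tsv"])
    assert back.name == probe.name and back.design_variant == probe.design_variant
    assert len(back.oligos) == len(probe.oligos)
    for a, b in zip(probe.oligos, back.oligos):
        assert a.full_seq == b.full_seq
        assert a.dye_role == b.dye_role
        assert a.candidate.target_seq == b.candidate.target_seq
        assert a.candidate.interval == b.candidate.interval
        assert a.candidate.homology_penalty == b.candidate.homology_penalty
    # BED rows and unique FASTA headers
    bed_lines = (tmp_path / "probe.bed").read_text().strip().splitlines()
    assert len(bed_lines) == len(probe.oligos)
    headers = [l for l in (tmp_path / "probe.fa").read_text().splitlines() if l.startswith(">")]
    assert len(set(headers)) == len(probe.oligos)


def test_export_deterministic(tmp_path, assembled_probes):
    probe = assembled_probes["design1"]
    export_probe(probe, tmp_path / "a")
    export_probe(probe, tmp_path / "b")
    assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()
    assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_fret_layout_roles_alternate_by_group(seed):
    # dye-role pattern follows groups of group_size regardless of inputs
    params = DesignParams(n_total=12, group_size=2)
    _, roles = pdm._ideal_offsets(params)
    for i, r in enumerate(roles):
        assert r == ("donor" if (i // 2) % 2 == 0 else "acceptor")
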