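"""Contact-matrix I/O, insulation scoring (against a double-loop oracle),
TAD calling and locus lookup."""

import numpy as np
import pytest

from tadscope import (
    ContactMatrix,
    Locus,
    Tad,
    TadSet,
    call_tads,
    find_boundaries,
    insulation,
    load_tads_bed,
    locate_tad,
    read_contact_matrix,
    write_tads_bed,
)
from tadscope.hic import write_coo, write_dense


def insulation_oracle(m, w):
    """Brute-force square-window insulation, straight from the definition."""
    n = m.shape[0]
    raw = np.full(n, np.nan)
    for b in range(n):
        if b - w < 0 or b + w >= n:
            continue
        vals = [m[i, j] for i in range(b - w, b) for j in range(b + 1, b + 1 + w)]
        raw[b] = np.mean(vals)
    mean_raw = np.nanmean(raw)
    return np.log2(raw / mean_raw)


def block_matrix(n=30, boundary=15, intra=60.0, inter=10.0):
    m = np.full((n, n), inter)
    m[:boundary, :boundary] = intra
    m[boundary:, boundary:] = intra
    i = np.arange(n)
    m = m / (1.0 + np.abs(i[:, None] - i[None, :]))
    return m


# ----------------------------------------------------------------------
# I/O


def test_coo_upper_triangle_mirrors_to_full_matrix(tmp_path):
    path = tmp_path / "m.coo.tsv"
    with open(path, "w") as fh:
        fh.write("bin_i\tbin_j\tcount\n0\t1\t5\n1\t2\t3\n0\t0\t7\n")
    cm = read_contact_matrix(path, format="coo", bin_size=40_000, chrom="c", n_bins=3)
    assert cm.m[1, 0] == 5 and cm.m[0, 1] == 5 and cm.m[0, 0] == 7


def test_dense_coo_dense_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    u = rng.poisson(5.0, size=(12, 12))
    m = np.triu(u) + np.triu(u, 1).T
    write_dense(m, tmp_path / "d.tsv")
    cm1 = read_contact_matrix(tmp_path / "d.tsv", "dense", chrom="c")
    write_coo(cm1.m, tmp_path / "d.coo.tsv")
    cm2 = read_contact_matrix(tmp_path / "d.coo.tsv", "coo", chrom="c", n_bins=12)
    write_dense(cm2.m, tmp_path / "d2.tsv")
    assert open(tmp_path / "d.tsv").read() == open(tmp_path / "d2.tsv").read()
    assert np.array_equal(cm1.m, cm2.m)


def test_dense_reader_rejects_ragged_and_negative(tmp_path):
    ragged = tmp_path / "r.tsv"
    ragged.write_text("1\t2\n1\t2\t3\n")
    with pytest.raises(ValueError, match="line 2"):
        read_contact_matrix(ragged, "dense")
    neg = tmp_path / "n.tsv"
    neg.write_text("1\t-2\n-2\t1\n")
    with pytest.raises(ValueError, match="negative"):
        read_contact_matrix(neg, "dense")


def test_asymmetric_input_symmetrized_with_warning(tmp_path):
    path = tmp_path / "a.tsv"
    path.write_text("1\t5\n2\t1\n")
    with pytest.warns(UserWarning, match="symmetriz"):
        cm = read_contact_matrix(path, "dense", chrom="c")
    assert cm.m[0, 1] == 5 and cm.m[1, 0] == 5


# ----------------------------------------------------------------------
# insulation


def test_uniform_matrix_gives_zero_insulation():
    cm = ContactMatrix("c", 40_000, np.full((30, 30), 7.0))
    track = insulation(cm, w=5)
    defined = track.defined()
    assert np.allclose(track.score[defined], 0.0)
    assert np.isnan(track.score[:5]).all() and np.isnan(track.score[-5:]).all()


def test_window_one_reduces_to_single_cell():
    rng = np.random.default_rng(1)
    u = rng.poisson(9.0, size=(10, 10)).astype(float)
    m = np.triu(u) + np.triu(u, 1).T
    track = insulation(ContactMatrix("c", 40_000, m), w=1)
    for b in range(1, 9):
        assert track.raw[b] == m[b - 1, b + 1]


def test_insulation_matches_brute_force_oracle_on_random_matrices():
    rng = np.random.default_rng(2)
    for _ in range(25):
        u = rng.uniform(0.5, 20.0, size=(40, 40))
        m = np.triu(u) + np.triu(u, 1).T
        cm = ContactMatrix("c", 40_000, m)
        for w in (1, 3, 5):
            got = insulation(cm, w=w).score
            want = insulation_oracle(m, w)
            both = ~np.isnan(want)
            assert np.abs(got[both] - want[both]).max() < 1e-10
            assert np.isnan(got[~both]).all()


def test_insulation_requires_enough_bins_and_warns_on_zero_matrix():
    with pytest.raises(ValueError, match="bins"):
        insulation(ContactMatrix("c", 40_000, np.zeros((8, 8))), w=5)
    with pytest.warns(UserWarning, match="zero"):
        track = insulation(ContactMatrix("c", 40_000, np.zeros((20, 20))), w=3)
    assert np.isnan(track.score).all()


# ----------------------------------------------------------------------
# TAD calling


def test_block_boundary_is_the_insulation_minimum():
    m = block_matrix()
    track = insulation(ContactMatrix("c", 40_000, m), w=5)
    defined = np.flatnonzero(track.defined())
    argmin = defined[np.nanargmin(track.score[defined])]
    assert abs(argmin - 15) <= 1


def test_flat_track_yields_single_tad_spanning_defined_range():
    cm = ContactMatrix("c", 40_000, np.full((30, 30), 5.0))
    tads = call_tads(insulation(cm, w=5))
    assert len(tads) == 1
    (t,) = tads.tads
    assert (t.start_bp, t.end_bp) == (5 * 40_000, 25 * 40_000)


def test_infinite_delta_gives_no_boundaries():
    m = block_matrix()
    track = insulation(ContactMatrix("c", 40_000, m), w=5)
    assert find_boundaries(track, delta_min=np.inf) == []


def test_two_block_matrix_called_as_two_tads():
    m = block_matrix(n=40, boundary=20, intra=90.0, inter=10.0)
    track = insulation(ContactMatrix("c", 40_000, m), w=5)
    tads = call_tads(track)
    spans = [(t.start_bp // 40_000, t.end_bp // 40_000) for t in tads]
    assert len(spans) == 2
    assert abs(spans[0][1] - 20) <= 1


def test_sub_tad_second_pass_on_internal_structure():
    """A stringent coarse pass keeps whole parents; the finer half-window
    pass re-segments their internal sub-structure at its own threshold."""
    n = 60
    m = np.full((n, n), 8.0)
    for parent in (slice(0, 30), slice(30, 60)):
        m[parent, parent] = 40.0
    for sub in (slice(0, 15), slice(15, 30), slice(30, 45), slice(45, 60)):
        m[sub, sub] = 120.0  # internal sub-structure inside each parent
    i = np.arange(n)
    m = m / (1.0 + np.abs(i[:, None] - i[None, :]))
    cm = ContactMatrix("c", 40_000, m)
    track = insulation(cm, w=5)
    # parent/background contrast is 5x (depth log2 5 ~ 2.3); internal
    # contrast is 3x (~1.6) and stays below the coarse-pass cut of 2.0
    tads = call_tads(track, delta_min=2.0, cm=cm, sub=True, sub_delta=0.5)
    parents = [t for t in tads if t.level == "tad"]
    subs = [t for t in tads if t.level == "sub_tad"]
    assert any(abs(t.start_bp // 40_000 - 30) <= 1 for t in parents)
    assert subs, "expected sub-TADs from the second pass"
    sub_edges = {t.start_bp // 40_000 for t in subs} | {t.end_bp // 40_000 for t in subs}
    assert any(abs(e - 15) <= 1 for e in sub_edges)
    assert any(abs(e - 45) <= 1 for e in sub_edges)
    tads.validate()


# ----------------------------------------------------------------------
# BED round trip and validation


def test_tad_bed_round_trip_bit_exact(tmp_path):
    ts = TadSet(
        tads=[
            Tad("chr1", 400_000, 1_000_000, "tad"),
            Tad("chr1", 520_000, 760_000, "sub_tad"),
            Tad("chr2", 0, 600_000, "tad"),
        ]
    )
    path = tmp_path / "tads.bed"
    write_tads_bed(ts, path)
    back = load_tads_bed(path)
    assert back.to_frame().equals(
        TadSet(sorted(ts.tads, key=lambda t: (t.chrom, t.start_bp, t.level))).to_frame()
    )
    write_tads_bed(back, tmp_path / "tads2.bed")
    assert open(path).read() == open(tmp_path / "tads2.bed").read()


def test_overlapping_same_level_tads_rejected(tmp_path):
    path = tmp_path / "bad.bed"
    path.write_text("chr1\t0\t100\ttad\nchr1\t50\t150\ttad\n")
    with pytest.raises(ValueError, match="overlap"):
        load_tads_bed(path)


def test_sub_tad_must_nest_in_exactly_one_tad():
    ts = TadSet(tads=[Tad("chr1", 0, 100, "tad"), Tad("chr1", 150, 200, "sub_tad")])
    with pytest.raises(ValueError, match="nested"):
        ts.validate()


# ----------------------------------------------------------------------
# locus lookup


def test_locus_half_open_boundary_semantics():
    ts = TadSet(tads=[Tad("chr1", 100, 200, "tad")])
    assert len(locate_tad(ts, Locus("l", "chr1", 100))) == 1  # start inclusive
    assert locate_tad(ts, Locus("l", "chr1", 200)) == []  # end exclusive
    with pytest.warns(UserWarning, match="absent"):
        assert locate_tad(ts, Locus("l", "chrZ", 100)) == []


def test_locate_tad_agrees_with_linear_scan_oracle():
    rng = np.random.default_rng(3)
    starts = np.sort(rng.choice(np.arange(0, 10_000, 10), size=40, replace=False))
    tads = [Tad("chr1", int(s), int(s) + int(rng.integers(5, 10)), "tad") for s in starts[::2]]
    ts = TadSet(tads=tads)
    for _ in range(1000):
        pos = int(rng.integers(0, 10_100))
        got = {(t.start_bp, t.end_bp) for t in locate_tad(ts, Locus("l", "chr1", pos))}
        want = {(t.start_bp, t.end_bp) for t in tads if t.start_bp <= pos < t.end_bp}
        assert got == want


def test_planted_locus_tad_recovered_from_generated_hic(default_study):
    """Calling TADs on the generated matrices localizes each planted locus
    inside (within one bin of) its target TAD."""
    cfg = default_study.cfg
    for locus_cfg in cfg.loci_plan:
        m = default_study.contact_matrices[locus_cfg.chrom]
        cm = ContactMatrix(locus_cfg.chrom, cfg.bin_size, m)
        tads = call_tads(insulation(cm, w=5))
        hits = locate_tad(tads, Locus(locus_cfg.name, locus_cfg.chrom, locus_cfg.snp_pos))
        assert len(hits) == 1
        lo, hi = cfg.tad_span_bp(cfg.tad_plan[locus_cfg.target_tad])
        assert abs(hits[0].start_bp - lo) <= cfg.bin_size
        assert abs(hits[0].end_bp - hi) <= cfg.bin_size
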