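import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from loyscan.cn_index import (
    Arm,
    GenomeArms,
    SegmentRecord,
    SegParseError,
    aneuploidy_index,
    arm_index,
    arm_index_matrix,
    linearize,
    purity_adjust,
    read_seg,
    sample_indices,
    segments_by_sample,
    to_linear_cn,
    y_index,
)

from conftest import make_segments


# ---------------------------------------------------------------------------
# read_seg


def write_seg_text(tmp_path, text, name="test.seg"):
    path = tmp_path / name
    path.write_text(text)
    return path


HEADER = "Sample\tChromosome\tStart\tEnd\tNum_Probes\tSegment_Mean\n"


def test_read_seg_coordinate_convention(tmp_path):
    path = write_seg_text(tmp_path, HEADER + "S1\tchrY\t1\t100\t10\t0.0\n")
    (rec,) = read_seg(path)
    assert rec.sample_id == "S1"
    assert rec.chromosome == "Y"
    assert rec.start == 0 and rec.end == 100
    assert rec.n_markers == 10


def test_read_seg_unknown_chromosome(tmp_path):
    path = write_seg_text(tmp_path, HEADER + "S1\tMT\t1\t100\t10\t0.0\n")
    with pytest.raises(SegParseError, match="line|:2"):
        read_seg(path)


def test_read_seg_bad_coordinates(tmp_path):
    path = write_seg_text(tmp_path, HEADER + "S1\t1\t200\t100\t10\t0.0\n")
    with pytest.raises(SegParseError, match=":2"):
        read_seg(path)


def test_read_seg_non_numeric_value(tmp_path):
    path = write_seg_text(tmp_path, HEADER + "S1\t1\t1\t100\t10\tNOPE\n")
    with pytest.raises(SegParseError, match=":2"):
        read_seg(path)


def test_read_seg_empty_file_warns(tmp_path, caplog):
    path = write_seg_text(tmp_path, HEADER)
    with caplog.at_level("WARNING"):
        records = read_seg(path)
    assert records == []
    assert any("no segments" in r.message for r in caplog.records)


def test_read_seg_bad_scale(tmp_path):
    path = write_seg_text(tmp_path, HEADER)
    with pytest.raises(ValueError, match="value_scale"):
        read_seg(path, value_scale="copies")


# ---------------------------------------------------------------------------
# to_linear_cn


@pytest.mark.parametrize(
    "value, scale, expected",
    [
        (0.0, "log2ratio", 2.0),
        (-1.0, "log2ratio", 1.0),
        (0.585, "log2ratio", 3.0000779785716363),  # 2 * 2**0.585
        (1.7, "linear", 1.7),
    ],
)
def test_to_linear_cn(value, scale, expected):
    assert to_linear_cn(value, scale) == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# arm_index


ARM = Arm("1", "p", 0, 1000)


def test_arm_index_full_coverage_diploid():
    segs = make_segments("S", [("1", 0, 1000, 2.0)])
    idx, cov = arm_index(segs, ARM)
    assert idx == pytest.approx(2.0)
    assert cov == pytest.approx(1.0)


def test_arm_index_symmetry():
    segs = make_segments("S", [("1", 0, 500, 1.0), ("1", 500, 1000, 3.0)])
    idx, cov = arm_index(segs, ARM)
    assert idx == pytest.approx(2.0)
    assert cov == pytest.approx(1.0)


def test_arm_index_partial_coverage_weighted():
    # 30% of the arm at CN 1, 70% at CN 2 -> 0.3*1 + 0.7*2 = 1.7
    segs = make_segments("S", [("1", 0, 300, 1.0), ("1", 300, 1000, 2.0)])
    idx, cov = arm_index(segs, ARM)
    assert idx == pytest.approx(1.7)
    assert cov == pytest.approx(1.0)


def test_arm_index_uncovered_is_absent():
    idx, cov = arm_index([], ARM)
    assert math.isnan(idx)
    assert cov == 0.0


def test_arm_index_respects_exclusions():
    # exclusion masks the CN-5 half entirely
    segs = make_segments("S", [("1", 0, 500, 2.0), ("1", 500, 1000, 5.0)])
    idx, cov = arm_index(segs, ARM, exclusions=[(500, 1000)])
    assert idx == pytest.approx(2.0)
    assert cov == pytest.approx(1.0)


def per_base_index(segments, arm, exclusions=()):
    """Brute-force oracle: explicit per-base average over the masked arm."""
    excluded = set()
    for s, e in exclusions:
        excluded.update(range(max(s, arm.start), min(e, arm.end)))
    values = {}
    for seg in segments:
        if seg.chromosome != arm.chromosome:
            continue
        for base in range(max(seg.start, arm.start), min(seg.end, arm.end)):
            if base not in excluded:
                values[base] = seg.value
    masked_len = arm.length - len(excluded)
    if not values:
        return float("nan"), 0.0
    return sum(values.values()) / len(values), len(values) / masked_len


def test_arm_index_matches_per_base_oracle_random():
    rng = np.random.default_rng(7)
    for trial in range(100):
        n_arms = rng.integers(1, 6)
        arms = []
        pos = 0
        for j in range(n_arms):
            length = int(rng.integers(50, 400))
            arms.append(Arm("1", f"a{j}", pos, pos + length))
            pos += length + int(rng.integers(0, 50))
        segs = []
        for _ in range(int(rng.integers(0, 21))):
            start = int(rng.integers(0, pos))
            end = start + int(rng.integers(1, 200))
            segs.append(SegmentRecord("S", "1", start, end, None,
                                      float(rng.uniform(0, 4))))
        arm = arms[int(rng.integers(0, n_arms))]
        exclusions = []
        if rng.random() < 0.5:
            ex_start = int(rng.integers(arm.start, arm.end))
            exclusions.append((ex_start, ex_start + int(rng.integers(1, 100))))
        # non-overlapping segments only: the weighted mean is defined segment-wise
        segs = _drop_overlaps(segs)
        got_idx, got_cov = arm_index(segs, arm, exclusions)
        exp_idx, exp_cov = per_base_index(segs, arm, exclusions)
        if math.isnan(exp_idx):
            assert math.isnan(got_idx)
        else:
            assert got_idx == pytest.approx(exp_idx, abs=1e-9)
            assert got_cov == pytest.approx(exp_cov, abs=1e-9)


def _drop_overlaps(segments):
    kept = []
    occupied = []
    for seg in segments:
        if all(seg.end <= s or seg.start >= e for s, e in occupied):
            kept.append(seg)
            occupied.append((seg.start, seg.end))
    return kept


# ---------------------------------------------------------------------------
# purity_adjust


def test_purity_adjust_pure_tumor():
    assert purity_adjust(1.0, 1.0, 1) == pytest.approx(1.0)


def test_purity_adjust_inverts_mixture():
    # 0.5 * x + 0.5 * 1 = 0.75  ->  x = 0.5
    assert purity_adjust(0.75, 0.5, 1) == pytest.approx(0.5)


def test_purity_adjust_floor_at_zero():
    assert purity_adjust(0.3, 0.5, 1) == 0.0


def test_purity_adjust_missing_purity_passthrough():
    assert purity_adjust(1.23, None, 2) == 1.23


def test_purity_adjust_zero_purity_errors():
    with pytest.raises(ValueError, match="purity"):
        purity_adjust(1.0, 0.0, 1)


@given(
    p=st.floats(0.01, 1.0),
    c=st.sampled_from([1.0, 2.0]),
    t=st.floats(0.0, 6.0),
)
@settings(max_examples=200, deadline=None)
def test_purity_inversion_property(p, c, t):
    observed = p * t + (1 - p) * c
    assert purity_adjust(observed, p, c) == pytest.approx(t, abs=1e-9)


# ---------------------------------------------------------------------------
# y_index


def test_y_index_single_segment(toy_genome):
    segs = make_segments("S", [("Y", 0, 1200, 1.0)])
    assert y_index(segs, toy_genome, purity=1.0) == pytest.approx(1.0)


def test_y_index_arm_specific_loss(toy_genome):
    # Yp at CN 1, Yq at CN 0: index = masked Yp length / total masked length
    segs = make_segments("S", [("Y", 0, 500, 1.0), ("Y", 600, 1200, 0.0)])
    yp_len = toy_genome.masked_length(toy_genome.arm("Yp"))
    yq_len = toy_genome.masked_length(toy_genome.arm("Yq"))
    expected = yp_len / (yp_len + yq_len)
    got = y_index(segs, toy_genome, purity=1.0)
    assert 0 < got < 1
    assert got == pytest.approx(expected)


def test_y_index_msy_masks_pars(genome):
    # CN 5 inside the PARs must not leak into the index
    segs = make_segments("S", [
        ("Y", 10000, 2649520, 5.0),       # PAR1 exactly
        ("Y", 2649520, 10104553, 1.0),    # rest of Yp
        ("Y", 13104553, 59034049, 1.0),   # Yq up to PAR2
        ("Y", 59034049, 59363566, 5.0),   # PAR2 exactly
    ])
    assert y_index(segs, genome, purity=1.0) == pytest.approx(1.0)


def test_y_index_absent_without_coverage(toy_genome, caplog):
    segs = make_segments("S", [("1", 0, 1000, 2.0)])
    with caplog.at_level("WARNING"):
        assert math.isnan(y_index(segs, toy_genome))
    assert any("Y coverage" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# aneuploidy_index


def test_aneuploidy_all_diploid(toy_genome):
    indices = {"1p": 2.0, "1q": 2.0, "2p": 2.0, "2q": 2.0}
    assert aneuploidy_index(indices, toy_genome) == pytest.approx(0.0)


def test_aneuploidy_single_gain(toy_genome):
    indices = {"1p": 3.0, "1q": 2.0, "2p": 2.0, "2q": 2.0}
    assert aneuploidy_index(indices, toy_genome) == pytest.approx(1.0)


def test_aneuploidy_brute_force_sum(toy_genome):
    indices = {"1p": 1.5, "1q": 2.5, "2p": 2.0, "2q": 2.0}
    expected = sum(abs(2 - v) for v in indices.values())
    assert aneuploidy_index(indices, toy_genome) == pytest.approx(expected)
    assert expected == 1.0


def test_aneuploidy_skips_excluded_arms(genome):
    indices = {"13p": 0.0, "1p": 2.0}
    assert aneuploidy_index(indices, genome) == pytest.approx(0.0)


def test_aneuploidy_monotone_in_loss(toy_genome):
    base = {"1p": 2.0, "1q": 2.0, "2p": 2.0, "2q": 2.0}
    previous = aneuploidy_index(base, toy_genome)
    for cn in (1.8, 1.5, 1.0, 0.5, 0.0):
        base["1q"] = cn
        current = aneuploidy_index(base, toy_genome)
        assert current >= previous
        previous = current


# ---------------------------------------------------------------------------
# scale invariance and the high-level table


def test_scale_invariance_of_indices(toy_genome):
    linear_rows = [("Y", 60, 1100, 1.0), ("1", 0, 1000, 3.0), ("1", 1200, 2000, 2.0),
                   ("2", 0, 600, 1.0), ("2", 700, 1500, 2.0)]
    linear_segs = make_segments("S", linear_rows)
    log_segs = make_segments(
        "S", [(c, s, e, math.log2(v / 2) if v > 0 else -20) for c, s, e, v in linear_rows]
    )
    relinearized = linearize(log_segs, "log2ratio")
    y_lin = y_index(linear_segs, toy_genome, purity=0.8)
    y_log = y_index(relinearized, toy_genome, purity=0.8)
    assert y_lin == pytest.approx(y_log, abs=1e-9)

    arm_values_lin = {
        a.name: arm_index(linear_segs, a)[0] for a in toy_genome.autosomal_arms()
    }
    arm_values_log = {
        a.name: arm_index(relinearized, a)[0] for a in toy_genome.autosomal_arms()
    }
    assert aneuploidy_index(arm_values_lin, toy_genome, purity=0.8) == pytest.approx(
        aneuploidy_index(arm_values_log, toy_genome, purity=0.8), abs=1e-9
    )


def test_sample_indices_frame(toy_genome):
    segs = make_segments("A", [("1", 0, 1000, 3.0), ("1", 1200, 2000, 2.0),
                               ("2", 0, 600, 2.0), ("2", 700, 1500, 2.0),
                               ("Y", 60, 1100, 1.0)])
    segs += make_segments("B", [("1", 0, 1000, 2.0), ("1", 1200, 2000, 2.0),
                                ("2", 0, 600, 2.0), ("2", 700, 1500, 2.0)])
    table = sample_indices(
        segments_by_sample(segs), toy_genome,
        purity={"A": 1.0}, sex={"A": "male", "B": "female"},
    )
    assert table.loc["A", "aneuploidy_index"] == pytest.approx(1.0)
    assert table.loc["A", "y_index"] == pytest.approx(1.0)
    assert bool(table.loc["A", "purity_adjusted"])
    assert math.isnan(table.loc["B", "y_index"])  # females carry no Y rows
    assert not bool(table.loc["B", "purity_adjusted"])


def test_arm_index_matrix_shape(toy_genome):
    segs = make_segments("A", [("1", 0, 1000, 2.0)])
    matrix = arm_index_matrix(segments_by_sample(segs), toy_genome)
    assert matrix.index.shape == (1, len(toy_genome.arms))
    assert matrix.index.loc["A", "1p"] == pytest.approx(2.0)
    assert matrix.covered_fraction.loc["A", "1q"] == 0.0
    assert matrix.low_confidence().loc["A", "1q"]


def test_genome_arms_packaged_table(genome):
    assert len(genome.arms) == 48
    assert genome.excluded_arms == {"13p", "14p", "15p", "22p"}
    assert len(genome.autosomal_arms()) == 40
    y_masked = sum(genome.masked_length(a) for a in genome.arms_of("Y"))
    y_total = sum(a.length for a in genome.arms_of("Y"))
    assert y_masked < y_total  # PARs removed
    exclude_21p = GenomeArms.grch37(exclude_21p=True)
    assert "21p" in exclude_21p.excluded_arms
    assert len(exclude_21p.autosomal_arms()) == 39
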