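"""Core estimator: coarse-graining, pattern counting, SampEn, MSE."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from segmse import (
    DegenerateSignalError,
    EntropyParams,
    InvalidScaleError,
    SegmentSet,
    SegmentTooShortError,
    coarse_grain,
    count_pattern_pairs,
    max_scale,
    mse,
    n_pattern_comparisons,
    sample_entropy,
)

from _oracles import (
    brute_force_counts,
    brute_force_sampen,
    continuous_mse_reference,
)


@pytest.mark.parametrize(
    "segment, s, expected",
    [
        ([1, 2, 3, 4, 5, 6], 2, [1.5, 3.5, 5.5]),
        ([1, 2, 3, 4, 5, 6, 7], 3, [2.0, 5.0]),  # trailing 7 dropped
        ([3.0, 1.0, 4.0], 1, [3.0, 1.0, 4.0]),
    ],
)
def test_coarse_grain_averages_nonoverlapping_windows(segment, s, expected):
    np.testing.assert_array_equal(coarse_grain(segment, s), expected)


@pytest.mark.parametrize("bad_scale", [0, -1, 7])
def test_coarse_grain_rejects_out_of_range_scales(bad_scale):
    with pytest.raises(InvalidScaleError):
        coarse_grain([1, 2, 3, 4, 5, 6], bad_scale)


@pytest.mark.parametrize(
    "n, m, expected", [(16, 2, 5), (1024, 2, 341), (3, 2, 1), (100, 1, 50)]
)
def test_max_scale_floor_rule(n, m, expected):
    assert max_scale(n, m) == expected


def test_max_scale_rejects_too_short_segments():
    with pytest.raises(SegmentTooShortError):
        max_scale(2, 2)


@pytest.mark.parametrize(
    "segments, m, tol, expected",
    [
        # all-equal segment: both m-templates extend to matching triples
        ([[0, 0, 0, 0]], 2, 0.1, (1, 1)),
        # identical segments match across the border-free pooled count
        ([[1, 2, 3], [1, 2, 3]], 2, 0.5, (1, 1)),
    ],
)
def test_count_pattern_pairs_hand_examples(segments, m, tol, expected):
    assert count_pattern_pairs(SegmentSet(segments), m, tol) == expected


def test_count_pattern_pairs_everything_matches_at_huge_tolerance(rng):
    segs = [rng.normal(size=7) for _ in range(3)]
    total_templates = sum(len(s) - 2 for s in segs)
    expect = total_templates * (total_templates - 1) // 2
    B, A = count_pattern_pairs(SegmentSet(segs), 2, 1e9)
    assert (B, A) == (expect, expect)


def test_count_pattern_pairs_error_names_offending_segment():
    with pytest.raises(SegmentTooShortError, match="segment 1"):
        count_pattern_pairs(
            SegmentSet([[1, 2, 3, 4], [1, 2]], allow_unequal=True), 2, 0.5)


@settings(max_examples=80, derandomize=True, deadline=None)
@given(
    data=st.data(),
    m=st.sampled_from([1, 2]),
    tol=st.floats(0.05, 3.0),
)
def test_counts_match_brute_force_enumeration(data, m, tol):
    """Kernel equals plain-Python pair enumeration on small segment sets."""
    n_segs = data.draw(st.integers(1, 3))
    segs = [
        data.draw(
            st.lists(
                st.floats(-5, 5, allow_nan=False, allow_infinity=False,
                          width=32),
                min_size=m + 1,
                max_size=8,
            )
        )
        for _ in range(n_segs)
    ]
    segset = SegmentSet(segs, allow_unequal=True)
    assert count_pattern_pairs(segset, m, tol) == \
        brute_force_counts(segs, m, tol)


def test_sampen_matches_brute_force_on_small_literal_series(rng):
    for m in (1, 2):
        for _ in range(20):
            x = rng.normal(size=8)
            got = sample_entropy(SegmentSet([x]), EntropyParams(m=m),
                                 tol=0.7)
            want = brute_force_sampen([x], m, 0.7)
            if np.isnan(want):
                assert not got.defined
            else:
                assert got.value == pytest.approx(want, abs=0)


def test_periodic_signal_has_zero_entropy():
    x = [1.0, 5.0, 9.0] * 20
    res = sample_entropy(SegmentSet([x]), EntropyParams(m=2), tol=0.5)
    assert res.defined
    assert res.A == res.B
    assert res.value == 0.0


def test_undefined_sampen_carries_counts():
    # one matching m-pair whose extensions diverge: B=1, A=0 -> undefined
    x = [0.0, 0.01, 10.0, 0.0, 0.01, 20.0]
    res = sample_entropy(SegmentSet([x]), EntropyParams(m=2), tol=0.1)
    assert not res.defined
    assert (res.B, res.A) == (1, 0)
    assert np.isnan(float(res))


def test_counts_invariant_to_segment_permutation(rng):
    segs = [rng.normal(size=9) for _ in range(4)]
    base = count_pattern_pairs(SegmentSet(segs), 2, 0.5)
    for _ in range(3):
        order = rng.permutation(4)
        shuffled = count_pattern_pairs(
            SegmentSet([segs[i] for i in order]), 2, 0.5)
        assert shuffled == base


def test_counts_decompose_over_segment_pairs(rng):
    """Pooled counts = within-segment + cross-segment pair contributions.

    This is the border-safety property: adding or removing other segments
    never alters the count contributed by a given pair of segments.
    """
    segs = [rng.normal(size=8) for _ in range(3)]
    tol = 0.6

    def count(subset):
        return np.array(count_pattern_pairs(SegmentSet(subset), 2, tol))

    full = count(segs)
    within = sum(count([s]) for s in segs)
    cross = sum(
        count([segs[i], segs[j]]) - count([segs[i]]) - count([segs[j]])
        for i in range(3) for j in range(i + 1, 3)
    )
    np.testing.assert_array_equal(full, within + cross)


def test_affine_invariance_with_data_derived_tolerance(rng):
    x = rng.normal(size=200)
    params = EntropyParams()
    base = sample_entropy(SegmentSet([x]), params)
    shifted = sample_entropy(SegmentSet([2.0 * x + 3.0]), params)
    assert (base.B, base.A) == (shifted.B, shifted.A)
    assert base.value == shifted.value


def test_single_segment_equals_continuous_reference_bitwise(rng):
    """j=1 code path is bit-identical to an independent continuous MSE."""
    x = rng.normal(size=300)
    scales = [1, 2, 3, 5, 8]
    prof = mse(SegmentSet.from_continuous(x), EntropyParams(), scales)
    ref = continuous_mse_reference(x, 2, 0.5, scales)
    np.testing.assert_array_equal(prof.entropy, ref)


def test_mse_profile_bookkeeping(rng):
    segs = [rng.normal(size=64) for _ in range(5)]
    segset = SegmentSet(segs)
    prof = mse(segset, EntropyParams(), scales=range(1, 8))
    assert np.all(prof.A <= prof.B)
    assert np.all(prof.entropy[prof.defined] >= 0)
    # tolerance fixed once from native data, reused at all scales
    assert prof.tolerance == 0.5 * segset.pooled_sd()
    # template bookkeeping at the coarse-grained length
    for i, s in enumerate(prof.scales):
        assert prof.n_comparisons[i] == n_pattern_comparisons(64 // s, 5, 2)


def test_mse_rejects_scales_beyond_max():
    segset = SegmentSet([np.arange(16.0)])
    with pytest.raises(InvalidScaleError):
        mse(segset, EntropyParams(), scales=[1, 6])  # max is 16//3 = 5


def test_mse_rejects_degenerate_signal():
    with pytest.raises(DegenerateSignalError):
        mse(SegmentSet([[1.0] * 10]), EntropyParams(), scales=[1])


def test_external_sd_policy_controls_tolerance(rng):
    x = rng.normal(size=100)
    params = EntropyParams(sd_policy="external")
    prof = mse(SegmentSet([x]), params, scales=[1], sd=2.5)
    assert prof.tolerance == 0.5 * 2.5
    with pytest.raises(ValueError):
        mse(SegmentSet([x]), params, scales=[1])  # sd missing


def test_unequal_segments_rejected_unless_flagged(rng):
    segs = [rng.normal(size=10), rng.normal(size=12)]
    with pytest.raises(ValueError, match="unequal"):
        SegmentSet(segs)
    segset = SegmentSet(segs, allow_unequal=True)
    assert segset.n == 10  # max scale follows the shortest segment
    assert segset.max_scale(2) == 3


@pytest.mark.parametrize(
    "n, j, m, expected", [(128, 10, 2, 1260), (3, 1, 2, 1), (3, 100, 2, 100)]
)
def test_n_pattern_comparisons_formula(n, j, m, expected):
    assert n_pattern_comparisons(n, j, m) == expected


def test_entropy_params_validation():
    with pytest.raises(ValueError):
        EntropyParams(m=0)
    with pytest.raises(ValueError):
        EntropyParams(r=-0.1)
    with pytest.raises(ValueError):
        EntropyParams(sd_policy="per-segment")
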