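import numpy as np
import pytest

from euglenakit.bts import (
    BTSParams,
    KYTE_DOOLITTLE,
    call_tmds,
    classify_bts,
    hydropathy_profile,
    transit_features,
)
from euglenakit.simulate import SimParams, generate_proteins


def brute_profile(aa, window):
    h = window // 2
    out = []
    for i in range(len(aa)):
        seg = aa[max(0, i - h) : min(len(aa), i + h + 1)]
        out.append(sum(KYTE_DOOLITTLE.get(a, 0.0) for a in seg) / len(seg))
    return out


def test_uniform_leucine_center_score():
    prof = hydropathy_profile("L" * 19, window=19)
    assert prof.scores[9] == pytest.approx(3.8)


def test_uniform_lysine_center_score():
    prof = hydropathy_profile("K" * 19, window=19)
    assert prof.scores[9] == pytest.approx(-3.9)


def test_profile_matches_brute_force():
    rng = np.random.default_rng(12)
    aa = "".join(np.array(list("ACDEFGHIKLMNPQRSTVWYX"))[rng.integers(0, 21, 200)])
    prof = hydropathy_profile(aa, window=19)
    assert np.allclose(prof.scores, brute_profile(aa, 19))
    assert len(prof) == len(aa)
    assert prof.scores.min() >= -4.5 and prof.scores.max() <= 4.5


def test_profile_rejects_even_or_tiny_window():
    with pytest.raises(ValueError):
        hydropathy_profile("LLLL", window=18)
    with pytest.raises(ValueError):
        hydropathy_profile("LLLL", window=3)


def test_empty_profile():
    assert len(hydropathy_profile("", 19)) == 0


def test_call_tmds_all_hydrophilic_is_empty():
    assert call_tmds(hydropathy_profile("K" * 60, 19)) == []


def test_call_tmds_two_hydrophobic_blocks():
    rng = np.random.default_rng(13)
    mid = "".join(np.array(list("STK"))[rng.integers(0, 3, 60)])
    aa = "L" * 20 + mid + "L" * 20
    calls = call_tmds(hydropathy_profile(aa, 19))
    assert len(calls) == 2
    assert calls[0].start == 0 and abs(calls[1].end - len(aa)) <= 1
    # oracle: direct run-length scan of the score vector
    scores = brute_profile(aa, 19)
    runs = []
    s = None
    for i, v in enumerate(scores + [-9]):
        if v >= 1.6 and s is None:
            s = i
        elif v < 1.6 and s is not None:
            runs.append((s, i))
            s = None
    runs = [r for r in runs if r[1] - r[0] >= 15]
    assert [(c.start, c.end) for c in calls] == runs


def test_call_tmds_merges_across_small_gap():
    # two hydrophobic runs separated by 2 sub-threshold positions merge
    class FakeProfile:
        scores = np.array([3.0] * 10 + [0.0] * 2 + [3.0] * 10)

    calls = call_tmds(FakeProfile(), threshold=1.6, min_tmd_len=15, merge_gap=3)
    assert len(calls) == 1 and (calls[0].start, calls[0].end) == (0, 22)
    assert call_tmds(FakeProfile(), threshold=1.6, min_tmd_len=15, merge_gap=1) == []


def test_transit_features_counting():
    assert transit_features("SSTTKKR")[:2] == (3, pytest.approx(4 / 7))
    charge, st, _ = transit_features("DDEE")
    assert charge == -4 and st == 0.0
    with pytest.raises(ValueError):
        transit_features("")


@pytest.fixture(scope="module")
def class_one():
    params = SimParams(seed=1, n_transcripts=1, spacing_tol=0)
    (aa, cls, spans) = generate_proteins(1, seed=1, params=params, bts_class="I")[0]
    return aa, spans


class TestClassify:
    def test_planted_class_one_recovered(self, class_one):
        aa, spans = class_one
        call = classify_bts(aa)
        assert call.bts_class == "I" and not call.flags
        assert abs(call.anchor_start_offset - spans["anchor"][0]) <= 2

    def test_anchor_deleted_becomes_class_two(self, class_one):
        aa, spans = class_one
        s, e = spans["anchor"]
        call = classify_bts(aa[:s] + aa[e:])
        assert call.bts_class == "II" and call.anchor_span is None

    def test_hydrophilic_protein_is_none(self):
        rng = np.random.default_rng(14)
        aa = "M" + "".join(np.array(list("STKRGNQDE"))[rng.integers(0, 9, 199)])
        call = classify_bts(aa)
        assert call.bts_class == "none" and "no_signal_tmd" in call.flags

    def test_atypical_spacing_flag_and_strict_mode(self, class_one):
        aa, spans = class_one
        s, _ = spans["anchor"]
        # move the anchor 15 residues downstream by stretching the transit
        stretched = aa[:s] + "STKSGNSQTKSGNSQ" + aa[s:]
        lenient = classify_bts(stretched)
        assert lenient.bts_class == "I" and "atypical_spacing" in lenient.flags
        strict = classify_bts(stretched, BTSParams(strict=True))
        assert strict.bts_class == "none"

    def test_too_short_protein(self):
        call = classify_bts("M" + "L" * 40)
        assert call.bts_class == "none" and "too_short" in call.flags

    def test_c_terminal_extension_never_changes_call(self, class_one):
        aa, _ = class_one
        rng = np.random.default_rng(15)
        base = classify_bts(aa)
        for n_extra in (1, 40, 400):
            extra = "".join(np.array(list("ACDEFGHIKLMNPQRSTVWY"))[rng.integers(0, 20, n_extra)])
            call = classify_bts(aa + extra)
            assert (call.bts_class, call.signal_span, call.transit_span,
                    call.anchor_span) == (base.bts_class, base.signal_span,
                                          base.transit_span, base.anchor_span)

    def test_exclusivity_and_span_nesting(self):
        protos = generate_proteins(150, seed=16)
        for aa, _cls, _spans in protos:
            call = classify_bts(aa)
            assert call.bts_class in ("I", "II", "none")
            if call.bts_class == "none":
                assert call.anchor_span is None
            else:
                assert call.signal_span is not None and call.transit_span is not None
                assert call.transit_span[1] <= 120
                if call.bts_class == "I":
                    assert call.anchor_span[0] >= call.transit_span[1]
                else:
                    assert call.anchor_span is None

    def test_spacing_anchor_alternative(self, class_one):
        aa, spans = class_one
        call = classify_bts(aa, BTSParams(spacing_anchor="tmd1_end", spacing_mean=40,
                                          spacing_tol=12))
        assert call.bts_class == "I"

    def test_class_balance_mirrors_default_mix(self):
        protos = generate_proteins(400, seed=18)
        calls = [classify_bts(aa) for aa, _, _ in protos]
        n1 = sum(c.bts_class == "I" for c in calls)
        n2 = sum(c.bts_class == "II" for c in calls)
        assert n1 > n2 > 0
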