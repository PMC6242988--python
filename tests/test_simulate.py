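import numpy as np
import pytest

from euglenakit.seqio import revcomp
from euglenakit.simulate import (
    SL_CORE_LEN,
    SL_EGRACILIS,
    SimParams,
    generate_proteins,
    generate_reads,
    generate_transcriptome,
    truth_to_tsv,
)

CORE = SL_EGRACILIS[-SL_CORE_LEN:]


def test_sl_quota_is_exact(default_sim_1000):
    params, _, truths = default_sim_1000
    planted = sum(t.sl_status != "absent" for t in truths)
    assert planted == round(params.sl_fraction * params.n_transcripts) == 485


def test_core_is_seven_nt_suffix_of_full_sl():
    assert CORE == "TTTTTCG" and SL_EGRACILIS.endswith(CORE)


def test_planted_sl_always_retains_core(default_sim_1000):
    _, _, truths = default_sim_1000
    for t in truths:
        if t.sl_status != "absent":
            assert t.sl_suffix_len >= SL_CORE_LEN
            assert t.original_sequence.startswith(SL_EGRACILIS[-t.sl_suffix_len :])


def test_truth_sequence_consistency(default_sim_1000):
    """Re-deriving orientation, SL status and CDS span from the emitted
    sequence matches the truth record for every transcript."""
    _, contigs, truths = default_sim_1000
    for c, t in zip(contigs, truths):
        forward = c.residues if t.orientation == "forward" else revcomp(c.residues)
        assert forward == t.original_sequence[t.truncated_5prime_nt :]
        if t.sl_core_survives:
            assert CORE in forward[:35]
        span = t.emitted_cds_span()
        if span is not None and t.orientation == "forward":
            s, e = span
            # planted CDS translates back to the planted protein
            from euglenakit.orfs import CODON_TO_AA

            cds = c.residues[s:e]
            aa = "".join(CODON_TO_AA.get(cds[i : i + 3], "*") for i in range(0, len(cds) - 3, 3))
            assert aa == t.aa_sequence


def test_forced_class_I_anchor_position():
    params = SimParams(seed=1, n_transcripts=1, bts_mix=(1.0, 0.0, 0.0), spacing_tol=0)
    _, truths = generate_transcriptome(params)
    assert truths[0].anchor_span[0] == 60


def test_revcomp_contigs_carry_core_when_planted():
    params = SimParams(seed=3, n_transcripts=25, revcomp_fraction=1.0)
    contigs, truths = generate_transcriptome(params)
    for c, t in zip(contigs, truths):
        assert t.orientation == "revcomp"
        assert (CORE in revcomp(c.residues)[:35]) == t.sl_core_survives


def test_determinism_identical_outputs():
    p = SimParams(seed=17, n_transcripts=40)
    a = generate_transcriptome(p)
    b = generate_transcriptome(SimParams(seed=17, n_transcripts=40))
    assert [c.residues for c in a[0]] == [c.residues for c in b[0]]
    assert a[1] == b[1]


def test_truncation_only_hits_sl_negative_by_default(default_sim_1000):
    _, _, truths = default_sim_1000
    for t in truths:
        if t.sl_status != "absent":
            assert t.truncated_5prime_nt == 0


def test_truncate_sl_positive_flag_can_remove_core():
    params = SimParams(seed=8, n_transcripts=300, truncate_sl_positive=True,
                       truncation_prob=0.5)
    _, truths = generate_transcriptome(params)
    clipped = [t for t in truths if t.sl_status != "absent" and t.truncated_5prime_nt > 0]
    assert clipped, "expected some truncated SL-positive transcripts"
    assert any(not t.sl_core_survives for t in clipped)


def test_planted_transit_peptides_satisfy_composition():
    protos = generate_proteins(100, seed=9, bts_class="I")
    for aa, _cls, spans in protos:
        s, e = spans["transit"]
        tp = aa[s:e]
        st = sum(a in "ST" for a in tp) / len(tp)
        charge = sum(a in "KR" for a in tp) - sum(a in "DE" for a in tp)
        assert st >= 0.2 and charge >= 2


def test_class_I_signal_is_hydrophobic():
    protos = generate_proteins(50, seed=10, bts_class="I")
    for aa, _cls, spans in protos:
        assert sum(a in "LAVIF" for a in aa[:15]) >= 8


def test_infeasible_params_rejected():
    with pytest.raises(ValueError):
        SimParams(seed=1, orf_length_range=(10, 50))
    with pytest.raises(ValueError):
        SimParams(seed=1, sl_fraction=1.5)
    with pytest.raises(ValueError):
        SimParams(seed=1, read_length=400)


@pytest.fixture(scope="module")
def clean_reads():
    params = SimParams(seed=21, n_transcripts=2, sl_fraction=1.0, error_rate=0.0,
                       truncation_prob=0.0, revcomp_fraction=0.0)
    contigs, truths = generate_transcriptome(params)
    m1, m2 = generate_reads(contigs, truths, params)
    return params, truths, m1, m2


class TestReads:
    def test_read_length_is_80(self, clean_reads):
        _, _, m1, m2 = clean_reads
        assert all(len(r) == 80 for r in m1 + m2)

    def test_error_free_reads_are_exact_substrings(self, clean_reads):
        _, truths, m1, m2 = clean_reads
        templates = {t.transcript_id: t.original_sequence for t in truths}
        for r in m1 + m2:
            tid = r.id.rsplit("_", 1)[0]
            tmpl = templates[tid]
            assert r.residues in tmpl or revcomp(r.residues) in tmpl

    def test_reads_cover_the_five_prime_terminus(self, clean_reads):
        _, truths, m1, _ = clean_reads
        t = truths[0]
        n_terminal = sum(r.id.startswith(t.transcript_id)
                         and r.residues == t.original_sequence[:80] for r in m1)
        assert n_terminal >= 2

    def test_coverage_within_20pct_for_long_transcripts(self, clean_reads):
        params, truths, m1, m2 = clean_reads
        for t in truths:
            L = len(t.original_sequence)
            if L < 2 * params.insert_mean:
                continue
            nt = sum(80 for r in m1 + m2 if r.id.startswith(t.transcript_id + "_"))
            assert 0.8 * params.coverage <= nt / L <= 1.2 * params.coverage

    def test_reads_deterministic(self, clean_reads):
        params, truths, m1, _ = clean_reads
        contigs, truths2 = generate_transcriptome(params)
        n1, _ = generate_reads(contigs, truths2, params)
        assert [(r.id, r.residues) for r in n1] == [(r.id, r.residues) for r in m1]

    def test_short_transcript_skipped_with_warning(self):
        from euglenakit.seqio import NucSequence

        params = SimParams(seed=2, n_transcripts=1)
        with pytest.warns(UserWarning, match="skipped"):
            m1, m2 = generate_reads([NucSequence(id="t", residues="ACGT")], [], params)
        assert m1 == [] and m2 == []


def test_truth_tsv_round_trippable(tmp_path, default_sim_1000):
    import pandas as pd

    _, _, truths = default_sim_1000
    path = tmp_path / "truth.tsv"
    truth_to_tsv(truths[:50], path)
    df = pd.read_csv(path, sep="\t")
    assert len(df) == 50
    assert list(df["transcript_id"]) == [t.transcript_id for t in truths[:50]]
    assert set(df["bts_class"]) <= {"I", "II", "none"}
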