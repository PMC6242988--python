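"""Synthetic euglenophyte transcriptome generator with per-transcript ground truth.

The generator emulates the structure the downstream analyses assume:

* mRNAs carrying the 26-nt *Euglena gracilis*-type spliced leader (SL),
  frequently 5'-truncated but always retaining the 3' core ``TTTTTCG``;
* a configurable fraction of SL-negative transcripts;
* contigs assembled in reverse-complement orientation and contigs missing
  part of their 5' end;
* ORFs encoding proteins with Class I / Class II bipartite plastid-targeting
  presequences (signal peptide + transit peptide, with or without an
  anchoring transmembrane domain placed by the 60 +/- 8 spacing rule) or no
  presequence at all;
* homomeric polyproteins (tandem monomers, each followed by a conserved
  decapeptide linker) and heteromeric two-protein fusions;
* 80-bp paired-end reads with substitution errors, drawn by fragmenting
  whole transcript copies so molecule termini are covered.

Everything is deterministic given ``SimParams.seed``: a master stream makes
the run-level draws (SL quota, linker, reference pool) and per-transcript
substreams make all remaining draws, so records are order-independent.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict, replace
from typing import Sequence

import numpy as np
from Bio.Data import CodonTable

from .seqio import NucSequence, ProteinSequence, SeqRead, revcomp

logger = logging.getLogger(__name__)

#: Spliced-leader RNA 5' addition in E. gracilis / E. longa.
SL_EGRACILIS = "ACTTTCTGAGTGTCTATTTTTTTTCG"
#: Minimal detectable SL remnant: the 7-nt 3' core.
SL_CORE_LEN = 7

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}

# Signal-peptide / anchor-TMD hydrophobic residues.
_SIGNAL_RES = "LAVIF"
_ANCHOR_RES = "IVLF"
_ANCHOR_W = np.array([0.35, 0.30, 0.20, 0.15])
# Transit-peptide composition: Ser/Thr-rich, net-positive, hydrophilic.
_TRANSIT_RES = "STKRGNPQA"
_TRANSIT_W = np.array([0.18, 0.12, 0.07, 0.07, 0.12, 0.10, 0.10, 0.10, 0.14])
_LINKER_RES = "GSTANPQDE"

_table = CodonTable.unambiguous_dna_by_id[1]
_SYNONYMS: dict[str, list[str]] = {}
for codon, aa in _table.forward_table.items():
    _SYNONYMS.setdefault(aa, []).append(codon)
for aa in _SYNONYMS:
    _SYNONYMS[aa].sort()
_STOPS = sorted(_table.stop_codons)


@dataclass
class SimParams:
    """Study-condition parameters of the simulated transcriptome."""

    seed: int
    n_transcripts: int = 1000
    sl_fraction: float = 0.485
    sl_full: str = SL_EGRACILIS
    sl_min_suffix: int = SL_CORE_LEN
    sl_quota: bool = True            # exact quota vs per-transcript Bernoulli
    revcomp_fraction: float = 0.3
    truncation_prob: float = 0.2     # P(5' truncation) for eligible contigs
    truncation_range: tuple[int, int] = (10, 200)
    truncate_sl_positive: bool = False
    gc_background: float = 0.5
    orf_length_range: tuple[int, int] = (100, 600)
    bts_mix: tuple[float, float, float] = (0.2, 0.075, 0.725)  # I, II, none
    spacing_mean: int = 60
    spacing_tol: int = 8
    signal_len: int = 20
    anchor_len: int = 19
    polyprotein_fraction: float = 0.05
    monomer_count_range: tuple[int, int] = (2, 4)
    fusion_fraction: float = 0.03
    linker: str | None = None        # fixed 10-mer; drawn once per run if None
    n_reference_proteins: int = 12
    reference_length_range: tuple[int, int] = (120, 250)
    monomer_unit_range: tuple[int, int] = (80, 180)
    utr5_range: tuple[int, int] = (10, 60)
    utr3_range: tuple[int, int] = (20, 100)
    read_length: int = 80
    coverage: float = 20.0
    insert_mean: int = 300
    insert_sd: float = 30.0
    error_rate: float = 0.005

    def __post_init__(self):
        for name in ("sl_fraction", "revcomp_fraction", "truncation_prob",
                     "polyprotein_fraction", "fusion_fraction", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(sum(self.bts_mix) - 1.0) > 1e-9:
            raise ValueError("bts_mix must sum to 1")
        if self.read_length > self.insert_mean:
            raise ValueError("read_length must not exceed insert_mean")
        if self.linker is not None and len(self.linker) != 10:
            raise ValueError("linker must be a decapeptide")
        presequence = self.spacing_mean + self.spacing_tol + self.anchor_len
        if self.orf_length_range[1] < presequence + 20:
            raise ValueError(
                "orf_length_range upper bound too small for a Class I "
                f"presequence of {presequence} residues"
            )
        if self.sl_min_suffix < SL_CORE_LEN or self.sl_min_suffix > len(self.sl_full):
            raise ValueError("sl_min_suffix outside [core length, SL length]")


@dataclass
class TruthRecord:
    """Ground truth for one simulated transcript (recovery-test oracle)."""

    transcript_id: str
    sl_status: str                   # present_full | present_truncated | absent
    sl_suffix_len: int               # planted retained 3'-suffix length (0 if absent)
    orientation: str                 # forward | revcomp
    truncated_5prime_nt: int
    orig_length: int
    cds_start: int                   # original forward-transcript coords,
    cds_end: int                     # stop codon included
    bts_class: str                   # I | II | none
    signal_span: tuple[int, int] | None
    transit_span: tuple[int, int] | None
    anchor_span: tuple[int, int] | None
    architecture: str                # monomer | polyprotein | fusion
    n_units: int = 1
    unit_len: int = 0
    period: int = 0
    segment_labels: tuple[str, ...] = ()
    segment_spans: tuple[tuple[int, int], ...] = ()
    aa_sequence: str = ""
    original_sequence: str = ""

    @property
    def sl_core_survives(self) -> bool:
        """True if the emitted contig still carries >= 7 nt of SL 3'-core."""
        if self.sl_status == "absent":
            return False
        return self.sl_suffix_len - self.truncated_5prime_nt >= SL_CORE_LEN

    @property
    def emitted_length(self) -> int:
        return self.orig_length - self.truncated_5prime_nt

    def emitted_cds_span(self) -> tuple[int, int] | None:
        """Planted CDS span in emitted-contig coordinates, or None if cut."""
        s = self.cds_start - self.truncated_5prime_nt
        e = self.cds_end - self.truncated_5prime_nt
        if s < 0:
            return None
        if self.orientation == "revcomp":
            return (self.emitted_length - e, self.emitted_length - s)
        return (s, e)


def _rng_for(seed: int, stream: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream, index)))


def _random_dna(rng, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _dna_without_atg(rng, length: int, gc: float) -> str:
    """Random DNA guaranteed to contain no ATG (keeps planted starts unique)."""
    s = _random_dna(rng, length, gc)
    for _ in range(50):
        i = s.find("ATG")
        if i == -1:
            return s
        s = s[:i + 1] + ("C" if s[i] != "C" else "G") + s[i + 2:]
        # replacing the T breaks this occurrence without creating A_G = ATG
    return s.replace("ATG", "ACG")


def _random_protein(rng, length: int) -> str:
    return "".join(np.array(list(AA20))[rng.integers(0, 20, size=length)])


def _make_signal(rng, length: int) -> str:
    core = "".join(np.array(list(_SIGNAL_RES))[rng.integers(0, len(_SIGNAL_RES), size=length - 1)])
    return "M" + core


def _make_transit(rng, length: int, min_charge: int = 5, min_st_frac: float = 0.25) -> str:
    aa = list("".join(np.array(list(_TRANSIT_RES))[
        rng.choice(len(_TRANSIT_RES), size=length, p=_TRANSIT_W)]))
    # enforce the planted composition guarantees (charge >= +2, S/T >= 0.2
    # with margin) by patching random positions deterministically
    want_st = max(int(np.ceil(min_st_frac * length)), 1)
    st_pos = [i for i, a in enumerate(aa) if a in "ST"]
    other = [i for i, a in enumerate(aa) if a not in "STKR"]
    rng.shuffle(other)
    while len(st_pos) < want_st and other:
        i = other.pop()
        aa[i] = "S" if rng.random() < 0.5 else "T"
        st_pos.append(i)
    kr = sum(a in "KR" for a in aa)
    while kr < min_charge and other:
        i = other.pop()
        aa[i] = "K" if rng.random() < 0.5 else "R"
        kr += 1
    return "".join(aa)


def _make_anchor(rng, length: int) -> str:
    return "".join(np.array(list(_ANCHOR_RES))[rng.choice(len(_ANCHOR_RES), size=length, p=_ANCHOR_W)])


def make_reference_pool(rng, params: SimParams) -> list[ProteinSequence]:
    """Mature-protein reference library used for polyprotein units and fusions."""
    lo, hi = params.reference_length_range
    pool = []
    for i in range(params.n_reference_proteins):
        length = int(rng.integers(lo, hi + 1))
        pool.append(ProteinSequence(id=f"ref{i:02d}", residues=_random_protein(rng, length)))
    return pool


def draw_linker(rng) -> str:
    """The run-level conserved decapeptide linker."""
    return "".join(np.array(list(_LINKER_RES))[rng.integers(0, len(_LINKER_RES), size=10)])


def build_protein(rng, bts_class: str, architecture: str, params: SimParams,
                  refs: Sequence[ProteinSequence], linker: str):
    """Construct one protein; returns (aa_sequence, spans dict).

    spans: signal/transit/anchor residue spans (or None), plus architecture
    fields (units, n_units, unit_len, period, labels, segment spans).
    """
    spans: dict = {"signal": None, "transit": None, "anchor": None,
                   "units": (), "n_units": 1, "unit_len": 0, "period": 0,
                   "labels": (), "segments": ()}
    if bts_class == "I":
        jitter = int(rng.integers(-params.spacing_tol, params.spacing_tol + 1))
        anchor_start = params.spacing_mean + jitter
        pres = (_make_signal(rng, params.signal_len)
                + _make_transit(rng, anchor_start - params.signal_len)
                + _make_anchor(rng, params.anchor_len))
        spans["signal"] = (0, params.signal_len)
        spans["transit"] = (params.signal_len, anchor_start)
        spans["anchor"] = (anchor_start, anchor_start + params.anchor_len)
    elif bts_class == "II":
        jitter = int(rng.integers(-params.spacing_tol, params.spacing_tol + 1))
        tp_len = params.spacing_mean - params.signal_len + jitter
        pres = _make_signal(rng, params.signal_len) + _make_transit(rng, tp_len)
        spans["signal"] = (0, params.signal_len)
        spans["transit"] = (params.signal_len, params.signal_len + tp_len)
    else:
        pres = "M"
    off = len(pres)

    if architecture == "polyprotein":
        ref = refs[int(rng.integers(0, len(refs)))]
        lo, hi = params.monomer_unit_range
        unit = ref.residues[: int(rng.integers(lo, min(hi, len(ref.residues)) + 1))]
        n = int(rng.integers(params.monomer_count_range[0], params.monomer_count_range[1] + 1))
        body = (unit + linker) * n
        period = len(unit) + len(linker)
        spans["units"] = tuple((off + m * period, off + (m + 1) * period) for m in range(n))
        spans.update(n_units=n, unit_len=len(unit), period=period, labels=(ref.id,))
    elif architecture == "fusion":
        i, j = rng.choice(len(refs), size=2, replace=False)
        a, b = refs[int(i)], refs[int(j)]
        body = a.residues + linker + b.residues
        spans["labels"] = (a.id, b.id)
        spans["segments"] = (
            (off, off + len(a.residues)),
            (off + len(a.residues) + len(linker), off + len(body)),
        )
    else:
        total = int(rng.integers(params.orf_length_range[0], params.orf_length_range[1] + 1))
        body = _random_protein(rng, max(total - len(pres), 60))
    return pres + body, spans


def reverse_translate(rng, aa_seq: str) -> str:
    """Uniform-synonymous-codon reverse translation plus a random stop codon."""
    codons = []
    for aa in aa_seq:
        syn = _SYNONYMS[aa]
        codons.append(syn[int(rng.integers(0, len(syn)))])
    codons.append(_STOPS[int(rng.integers(0, len(_STOPS)))])
    return "".join(codons)


def _draw_class(rng, mix) -> str:
    return ("I", "II", "none")[int(rng.choice(3, p=np.asarray(mix)))]


def _draw_architecture(rng, params) -> str:
    u = rng.random()
    if u < params.polyprotein_fraction:
        return "polyprotein"
    if u < params.polyprotein_fraction + params.fusion_fraction:
        return "fusion"
    return "monomer"


def run_level_pool(params: SimParams):
    """Run-level draws shared by all transcripts: (linker, reference pool).

    Deterministic given params.seed; downstream stages re-derive the same
    pool to use it as the fusion reference library.
    """
    master = np.random.default_rng(np.random.SeedSequence(entropy=params.seed, spawn_key=(0,)))
    linker = params.linker if params.linker is not None else draw_linker(master)
    refs = make_reference_pool(master, params)
    return master, linker, refs


def generate_transcriptome(params: SimParams):
    """Generate contigs and truth records; deterministic given params.seed.

    Returns (list[NucSequence], list[TruthRecord]).  SL positivity uses an
    exact quota by default so census tests are non-flaky.
    """
    n = params.n_transcripts
    master, linker, refs = run_level_pool(params)
    if params.sl_quota:
        n_pos = round(params.sl_fraction * n)
        sl_positive = set(master.permutation(n)[:n_pos].tolist())
    else:
        sl_positive = None  # decided per transcript below

    contigs, truths = [], []
    for i in range(n):
        rng = _rng_for(params.seed, 1, i)
        tid = f"tx{i:05d}"
        is_sl = (i in sl_positive) if sl_positive is not None else bool(rng.random() < params.sl_fraction)
        if is_sl:
            suffix_len = int(rng.integers(params.sl_min_suffix, len(params.sl_full) + 1))
            sl_part = params.sl_full[-suffix_len:]
            status = "present_full" if suffix_len == len(params.sl_full) else "present_truncated"
        else:
            suffix_len, sl_part, status = 0, "", "absent"

        bts_class = _draw_class(rng, params.bts_mix)
        architecture = _draw_architecture(rng, params)
        aa, spans = build_protein(rng, bts_class, architecture, params, refs, linker)
        cds = reverse_translate(rng, aa)
        utr5 = _dna_without_atg(rng, int(rng.integers(*params.utr5_range)), params.gc_background)
        utr3 = _random_dna(rng, int(rng.integers(params.utr3_range[0], params.utr3_range[1] + 1)), params.gc_background)
        orig = sl_part + utr5 + cds + utr3
        cds_start = len(sl_part) + len(utr5)

        trunc = 0
        eligible = (not is_sl) or params.truncate_sl_positive
        if eligible and rng.random() < params.truncation_prob:
            lo, hi = params.truncation_range
            trunc = int(rng.integers(lo, hi + 1))
            trunc = max(0, min(trunc, len(orig) - 100))
        emitted = orig[trunc:]
        orientation = "forward"
        if rng.random() < params.revcomp_fraction:
            emitted = revcomp(emitted)
            orientation = "revcomp"

        contigs.append(NucSequence(id=tid, residues=emitted))
        truths.append(TruthRecord(
            transcript_id=tid,
            sl_status=status,
            sl_suffix_len=suffix_len,
            orientation=orientation,
            truncated_5prime_nt=trunc,
            orig_length=len(orig),
            cds_start=cds_start,
            cds_end=cds_start + len(cds),
            bts_class=bts_class,
            signal_span=spans["signal"],
            transit_span=spans["transit"],
            anchor_span=spans["anchor"],
            architecture=architecture,
            n_units=spans["n_units"],
            unit_len=spans["unit_len"],
            period=spans["period"],
            segment_labels=spans["labels"],
            segment_spans=spans["segments"],
            aa_sequence=aa,
            original_sequence=orig,
        ))
    return contigs, truths


def generate_proteins(n: int, seed: int, params: SimParams | None = None,
                      bts_class: str | None = None, architecture: str = "monomer"):
    """Generate bare proteins with truth spans (for classifier/architecture tests).

    ``bts_class=None`` draws from ``params.bts_mix``.  Returns a list of
    (aa_sequence, bts_class, spans-dict) tuples.
    """
    params = params or SimParams(seed=seed, n_transcripts=n)
    _, linker, refs = run_level_pool(replace(params, seed=seed))
    out = []
    for i in range(n):
        rng = _rng_for(seed, 3, i)
        cls = bts_class if bts_class is not None else _draw_class(rng, params.bts_mix)
        aa, spans = build_protein(rng, cls, architecture, params, refs, linker)
        out.append((aa, cls, spans))
    return out


def mutate_protein(aa_seq: str, rate: float, rng) -> str:
    """Substitute residues at the given per-position rate (noise model)."""
    aa = list(aa_seq)
    hits = np.flatnonzero(rng.random(len(aa)) < rate)
    for i in hits:
        choices = [c for c in AA20 if c != aa[i]]
        aa[i] = choices[int(rng.integers(0, len(choices)))]
    return "".join(aa)


def generate_reads(transcripts: Sequence[NucSequence], truths: Sequence[TruthRecord],
                   params: SimParams):
    """Simulate 80-bp paired-end reads from the original forward transcripts.

    Each of ~coverage*insert/(2*read_length) copies of every transcript is
    fragmented end-to-end (fragment lengths ~ N(insert_mean, insert_sd),
    floored at read_length), so molecule termini are fully covered and 5'
    extension is testable.  Substitution errors at ``error_rate``.
    Returns (mate1 reads, mate2 reads).
    """
    if not transcripts:
        raise ValueError("no transcripts to sequence")
    truth_by_id = {t.transcript_id: t for t in truths}
    rl = params.read_length
    n_copies = max(1, round(params.coverage * params.insert_mean / (2 * rl)))
    mate1: list[SeqRead] = []
    mate2: list[SeqRead] = []
    n_skipped = 0
    bases = np.array(list("ACGT"))
    for idx, contig in enumerate(transcripts):
        truth = truth_by_id.get(contig.id)
        template = truth.original_sequence if truth else contig.residues
        L = len(template)
        if L < rl:
            n_skipped += 1
            continue
        rng = _rng_for(params.seed, 2, idx)
        pair_no = 0
        for _ in range(n_copies):
            pos = 0
            while pos < L:
                frag_len = int(max(rl, round(rng.normal(params.insert_mean, params.insert_sd))))
                frag = template[pos : pos + frag_len]
                pos += frag_len
                if len(frag) < rl:
                    break
                r1 = frag[:rl]
                r2 = revcomp(frag)[:rl]
                if params.error_rate > 0:
                    r1 = _substitute(r1, params.error_rate, rng, bases)
                    r2 = _substitute(r2, params.error_rate, rng, bases)
                pair_no += 1
                name = f"{contig.id}_p{pair_no:05d}"
                mate1.append(SeqRead(id=f"{name}/1", residues=r1, quality=[40] * rl, mate=1))
                mate2.append(SeqRead(id=f"{name}/2", residues=r2, quality=[40] * rl, mate=2))
    if n_skipped:
        warnings.warn(f"{n_skipped} transcript(s) shorter than read length skipped")
    return mate1, mate2


def _substitute(seq: str, rate: float, rng, bases) -> str:
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if hits.size == 0:
        return seq
    out = list(seq)
    for i in hits:
        alternatives = [b for b in "ACGT" if b != out[i]]
        out[i] = alternatives[int(rng.integers(0, 3))]
    return "".join(out)


TRUTH_COLUMNS = [
    "transcript_id", "sl_status", "sl_suffix_len", "orientation",
    "truncated_5prime_nt", "orig_length", "cds_start", "cds_end", "bts_class",
    "signal_span", "transit_span", "anchor_span", "architecture", "n_units",
    "unit_len", "period", "segment_labels", "segment_spans", "aa_sequence",
]


def truth_to_tsv(truths: Sequence[TruthRecord], path) -> None:
    """Write truth records as a documented TSV ('.' for missing values)."""
    import pandas as pd

    rows = []
    for t in truths:
        d = asdict(t)
        d.pop("original_sequence")
        for key in ("signal_span", "transit_span", "anchor_span"):
            d[key] = "." if d[key] is None else f"{d[key][0]}-{d[key][1]}"
        d["segment_labels"] = ",".join(d["segment_labels"]) or "."
        d["segment_spans"] = ",".join(f"{s}-{e}" for s, e in d["segment_spans"]) or "."
        rows.append(d)
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)
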