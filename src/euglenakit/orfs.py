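"""Protein-model derivation: six-frame translation and ORF selection.

Maximal stop-to-stop ORFs are enumerated on both strands, trimmed to their
first in-frame ATG when one exists (otherwise reported 5'-open, which
matters for 5'-truncated contigs), and the protein model for a transcript
is chosen as the longest ORF with spliced-leader-orientation-aware
tie-breaking.
"""
from __future__ import annotations

from dataclasses import dataclass

from Bio.Data import CodonTable

from .seqio import NucSequence, revcomp
from .slscan import SLMatch

_table = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_table.forward_table)
STOP_CODONS = frozenset(_table.stop_codons)


def translate_codon(codon: str) -> str:
    """Standard-code translation; codons with N (or other ambiguity) give X."""
    return CODON_TO_AA.get(codon, "X")


@dataclass
class ProteinModel:
    """A translation product with its CDS placed on the forward strand.

    ``frame`` is the codon offset (0/1/2) on the chosen strand;
    ``cds_start``/``cds_end`` are 0-based half-open forward-strand nt
    coordinates and include the stop codon when ``has_terminator``.
    """

    transcript_id: str
    strand: str
    frame: int
    cds_start: int
    cds_end: int
    aa_sequence: str
    has_initiator: bool
    has_terminator: bool

    def __post_init__(self):
        if (self.cds_end - self.cds_start) % 3:
            raise ValueError("CDS length not divisible by 3")

    def __len__(self) -> int:
        return len(self.aa_sequence)


def _frame_orfs(seq_id: str, s: str, strand: str, L: int, min_aa: int) -> list[ProteinModel]:
    models = []
    for frame in range(3):
        n_codons = (len(s) - frame) // 3
        codons = [s[frame + 3 * i : frame + 3 * i + 3] for i in range(n_codons)]
        seg_start = 0
        for idx in range(n_codons + 1):
            at_end = idx == n_codons
            if not at_end and codons[idx] not in STOP_CODONS:
                continue
            # segment of coding codons is [seg_start, idx); stop at idx if any
            has_term = not at_end
            first_atg = next((j for j in range(seg_start, idx) if codons[j] == "ATG"), None)
            start_codon = first_atg if first_atg is not None else seg_start
            aa = "".join(translate_codon(c) for c in codons[start_codon:idx])
            if len(aa) >= min_aa:
                nt_start = frame + 3 * start_codon
                nt_end = frame + 3 * (idx + (1 if has_term else 0))
                if strand == "-":
                    cds_start, cds_end = L - nt_end, L - nt_start
                else:
                    cds_start, cds_end = nt_start, nt_end
                models.append(ProteinModel(
                    transcript_id=seq_id, strand=strand, frame=frame,
                    cds_start=cds_start, cds_end=cds_end, aa_sequence=aa,
                    has_initiator=first_atg is not None, has_terminator=has_term,
                ))
            seg_start = idx + 1
    return models


def six_frame_orfs(seq: NucSequence, min_aa: int = 50) -> list[ProteinModel]:
    """All maximal ORFs of >= min_aa residues in all six frames.

    Codons containing N translate to X; stop detection is exact, so
    N-containing codons never terminate an ORF.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    s = seq.residues
    models = _frame_orfs(seq.id, s, "+", len(s), min_aa)
    models += _frame_orfs(seq.id, revcomp(s), "-", len(s), min_aa)
    models.sort(key=lambda m: (m.strand, m.frame, m.cds_start))
    return models


def select_model(orfs: list[ProteinModel], sl_match: SLMatch | None = None) -> ProteinModel | None:
    """Pick the transcript's protein model: longest ORF, ties broken by
    (1) strand consistent with the SL orientation when detected,
    (2) forward strand, (3) smallest cds_start."""
    if not orfs:
        return None
    preferred = "+"
    if sl_match is not None and sl_match.detected and sl_match.orientation == "reverse":
        preferred = "-"
    return min(orfs, key=lambda m: (
        -len(m.aa_sequence),
        0 if m.strand == preferred else 1,
        0 if m.strand == "+" else 1,
        m.cds_start,
    ))


def models_to_dataframe(models):
    import pandas as pd

    return pd.DataFrame([{
        "transcript_id": m.transcript_id,
        "strand": m.strand,
        "frame": m.frame,
        "cds_start": m.cds_start,
        "cds_end": m.cds_end,
        "aa_length": len(m.aa_sequence),
        "has_initiator": m.has_initiator,
        "has_terminator": m.has_terminator,
    } for m in models])
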