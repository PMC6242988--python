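"""Greedy iterative 5'-end contig extension by read recruitment.

Reads whose suffix overlaps the current contig prefix (ungapped, seeded
through a k-mer index and verified with a mismatch budget) contribute a 5'
overhang; a conservative column-wise consensus over the overhang is
prepended and the process repeats until the spliced-leader core appears
within the terminal window, no read overlaps, the consensus is ambiguous,
or the iteration cap is hit.  The module is fully deterministic — there is
no randomness anywhere in it.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Sequence

from .seqio import NucSequence, SeqRead, revcomp
from .simulate import SL_EGRACILIS
from .slscan import DEFAULT_MIN_CORE, DEFAULT_WINDOW


@dataclass
class ExtensionResult:
    contig_id: str
    extended_sequence: str
    added_prefix: str
    n_iterations: int
    reads_used: list[int] = field(default_factory=list)
    stop_reason: str = "no_overlap"  # sl_found|no_overlap|ambiguous_consensus|max_iterations


class ReadIndex:
    """k-mer -> (read, orientation, position) postings over both strands."""

    def __init__(self, reads: Sequence[SeqRead], k: int = 15):
        if k < 11:
            raise ValueError("k must be >= 11")
        self.k = k
        self.oriented: list[str] = []
        self.postings: dict[str, list[tuple[int, int]]] = defaultdict(list)
        self.max_read_len = 0
        for read in reads:
            for orient_seq in (read.residues, revcomp(read.residues)):
                ridx = len(self.oriented)
                self.oriented.append(orient_seq)
                self.max_read_len = max(self.max_read_len, len(orient_seq))
                for pos in range(len(orient_seq) - k + 1):
                    self.postings[orient_seq[pos : pos + k]].append((ridx, pos))

    def lookup(self, kmer: str) -> list[tuple[int, int]]:
        return self.postings.get(kmer, [])


def build_read_index(reads: Sequence[SeqRead], k: int = 15) -> ReadIndex:
    """Index reads (both orientations) for overlap seeding."""
    return ReadIndex(reads, k)


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _recruit(seq: str, index: ReadIndex, min_overlap: int,
             max_mismatch_frac: float) -> dict[tuple[int, int], str]:
    """Oriented reads whose suffix overlaps the contig prefix with a 5' overhang.

    Returns {(oriented-read idx, shift): oriented read}, shift < 0 being the
    contig coordinate of the read's first base.
    """
    k = index.k
    limit = min(len(seq), index.max_read_len)
    candidates: dict[tuple[int, int], str] = {}
    for p in range(0, max(0, limit - k + 1)):
        kmer = seq[p : p + k]
        for ridx, pos in index.lookup(kmer):
            shift = p - pos
            if shift >= 0:
                continue
            key = (ridx, shift)
            if key in candidates:
                continue
            r = index.oriented[ridx]
            overlap = min(len(r) + shift, len(seq))
            if overlap < min_overlap:
                continue
            if _mismatches(r[-shift : -shift + overlap], seq[:overlap]) <= max_mismatch_frac * overlap:
                candidates[key] = r
    return candidates


def _consensus_prefix(candidates: dict[tuple[int, int], str],
                      min_cov: int, min_agree: float) -> str:
    """Column-wise consensus over overhang columns, left of the contig start,
    extending leftward until the first failing column."""
    overhangs = [(-shift, r) for (_ridx, shift), r in candidates.items()]
    max_col = max(oh for oh, _ in overhangs)
    columns = []
    for c in range(1, max_col + 1):
        bases = Counter(r[oh - c] for oh, r in overhangs if oh >= c)
        cov = sum(bases.values())
        if cov < min_cov:
            break
        base, count = min(bases.items(), key=lambda kv: (-kv[1], kv[0]))
        if count / cov < min_agree:
            break
        columns.append(base)
    return "".join(reversed(columns))


def extend_5prime(contig: NucSequence, index: ReadIndex, sl: str = SL_EGRACILIS,
                  min_overlap: int = 25, max_mismatch_frac: float = 0.04,
                  min_cov: int = 2, min_agree: float = 0.7, max_iter: int = 50,
                  window: int = DEFAULT_WINDOW, min_core: int = DEFAULT_MIN_CORE) -> ExtensionResult:
    """Iteratively extend the 5' end of a contig from indexed reads."""
    if len(contig.residues) < min_overlap:
        raise ValueError("contig shorter than min_overlap")
    core = sl[-min_core:]
    seq = contig.residues
    added = ""
    reads_used: list[int] = []

    def sl_present(s: str) -> bool:
        return s.find(core, 0, window) != -1

    if sl_present(seq):
        return ExtensionResult(contig.id, seq, "", 0, [], "sl_found")
    for iteration in range(max_iter):
        candidates = _recruit(seq, index, min_overlap, max_mismatch_frac)
        if not candidates:
            return ExtensionResult(contig.id, seq, added, iteration, reads_used, "no_overlap")
        reads_used.append(len(candidates))
        prefix = _consensus_prefix(candidates, min_cov, min_agree)
        if not prefix:
            return ExtensionResult(contig.id, seq, added, iteration + 1,
                                   reads_used, "ambiguous_consensus")
        seq = prefix + seq
        added = prefix + added
        if sl_present(seq):
            return ExtensionResult(contig.id, seq, added, iteration + 1, reads_used, "sl_found")
    return ExtensionResult(contig.id, seq, added, max_iter, reads_used, "max_iterations")


def results_to_dataframe(results):
    import pandas as pd

    return pd.DataFrame([{
        "contig_id": r.contig_id,
        "added_nt": len(r.added_prefix),
        "n_iterations": r.n_iterations,
        "reads_used": ",".join(map(str, r.reads_used)) or ".",
        "stop_reason": r.stop_reason,
    } for r in results])
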