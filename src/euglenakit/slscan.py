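"""Spliced-leader census: call SL presence at contig termini.

A transcript is SL-positive if at least the SL 3' core (``TTTTTCG`` for the
26-nt euglenid SL) lies entirely within ``window`` nt of the appropriate
contig end.  Contigs assembled in reverse-complement orientation are handled
by also searching for the reverse complement of the core within the terminal
window of the 3' end.  The default ("strict") mode pairs orientation with
the end scanned (forward core near the 5' end, reverse-complement core near
the 3' end); ``loose=True`` additionally accepts the two mirrored
combinations, the most literal reading of "either end".
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .seqio import Feature, NucSequence, revcomp
from .simulate import SL_EGRACILIS

DEFAULT_WINDOW = 35
DEFAULT_MIN_CORE = 7


@dataclass
class SLMatch:
    """Per-contig SL call.

    For a forward match, ``match_start``..``core_end`` spans the full matched
    SL suffix, ``core_end`` being the exclusive end of the core.  For a
    reverse match, ``match_start`` is the start of the reverse-complemented
    core and the matched region runs rightward for ``matched_length`` nt.
    """

    transcript_id: str
    detected: bool
    orientation: str = "none"        # forward | reverse | none
    match_start: int | None = None
    core_end: int | None = None
    matched_length: int = 0
    end_scanned: str | None = None   # five_prime | three_prime
    ambiguous: bool = False


@dataclass
class ScanSummary:
    """Assembly-wide SL census."""

    n_total: int
    n_sl_positive: int
    n_forward: int
    n_reverse: int
    pct_sl_positive: float
    mode: str = "strict"


def _extend_forward(seq: str, core_start: int, sl: str, min_core: int) -> int:
    """Longest k with the k-long 3'-suffix of sl ending at core_start+min_core."""
    core_end = core_start + min_core
    k = min_core
    while k < len(sl) and core_end - k - 1 >= 0 and seq[core_end - k - 1] == sl[-(k + 1)]:
        k += 1
    return k


def _extend_reverse(seq: str, pos: int, rc_sl: str, min_core: int) -> int:
    """Longest k with revcomp(sl 3'-suffix of length k) starting at pos."""
    k = min_core
    while k < len(rc_sl) and pos + k < len(seq) and seq[pos + k] == rc_sl[k]:
        k += 1
    return k


def scan_transcript(seq: NucSequence, sl: str = SL_EGRACILIS,
                    window: int = DEFAULT_WINDOW, min_core: int = DEFAULT_MIN_CORE,
                    loose: bool = False) -> SLMatch:
    """Call SL presence on one contig.

    Detected iff the min_core-long 3' suffix of ``sl`` occurs entirely within
    the first ``window`` nt (forward), or its reverse complement occurs
    entirely within the last ``window`` nt (reverse).  When both ends match,
    the forward call wins and the match is flagged ambiguous.  N never
    matches (exact string comparison).
    """
    if len(sl) < min_core:
        raise ValueError("sl shorter than min_core")
    if window < min_core:
        raise ValueError("window shorter than min_core")
    s = seq.residues
    L = len(s)
    core = sl[-min_core:]
    rc_sl = revcomp(sl)
    rc_core = rc_sl[:min_core]

    fwd5 = s.find(core, 0, window)
    rev3 = s.rfind(rc_core, max(0, L - window), L)
    hits: list[tuple[str, str, int]] = []  # (orientation, end_scanned, pos)
    if fwd5 != -1:
        hits.append(("forward", "five_prime", fwd5))
    if rev3 != -1:
        hits.append(("reverse", "three_prime", rev3))
    if loose and not hits:
        fwd3 = s.find(core, max(0, L - window), L)
        rev5 = s.find(rc_core, 0, window)
        if fwd3 != -1:
            hits.append(("forward", "three_prime", fwd3))
        if rev5 != -1:
            hits.append(("reverse", "five_prime", rev5))

    if not hits:
        return SLMatch(transcript_id=seq.id, detected=False)
    orientation, end_scanned, pos = hits[0]
    if orientation == "forward":
        k = _extend_forward(s, pos, sl, min_core)
        return SLMatch(
            transcript_id=seq.id, detected=True, orientation="forward",
            match_start=pos + min_core - k, core_end=pos + min_core,
            matched_length=k, end_scanned=end_scanned, ambiguous=len(hits) > 1,
        )
    k = _extend_reverse(s, pos, rc_sl, min_core)
    return SLMatch(
        transcript_id=seq.id, detected=True, orientation="reverse",
        match_start=pos, core_end=pos + min_core, matched_length=k,
        end_scanned=end_scanned, ambiguous=len(hits) > 1,
    )


def scan_assembly(seqs: Sequence[NucSequence], sl: str = SL_EGRACILIS,
                  window: int = DEFAULT_WINDOW, min_core: int = DEFAULT_MIN_CORE,
                  loose: bool = False):
    """Scan every contig; returns (list[SLMatch], ScanSummary)."""
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dupes = sorted({i for i in ids if i in seen or seen.add(i)})
        raise ValueError(f"duplicate transcript ids: {dupes}")
    matches = [scan_transcript(s, sl, window, min_core, loose) for s in seqs]
    n_forward = sum(m.orientation == "forward" for m in matches)
    n_reverse = sum(m.orientation == "reverse" for m in matches)
    n_pos = n_forward + n_reverse
    summary = ScanSummary(
        n_total=len(matches),
        n_sl_positive=n_pos,
        n_forward=n_forward,
        n_reverse=n_reverse,
        pct_sl_positive=(100.0 * n_pos / len(matches)) if matches else 0.0,
        mode="loose" if loose else "strict",
    )
    return matches, summary


def matches_to_features(matches: Sequence[SLMatch]) -> list[Feature]:
    """SL_match GFF3 features for detected contigs."""
    features = []
    for m in matches:
        if not m.detected:
            continue
        if m.orientation == "forward":
            start, end, strand = m.match_start, m.core_end, "+"
        else:
            start, end, strand = m.match_start, m.match_start + m.matched_length, "-"
        features.append(Feature(
            seq_id=m.transcript_id, kind="SL_match", start=start, end=end,
            strand=strand,
            attributes={"matched_length": m.matched_length,
                        "end_scanned": m.end_scanned,
                        "ambiguous": str(m.ambiguous).lower()},
        ))
    return features


def matches_to_dataframe(matches: Sequence[SLMatch]):
    import pandas as pd

    return pd.DataFrame([{
        "transcript_id": m.transcript_id,
        "detected": m.detected,
        "orientation": m.orientation,
        "match_start": "." if m.match_start is None else m.match_start,
        "core_end": "." if m.core_end is None else m.core_end,
        "matched_length": m.matched_length,
        "end_scanned": m.end_scanned or ".",
        "ambiguous": m.ambiguous,
    } for m in matches])
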