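"""Bipartite plastid-targeting presequence (BTS) classification.

Euglenophyte plastid proteins carry an N-terminal bipartite topogenic
signal: a signal peptide (whose hydrophobic core behaves like a
transmembrane domain), a hydrophilic Ser/Thr-rich net-positive plastid
transit peptide, and — in Class I presequences — an anchoring TMD that
follows the transit peptide at a characteristic spacing of 60 +/- 8
residues; Class II presequences lack the anchor.  This module implements
that structural model with explicit, parameterised heuristics: a
Kyte-Doolittle sliding-window hydropathy profile, a run-length TMD caller,
and composition features for the transit segment.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .orfs import ProteinModel

#: Kyte-Doolittle hydropathy scale (X scores 0).
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}


@dataclass
class HydropathyProfile:
    protein_id: str
    window: int
    scores: np.ndarray

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class TMDCall:
    """A hydrophobic segment called from the hydropathy profile."""

    start: int
    end: int
    mean_hydropathy: float
    peak_hydropathy: float

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class BTSParams:
    """All classifier thresholds in one place."""

    window: int = 19                 # hydropathy window (residues, odd)
    tmd_threshold: float = 1.6       # minimum windowed score inside a TMD
    min_tmd_len: int = 15
    merge_gap: int = 3
    signal_start_max: int = 15       # TMD1 must start within this offset
    tmd2_start_max: int = 100        # anchor search window
    spacing_mean: int = 60           # the 60 +/- 8 spacing rule
    spacing_tol: int = 8
    spacing_anchor: str = "n_terminus"  # or "tmd1_end"
    transit_min_charge: int = 1
    transit_min_st: float = 0.15
    transit_default_len: int = 60    # transit extent for Class II candidates
    min_transit_len: int = 5
    decision_prefix: int = 120       # only this N-terminal prefix is examined
    min_protein_len: int = 60
    strict: bool = False             # atypical spacing -> none instead of flag


@dataclass
class BTSCall:
    protein_id: str
    bts_class: str                   # "I" | "II" | "none"
    signal_span: tuple[int, int] | None = None
    transit_span: tuple[int, int] | None = None
    anchor_span: tuple[int, int] | None = None
    tp_net_charge: int | None = None
    tp_st_fraction: float | None = None
    tp_mean_hydropathy: float | None = None
    anchor_start_offset: int | None = None
    flags: frozenset = frozenset()


def hydropathy_profile(aa_seq: str, window: int = 19, protein_id: str = "") -> HydropathyProfile:
    """Windowed-mean Kyte-Doolittle profile; terminal windows are truncated
    to the sequence bounds rather than padded."""
    if window < 5 or window % 2 == 0:
        raise ValueError("window must be odd and >= 5")
    values = np.array([KYTE_DOOLITTLE.get(a, 0.0) for a in aa_seq])
    if values.size == 0:
        return HydropathyProfile(protein_id, window, np.empty(0))
    h = window // 2
    cum = np.concatenate([[0.0], np.cumsum(values)])
    idx = np.arange(values.size)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h + 1, values.size)
    scores = (cum[hi] - cum[lo]) / (hi - lo)
    return HydropathyProfile(protein_id, window, scores)


def call_tmds(profile: HydropathyProfile, threshold: float = 1.6,
              min_tmd_len: int = 15, merge_gap: int = 3) -> list[TMDCall]:
    """Maximal runs of profile positions >= threshold; runs separated by
    <= merge_gap positions are merged; runs shorter than min_tmd_len dropped."""
    above = profile.scores >= threshold
    runs: list[list[int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append([start, i])
            start = None
    if start is not None:
        runs.append([start, len(above)])
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] <= merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    calls = []
    for s, e in merged:
        if e - s >= min_tmd_len:
            seg = profile.scores[s:e]
            calls.append(TMDCall(start=s, end=e,
                                 mean_hydropathy=float(seg.mean()),
                                 peak_hydropathy=float(seg.max())))
    return calls


def transit_features(aa_subseq: str) -> tuple[int, float, float]:
    """(net charge K+R-D-E, S+T fraction, mean Kyte-Doolittle hydropathy)."""
    if not aa_subseq:
        raise ValueError("empty transit segment")
    charge = sum(a in "KR" for a in aa_subseq) - sum(a in "DE" for a in aa_subseq)
    st = sum(a in "ST" for a in aa_subseq) / len(aa_subseq)
    mean_h = float(np.mean([KYTE_DOOLITTLE.get(a, 0.0) for a in aa_subseq]))
    return charge, st, mean_h


def classify_bts(protein: ProteinModel | str, params: BTSParams | None = None,
                 protein_id: str | None = None) -> BTSCall:
    """Classify a protein's N-terminus as Class I / Class II / no BTS.

    Decision procedure, applied to the first ``decision_prefix`` residues
    only (so C-terminal extensions never change the call):

    1. TMD1 := first called TMD starting within ``signal_start_max``
       residues of the N-terminus (the signal-peptide hydrophobic core);
       absent -> none.
    2. Transit segment := TMD1 end up to the next TMD start (or
       ``transit_default_len`` residues); must be net-positive
       (>= transit_min_charge), S/T-rich (>= transit_min_st) and
       hydrophilic on average; fail -> none.
    3. TMD2 := next TMD starting within ``tmd2_start_max``.  Present with
       spacing inside ``spacing_mean +/- spacing_tol`` -> Class I; present
       outside -> Class I flagged ``atypical_spacing`` (strict mode: none);
       absent -> Class II.
    """
    params = params or BTSParams()
    if isinstance(protein, ProteinModel):
        aa, pid = protein.aa_sequence, protein.transcript_id
    else:
        aa, pid = protein, (protein_id or "")
    if len(aa) < params.min_protein_len:
        return BTSCall(protein_id=pid, bts_class="none", flags=frozenset({"too_short"}))
    prefix = aa[: params.decision_prefix]
    profile = hydropathy_profile(prefix, params.window, pid)
    tmds = call_tmds(profile, params.tmd_threshold, params.min_tmd_len, params.merge_gap)

    tmd1 = next((t for t in tmds if t.start <= params.signal_start_max), None)
    if tmd1 is None:
        return BTSCall(protein_id=pid, bts_class="none", flags=frozenset({"no_signal_tmd"}))
    tmd2 = next((t for t in tmds if t.start > tmd1.start and t.start <= params.tmd2_start_max), None)

    transit_end = tmd2.start if tmd2 is not None else min(
        tmd1.end + params.transit_default_len, len(prefix))
    transit_span = (tmd1.end, transit_end)
    if transit_end - tmd1.end < params.min_transit_len:
        return BTSCall(protein_id=pid, bts_class="none", flags=frozenset({"no_transit"}))
    charge, st, mean_h = transit_features(prefix[tmd1.end:transit_end])
    if charge < params.transit_min_charge or st < params.transit_min_st or mean_h >= 0:
        return BTSCall(protein_id=pid, bts_class="none", flags=frozenset({"weak_transit"}),
                       tp_net_charge=charge, tp_st_fraction=st, tp_mean_hydropathy=mean_h)

    common = dict(protein_id=pid, signal_span=(0, tmd1.end), transit_span=transit_span,
                  tp_net_charge=charge, tp_st_fraction=st, tp_mean_hydropathy=mean_h)
    if tmd2 is None:
        return BTSCall(bts_class="II", **common)
    spacing = tmd2.start if params.spacing_anchor == "n_terminus" else tmd2.start - tmd1.end
    lo = params.spacing_mean - params.spacing_tol
    hi = params.spacing_mean + params.spacing_tol
    flags = frozenset() if lo <= spacing <= hi else frozenset({"atypical_spacing"})
    if flags and params.strict:
        return BTSCall(protein_id=pid, bts_class="none", flags=flags,
                       tp_net_charge=charge, tp_st_fraction=st, tp_mean_hydropathy=mean_h)
    return BTSCall(bts_class="I", anchor_span=(tmd2.start, tmd2.end),
                   anchor_start_offset=tmd2.start, flags=flags, **common)


def calls_to_dataframe(calls):
    import pandas as pd

    def span(v):
        return "." if v is None else f"{v[0]}-{v[1]}"

    return pd.DataFrame([{
        "protein_id": c.protein_id,
        "bts_class": c.bts_class,
        "signal_span": span(c.signal_span),
        "transit_span": span(c.transit_span),
        "anchor_span": span(c.anchor_span),
        "tp_net_charge": "." if c.tp_net_charge is None else c.tp_net_charge,
        "tp_st_fraction": "." if c.tp_st_fraction is None else round(c.tp_st_fraction, 4),
        "tp_mean_hydropathy": "." if c.tp_mean_hydropathy is None else round(c.tp_mean_hydropathy, 4),
        "anchor_start_offset": "." if c.anchor_start_offset is None else c.anchor_start_offset,
        "flags": ",".join(sorted(c.flags)) or ".",
    } for c in calls])
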