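"""End-to-end orchestration: simulate -> SL scan -> ORFs -> BTS -> architecture
-> 5' extension, with aggregate reporting and truth-based evaluation.

The report is written both as JSON (machine interface) and as TSVs (human
interface); the full parameter set, seed and package version are embedded
for provenance.  Given a fixed seed and configuration the whole run is
deterministic (the JSON is byte-identical apart from its timestamp field).
"""
from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .architecture import ArchitectureCall, calls_to_dataframe as arch_to_df, detect_fusion, detect_tandem
from .bts import BTSCall, BTSParams, calls_to_dataframe as bts_to_df, classify_bts
from .extend import build_read_index, extend_5prime, results_to_dataframe
from .orfs import models_to_dataframe, select_model, six_frame_orfs
from .seqio import NucSequence, ProteinSequence, revcomp, write_fasta, write_fastq, write_gff3
from .simulate import SimParams, TruthRecord, generate_reads, generate_transcriptome, truth_to_tsv
from .slscan import SLMatch, matches_to_dataframe, matches_to_features, scan_assembly

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int
    sim: SimParams | None = None
    bts_params: BTSParams = field(default_factory=BTSParams)
    sl_window: int = 35
    sl_min_core: int = 7
    sl_loose: bool = False
    min_aa: int = 50
    run_simulate: bool = True
    run_slscan: bool = True
    run_orfs: bool = True
    run_bts: bool = True
    run_arch: bool = True
    run_extend: bool = True
    max_extend: int = 25             # cap on contigs taken into extension

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        if self.sim is None:
            self.sim = SimParams(seed=self.seed)


@dataclass
class PipelineReport:
    counts: dict = field(default_factory=dict)
    scan_summary: dict | None = None
    bts_tally: dict = field(default_factory=dict)
    arch_tally: dict = field(default_factory=dict)
    extend_tally: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    timestamp: str = ""

    def to_json(self, include_timestamp: bool = True) -> str:
        d = dataclasses.asdict(self)
        if not include_timestamp:
            d.pop("timestamp")
        return json.dumps(d, indent=2, sort_keys=True, default=str)


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run the configured stages in order, writing standard-format files."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(
        provenance={
            "version": __version__,
            "seed": config.seed,
            "sim_params": dataclasses.asdict(config.sim),
            "bts_params": dataclasses.asdict(config.bts_params),
            "sl_window": config.sl_window,
            "sl_min_core": config.sl_min_core,
            "sl_loose": config.sl_loose,
            "min_aa": config.min_aa,
        },
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    if not config.run_simulate:
        raise ValueError("pipeline currently starts from the simulate stage")
    logger.info("simulate: %d transcripts", config.sim.n_transcripts)
    contigs, truths = generate_transcriptome(config.sim)
    write_fasta(contigs, out / "transcripts.fasta")
    truth_to_tsv(truths, out / "truth.tsv")
    report.counts["transcripts"] = len(contigs)

    matches: list[SLMatch] = []
    if config.run_slscan:
        matches, summary = scan_assembly(
            contigs, config.sim.sl_full, config.sl_window, config.sl_min_core, config.sl_loose)
        matches_to_dataframe(matches).to_csv(out / "sl_calls.tsv", sep="\t", index=False)
        pd.DataFrame([dataclasses.asdict(summary)]).to_csv(out / "sl_summary.tsv", sep="\t", index=False)
        write_gff3(matches_to_features(matches), out / "sl_calls.gff3")
        report.scan_summary = dataclasses.asdict(summary)
        logger.info("slscan: %d/%d SL-positive (%.1f%%)",
                    summary.n_sl_positive, summary.n_total, summary.pct_sl_positive)

    proteins: list[ProteinSequence] = []
    models = {}
    if config.run_orfs:
        match_by_id = {m.transcript_id: m for m in matches}
        selected = []
        for contig in contigs:
            model = select_model(six_frame_orfs(contig, config.min_aa),
                                 match_by_id.get(contig.id))
            if model is not None:
                selected.append(model)
                models[contig.id] = model
                proteins.append(ProteinSequence(id=contig.id, residues=model.aa_sequence))
        models_to_dataframe(selected).to_csv(out / "protein_models.tsv", sep="\t", index=False)
        write_fasta(proteins, out / "proteins.fasta")
        report.counts["protein_models"] = len(selected)
        logger.info("orfs: %d protein models", len(selected))

    if config.run_bts and proteins:
        calls = [classify_bts(p.residues, config.bts_params, p.id) for p in proteins]
        bts_to_df(calls).to_csv(out / "bts_calls.tsv", sep="\t", index=False)
        tally = {"I": 0, "II": 0, "none": 0}
        for c in calls:
            tally[c.bts_class] += 1
        report.bts_tally = tally
        logger.info("bts: %s", tally)

    if config.run_arch and proteins:
        # the generator's reference pool doubles as the fusion reference library
        from .simulate import run_level_pool

        _, _, refs = run_level_pool(config.sim)
        write_fasta(refs, out / "references.fasta")
        arch_calls: list[ArchitectureCall] = []
        for p in proteins:
            call = detect_tandem(p.residues, protein_id=p.id)
            if call.kind == "monomer":
                fusion = detect_fusion(p.residues, refs, protein_id=p.id)
                if fusion.kind == "fusion":
                    call = fusion
            arch_calls.append(call)
        arch_to_df(arch_calls).to_csv(out / "architecture.tsv", sep="\t", index=False)
        tally = {"monomer": 0, "polyprotein": 0, "fusion": 0}
        for c in arch_calls:
            tally[c.kind] += 1
        report.arch_tally = tally
        logger.info("arch: %s", tally)

    if config.run_extend:
        mate1, mate2 = generate_reads(contigs, truths, config.sim)
        write_fastq(mate1, out / "reads_1.fastq")
        write_fastq(mate2, out / "reads_2.fastq")
        report.counts["read_pairs"] = len(mate1)
        index = build_read_index(mate1 + mate2)
        sl_negative = [c for c in contigs
                       if not next((m.detected for m in matches if m.transcript_id == c.id), False)]
        tally = {"sl_found": 0, "no_overlap": 0, "ambiguous_consensus": 0, "max_iterations": 0}
        results = []
        extended = []
        for contig in sl_negative[: config.max_extend]:
            fwd = extend_5prime(contig, index, config.sim.sl_full,
                                window=config.sl_window, min_core=config.sl_min_core)
            rev = extend_5prime(NucSequence(id=contig.id, residues=revcomp(contig.residues)),
                                index, config.sim.sl_full,
                                window=config.sl_window, min_core=config.sl_min_core)
            result = fwd
            if rev.stop_reason == "sl_found" and fwd.stop_reason != "sl_found":
                result = rev
            elif fwd.stop_reason != "sl_found" and len(rev.added_prefix) > len(fwd.added_prefix):
                result = rev
            results.append(result)
            tally[result.stop_reason] += 1
            extended.append(NucSequence(id=contig.id, residues=result.extended_sequence))
        results_to_dataframe(results).to_csv(out / "extension.tsv", sep="\t", index=False)
        write_fasta(extended, out / "extended.fasta")
        report.extend_tally = tally
        report.counts["extended_contigs"] = len(results)
        logger.info("extend: %s", tally)

    (out / "report.json").write_text(report.to_json())
    return report


def evaluate_against_truth(calls: dict, truths: list[TruthRecord]) -> pd.DataFrame:
    """Compare stage calls to generator ground truth.

    ``calls`` maps stage name to call list: ``"sl"`` -> SLMatch, ``"bts"``
    -> BTSCall, ``"arch"`` -> ArchitectureCall.  Ids must match the truth
    ids (orphans raise).  Returns a tidy metrics table with columns
    (stage, metric, value); BTS confusion cells appear as
    ``confusion[truth->called]`` rows.
    """
    truth_by_id = {t.transcript_id: t for t in truths}
    rows = []
    for stage, stage_calls in calls.items():
        ids = [getattr(c, "transcript_id", getattr(c, "protein_id", None)) for c in stage_calls]
        orphans = sorted(set(ids) - set(truth_by_id))
        if orphans:
            raise ValueError(f"{stage}: calls without truth records: {orphans}")
        if stage == "sl":
            tp = fp = tn = fn = 0
            for c in stage_calls:
                expected = truth_by_id[c.transcript_id].sl_core_survives
                if c.detected and expected:
                    tp += 1
                elif c.detected:
                    fp += 1
                elif expected:
                    fn += 1
                else:
                    tn += 1
            rows += [
                ("sl", "sensitivity", tp / (tp + fn) if tp + fn else float("nan")),
                ("sl", "specificity", tn / (tn + fp) if tn + fp else float("nan")),
                ("sl", "accuracy", (tp + tn) / len(stage_calls)),
            ]
        elif stage == "bts":
            classes = ("I", "II", "none")
            confusion = {(a, b): 0 for a in classes for b in classes}
            for c in stage_calls:
                confusion[(truth_by_id[c.protein_id].bts_class, c.bts_class)] += 1
            correct = sum(confusion[(a, a)] for a in classes)
            rows.append(("bts", "accuracy", correct / len(stage_calls)))
            for cls in classes:
                total = sum(confusion[(cls, b)] for b in classes)
                if total:
                    rows.append((f"bts", f"sensitivity[{cls}]", confusion[(cls, cls)] / total))
            for (a, b), count in sorted(confusion.items()):
                rows.append(("bts", f"confusion[{a}->{b}]", count))
        elif stage == "arch":
            correct = sum(c.kind == truth_by_id[c.protein_id].architecture for c in stage_calls)
            rows.append(("arch", "kind_accuracy", correct / len(stage_calls)))
            poly = [c for c in stage_calls
                    if truth_by_id[c.protein_id].architecture == "polyprotein"]
            if poly:
                exact = sum(c.n_units == truth_by_id[c.protein_id].n_units for c in poly)
                rows.append(("arch", "n_units_exact", exact / len(poly)))
        else:
            raise ValueError(f"unknown stage {stage!r}")
    return pd.DataFrame(rows, columns=["stage", "metric", "value"])
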