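"""End-to-end pipeline driver: detect -> consolidate -> curate -> annotate
-> summarize -> motifs -> (optional) reference comparison.

The pipeline is configured from a plain YAML file; every stage writes its
artifact under the output directory, logs its in/out counts, and a run
manifest records all parameters and the seed.  Outputs contain no
timestamps, so re-running an identical configuration reproduces the
report byte for byte.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from . import genome_io, promoter_motifs, reference_compare
from .core import AnnotatedTss, EndProfile, FeatureTable, GenomeSet, TssCall
from .promoter_motifs import MotifWindowSpec
from .tss_annotation import ClassParams, classify_all, summarize
from .tss_curation import CurationParams, cluster_and_select, consolidate_replicates, filter_trna
from .tss_detection import DetectionParams, call_tss_all

logger = logging.getLogger("tssatlas")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending record."""


@dataclass
class PipelineConfig:
    genome: str = ""
    features: str = ""
    outdir: str = "tssatlas_out"
    # conditions: {name: {replicate: {"plus": [fwd, rev], "minus": [fwd, rev]}}}
    conditions: Dict[str, Dict[str, Dict[str, List[str]]]] = field(default_factory=dict)
    detection: DetectionParams = field(default_factory=DetectionParams)
    curation: CurationParams = field(default_factory=CurationParams)
    classes: ClassParams = field(default_factory=ClassParams)
    motif_min_sequences: int = 10
    reference: Optional[str] = None
    reference_tolerance: int = 5
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key, klass in (
            ("detection", DetectionParams),
            ("curation", CurationParams),
            ("classes", ClassParams),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = klass(**kwargs[key])
        return cls(**kwargs)

    def validate(self) -> None:
        missing = []
        for label, path in [("genome", self.genome), ("features", self.features)]:
            if not path or not os.path.exists(path):
                missing.append(f"{label} file {path!r}")
        if not self.conditions:
            missing.append("at least one condition with library paths")
        for cond, reps in self.conditions.items():
            for rep, libs in reps.items():
                for kind in ("plus", "minus"):
                    if kind not in libs:
                        missing.append(f"{cond}/{rep}: missing {kind}-library paths")
                        continue
                    for p in libs[kind]:
                        if not os.path.exists(p):
                            missing.append(f"{cond}/{rep}/{kind}: {p!r}")
        if self.reference is not None and not os.path.exists(self.reference):
            missing.append(f"reference TSV {self.reference!r}")
        if missing:
            raise PipelineError("startup: missing inputs: " + "; ".join(missing))


@dataclass
class PipelineReport:
    outdir: str
    counts: Dict[str, int]
    annotated: List[AnnotatedTss]
    summary: Dict[str, object]


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run the full analysis and write all artifacts under ``config.outdir``."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    os.makedirs(config.outdir, exist_ok=True)
    counts: Dict[str, int] = {}

    genome = genome_io.read_fasta(config.genome)
    features = genome_io.read_gff3(config.features, genome=genome)
    logger.info("loaded %d replicons, %d features", len(genome), len(features))

    # detection per condition, consolidation across replicates
    per_condition: Dict[str, List[TssCall]] = {}
    n_called = 0
    for cond in sorted(config.conditions):
        rep_calls: List[List[TssCall]] = []
        for rep in sorted(config.conditions[cond]):
            libs = config.conditions[cond][rep]
            try:
                plus = genome_io.read_bedgraph_pair(*libs["plus"], "plus_lib", cond, rep)
                minus = genome_io.read_bedgraph_pair(*libs["minus"], "minus_lib", cond, rep)
            except Exception as e:
                raise PipelineError(f"detect: reading {cond}/{rep}: {e}") from e
            calls = call_tss_all(plus, minus, config.detection)
            logger.info("detect %s/%s: %d calls", cond, rep, len(calls))
            rep_calls.append(calls)
            genome_io.write_calls(
                calls, os.path.join(config.outdir, f"calls_{cond}_{rep}.tsv")
            )
        n_called += sum(len(c) for c in rep_calls)
        merged = rep_calls[0]
        for other in rep_calls[1:]:
            merged = consolidate_replicates(merged, other, config.curation)
        per_condition[cond] = merged
        genome_io.write_calls(
            merged, os.path.join(config.outdir, f"consolidated_{cond}.tsv")
        )
    counts["called"] = n_called
    counts["consolidated"] = sum(len(v) for v in per_condition.values())

    # curation: cluster resolution against the other condition, then union
    curated_by_cond: Dict[str, List[TssCall]] = {}
    for cond, calls in per_condition.items():
        others = [c for k, v in per_condition.items() if k != cond for c in v]
        curated_by_cond[cond] = cluster_and_select(calls, others, config.curation)
    union: Dict[Tuple[str, str, int], TssCall] = {}
    cond_hits: Dict[Tuple[str, str, int], List[str]] = {}
    for cond in sorted(curated_by_cond):
        for c in curated_by_cond[cond]:
            key = c.key()
            cond_hits.setdefault(key, []).append(cond)
            if key in union:
                prev = union[key]
                union[key] = TssCall(
                    replicon=c.replicon,
                    position=c.position,
                    strand=c.strand,
                    k_plus=prev.k_plus + c.k_plus,
                    k_minus=prev.k_minus + c.k_minus,
                    p_value=min(prev.p_value, c.p_value),
                    condition="",
                    replicate_support=prev.replicate_support + c.replicate_support,
                )
            else:
                union[key] = c
    clustered = sorted(union.values(), key=lambda c: (c.replicon, c.strand, c.position))
    kept, removed = filter_trna(clustered, features, config.curation)
    counts["clustered"] = len(clustered)
    counts["curated"] = len(kept)
    counts["trna_removed"] = len(removed)
    genome_io.write_calls(removed, os.path.join(config.outdir, "removed_trna.tsv"))
    logger.info(
        "curation: %d clustered, %d kept, %d tRNA-associated removed",
        len(clustered), len(kept), len(removed),
    )

    # annotation
    annotated = classify_all(kept, features, config.classes)
    for a in annotated:
        a.conditions_detected = tuple(cond_hits.get(a.call.key(), ()))
    genome_io.write_tss_outputs(
        annotated,
        os.path.join(config.outdir, "tss_annotated.tsv"),
        os.path.join(config.outdir, "tss_annotated.gff3"),
    )
    counts["annotated"] = len(annotated)

    summary = summarize(annotated, genome, config.classes)
    summary["per_replicon"].to_csv(
        os.path.join(config.outdir, "summary_per_replicon.tsv"), sep="\t", index=False
    )
    summary["class_counts"].to_csv(
        os.path.join(config.outdir, "summary_classes.tsv"), sep="\t", index=False
    )
    summary["utr_hist"].to_csv(
        os.path.join(config.outdir, "summary_utr_hist.tsv"), sep="\t", index=False
    )

    # promoter motifs from primary (P / IP) TSSs
    primary = [a for a in annotated if "P" in a.labels]
    motif_report = {}
    for spec in (MotifWindowSpec.minus10(), MotifWindowSpec.minus35()):
        if len(primary) < config.motif_min_sequences:
            logger.info("motifs %s: skipped (%d primary TSSs)", spec.name, len(primary))
            continue
        pos, neg, skipped = promoter_motifs.extract_window_sets(primary, genome, spec)
        promoter_motifs.write_fasta_set(
            pos, os.path.join(config.outdir, f"motif_{spec.name}_positive.fasta")
        )
        promoter_motifs.write_fasta_set(
            neg, os.path.join(config.outdir, f"motif_{spec.name}_negative.fasta")
        )
        if len(pos) < config.motif_min_sequences or not neg:
            continue
        pwm = promoter_motifs.oops_em(pos, width=6, negatives=neg, seed=config.seed)
        enr = promoter_motifs.score_enrichment(pwm, pos, neg, seed=config.seed)
        motif_report[spec.name] = {
            "consensus": pwm.consensus,
            "iterations": pwm.iterations,
            "enrichment_statistic": enr.statistic,
            "enrichment_p": enr.p_value,
            "n_positive": len(pos),
            "n_skipped": skipped,
        }
        with open(os.path.join(config.outdir, f"motif_{spec.name}.txt"), "w") as fh:
            fh.write(promoter_motifs.text_logo(pwm) + "\n")

    # optional comparison against published TSSs
    if config.reference is not None:
        refs = reference_compare.load_reference_table(config.reference)
        matches = reference_compare.match_reference(
            kept, refs, tolerance=config.reference_tolerance
        )
        matches.to_csv(
            os.path.join(config.outdir, "reference_matches.tsv"), sep="\t", index=False
        )
        counts["reference_matched"] = int(matches["matched"].sum())

    manifest = {
        "seed": config.seed,
        "detection": asdict(config.detection),
        "curation": asdict(config.curation),
        "classes": asdict(config.classes),
        "counts": counts,
        "motifs": motif_report,
        "utr_stats": summary["utr_stats"],
    }
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    if not (counts["curated"] <= counts["consolidated"]):
        raise PipelineError("curate: stage counts not monotone")
    return PipelineReport(config.outdir, counts, annotated, summary)
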