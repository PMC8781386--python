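"""End-to-end orchestration: select -> call -> simulate-null -> classify -> score."""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from tandemshm import calling, nullsim, scoring, selection, synth, tandems
from tandemshm.io_model import (
    GermlineAllele,
    RepertoireRecord,
    SubstitutionEvent,
    TandemShmError,
    ValidationError,
    read_dbs_catalogs,
    read_germline_fasta,
    read_rearrangements,
)

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

#: report keys required by the schema check on write
_REPORT_REQUIRED_KEYS = (
    "schema_version",
    "parameters",
    "stage_counts",
    "run_lengths",
    "ts_tv",
    "null_simulation",
    "corrected_incidence",
    "tandems",
    "resistance",
)


@dataclass
class PipelineConfig:
    """Every CLI flag, mirrored; file paths may be replaced by a synthetic
    repertoire config."""

    germline_fasta: str | None = None
    rearrangement_tsv: str | None = None
    germline_config: str | None = None
    dbs_catalog: str | None = None
    synthetic: synth.SyntheticConfig | None = None
    seed: int = 0
    reps: int = 100_000
    top_alleles: int = 20
    identity_threshold: float = 0.95
    max_mutation_fraction: float = 0.05
    collapse: bool = True
    scan_end: int | None = None

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        data = dict(data)
        synth_cfg = data.pop("synthetic", None)
        config = cls(**data)
        if synth_cfg is not None:
            config.synthetic = synth.SyntheticConfig(**synth_cfg)
        return config

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            with open(path, "rb") as fh:
                return cls.from_dict(tomllib.load(fh))
        if path.suffix in (".yaml", ".yml"):
            import yaml

            with open(path) as fh:
                return cls.from_dict(yaml.safe_load(fh))
        raise ValidationError(f"unsupported config format: {path.suffix!r}")


class StageError(TandemShmError):
    """An error raised by a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


def _load_inputs(
    config: PipelineConfig,
) -> tuple[list[GermlineAllele], list[RepertoireRecord]]:
    if config.synthetic is not None:
        scfg = config.synthetic
        alleles = synth.generate_toy_alleles(
            scfg.n_alleles, scfg.v_length, seed=scfg.seed
        )
        records, _ = synth.simulate_repertoire(scfg, alleles)
        if scfg.clonal_factor > 1:
            records = synth.expand_clones(
                records, scfg.clonal_factor, seed=scfg.seed + 1
            )
        return alleles, records
    if not config.germline_fasta or not config.rearrangement_tsv:
        raise ValidationError(
            "either a synthetic config or germline_fasta + rearrangement_tsv "
            "must be provided"
        )
    alleles = read_germline_fasta(config.germline_fasta, config.germline_config)
    records = read_rearrangements(config.rearrangement_tsv)
    return alleles, records


def select_records(
    records: Sequence[RepertoireRecord],
    allele_map: Mapping[str, GermlineAllele],
    config: PipelineConfig,
) -> tuple[list[RepertoireRecord], dict]:
    """Annotate mutation counts, collapse clones, and filter by load."""
    annotated = []
    unknown = 0
    for r in records:
        name = r.v_call.split(",")[0].strip()
        allele = allele_map.get(name)
        if allele is None:
            unknown += 1
            continue
        r.mutation_count = calling.count_mutated_positions(
            r, allele, end=config.scan_end
        )
        annotated.append(r)
    if unknown:
        logger.info("dropped %d records with unknown V allele", unknown)
    collapsed = (
        selection.collapse_clones(annotated, config.identity_threshold)
        if config.collapse
        else list(annotated)
    )
    kept, unmutated, hypermutated = selection.filter_by_mutation_load(
        collapsed, allele_map, config.max_mutation_fraction
    )
    bins = selection.bin_by_mutation_load(hypermutated, allele_map)
    counts = {
        "input": len(records),
        "known_allele": len(annotated),
        "after_collapse": len(collapsed),
        "kept": len(kept),
        "excluded_unmutated": len(unmutated),
        "excluded_hypermutated": len(hypermutated),
        "hypermutated_bins": {b: len(v) for b, v in bins.items()},
    }
    return kept, counts


def call_events(
    records: Sequence[RepertoireRecord],
    allele_map: Mapping[str, GermlineAllele],
    scan_end: int | None = None,
) -> list[SubstitutionEvent]:
    events: list[SubstitutionEvent] = []
    for r in records:
        allele = allele_map[r.v_call.split(",")[0].strip()]
        events.extend(calling.call_substitutions(r, allele, end=scan_end))
    return events


def _tandem_section(
    events: Sequence[SubstitutionEvent],
    allele_map: Mapping[str, GermlineAllele],
    dbs_catalog_path: str | None,
) -> dict:
    tdns = [e for e in events if e.k == 2]
    cats = tandems.category_counts(tdns)
    total = sum(cats.values())
    expected = tandems.expected_category_fractions()
    pooled = {
        "inversion": cats[tandems.INVERSION],
        "juxtalocation": cats[tandems.JUXTALOCATION_5P] + cats[tandems.JUXTALOCATION_3P],
        "other": cats[tandems.OTHER],
    }
    tests = {}
    if total > 0:
        for name, count in pooled.items():
            z, p = tandems.compare_fraction_to_expected(count, total, expected[name])
            tests[name] = {
                "observed_fraction": count / total,
                "expected_fraction": expected[name],
                "z": z,
                "p_value": p,
            }

    effects: Counter = Counter()
    slots: Counter = Counter()
    motif_hits: Counter = Counter()
    containment: Counter = Counter()
    for e in tdns:
        allele = allele_map.get(e.allele_name)
        if allele is None:
            continue
        call = tandems.classify_effect(e, allele)
        if call is not None:
            effects[f"slot{call.codon_slot}:{call.effect}"] += 1
            slots[f"slot{call.codon_slot}"] += 1
        annotation = tandems.annotate_aid_motifs(e, allele)
        for (motif, end, strand), flag in annotation.flags.items():
            if flag:
                motif_hits[f"{motif}/{end}/{strand}"] += 1
        containment[tandems.germline_context_containment(e, allele)] += 1

    table = tandems.build_dinuc_table(tdns)
    catalog = tandems.to_dbs78(table)
    section = {
        "n_tdns": total,
        "categories": cats,
        "pooled": pooled,
        "expected_fractions": expected,
        "fraction_tests": tests,
        "effects_by_slot": dict(effects),
        "slot_counts": dict(slots),
        "motif_summary": dict(motif_hits),
        "context_containment": dict(containment),
        "dinuc_table_total": table.total,
        "dbs78": catalog.values.tolist(),
    }
    if dbs_catalog_path and catalog.total > 0:
        cosines = {}
        for name, reference in read_dbs_catalogs(dbs_catalog_path).items():
            if reference.total > 0:
                cosines[name] = tandems.cosine_similarity(catalog, reference)
        section["cosine_similarities"] = cosines
    return section


def _resistance_section(
    events: Sequence[SubstitutionEvent],
    alleles: Sequence[GermlineAllele],
    usage_weights: Mapping[str, float],
) -> dict:
    track = scoring.build_resistance_track(events, alleles, usage_weights)
    section = {
        "n_positions": track.n_positions,
        "positions_with_sns": int(np.sum(track.n_sns > 0)),
        "total_tdns_attributed": float(track.tdns_count.sum()),
    }
    try:
        fit = scoring.quasipoisson_regression(track.tdns_count, track.score)
        section["fit"] = fit.to_dict()
    except ValidationError as exc:
        logger.info("resistance regression skipped: %s", exc)
        section["fit"] = None
        section["fit_skipped_reason"] = str(exc)
    return section


def validate_report(report: Mapping) -> None:
    missing = [k for k in _REPORT_REQUIRED_KEYS if k not in report]
    if missing:
        raise ValidationError(f"report is missing required keys {missing}")
    if report["schema_version"] != REPORT_SCHEMA_VERSION:
        raise ValidationError("report schema version mismatch")


def run_full_analysis(config: PipelineConfig) -> dict:
    """Run the whole pipeline and return the analysis report.

    Stage order: load -> select -> call -> simulate-null -> classify ->
    score.  Any stage error propagates wrapped in :class:`StageError`
    naming the stage.
    """

    def stage(name, fn, *args, **kwargs):
        try:
            out = fn(*args, **kwargs)
        except TandemShmError as exc:
            raise StageError(name, exc) from exc
        logger.info("stage %s done", name)
        return out

    alleles, records = stage("load", _load_inputs, config)
    allele_map = {a.name: a for a in alleles}
    kept, stage_counts = stage("select", select_records, records, allele_map, config)
    events = stage("call", call_events, kept, allele_map, config.scan_end)
    stage_counts["events"] = len(events)

    run_lengths = calling.tabulate_run_lengths(events)
    ts_tv = calling.compute_ts_tv(events)

    usage = Counter(r.v_call.split(",")[0].strip() for r in kept)
    top = [name for name, _ in usage.most_common(config.top_alleles)]
    profiles = {
        name: nullsim.build_position_profile(kept, allele_map[name], events)
        for name in top
    }
    result = stage(
        "simulate-null",
        nullsim.run_null_simulation,
        kept,
        profiles,
        events,
        config.reps,
        config.seed,
    )
    modelled_events = sum(s.observed for s in result.stats.values())
    extrapolation = len(events) / modelled_events if modelled_events else float("nan")
    try:
        incidence = nullsim.corrected_incidence(result)
    except ValidationError as exc:
        raise StageError("simulate-null", exc) from exc

    tandem_section = stage(
        "classify", _tandem_section, events, allele_map, config.dbs_catalog
    )
    weights = {name: float(c) for name, c in usage.items()}
    used_alleles = [allele_map[name] for name in sorted(weights)]
    resistance = stage("score", _resistance_section, events, used_alleles, weights)

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "parameters": {
            "seed": config.seed,
            "reps": config.reps,
            "top_alleles": config.top_alleles,
            "identity_threshold": config.identity_threshold,
            "max_mutation_fraction": config.max_mutation_fraction,
            "collapse": config.collapse,
            "scan_end": config.scan_end,
            "synthetic": (
                None if config.synthetic is None else vars(config.synthetic)
            ),
        },
        "stage_counts": stage_counts,
        "run_lengths": {str(k): v for k, v in sorted(run_lengths.items())},
        "ts_tv": None if np.isnan(ts_tv) else ts_tv,
        "null_simulation": result.to_dict(),
        "corrected_incidence": {
            "adjusted_sns": incidence["adjusted_sns"],
            "corrected_counts": {
                str(k): v for k, v in incidence["corrected_counts"].items()
            },
            "denominator": incidence["denominator"],
            "incidence": {str(k): v for k, v in incidence["incidence"].items()},
            "cumulative_tandem_incidence": incidence["cumulative_tandem_incidence"],
            "cumulative_se_mc": incidence["cumulative_se_mc"],
        },
        "extrapolation_factor": extrapolation,
        "tandems": tandem_section,
        "resistance": resistance,
    }
    validate_report(report)
    return report
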