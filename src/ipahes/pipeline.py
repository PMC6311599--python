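"""End-to-end pipeline: synth -> select -> link -> anchors -> summarize.

Every stage is a pure function of its inputs and configuration; all
randomness lives in the synthetic generator, so a fixed config + seed
reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import defaults, io, synth
from .anchors import AnchorConfig, first_symptom_specialty_distribution, validation_eligibility
from .hcru import summarize
from .linkage import LinkPolicy, LinkStatus, link, merge_registries
from .records import FinalDiagnosis
from .selection import SelectionConfig, demographics_profile, select

log = logging.getLogger("ipahes")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    out_dir: Path
    seed: int = 0
    # synthetic-data branch
    n_cases: int = 200
    n_per_violator: int = 40
    n_validation_cases: int = 200
    # or pre-existing tables
    episodes_path: Optional[Path] = None
    demographics_path: Optional[Path] = None
    registry_path: Optional[Path] = None
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    anchor: AnchorConfig = field(default_factory=AnchorConfig)
    link_policy: LinkPolicy = LinkPolicy.STRICT

    @property
    def uses_synth(self) -> bool:
        return self.episodes_path is None


def load_run_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file; referenced files must exist
    (a missing code-list or table aborts before any computation)."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    base = path.parent

    def resolve(p: Optional[str]) -> Optional[Path]:
        if p is None:
            return None
        rp = (base / p) if not Path(p).is_absolute() else Path(p)
        if not rp.exists():
            raise FileNotFoundError(f"config {path}: referenced file missing: {rp}")
        return rp

    sel_kwargs = {}
    sel_raw = raw.get("selection", {})
    for key, attr in [
        ("ph_codes", "ph_codes"),
        ("non_ipah_codes", "non_ipah_exclusion_codes"),
        ("rhc_codes", "rhc_procedure_codes"),
    ]:
        if key in sel_raw:
            sel_kwargs[attr] = io.load_code_list(resolve(sel_raw[key]))
    if "earliest_diagnosis" in sel_raw:
        sel_kwargs["earliest_diagnosis_for_inclusion"] = _dt.date.fromisoformat(
            str(sel_raw["earliest_diagnosis"])
        )
    if "hcru_cap" in sel_raw:
        sel_kwargs["hcru_cap"] = int(sel_raw["hcru_cap"])

    anc_kwargs = {}
    anc_raw = raw.get("anchors", {})
    if "symptom_codes_icd10" in anc_raw:
        anc_kwargs["symptom_codes_icd10"] = io.load_code_list(resolve(anc_raw["symptom_codes_icd10"]))
    if "symptom_codes_opcs" in anc_raw:
        anc_kwargs["symptom_codes_opcs"] = io.load_code_list(resolve(anc_raw["symptom_codes_opcs"]))

    inputs = raw.get("inputs", {})
    synth_raw = raw.get("synth", {})
    return RunConfig(
        out_dir=Path(raw.get("out_dir", "ipahes_out")),
        seed=int(raw.get("seed", 0)),
        n_cases=int(synth_raw.get("n_cases", 200)),
        n_per_violator=int(synth_raw.get("n_per_violator", 40)),
        n_validation_cases=int(synth_raw.get("n_validation_cases", 200)),
        episodes_path=resolve(inputs.get("episodes")),
        demographics_path=resolve(inputs.get("demographics")),
        registry_path=resolve(inputs.get("registry")),
        selection=SelectionConfig(**sel_kwargs),
        anchor=AnchorConfig(**anc_kwargs),
    )


def _default_dataset(cfg: RunConfig) -> synth.GeneratedDataset:
    gen = synth.default_phase1_config(cfg.seed, cfg.n_cases, cfg.n_per_violator)
    subpops = list(gen.subpopulations) + [synth.phase2_case_spec(cfg.n_validation_cases)]
    return synth.generate(dataclasses.replace(gen, subpopulations=subpops))


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Run all stages and write the artifact set; returns the manifest.

    On any stage error, partially written outputs are removed and a
    PipelineError naming the stage is raised.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}

    def emit(name: str, writer) -> None:
        p = out / name
        writer(p)
        manifest[name] = p
        log.info("wrote %s", p)

    try:
        # --- inputs -------------------------------------------------------
        stage = "synth"
        if cfg.uses_synth:
            ds = _default_dataset(cfg)
            records = ds.records()
            registry_rows = ds.registry
            emit("episodes.csv", lambda p: io.write_events(records, p, out / "demographics.csv"))
            manifest["demographics.csv"] = out / "demographics.csv"
            emit("registry.csv", lambda p: io.write_registry(registry_rows, p))
            emit("ground_truth.csv", lambda p: ds.ground_truth.to_csv(p, index=False))
        else:
            stage = "load"
            records = io.read_events(cfg.episodes_path, cfg.demographics_path)
            registry_rows = io.read_registry(cfg.registry_path) if cfg.registry_path else []
        demographics = {r.patient_id: r.demographics for r in records}
        log.info("input: %d patients, %d events", len(records), sum(len(r.events) for r in records))

        # --- Phase-1 arm: selection cascade -------------------------------
        stage = "select"
        outcomes, attrition = select(records, cfg.selection)
        emit(
            "outcomes.csv",
            lambda p: pd.DataFrame(
                [
                    {
                        "patient_id": o.patient_id,
                        "included": o.included,
                        "exclusion_rule": o.exclusion_rule.value,
                        "diagnosis_date": o.diagnosis_date.isoformat() if o.diagnosis_date else "",
                    }
                    for o in outcomes
                ]
            ).to_csv(p, index=False),
        )
        emit("attrition.csv", lambda p: attrition.to_frame().to_csv(p, index=False))

        included = {o.patient_id: o.diagnosis_date for o in outcomes if o.included}
        records_by_id = {r.patient_id: r for r in records}
        phase1_summary = (
            summarize(records_by_id, included, vocabulary=cfg.anchor.specialty_vocabulary)
            if included
            else None
        )
        if phase1_summary is not None:
            emit("hcru_summary_phase1.csv", lambda p: phase1_summary.table.to_csv(p, index=False))

        # --- Phase-2 arm: merge, link, anchors, summarize ------------------
        stage = "link"
        merged = merge_registries(registry_rows)
        results, rate = link(merged, demographics.values(), cfg.link_policy)
        emit(
            "linkage_results.csv",
            lambda p: pd.DataFrame(
                [
                    {
                        "nhs_identifier": r.registry_record.nhs_identifier or "",
                        "final_diagnosis": r.registry_record.final_diagnosis.value,
                        "status": r.status.value,
                        "linked_patient_id": r.linked_patient_id or "",
                        "mismatched_fields": ";".join(sorted(r.mismatched_fields)),
                    }
                    for r in results
                ]
            ).to_csv(p, index=False),
        )
        log.info("linkage rate: %.1f%%", rate)

        stage = "anchors"
        ipah_results = [
            r for r in results if r.registry_record.final_diagnosis is FinalDiagnosis.IPAH
        ]
        first_visits = {
            (r.registry_record.nhs_identifier or f"<none:{i}>"): r.registry_record.first_visit_date
            for i, r in enumerate(ipah_results)
        }
        linked_ids = [
            r.linked_patient_id for r in ipah_results if r.status is LinkStatus.LINKED
        ]
        eligible, v_attrition = validation_eligibility(
            records_by_id, first_visits, linked_ids, cfg.anchor
        )
        emit("validation_attrition.csv", lambda p: io.write_attrition(v_attrition, p))
        emit(
            "anchors.csv",
            lambda p: pd.DataFrame(
                [
                    {
                        "patient_id": a.patient_id,
                        "index_date": a.index_date.isoformat(),
                        "lookback_date": a.lookback_date.isoformat(),
                        "first_symptom_date": a.first_symptom_date.isoformat()
                        if a.first_symptom_date
                        else "",
                        "first_symptom_specialty": a.first_symptom_specialty or "",
                        "first_center_visit": a.first_center_visit.isoformat(),
                    }
                    for a in eligible.values()
                ]
            ).to_csv(p, index=False),
        )

        stage = "summarize"
        report_lines = [
            "ipahes pipeline report",
            "======================",
            "",
            "Phase-1 selection attrition:",
            *(f"  {rule:<22s} {n:>7d}" for rule, n in attrition.rows),
            "",
            f"Linkage rate: {rate:.1f}% ({len(results)} registry records)",
            "",
            "Validation-cohort attrition:",
            *(f"  {rule:<22s} {n:>7d}" for rule, n in v_attrition),
        ]
        if eligible:
            anchors_dates = {pid: a.index_date for pid, a in eligible.items()}
            lookbacks = {pid: a.lookback_date for pid, a in eligible.items()}
            phase2_summary = summarize(
                records_by_id,
                anchors_dates,
                vocabulary=cfg.anchor.specialty_vocabulary,
                observation_start=lookbacks,
            )
            emit("hcru_summary.csv", lambda p: phase2_summary.table.to_csv(p, index=False))
            dist, n_absent = first_symptom_specialty_distribution(eligible.values())
            overview = {
                "n_eligible": phase2_summary.n_patients,
                "mean_events_3y": phase2_summary.mean_total_span,
                "mean_distinct_providers": phase2_summary.mean_distinct_providers,
                "mean_distinct_specialties": phase2_summary.mean_distinct_specialties,
                "cardio_thoracic_share": phase2_summary.cardio_thoracic_share,
                "n_without_first_symptom": n_absent,
            }
            emit(
                "cohort_overview.csv",
                lambda p: pd.DataFrame([overview]).to_csv(p, index=False),
            )
            report_lines += [
                "",
                f"Eligible validation cohort: {phase2_summary.n_patients} patients",
                f"Mean events in 3 pre-index years: {phase2_summary.mean_total_span:.1f}",
                f"Cardiology/thoracic share: {100 * phase2_summary.cardio_thoracic_share:.1f}%",
                "First-symptom specialty distribution (%):",
                *(f"  {k:<22s} {v:>6.1f}" for k, v in dist.items()),
            ]
        emit("report.txt", lambda p: p.write_text("\n".join(report_lines) + "\n"))
        return manifest
    except Exception as exc:
        for p in manifest.values():
            p.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc
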