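"""End-to-end orchestration: inputs -> QC -> annotation/recalibration ->
isobar resolution -> records -> validation/summary -> deposition.

Every stage writes its artifact under the output directory and the run
returns (and writes) a manifest with paths and counts.  Failures local to
one compound (e.g. a rejected spectrum) never abort the run; they are
logged with machine-readable reasons.  With a fixed seed and an injected
record date the artifacts are byte-for-byte reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple


from . import annotate, deposition, isobars, msio, prescreen, records

logger = logging.getLogger("mixlib")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    mzml_dir: str
    compounds: str
    setid: str
    settings: str
    output_dir: str
    thresholds: prescreen.QCThresholds = field(
        default_factory=prescreen.QCThresholds)
    pre_recal_ppm: float = annotate.PRE_RECAL_PPM
    post_recal_ppm: float = annotate.POST_RECAL_PPM
    rt_anchor_tol: float = 0.5  # minutes
    isolation_window: float = isobars.ISOLATION_WINDOW_DA
    badlist: Optional[str] = None
    adduct_positive: str = "[M+H]+"
    adduct_negative: str = "[M-H]-"
    record_date: str = "2021.01.28"
    serial_start: int = 100001
    seed: int = 0

    def validate(self) -> None:
        for name in ("mzml_dir", "compounds", "setid", "settings"):
            path = Path(getattr(self, name))
            if not path.exists():
                raise FileNotFoundError(f"{name}: {path}")
        if self.badlist and not Path(self.badlist).exists():
            raise FileNotFoundError(f"badlist: {self.badlist}")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        thresholds = prescreen.QCThresholds(**data.pop("thresholds", {}))
        return cls(thresholds=thresholds, **data)


def _discover_runs(mzml_dir) -> List[Tuple[str, str, float, Path]]:
    """(mix, mode, CE, path) per run file named mix<MIX>_<pos|neg>_ce<CE>."""
    out = []
    for path in sorted(Path(mzml_dir).glob("*.mzML")):
        stem = path.stem
        try:
            mix_part, mode_part, ce_part = stem.split("_")
            mix = mix_part.removeprefix("mix")
            mode = "+" if mode_part == "pos" else "-"
            ce = float(ce_part.removeprefix("ce"))
        except ValueError:
            logger.warning("skipping unrecognized run file name %s", path.name)
            continue
        out.append((mix, mode, ce, path))
    return out


def _qc_grade_peaks(qc_results: Mapping[Tuple[str, str], prescreen.QCResult],
                    group: isobars.IsobarGroup,
                    thresholds: prescreen.QCThresholds
                    ) -> List[prescreen.ChromPeak]:
    """Distinct QC-grade chromatographic peaks in a group's m/z window.

    Group members share (within tolerance) one EIC, so peaks of different
    members at the same RT are the same physical peak; deduplicate by RT.
    """
    peaks: List[prescreen.ChromPeak] = []
    seen = set()
    for cid in group.members:
        result = qc_results.get((group.mix, cid))
        if result is None:
            continue
        for peak in result.peaks:
            key = round(peak.rt, 3)
            if (peak.intensity >= thresholds.min_intensity
                    and peak.snr >= thresholds.min_snr
                    and key not in seen):
                seen.add(key)
                peaks.append(peak)
    return sorted(peaks, key=lambda p: p.rt)


def run_pipeline(config: PipelineConfig) -> Dict:
    """Run all stages; returns the artifact manifest (also written to
    ``manifest.json`` in the output directory)."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    entries, problems = msio.read_compound_list(config.compounds)
    by_id = {e.identifier: e for e in entries}
    design = msio.read_setid(config.setid, compounds=entries)
    settings = msio.read_settings(config.settings)
    exclusions: List[Dict[str, str]] = []
    for problem in problems:
        exclusions.append({"stage": "input", "reason": "bad_smiles",
                           "detail": problem})

    run_index = _discover_runs(config.mzml_dir)
    adduct_of = {"+": config.adduct_positive, "-": config.adduct_negative}

    # ---- stage 1: prescreen ------------------------------------------------
    qc_results: List[prescreen.QCResult] = []
    #: reference (lowest-CE) QC per (mode, mix, compound), for RT anchoring
    reference_qc: Dict[str, Dict[Tuple[str, str], prescreen.QCResult]] = {}
    runs_by_key: Dict[Tuple[str, str, float], msio.Run] = {}
    for mix, mode, ce, path in run_index:
        run = msio.read_run(path, mix=mix, mode=mode, collision_energy=ce)
        runs_by_key[(mix, mode, ce)] = run
        members = [by_id[c] for c in sorted(design.compounds_in(mix))
                   if c in by_id]
        for entry in members:
            result = prescreen.qc_compound(
                run, entry, adduct_of[mode], config.thresholds)
            qc_results.append(result)
            ref = reference_qc.setdefault(mode, {})
            key = (mix, entry.identifier)
            if key not in ref or (ref[key].collision_energy or 0.0) > ce:
                ref[key] = result
    qc_table = prescreen.prescreen_table(qc_results)
    qc_path = outdir / "prescreen.csv"
    qc_table.to_csv(qc_path, index=False)

    # ---- stage 2: isobar grouping + resolution per mode --------------------
    assignments_all: List[isobars.Assignment] = []
    assignment_of: Dict[Tuple[str, str, str], isobars.Assignment] = {}
    for mode in sorted(reference_qc):
        groups = isobars.group_isobars(
            design, by_id, adduct_of[mode], config.isolation_window)
        detections = {
            g: _qc_grade_peaks(reference_qc[mode], g, config.thresholds)
            for g in groups
        }
        for assignment in isobars.resolve(groups, detections,
                                          rt_tol=config.rt_anchor_tol):
            assignments_all.append(assignment)
            assignment_of[(mode, assignment.mix,
                           assignment.compound_id)] = assignment
    assign_rows = [
        {"mode": mode, "mix": a.mix, "compound": a.compound_id,
         "level": a.level, "rationale": a.rationale,
         "rt": "" if a.rt is None else f"{a.rt:.3f}"}
        for (mode, _, _), a in sorted(assignment_of.items())
    ]
    import pandas as pd

    assign_path = outdir / "assignments.csv"
    pd.DataFrame(assign_rows, columns=[
        "mode", "mix", "compound", "level", "rationale", "rt"]
    ).to_csv(assign_path, index=False)

    # ---- stage 3: annotation + recalibration per run -----------------------
    spectra: List[annotate.CleanSpectrum] = []
    for (mix, mode, ce), run in sorted(runs_by_key.items()):
        annotated_by_compound: List[Tuple[msio.CompoundEntry, int,
                                          List[annotate.AnnotatedPeak]]] = []
        for entry_id in sorted(design.compounds_in(mix)):
            entry = by_id.get(entry_id)
            if entry is None:
                continue
            assignment = assignment_of.get((mode, mix, entry_id))
            if assignment is None or assignment.level != isobars.LEVEL_CONFIRMED:
                continue
            qc = next((r for r in qc_results
                       if r.mix == mix and r.compound_id == entry_id
                       and r.polarity == mode and r.collision_energy == ce),
                      None)
            if qc is None or not qc.verdict or not qc.ms2_matches:
                continue
            # the matched MS2 nearest the assigned peak's RT
            scan_idx = min(
                qc.ms2_matches,
                key=lambda i: abs(run.scans[i].retention_time
                                  - (assignment.rt or 0.0)))
            scan = run.scans[scan_idx]
            if abs(scan.retention_time - (assignment.rt or 0.0)) \
                    > config.rt_anchor_tol:
                exclusions.append({
                    "stage": "annotate", "reason": "no_ms2_at_assigned_rt",
                    "detail": f"{entry_id} {mix} {mode} ce{ce:g}"})
                continue
            try:
                annotated = annotate.annotate_spectrum(
                    scan, entry, adduct_of[mode], config.pre_recal_ppm)
            except ValueError as exc:
                exclusions.append({"stage": "annotate",
                                   "reason": "annotation_failed",
                                   "detail": f"{entry_id}: {exc}"})
                continue
            annotated_by_compound.append((entry, scan_idx, annotated))
        if not annotated_by_compound:
            continue
        pairs = annotate.collect_calibration_pairs(
            [a for (_, _, a) in annotated_by_compound])
        model = None
        if len(pairs) >= 2:
            model = annotate.fit_recalibration(pairs)
        for entry, scan_idx, annotated in annotated_by_compound:
            scan = run.scans[scan_idx]
            if model is not None:
                scan = annotate.apply_recalibration(scan, model)
                annotated = annotate.annotate_spectrum(
                    scan, entry, adduct_of[mode], config.post_recal_ppm)
            assignment = assignment_of[(mode, mix, entry.identifier)]
            spectrum = annotate.clean_spectrum(
                annotated,
                compound_id=entry.identifier, mix=mix, polarity=mode,
                collision_energy=ce,
                precursor_mz=entry.ion_mz(adduct_of[mode]),
                retention_time=float(assignment.rt or 0.0),
                provenance={
                    "pre_recal_ppm": config.pre_recal_ppm,
                    "post_recal_ppm": config.post_recal_ppm,
                    "recal_kind": 1.0 if model is None else 2.0,
                },
            )
            if spectrum.n_peaks:
                spectra.append(spectrum)
    spectra_path = outdir / "spectra.jsonl"
    with open(spectra_path, "w") as handle:
        for spectrum in spectra:
            handle.write(annotate.spectrum_to_json(spectrum) + "\n")

    # ---- stage 4: isobar filter + record build -----------------------------
    kept, exclusion_log = isobars.filter_records(spectra, assignments_all)
    for line in exclusion_log:
        exclusions.append({"stage": "isobar_filter",
                           "reason": "not_level1", "detail": line})
    records_dir = outdir / "records"
    records_dir.mkdir(exist_ok=True)
    built: List[records.MassBankRecord] = []
    serial = config.serial_start
    for spectrum in sorted(kept, key=lambda s: (
            s.compound_id, s.mix, s.polarity,
            s.collision_energy or 0.0)):
        entry = by_id[spectrum.compound_id]
        assignment = assignment_of[(spectrum.polarity, spectrum.mix,
                                    spectrum.compound_id)]
        adduct = adduct_of[spectrum.polarity]
        code = f"{settings.accession_prefix}{serial:06d}"
        try:
            record = records.build_record(
                entry, spectrum, assignment, settings, code,
                adduct=adduct, date=config.record_date,
                base_peak_min=settings.base_peak_min)
        except records.RecordRejected as exc:
            exclusions.append({"stage": "record", "reason": "rejected",
                               "detail": str(exc)})
            continue
        records.write_record(record, records_dir / f"{record.accession}.txt")
        built.append(record)
        serial += 1

    # ---- stage 5: validation + summary -------------------------------------
    reports = [records.validate_record(r) for r in built]
    invalid = [rep for rep in reports if not rep.ok]
    summary = records.summarize_records(records_dir, [
        "ACCESSION", "CH$NAME", "CH$FORMULA", "CH$EXACT_MASS",
        "AC$MASS_SPECTROMETRY: COLLISION_ENERGY",
        "AC$CHROMATOGRAPHY: RETENTION_TIME", "PK$SPLASH", "PK$NUM_PEAK",
    ])
    summary_path = outdir / "record_summary.csv"
    summary.to_csv(summary_path, index=False)

    # ---- stage 6: deposition ------------------------------------------------
    rows = [deposition.extract_fields(r) for r in built]
    badlist = (deposition.BadList.from_file(config.badlist)
               if config.badlist else deposition.BadList())
    substances, removal_counts = deposition.build_substance_table(
        rows, badlist)
    annotations, mapping = deposition.build_annotation_table(rows)
    substances_path = outdir / "substances.csv"
    substances.to_csv(substances_path, index=False)
    annotations_path = outdir / "annotations.csv"
    annotations.to_csv(annotations_path, index=False)
    mapping_path = outdir / "mapping.json"
    mapping_path.write_text(json.dumps(mapping or {}, sort_keys=True,
                                       indent=0) + "\n")

    exclusions_path = outdir / "exclusions.jsonl"
    with open(exclusions_path, "w") as handle:
        for item in exclusions:
            handle.write(json.dumps(item, sort_keys=True) + "\n")

    artifacts = {
        "prescreen": qc_path,
        "assignments": assign_path,
        "spectra": spectra_path,
        "records_dir": records_dir,
        "record_summary": summary_path,
        "substances": substances_path,
        "annotations": annotations_path,
        "mapping": mapping_path,
        "exclusions": exclusions_path,
    }
    manifest = {
        "artifacts": {k: str(v) for k, v in artifacts.items()},
        "counts": {
            "compounds": len(entries),
            "runs": len(run_index),
            "qc_rows": int(len(qc_table)),
            "qc_passes": int((qc_table["verdict"] == "pass").sum()),
            "assignments_level1": sum(
                1 for a in assignment_of.values()
                if a.level == isobars.LEVEL_CONFIRMED),
            "spectra": len(spectra),
            "spectra_retained": len(kept),
            "records": len(built),
            "records_invalid": len(invalid),
            "deposition_rows": int(len(annotations)),
            "substances": int(len(substances)),
            "substance_removals": removal_counts,
            "exclusions": len(exclusions),
        },
    }
    # the on-disk manifest uses paths relative to the output directory so
    # that reruns in different locations stay byte-identical
    disk_manifest = dict(manifest)
    disk_manifest["artifacts"] = {k: v.name for k, v in artifacts.items()}
    (outdir / "manifest.json").write_text(
        json.dumps(disk_manifest, sort_keys=True, indent=2) + "\n")
    return manifest
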