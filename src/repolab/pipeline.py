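"""Cohort orchestration: simulate or load, per-subject markers, statistics.

``run_subject`` carries one recording through quality control, beat
segmentation, morphology (both a random beat and the averaged beat) and V5
interval measurement, catching stage failures so one bad record never aborts
a cohort run.  ``run_cohort`` drives the whole study: subject loop, summary
table, confounder model, and a manifest that makes the run reproducible.
Cohort-level exclusions are declarative filters (column / op / value)
applied to the covariate table before any ECG is analysed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import operator
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .beat_processing import (average_beat, detect_r_peaks, quality_check,
                              segment_beats, select_random_beat)
from .cohort_stats import build_summary_table, fit_linear_model
from .ecg_io import EcgRecord, read_cohort, read_ecg
from .errors import NoUsableSubjectsError, RepolabError
from .intervals import measure_intervals
from .morphology import compute_markers
from .synthetic_ecg import CohortSimConfig, generate_cohort

logger = logging.getLogger(__name__)

#: Exclusion filters mirroring a pre-ECG clinical screen: subjects matching
#: any filter are removed.  Filters referring to columns absent from the
#: covariate table are skipped.
DEFAULT_EXCLUSION_FILTERS = (
    {"column": "age", "op": "<", "value": 18},
    {"column": "history_mi", "op": "==", "value": 1},
    {"column": "prior_angiography", "op": "==", "value": 1},
    {"column": "cabg", "op": "==", "value": 1},
    {"column": "fhx_sudden_death", "op": "==", "value": 1},
    {"column": "pregnant", "op": "==", "value": 1},
    {"column": "surgery_or_malignancy", "op": "==", "value": 1},
    {"column": "atrial_fibrillation", "op": "==", "value": 1},
    {"column": "pacemaker", "op": "==", "value": 1},
)

_OPS = {"==": operator.eq, "!=": operator.ne, "<": operator.lt,
        "<=": operator.le, ">": operator.gt, ">=": operator.ge,
        "in": lambda s, v: s.isin(v)}


def apply_exclusions(cohort: pd.DataFrame, filters=DEFAULT_EXCLUSION_FILTERS
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply declarative exclusion filters to a covariate table.

    Returns ``(included, bookkeeping)`` where the bookkeeping frame lists one
    row per filter with the number of subjects it excluded (counted after
    the preceding filters, so the counts sum to the total excluded).
    """
    remaining = cohort.copy()
    rows = []
    for f in filters:
        col, op, value = f["column"], f["op"], f["value"]
        if col not in remaining.columns:
            continue
        series = remaining[col]
        hit = _OPS[op](series, value) if op == "in" else _OPS[op](series, value)
        hit = hit.fillna(False).astype(bool)
        rows.append({"column": col, "op": op, "value": value,
                     "excluded": int(hit.sum())})
        remaining = remaining[~hit]
    return remaining, pd.DataFrame(rows)


@dataclass
class RunConfig:
    """Everything a cohort run needs; hashable into the manifest."""
    seed: int = 0
    modes: tuple[str, ...] = ("random", "averaged")
    input_dir: str | None = None            # None -> simulate
    sim: CohortSimConfig | None = None
    out_dir: str = "results"
    qrs_energy_threshold: float = 0.7
    exclusion_filters: tuple = DEFAULT_EXCLUSION_FILTERS

    def __post_init__(self) -> None:
        if not self.modes:
            raise ValueError("at least one beat mode required")
        if self.input_dir is None and self.sim is None:
            self.sim = CohortSimConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "modes"},
                  modes=tuple(raw.get("modes", ("random", "averaged"))))
        if sim is not None:
            cfg.sim = CohortSimConfig(**sim)
        return cfg

    def digest(self) -> str:
        payload = dataclasses.asdict(self)
        if self.sim is not None:
            payload["sim"] = dataclasses.asdict(self.sim)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _subject_seed(base_seed: int, subject_id: str) -> int:
    return int(np.random.SeedSequence(
        [base_seed, zlib.crc32(subject_id.encode())]).generate_state(1)[0] % (2**31))


def run_subject(record: EcgRecord, config: RunConfig) -> dict:
    """Analyse one recording into a flat result row.

    The row always contains the subject id and QC outcome; markers and
    intervals are filled only for usable records, and any stage error is
    captured in the ``error`` field instead of propagating.
    """
    row: dict = {"subject_id": record.subject_id, "usable": False, "error": ""}
    try:
        qc = quality_check(record)
        row["qc_displaced"] = ",".join(qc.displaced_leads)
        row["qc_interference"] = ",".join(qc.high_interference_leads)
        if not qc.usable:
            row["error"] = "failed quality control"
            return row
        r_idx = detect_r_peaks(record)
        beats = segment_beats(record, r_idx)
        chosen = {}
        if "averaged" in config.modes:
            chosen["averaged"] = average_beat(beats)
        if "random" in config.modes:
            chosen["random"] = select_random_beat(
                beats, seed=_subject_seed(config.seed, record.subject_id))
        for mode, beat in chosen.items():
            m = compute_markers(beat, energy_threshold=config.qrs_energy_threshold)
            row[f"tcrt_{mode}"] = m.tcrt
            row[f"tmd_{mode}"] = m.tmd
            row[f"tmd_pre_{mode}"] = m.tmd_pre
            row[f"tmd_post_{mode}"] = m.tmd_post
            row[f"energy_fraction_3_{mode}"] = m.energy_fraction_3
        # intervals from the averaged beat (mode-consistent with morphology)
        beat = chosen.get("averaged") or next(iter(chosen.values()))
        try:
            from .decomposition import detect_landmarks, energy_vector, svd_decompose
            dec = svd_decompose(beat.samples, beat.fs, r_index=beat.r_index)
            lm = detect_landmarks(energy_vector(dec), r_hint=beat.r_index)
            v5 = beat.samples[beat.lead_names.index("V5")]
            rr = float(np.mean(np.diff(r_idx))) / record.fs
            iv = measure_intervals(v5, lm, rr=rr, fs=beat.fs)
            row.update(iv.report())
        except RepolabError as exc:  # interval failure leaves missing cells
            logger.warning("subject %s: interval measurement failed (%s)",
                           record.subject_id, exc)
        row["usable"] = True
    except RepolabError as exc:
        row["error"] = str(exc)
        logger.warning("subject %s failed: %s", record.subject_id, exc)
    return row


def _load_records(input_dir: Path) -> tuple[list[EcgRecord], pd.DataFrame]:
    cohort = read_cohort(input_dir / "cohort.csv")
    records = []
    for sid in cohort["subject_id"]:
        csv = input_dir / f"{sid}.csv"
        if csv.exists():
            records.append(read_ecg(csv, format="csv"))
        else:
            records.append(read_ecg(input_dir / sid, format="wfdb"))
    return records, cohort


def _fit_confounder_model(usable: pd.DataFrame, outcome: str):
    """Fit the confounder OLS defensively: drop covariates that are constant
    in the analysed subset and skip the model entirely when the cohort is
    too small to identify it."""
    from .cohort_stats import _DEFAULT_COVARIATES

    covariates = [c for c in _DEFAULT_COVARIATES
                  if c in usable.columns and usable[c].nunique() > 1]
    if len(usable.dropna(subset=[outcome])) < len(covariates) + 3:
        logger.warning("cohort too small for the %d-covariate linear model; "
                       "skipped", len(covariates))
        return None
    try:
        return fit_linear_model(usable, outcome=outcome, covariates=covariates)
    except RepolabError as exc:
        logger.warning("confounder model not fitted: %s", exc)
        return None


MARKER_COLUMNS = ("tcrt_random", "tmd_random", "tmd_pre_random", "tmd_post_random",
                  "tcrt_averaged", "tmd_averaged", "tmd_pre_averaged",
                  "tmd_post_averaged", "qt_ms", "qtc_ms", "tpe_ms",
                  "tpe_qt", "tpe_qtc")


def run_cohort(config: RunConfig) -> dict:
    """Full study pipeline; returns the result artefacts and writes them.

    Deterministic given (inputs, seed).  Output files: ``results.csv``,
    ``summary.csv``/``summary.json``, ``model.json``, ``manifest.json`` and
    ``run.log`` under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root_logger = logging.getLogger("repolab")
    root_logger.addHandler(handler)
    try:
        if config.input_dir is not None:
            records, cohort = _load_records(Path(config.input_dir))
        else:
            records, cohort = generate_cohort(config.sim)
        cohort, exclusions = apply_exclusions(cohort, config.exclusion_filters)
        by_id = {r.subject_id: r for r in records}
        rows = [run_subject(by_id[sid], config) for sid in cohort["subject_id"]]
        results = pd.DataFrame(rows)
        if not results["usable"].any():
            raise NoUsableSubjectsError("no usable subjects")
        merged = cohort.merge(results, on="subject_id", how="inner")
        usable = merged[merged["usable"]]
        group_counts = usable["group"].value_counts()
        if (group_counts < 2).any() or len(group_counts) < 2:
            logger.warning("fewer than 2 usable subjects in a group; "
                           "group comparisons skipped")
            summary = pd.DataFrame()
            model = None
        else:
            variables = [c for c in usable.columns
                         if c in ("age", "sex", "height", "weight", "bmi",
                                  "sbp", "dbp") or c in
                         ("dyslipidemia", "hypertension", "fhx_ihd", "aspirin",
                          "acei_arb", "ccb", "beta_blocker", "statin",
                          "thiazide", "current_smoker", "past_smoker")
                         or c in MARKER_COLUMNS]
            summary = build_summary_table(usable, variables=variables)
            outcome = ("tcrt_averaged" if "tcrt_averaged" in usable.columns
                       else "tcrt_random")
            model = _fit_confounder_model(usable, outcome)

        results.to_csv(out / "results.csv", index=False, float_format="%.6f")
        summary.to_csv(out / "summary.csv", index=False)
        summary.to_json(out / "summary.json", orient="records", indent=2)
        if model is not None:
            (out / "model.json").write_text(json.dumps({
                "outcome": model.outcome, "n": model.n,
                "r_squared": model.r_squared,
                "coefficients": model.coefficients.round(6).to_dict(orient="index"),
            }, indent=2))
        (out / "manifest.json").write_text(json.dumps({
            "version": __version__, "seed": config.seed,
            "config_hash": config.digest(),
            "n_recruited": int(len(records)),
            "n_included": int(len(cohort)),
            "n_usable": int(usable.shape[0]),
        }, indent=2))
        exclusions.to_csv(out / "exclusions.csv", index=False)
        return {"results": results, "summary": summary, "model": model,
                "cohort": cohort, "exclusions": exclusions}
    finally:
        root_logger.removeHandler(handler)
        handler.close()
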