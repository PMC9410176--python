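"""Reading and writing 12-lead ECG recordings and cohort covariate tables.

Two interchange dialects are supported:

* **CSV** — one column per lead, header row with lead names, plus a JSON
  sidecar (``<stem>.json``) declaring ``fs`` (Hz), ``units`` and an optional
  ``subject_id``.
* **WFDB** — a self-contained subset of the WFDB conventions: a text ``.hea``
  header and a single interleaved 16-bit little-endian ``.dat`` file.

The canonical in-memory amplitude unit is millivolts.  Of the 12 standard
leads only eight (I, II, V1–V6) carry independent information; the limb
leads III, aVR, aVL and aVF are fixed linear combinations (Einthoven /
Goldberger) and are reconstructed, never analysed.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import IncompleteLeadSetError, NoGroupLabelError, UnsupportedFormatError

logger = logging.getLogger(__name__)

#: Canonical 12-lead order used throughout the package.
STANDARD_LEADS = ("I", "II", "III", "aVR", "aVL", "aVF",
                  "V1", "V2", "V3", "V4", "V5", "V6")

#: The eight linearly independent surface leads, in the fixed order every
#: decomposition consumes.
INDEPENDENT_LEADS = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")

#: Synonym table applied when normalising lead names from input files.
LEAD_SYNONYMS = {
    "MLI": "I", "MLII": "II", "MLIII": "III",
    "L1": "I", "L2": "II", "L3": "III",
    "LEAD_I": "I", "LEAD_II": "II", "LEAD_III": "III",
    "AVR": "aVR", "AVL": "aVL", "AVF": "aVF",
}

#: Per-mV gain used when quantising to 16-bit WFDB samples (1 µV LSB).
WFDB_GAIN = 1000.0


def normalize_lead_name(name: str) -> str:
    """Map a lead label from an input file onto the canonical spelling."""
    key = name.strip()
    upper = key.upper()
    if upper in LEAD_SYNONYMS:
        return LEAD_SYNONYMS[upper]
    for canonical in STANDARD_LEADS:
        if upper == canonical.upper():
            return canonical
    return key


@dataclass
class EcgRecord:
    """A uniformly sampled multi-lead ECG recording in millivolts."""

    samples: np.ndarray          # (n_leads, n_samples)
    lead_names: tuple[str, ...]
    fs: float                    # Hz
    subject_id: str = "anonymous"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.lead_names = tuple(self.lead_names)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (leads x time) array")
        if self.samples.shape[0] != len(self.lead_names):
            raise ValueError("lead_names length must match samples rows")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite samples in record")
        missing = [l for l in INDEPENDENT_LEADS if l not in self.lead_names]
        if missing:
            raise IncompleteLeadSetError(
                f"incomplete lead set: missing {', '.join(missing)}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        """Return one lead's samples by canonical name."""
        try:
            return self.samples[self.lead_names.index(name)]
        except ValueError:
            raise IncompleteLeadSetError(f"incomplete lead set: missing {name}")


def derive_independent_leads(record: EcgRecord) -> np.ndarray:
    """Extract the 8 independent leads as an ordered (8, N) matrix.

    Rows follow :data:`INDEPENDENT_LEADS` (I, II, V1..V6).  If lead III is
    present, the Einthoven identity III = II - I is checked and a warning is
    logged when it is violated beyond 50 µV RMS; the output is unaffected.
    """
    matrix = np.vstack([record.lead(name) for name in INDEPENDENT_LEADS])
    if "III" in record.lead_names:
        resid = record.lead("III") - (record.lead("II") - record.lead("I"))
        rms = float(np.sqrt(np.mean(resid ** 2)))
        if rms > 0.05:
            logger.warning(
                "record %s: Einthoven identity III = II - I violated "
                "(residual RMS %.3f mV)", record.subject_id, rms)
    return matrix


def limb_leads_from_independent(lead_i: np.ndarray, lead_ii: np.ndarray):
    """Reconstruct III, aVR, aVL, aVF from leads I and II."""
    lead_iii = lead_ii - lead_i
    avr = -(lead_i + lead_ii) / 2.0
    avl = lead_i - lead_ii / 2.0
    avf = lead_ii - lead_i / 2.0
    return lead_iii, avr, avl, avf


# ---------------------------------------------------------------------------
# CSV dialect (lead-per-column + JSON sidecar)
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_ecg_csv(path) -> EcgRecord:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise UnsupportedFormatError(
            f"unsupported format dialect: missing sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    if "fs" not in meta:
        raise UnsupportedFormatError(
            "unsupported format dialect: sidecar lacks 'fs'")
    df = pd.read_csv(path)
    names = tuple(normalize_lead_name(c) for c in df.columns)
    samples = df.to_numpy(dtype=float).T
    units = str(meta.get("units", "mV")).lower()
    if units in ("uv", "µv", "microvolt", "microvolts"):
        samples = samples / 1000.0
    elif units not in ("mv", "millivolt", "millivolts"):
        raise UnsupportedFormatError(f"unsupported format dialect: units {units!r}")
    return EcgRecord(samples=samples, lead_names=names, fs=float(meta["fs"]),
                     subject_id=str(meta.get("subject_id", path.stem)))


def write_ecg_csv(record: EcgRecord, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(record.samples.T, columns=list(record.lead_names))
    df.to_csv(path, index=False, float_format="%.6f")
    _sidecar_path(path).write_text(json.dumps(
        {"fs": record.fs, "units": "mV", "subject_id": record.subject_id}))
    return path


# ---------------------------------------------------------------------------
# WFDB dialect (format 16, single interleaved .dat)
# ---------------------------------------------------------------------------

def write_ecg_wfdb(record: EcgRecord, path_prefix) -> Path:
    """Write a WFDB record (``<prefix>.hea`` + ``<prefix>.dat``, format 16).

    Samples are quantised at 1 µV per ADC unit (gain 1000/mV); values are
    clipped to the int16 range.
    """
    prefix = Path(path_prefix)
    name = prefix.name
    n_sig, n_samp = record.samples.shape
    adc = np.clip(np.round(record.samples * WFDB_GAIN), -32768, 32767).astype("<i2")
    lines = [f"{name} {n_sig} {record.fs:g} {n_samp}"]
    for k, lead in enumerate(record.lead_names):
        init = int(adc[k, 0]) if n_samp else 0
        lines.append(f"{name}.dat 16 {WFDB_GAIN:g}(0)/mV 16 0 {init} 0 0 {lead}")
    lines.append(f"# subject_id: {record.subject_id}")
    prefix.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    adc.T.tofile(prefix.with_suffix(".dat"))
    return prefix


def read_ecg_wfdb(path_prefix) -> EcgRecord:
    """Read a WFDB record written in the format-16 single-file convention."""
    prefix = Path(path_prefix)
    if prefix.suffix in (".hea", ".dat"):
        prefix = prefix.with_suffix("")
    hea = prefix.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(hea)
    lines = [l.rstrip() for l in hea.read_text().splitlines() if l.strip()]
    head = lines[0].split()
    n_sig, fs, n_samp = int(head[1]), float(head[2]), int(head[3])
    names, gains = [], []
    subject_id = prefix.name
    for line in lines[1:]:
        if line.startswith("#"):
            if "subject_id:" in line:
                subject_id = line.split("subject_id:")[1].strip()
            continue
        parts = line.split()
        if parts[1] != "16":
            raise UnsupportedFormatError(
                f"unsupported format dialect: WFDB format {parts[1]}")
        gain_field = parts[2].split("(")[0].split("/")[0]
        gains.append(float(gain_field) if float(gain_field) != 0 else WFDB_GAIN)
        names.append(normalize_lead_name(parts[-1]))
    if len(names) != n_sig:
        raise UnsupportedFormatError(
            "unsupported format dialect: signal line count mismatch")
    raw = np.fromfile(prefix.with_suffix(".dat"), dtype="<i2")
    if raw.size != n_sig * n_samp:
        raise UnsupportedFormatError(
            "unsupported format dialect: sample count mismatch")
    samples = raw.reshape(n_samp, n_sig).T.astype(float)
    samples /= np.asarray(gains)[:, None]
    return EcgRecord(samples=samples, lead_names=tuple(names), fs=fs,
                     subject_id=subject_id)


def read_ecg(path, format: str | None = None) -> EcgRecord:
    """Read a 12-lead recording, auto-detecting the dialect from the suffix.

    Parameters
    ----------
    path:
        ``.csv`` file (with JSON sidecar) or WFDB prefix / ``.hea`` path.
    format:
        Force ``"csv"`` or ``"wfdb"`` instead of suffix detection.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix == ".csv" else "wfdb"
    if format == "csv":
        return read_ecg_csv(path)
    if format == "wfdb":
        return read_ecg_wfdb(path)
    raise UnsupportedFormatError(f"unsupported format dialect: {format!r}")


# ---------------------------------------------------------------------------
# Cohort covariate table
# ---------------------------------------------------------------------------

#: Column holding the case/control label.
GROUP_COLUMN = "group"
#: Recognised group label values.
GROUP_CASE = "DM/IFG"
GROUP_CONTROL = "control"

#: Binary clinical covariates of the standard cohort schema.
BINARY_COVARIATES = (
    "dyslipidemia", "hypertension", "fhx_ihd", "aspirin", "acei_arb",
    "ccb", "beta_blocker", "statin", "thiazide",
    "current_smoker", "past_smoker",
)


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort covariate CSV.

    The table must contain a ``group`` column; unknown columns are kept as
    opaque covariates.  When weight (kg), height (m) and BMI (kg/m^2) are all
    present, BMI is cross-checked against weight/height^2 and inconsistent
    rows (absolute difference >= 0.1) trigger a validation warning.
    """
    df = pd.read_csv(path)
    if GROUP_COLUMN not in df.columns:
        raise NoGroupLabelError("no group label")
    if df[GROUP_COLUMN].isna().any():
        raise NoGroupLabelError("no group label: missing values in 'group'")
    if {"weight", "height", "bmi"} <= set(df.columns):
        with np.errstate(divide="ignore", invalid="ignore"):
            implied = df["weight"] / df["height"] ** 2
        bad = (np.abs(implied - df["bmi"]) >= 0.1) & implied.notna() & df["bmi"].notna()
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} row(s) with BMI inconsistent with "
                "weight/height^2 by >= 0.1", stacklevel=2)
    return df
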