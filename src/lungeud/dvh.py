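"""Dose-volume histogram data model, CSV I/O, cohorts and elementary dose metrics.

A dose-volume histogram (DVH) records how a structure's volume is distributed
over radiation dose. The cumulative form V(d) gives the fraction of volume
receiving at least dose d; the differential form gives the fraction of volume
in each dose bin. All internal computation uses the differential form on
half-open bins [edge_i, edge_{i+1}) with the bin midpoint as representative
dose, and the canonical dose unit is Gy.

CSV dialects
------------
Two dialects are supported for on-disk DVH tables, both two numeric columns
with header ``dose,volume`` and ``#`` comment lines:

``cumulative_pct``
    Rows are (dose edge, percent of volume receiving >= dose). The curve must
    be non-increasing, start above zero and end at exactly zero volume.
``differential_fraction``
    Rows are (representative dose, fractional volume). Bin edges are
    reconstructed from midpoints between consecutive doses.

A labelled cohort is stored as a manifest CSV with columns ``patient_id,
rp2_label, vol_lung_cc, vol_ptv_cc, saa_deg, dvh_whole_path,
dvh_affected_path`` where DVH paths are relative to the manifest location.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "MalformedDVHError",
    "DoseVolumeHistogram",
    "PatientRecord",
    "Cohort",
    "read_dvh_table",
    "write_dvh_table",
    "v_dose",
    "mean_dose",
    "read_cohort",
    "write_cohort",
]

#: Absolute tolerance on fractional-volume bookkeeping.
VOLUME_TOL = 1e-9

_DIALECTS = ("cumulative_pct", "differential_fraction")
_DOSE_UNITS = ("Gy", "cGy")

MANIFEST_COLUMNS = [
    "patient_id",
    "rp2_label",
    "vol_lung_cc",
    "vol_ptv_cc",
    "saa_deg",
    "dvh_whole_path",
    "dvh_affected_path",
]


class MalformedDVHError(ValueError):
    """Raised when a DVH table or DVH construction violates the format contract."""


@dataclass
class DoseVolumeHistogram:
    """Binned dose -> fractional volume distribution for one structure.

    Parameters
    ----------
    structure_label
        Name of the anatomical structure (e.g. ``"whole_lung"``).
    bin_edges
        Strictly increasing dose values in Gy, length ``B + 1``.
    diff_volume
        Fractional volume per bin, length ``B``; non-negative and summing
        to 1 within :data:`VOLUME_TOL`.
    form_of_origin
        Whether the source table was ``"cumulative"`` or ``"differential"``.
    """

    structure_label: str
    bin_edges: np.ndarray
    diff_volume: np.ndarray
    form_of_origin: str = "differential"

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.diff_volume = np.asarray(self.diff_volume, dtype=float)
        if self.bin_edges.ndim != 1 or self.diff_volume.ndim != 1:
            raise MalformedDVHError("bin_edges and diff_volume must be 1-D")
        if self.diff_volume.size == 0:
            raise MalformedDVHError("DVH must contain at least one bin")
        if self.bin_edges.size != self.diff_volume.size + 1:
            raise MalformedDVHError(
                f"need {self.diff_volume.size + 1} bin edges for "
                f"{self.diff_volume.size} bins, got {self.bin_edges.size}"
            )
        if self.bin_edges[0] < 0 or not np.all(np.isfinite(self.bin_edges)):
            raise MalformedDVHError("bin edges must be finite and non-negative")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise MalformedDVHError("bin edges must be strictly increasing")
        if np.any(self.diff_volume < -VOLUME_TOL) or not np.all(
            np.isfinite(self.diff_volume)
        ):
            raise MalformedDVHError("fractional volumes must be finite and >= 0")
        self.diff_volume = np.clip(self.diff_volume, 0.0, None)
        total = float(self.diff_volume.sum())
        if abs(total - 1.0) > VOLUME_TOL:
            raise MalformedDVHError(
                f"fractional volumes must sum to 1 (got {total:.12g})"
            )
        if self.form_of_origin not in ("cumulative", "differential"):
            raise ValueError(f"unknown form_of_origin {self.form_of_origin!r}")

    @property
    def n_bins(self) -> int:
        return int(self.diff_volume.size)

    @property
    def midpoints(self) -> np.ndarray:
        """Representative dose of each bin (midpoint), in Gy."""
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def cumulative(self) -> np.ndarray:
        """Fraction of volume receiving >= each bin edge (length ``B + 1``).

        Starts at 1 and ends at 0 by construction.
        """
        tail = np.cumsum(self.diff_volume[::-1])[::-1]
        return np.concatenate([tail, [0.0]])

    def copy(self, structure_label: str | None = None) -> "DoseVolumeHistogram":
        return DoseVolumeHistogram(
            structure_label=structure_label or self.structure_label,
            bin_edges=self.bin_edges.copy(),
            diff_volume=self.diff_volume.copy(),
            form_of_origin=self.form_of_origin,
        )


def v_dose(dvh: DoseVolumeHistogram, threshold: float) -> float:
    """Percent of structure volume receiving at least ``threshold`` Gy.

    The field's V_x metric (V5, V10, V20, V30, ...). Bins count toward the
    total when their representative (midpoint) dose is >= the threshold, so
    ``v_dose(dvh, 0) == 100``.
    """
    if threshold < 0:
        raise ValueError("dose threshold must be >= 0")
    return float(100.0 * dvh.diff_volume[dvh.midpoints >= threshold].sum())


def mean_dose(dvh: DoseVolumeHistogram) -> float:
    """Volume-weighted mean dose in Gy (the MLD when applied to lung)."""
    return float(np.dot(dvh.diff_volume, dvh.midpoints))


# ---------------------------------------------------------------------------
# DVH table I/O
# ---------------------------------------------------------------------------


def _read_structure_label(path: Path) -> str | None:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if body.lower().startswith("structure:"):
                return body.split(":", 1)[1].strip()
    return None


def read_dvh_table(
    path: str | Path,
    dialect: str,
    dose_unit: str = "Gy",
) -> DoseVolumeHistogram:
    """Read a two-column DVH CSV and return the canonical differential form.

    Doses are converted to Gy on ingest (``dose_unit="cGy"`` divides by 100);
    percent volumes in the cumulative dialect are divided by 100. The dose
    column must be sorted strictly ascending.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"dialect must be one of {_DIALECTS}, got {dialect!r}")
    if dose_unit not in _DOSE_UNITS:
        raise ValueError(f"dose_unit must be one of {_DOSE_UNITS}, got {dose_unit!r}")
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    df.columns = [str(c).strip().lower() for c in df.columns]
    if not {"dose", "volume"}.issubset(df.columns):
        raise MalformedDVHError(
            f"{path}: expected columns 'dose,volume', got {list(df.columns)}"
        )
    dose = df["dose"].to_numpy(dtype=float)
    volume = df["volume"].to_numpy(dtype=float)
    if dose.size == 0:
        raise MalformedDVHError(f"{path}: empty DVH table")
    if np.any(dose < 0) or np.any(volume < 0):
        raise MalformedDVHError(f"{path}: negative dose or volume")
    if np.any(np.diff(dose) <= 0):
        raise MalformedDVHError(f"{path}: dose column must be strictly ascending")
    if dose_unit == "cGy":
        dose = dose / 100.0
    label = _read_structure_label(path) or path.stem

    if dialect == "cumulative_pct":
        if dose.size < 2:
            raise MalformedDVHError(f"{path}: cumulative DVH needs >= 2 rows")
        cum = volume / 100.0
        if np.any(np.diff(cum) > VOLUME_TOL):
            raise MalformedDVHError(f"{path}: cumulative volume must be non-increasing")
        if cum[0] <= 0:
            raise MalformedDVHError(f"{path}: cumulative curve starts at zero volume")
        if cum[-1] > VOLUME_TOL:
            raise MalformedDVHError(
                f"{path}: cumulative curve must end at zero volume "
                "(append a terminal row at the maximum dose)"
            )
        diff = np.clip(cum[:-1] - cum[1:], 0.0, None)
        diff = diff / cum[0]
        return DoseVolumeHistogram(label, dose, diff, form_of_origin="cumulative")

    # differential_fraction: rows are (representative dose, fraction)
    total = volume.sum()
    if total <= 0:
        raise MalformedDVHError(f"{path}: differential DVH has zero total volume")
    frac = volume / total
    if dose.size == 1:
        half = 0.5 * dose[0] if dose[0] > 0 else 0.5
        edges = np.array([dose[0] - half, dose[0] + half])
    else:
        inner = 0.5 * (dose[:-1] + dose[1:])
        first = max(0.0, dose[0] - (inner[0] - dose[0]))
        last = dose[-1] + (dose[-1] - inner[-1])
        edges = np.concatenate([[first], inner, [last]])
    return DoseVolumeHistogram(label, edges, frac, form_of_origin="differential")


def write_dvh_table(
    dvh: DoseVolumeHistogram,
    path: str | Path,
    dialect: str,
) -> None:
    """Write a DVH to CSV in the requested dialect.

    ``read_dvh_table(write_dvh_table(x))`` reproduces ``diff_volume`` within
    :data:`VOLUME_TOL` for both dialects.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"dialect must be one of {_DIALECTS}, got {dialect!r}")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# structure: {dvh.structure_label}\n")
        fh.write(f"# dialect: {dialect}\n")
        fh.write("dose,volume\n")
        if dialect == "cumulative_pct":
            cum = dvh.cumulative
            for d, c in zip(dvh.bin_edges, cum):
                fh.write(f"{d:.10g},{100.0 * c:.12g}\n")
        else:
            for d, v in zip(dvh.midpoints, dvh.diff_volume):
                fh.write(f"{d:.10g},{v:.12g}\n")


# ---------------------------------------------------------------------------
# Patients and cohorts
# ---------------------------------------------------------------------------


@dataclass
class PatientRecord:
    """DVHs, structure volumes and RP 2+ outcome for one patient.

    ``rp2_label`` is 1 when the patient developed radiation pneumonitis of
    RTOG grade >= 2 within the follow-up window, else 0. ``saa_deg`` is the
    sum of VMAT arc angles in degrees (informational). ``covariates`` holds
    clinical attributes that are never used as model inputs.
    """

    patient_id: str
    rp2_label: int
    dvh_whole_lung: DoseVolumeHistogram
    dvh_affected_lung: DoseVolumeHistogram
    vol_lung_cc: float
    vol_ptv_cc: float
    saa_deg: float | None = None
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if int(self.rp2_label) not in (0, 1):
            raise ValueError(f"rp2_label must be 0 or 1, got {self.rp2_label!r}")
        self.rp2_label = int(self.rp2_label)
        if not (self.vol_lung_cc > 0 and self.vol_ptv_cc > 0):
            raise ValueError("structure volumes must be > 0")
        if not 0 < self.ptv_to_lung_ratio < 1:
            raise ValueError(
                f"PTV-to-lung ratio must lie in (0, 1), got "
                f"{self.ptv_to_lung_ratio:.4g}"
            )

    @property
    def ptv_to_lung_ratio(self) -> float:
        return float(self.vol_ptv_cc) / float(self.vol_lung_cc)


@dataclass
class Cohort:
    """Ordered collection of labelled patient records."""

    records: list
    provenance: str = "file"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("cohort must contain at least one record")
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("patient_id values must be unique within a cohort")
        if self.provenance not in ("synthetic", "file"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.rp2_label for r in self.records], dtype=int)

    def subset(self, rp2_label: int) -> list:
        return [r for r in self.records if r.rp2_label == rp2_label]

    def require_both_classes(self) -> None:
        labels = self.labels
        if labels.min() == labels.max():
            raise ValueError(
                "group comparison requires both RP 2+ and non-RP 2+ patients; "
                "this cohort contains a single outcome class"
            )

    def summary(self) -> dict:
        """Cohort size, number of RP 2+ events and incidence in percent."""
        labels = self.labels
        n = int(labels.size)
        pos = int(labels.sum())
        return {
            "n": n,
            "n_rp2": pos,
            "incidence_pct": 100.0 * pos / n,
        }


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write a cohort as manifest CSV plus per-patient DVH CSVs.

    DVHs are exported in the ``cumulative_pct`` dialect with doses in Gy,
    under ``<outdir>/dvh/``. Returns the manifest path.
    """
    outdir = Path(outdir)
    dvh_dir = outdir / "dvh"
    dvh_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort:
        whole_rel = f"dvh/{rec.patient_id}_whole.csv"
        affected_rel = f"dvh/{rec.patient_id}_affected.csv"
        write_dvh_table(rec.dvh_whole_lung, outdir / whole_rel, "cumulative_pct")
        write_dvh_table(rec.dvh_affected_lung, outdir / affected_rel, "cumulative_pct")
        rows.append(
            {
                "patient_id": rec.patient_id,
                "rp2_label": rec.rp2_label,
                "vol_lung_cc": rec.vol_lung_cc,
                "vol_ptv_cc": rec.vol_ptv_cc,
                "saa_deg": rec.saa_deg if rec.saa_deg is not None else np.nan,
                "dvh_whole_path": whole_rel,
                "dvh_affected_path": affected_rel,
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path: str | Path) -> Cohort:
    """Load a cohort from a manifest CSV (DVH paths relative to the manifest)."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"cohort manifest not found: {manifest_path}")
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise MalformedDVHError(
            f"{manifest_path}: manifest missing columns {sorted(missing)}"
        )
    records = []
    for row in df.itertuples(index=False):
        saa = float(row.saa_deg) if np.isfinite(row.saa_deg) else None
        records.append(
            PatientRecord(
                patient_id=str(row.patient_id),
                rp2_label=int(row.rp2_label),
                dvh_whole_lung=read_dvh_table(
                    base / row.dvh_whole_path, "cumulative_pct"
                ),
                dvh_affected_lung=read_dvh_table(
                    base / row.dvh_affected_path, "cumulative_pct"
                ),
                vol_lung_cc=float(row.vol_lung_cc),
                vol_ptv_cc=float(row.vol_ptv_cc),
                saa_deg=saa,
            )
        )
    return Cohort(records=records, provenance="file")
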