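"""The QC metric set: one value per monitored parameter per run.

Two metric families are computed. *Id-free* metrics come from the targeted
features and the scan metadata alone (peptide areas, mass accuracy, RT
drift, injection-time medians, chromatographic resolution, peak capacity,
TIC, spectra counts). *Id-based* metrics additionally consume a
database-search results table (PSM/peptide/protein counts, missed
cleavages, precursor delta ppm, id ratio).

Metric identifiers form a closed vocabulary; metrics standardized by the
HUPO-PSI quality-control CV carry their accession, the rest a local one.
An absent metric is a gap in the longitudinal series, never a zero.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .mzml_io import RunData
from .peptide_chem import PeptideTarget, count_missed_cleavages, parse_peptide
from .xic_features import Feature, detect_peak, extract_xic, PPM_TOL, RT_TOL

logger = logging.getLogger(__name__)

__all__ = [
    "MetricRecord",
    "MetricSet",
    "IdRow",
    "IdResults",
    "read_id_table",
    "CV_ACCESSIONS",
    "RESOLUTION_PAIRS",
    "extract_panel_features",
    "peptide_area",
    "mass_accuracy",
    "peptide_rt",
    "rt_drift",
    "median_injection_time",
    "chromatographic_resolution",
    "peak_capacity",
    "tic_metrics",
    "spectra_counts",
    "id_metrics",
    "compute_all",
]

#: HUPO-PSI QC CV accessions for the metrics that have one; metrics absent
#: here are exported under the local namespace.
CV_ACCESSIONS: dict[str, str] = {
    "mass_accuracy": "QC:0000038",
    "median_injection_time_ms1": "MS:1000927",
    "median_injection_time_ms2": "MS:1000927",
    "total_ion_current": "QC:0000048",
    "ms1_spectra_count": "QC:0000006",
    "ms2_spectra_count": "QC:0000007",
    "chromatogram_count": "QC:0000008",
    "tic_slump": "QC:0000023",
    "total_missed_cleavages": "QC:0000037",
    "total_identified_proteins": "QC:0000032",
    "total_uniquely_identified_proteins": "QC:0000033",
    "total_psms": "QC:0000029",
    "total_identified_peptides": "QC:0000030",
    "total_uniquely_identified_peptides": "QC:0000031",
    "mean_delta_ppm": "QC:0000040",
    "median_delta_ppm": "QC:0000041",
    "id_ratio": "QC:0000035",
    "number_of_features": "QC:0000046",
}

#: Fixed peptide pairs for chromatographic resolution (QC2 panel members).
RESOLUTION_PAIRS: tuple[tuple[str, str], ...] = (
    ("SLADELALVDVLEDK", "RFPGYDSESK"),
    ("FEELNMDLFR", "LAVDEEENADNNTK"),
)

#: Disagreement (ppm) between the table's theoretical m/z and a recomputed
#: one above which a calibration warning is logged.
THEO_MZ_WARN_PPM = 20.0


@dataclass(frozen=True)
class MetricRecord:
    """One (run, metric, value) observation — the longitudinal atom."""

    metric_id: str
    value: float
    units: str = ""
    cv_accession: Optional[str] = None
    target: Optional[str] = None
    run_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError(f"metric {self.metric_id} has non-finite value")


@dataclass
class MetricSet:
    """All metric records for one run."""

    run_id: Optional[str] = None
    instrument: Optional[str] = None
    qc_type: Optional[str] = None
    acquired_at: Optional[datetime] = None
    records: list[MetricRecord] = field(default_factory=list)

    def add(self, record: Optional[MetricRecord]) -> None:
        if record is None:
            return
        if any(
            r.metric_id == record.metric_id and r.target == record.target
            for r in self.records
        ):
            raise ValueError(
                f"duplicate record for ({record.metric_id}, {record.target})"
            )
        self.records.append(record)

    def extend(self, records: Iterable[Optional[MetricRecord]]) -> None:
        for r in records:
            self.add(r)

    def get(self, metric_id: str, target: Optional[str] = None) -> Optional[MetricRecord]:
        for r in self.records:
            if r.metric_id == metric_id and r.target == target:
                return r
        return None

    def value(self, metric_id: str, target: Optional[str] = None) -> Optional[float]:
        r = self.get(metric_id, target)
        return None if r is None else r.value

    def quant_details(self) -> list[MetricRecord]:
        """The per-peptide quantification record set (the peak areas)."""
        return [r for r in self.records if r.metric_id == "peptide_area"]


def _rec(metric_id: str, value: float, units: str = "", target: Optional[str] = None,
         run_id: Optional[str] = None) -> MetricRecord:
    return MetricRecord(
        metric_id=metric_id,
        value=float(value),
        units=units,
        cv_accession=CV_ACCESSIONS.get(metric_id),
        target=target,
        run_id=run_id,
    )


# --- identification results ---------------------------------------------------

@dataclass(frozen=True)
class IdRow:
    """One peptide-spectrum match from the search-results table."""

    spectrum_index: int
    peptide: str  # sequence with inline (CAM) tags
    proteins: tuple[str, ...]
    observed_mz: float
    theoretical_mz: float
    charge: int

    def __post_init__(self) -> None:
        if self.observed_mz <= 0 or self.theoretical_mz <= 0:
            raise ValueError("m/z values must be positive")


@dataclass
class IdResults:
    rows: list[IdRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)


ID_TABLE_COLUMNS = (
    "spectrum_index",
    "peptide",
    "proteins",
    "observed_mz",
    "theoretical_mz",
    "charge",
)


def read_id_table(path: str | Path) -> IdResults:
    """Read identification results from a tab-separated table.

    Header columns: ``spectrum_index``, ``peptide`` (inline CAM tags),
    ``proteins`` (``;``-separated accessions), ``observed_mz``,
    ``theoretical_mz``, ``charge``.
    """
    rows: list[IdRow] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(ID_TABLE_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"id table missing columns: {sorted(missing)}")
        for row in reader:
            rows.append(
                IdRow(
                    spectrum_index=int(row["spectrum_index"]),
                    peptide=row["peptide"].strip(),
                    proteins=tuple(
                        p for p in row["proteins"].split(";") if p.strip()
                    ),
                    observed_mz=float(row["observed_mz"]),
                    theoretical_mz=float(row["theoretical_mz"]),
                    charge=int(row["charge"]),
                )
            )
    return IdResults(rows)


# --- feature-derived metrics ---------------------------------------------------

def extract_panel_features(
    run: RunData,
    targets: Sequence[PeptideTarget],
    ppm_tol: float = PPM_TOL,
    rt_tol: float = RT_TOL,
) -> dict[str, Feature]:
    """Extract and detect one feature per panel target, keyed by sequence."""
    return {
        t.sequence: detect_peak(extract_xic(run, t, ppm_tol=ppm_tol, rt_tol=rt_tol))
        for t in targets
    }


def peptide_area(features: Mapping[str, Feature], run_id=None) -> list[MetricRecord]:
    """Per-peptide feature areas; not-found targets leave a gap."""
    return [
        _rec("peptide_area", f.area, "intensity*s", target=seq, run_id=run_id)
        for seq, f in features.items()
        if f.found
    ]


def mass_accuracy(feature: Feature, run_id=None) -> Optional[MetricRecord]:
    """Signed ppm error: 1e6 × (observed − theoretical) / theoretical."""
    if not feature.found or feature.observed_mz is None:
        return None
    theo = feature.target.theoretical_mz
    ppm = 1e6 * (feature.observed_mz - theo) / theo
    return _rec("mass_accuracy", ppm, "ppm", target=feature.target.sequence, run_id=run_id)


def peptide_rt(feature: Feature, run_id=None) -> Optional[MetricRecord]:
    """Apex retention time per peptide (auxiliary; feeds RT drift)."""
    if not feature.found:
        return None
    return _rec("peptide_rt", feature.apex_rt, "s", target=feature.target.sequence, run_id=run_id)


def rt_drift(
    current_rts: Mapping[str, float],
    previous_rts: Mapping[str, float],
    run_id=None,
) -> list[MetricRecord]:
    """Per-peptide apex-RT difference to the previous run of the series."""
    return [
        _rec("retention_time_drift", current_rts[seq] - previous_rts[seq], "s",
             target=seq, run_id=run_id)
        for seq in current_rts
        if seq in previous_rts
    ]


def median_injection_time(run: RunData, ms_level: int, run_id=None) -> Optional[MetricRecord]:
    """Median ion injection time over all scans of one MS level (ms)."""
    times = [
        s.injection_time
        for s in run.spectra
        if s.ms_level == ms_level and s.injection_time is not None
    ]
    if not times:
        return None
    return _rec(
        f"median_injection_time_ms{ms_level}",
        float(np.median(times)),
        "ms",
        run_id=run_id,
    )


def chromatographic_resolution(
    features: Mapping[str, Feature],
    pairs: Sequence[tuple[str, str]] = RESOLUTION_PAIRS,
    run_id=None,
) -> list[MetricRecord]:
    """Per fixed pair: (RT(pep1) − RT(pep2)) / (FWHM(pep1) + FWHM(pep2))."""
    records = []
    for pep1, pep2 in pairs:
        f1, f2 = features.get(pep1), features.get(pep2)
        if f1 is None or f2 is None or not (f1.found and f2.found):
            continue
        value = (f1.apex_rt - f2.apex_rt) / (f1.fwhm + f2.fwhm)
        records.append(
            _rec("chromatographic_resolution", value, "", target=f"{pep1}/{pep2}",
                 run_id=run_id)
        )
    return records


def peak_capacity(features: Mapping[str, Feature], run_id=None) -> Optional[MetricRecord]:
    """(max RT − min RT) over found features / mean FWHM; needs ≥ 2 features."""
    found = [f for f in features.values() if f.found]
    if len(found) < 2:
        return None
    rts = [f.apex_rt for f in found]
    value = (max(rts) - min(rts)) / float(np.mean([f.fwhm for f in found]))
    return _rec("peak_capacity", value, "", run_id=run_id)


def tic_metrics(
    run: RunData, run_id=None, n_segments: int = 4
) -> tuple[list[MetricRecord], tuple[np.ndarray, np.ndarray]]:
    """Total ion current and TIC slump, plus the TIC-vs-RT trace.

    Total ion current is the scalar sum of per-scan MS1 TIC (one number per
    run, as longitudinal classification requires). TIC slump divides the
    run's RT span into ``n_segments`` equal segments and reports the final
    segment's TIC sum over the median segment sum: values well below 1
    flag late-gradient signal collapse. The (rt, tic) trace is returned for
    plotting and carry-over inspection, not stored as a metric.
    """
    ms1 = run.ms1_spectra()
    if not ms1:
        return [], (np.empty(0), np.empty(0))
    rts = np.asarray([s.rt for s in ms1])
    tics = np.asarray([s.tic for s in ms1])
    records = [_rec("total_ion_current", float(tics.sum()), "counts", run_id=run_id)]
    if len(ms1) >= n_segments:
        edges = np.linspace(rts[0], rts[-1], n_segments + 1)
        idx = np.clip(np.searchsorted(edges, rts, side="right") - 1, 0, n_segments - 1)
        sums = np.bincount(idx, weights=tics, minlength=n_segments)
        med = float(np.median(sums))
        if med > 0:
            records.append(_rec("tic_slump", float(sums[-1]) / med, "", run_id=run_id))
    return records, (rts, tics)


def spectra_counts(run: RunData, run_id=None) -> list[MetricRecord]:
    """MS1/MS2 spectra counts and chromatogram count."""
    return [
        _rec("ms1_spectra_count", run.ms1_count, "count", run_id=run_id),
        _rec("ms2_spectra_count", run.ms2_count, "count", run_id=run_id),
        _rec("chromatogram_count", run.chromatogram_count, "count", run_id=run_id),
    ]


def id_metrics(run: RunData, ids: IdResults, run_id=None) -> list[MetricRecord]:
    """Identification metrics from the search-results table.

    PSMs = row count; identified peptides = distinct modified sequences;
    uniquely identified peptides = peptides whose protein set has exactly
    one accession; identified proteins = distinct accessions; uniquely
    identified proteins = accessions supported by at least one peptide
    unique to them; missed cleavages summed over PSM sequences; delta ppm
    per PSM from the table's own precursor m/z values (mean and median);
    Id Ratio = PSMs / MS2 spectra count.
    """
    valid = {s.index for s in run.spectra}
    for i, row in enumerate(ids.rows):
        if row.spectrum_index not in valid:
            raise ValueError(
                f"id table row {i} references nonexistent spectrum "
                f"{row.spectrum_index}"
            )

    psms = len(ids.rows)
    pep_proteins: dict[str, set[str]] = {}
    for row in ids.rows:
        pep_proteins.setdefault(row.peptide, set()).update(row.proteins)
    peptides = set(pep_proteins)
    unique_peps = {p for p, prots in pep_proteins.items() if len(prots) == 1}
    proteins = set().union(*pep_proteins.values()) if pep_proteins else set()
    unique_prots = {next(iter(pep_proteins[p])) for p in unique_peps}
    missed = sum(count_missed_cleavages(parse_peptide(r.peptide)) for r in ids.rows)

    records = [
        _rec("total_psms", psms, "count", run_id=run_id),
        _rec("total_identified_peptides", len(peptides), "count", run_id=run_id),
        _rec("total_uniquely_identified_peptides", len(unique_peps), "count", run_id=run_id),
        _rec("total_identified_proteins", len(proteins), "count", run_id=run_id),
        _rec("total_uniquely_identified_proteins", len(unique_prots), "count", run_id=run_id),
        _rec("total_missed_cleavages", missed, "count", run_id=run_id),
    ]
    ms2 = run.ms2_count
    records.append(_rec("id_ratio", psms / ms2 if ms2 else 0.0, "", run_id=run_id))
    if ids.rows:
        deltas = [
            1e6 * (r.observed_mz - r.theoretical_mz) / r.theoretical_mz
            for r in ids.rows
        ]
        records.append(_rec("mean_delta_ppm", float(np.mean(deltas)), "ppm", run_id=run_id))
        records.append(_rec("median_delta_ppm", float(np.median(deltas)), "ppm", run_id=run_id))
        _warn_on_calibration_disagreement(ids)
    return records


def _warn_on_calibration_disagreement(ids: IdResults) -> None:
    """Cross-check the table's theoretical m/z against a recomputation."""
    from .peptide_chem import mz as _mz

    for row in ids.rows:
        try:
            recomputed = _mz(parse_peptide(row.peptide), row.charge)
        except ValueError:
            continue
        dis = abs(1e6 * (row.theoretical_mz - recomputed) / recomputed)
        if dis > THEO_MZ_WARN_PPM:
            logger.warning(
                "theoretical m/z for %s disagrees with recomputation by %.1f ppm",
                row.peptide, dis,
            )


# --- the full per-run metric set ------------------------------------------------

def compute_all(
    run: RunData,
    targets: Sequence[PeptideTarget],
    previous: Optional[MetricSet] = None,
    ids: Optional[IdResults] = None,
    ppm_tol: float = PPM_TOL,
    rt_tol: float = RT_TOL,
) -> MetricSet:
    """Compute every metric whose inputs are available for one run.

    Id metrics are emitted only when ``ids`` is supplied (the id-based
    workflow); chromatographic-resolution pairs only when the pair members
    are in the panel (QC2); RT drift only when ``previous`` (the most
    recent earlier metric set of the same instrument/QC-type series)
    carries peptide RTs.
    """
    run_id = run.source_name
    ms = MetricSet(
        run_id=run_id,
        instrument=run.instrument,
        qc_type=run.qc_type,
        acquired_at=run.acquired_at,
    )
    features = extract_panel_features(run, targets, ppm_tol=ppm_tol, rt_tol=rt_tol)

    ms.extend(peptide_area(features, run_id))
    ms.extend(mass_accuracy(f, run_id) for f in features.values())
    ms.extend(peptide_rt(f, run_id) for f in features.values())
    if previous is not None:
        prev_rts = {
            r.target: r.value for r in previous.records if r.metric_id == "peptide_rt"
        }
        curr_rts = {f.target.sequence: f.apex_rt for f in features.values() if f.found}
        ms.extend(rt_drift(curr_rts, prev_rts, run_id))
    ms.add(median_injection_time(run, 1, run_id))
    ms.add(median_injection_time(run, 2, run_id))
    ms.extend(chromatographic_resolution(features, run_id=run_id))
    ms.add(peak_capacity(features, run_id))
    tic_records, _trace = tic_metrics(run, run_id)
    ms.extend(tic_records)
    ms.extend(spectra_counts(run, run_id))
    ms.add(
        _rec(
            "number_of_features",
            sum(1 for f in features.values() if f.found),
            "count",
            run_id=run_id,
        )
    )
    if ids is not None:
        ms.extend(id_metrics(run, ids, run_id))
    return ms
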