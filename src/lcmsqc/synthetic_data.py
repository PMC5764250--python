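"""Ground-truthed synthetic QC acquisitions.

Emulates the two QC acquisition shapes — a short-gradient low-complexity
run (QC1, tryptic BSA) and a long-gradient high-complexity run (QC2, HeLa
digest) — as centroided MS1 scans on a fixed interval in which every
monitored peptide elutes as a Gaussian peak of known retention time,
amplitude and width, sampled at ≥8 points across its FWHM. MS2 scans are
structural filler (precursor-tagged spectra with dummy fragments):
identification metrics are exercised with directly constructed results
tables, since database searching is out of scope.

Controllable: global and per-peptide mass error (ppm), per-run RT shift,
intensity scaling, injection-time distributions per MS level, multiplicative
intensity noise plus a uniform low-level baseline, and SRM-style output
(chromatograms instead of spectra). Longitudinal series add programmed
faults — mass-calibration steps, cumulative RT drift, sensitivity drops,
and carry-over peaks in the following run.

Gradient lengths default to scaled-down values (QC1 900 s, QC2 1800 s
nominal 6000) so full test suites run in minutes; method-faithful lengths
are plain recipe fields.

Everything is reproducible: a fixed seed yields byte-identical mzML.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .mzml_io import Chromatogram, RunData, SpectrumMeta
from .peptide_chem import PeptideTarget, qc_panel

__all__ = [
    "PeakSpec",
    "RunRecipe",
    "Fault",
    "SeriesRecipe",
    "GroundTruthPeak",
    "generate_run",
    "generate_series",
    "write_truth",
    "GAUSS_FWHM",
]

#: FWHM of a Gaussian of unit sd.
GAUSS_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))

_PANEL_DEFAULTS = {
    # gradient length (s), MS1 scan interval (s), chromatographic sd (s)
    "QC1": (900.0, 1.5, 6.0),
    "QC2": (6000.0, 4.0, 16.0),
}


@dataclass(frozen=True)
class PeakSpec:
    """One simulated chromatographic peak.

    Panel peptides carry a ``sequence`` (m/z derived from the target);
    off-panel contaminant/carry-over peaks carry an explicit ``mz``.
    """

    rt: float
    amplitude: float
    sigma: float  # chromatographic sd, seconds
    sequence: Optional[str] = None
    mz: Optional[float] = None
    mass_offset_ppm: float = 0.0  # per-peptide calibration error

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("peak sigma must be positive")
        if self.amplitude < 0:
            raise ValueError("peak amplitude must be non-negative")
        if self.sequence is None and self.mz is None:
            raise ValueError("peak needs a sequence or an explicit m/z")


@dataclass(frozen=True)
class RunRecipe:
    """Declarative description of one synthetic acquisition."""

    panel: str = "QC1"
    gradient_length: float = 900.0
    scan_interval: float = 1.5
    peaks: tuple[PeakSpec, ...] = ()
    mass_offset_ppm: float = 0.0  # global calibration error
    rt_shift: float = 0.0  # per-run shift of every elution apex
    ms2_per_ms1: int = 2
    injection_ms1: tuple[float, float] = (10.0, 2.0)  # mean, sd (ms)
    injection_ms2: tuple[float, float] = (25.0, 5.0)
    noise_rel: float = 0.05  # multiplicative Gaussian sd on intensities
    baseline_peaks: int = 10  # uniform low-level noise centroids per MS1 scan
    baseline_level: float = 1e3
    peak_support_sigmas: float = 4.0  # peaks emitted within ±k·sigma only
    srm: bool = False
    instrument: str = "instrA"
    acquired_at: datetime = datetime(2017, 3, 1, 9, 0, 0)
    run_label: str = "run000"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gradient_length <= 0 or self.scan_interval <= 0:
            raise ValueError("durations and intervals must be positive")
        if self.ms2_per_ms1 < 0:
            raise ValueError("ms2_per_ms1 must be non-negative")

    @classmethod
    def for_panel(cls, panel: str, seed: int = 0, **overrides) -> "RunRecipe":
        """A recipe with the panel's default run shape.

        Panel peptides elute evenly spaced across the middle 70% of the
        gradient with amplitudes staggered over roughly one decade.
        """
        gradient, interval, sigma = _PANEL_DEFAULTS[panel.upper()]
        gradient = overrides.pop("gradient_length", gradient)
        interval = overrides.pop("scan_interval", interval)
        sigma = overrides.pop("peak_sigma", sigma)
        targets = qc_panel(panel)
        n = len(targets)
        rts = np.linspace(0.15 * gradient, 0.85 * gradient, n)
        amplitudes = 1e6 * (1.0 + 0.9 * np.cos(np.arange(n)))  # staggered, deterministic
        peaks = tuple(
            PeakSpec(rt=float(rts[i]), amplitude=float(amplitudes[i]),
                     sigma=sigma, sequence=t.sequence)
            for i, t in enumerate(targets)
        )
        return cls(panel=panel.upper(), gradient_length=gradient,
                   scan_interval=interval, peaks=peaks, seed=seed, **overrides)

    def targets(self) -> list[PeptideTarget]:
        """Panel targets with expected RT set to each peak's nominal RT."""
        by_seq = {t.sequence: t for t in qc_panel(self.panel)}
        out = []
        for p in self.peaks:
            if p.sequence is not None and p.sequence in by_seq:
                out.append(replace(by_seq[p.sequence], expected_rt=p.rt))
        return out

    @property
    def source_name(self) -> str:
        return (
            f"{self.acquired_at:%Y%m%dT%H%M%S}_{self.instrument}_"
            f"{self.panel}_{self.run_label}.mzML"
        )


@dataclass(frozen=True)
class GroundTruthPeak:
    """True parameters of one simulated peak (noiseless analytic values)."""

    sequence: Optional[str]
    mz: float
    rt: float  # apex, includes the run's RT shift
    amplitude: float
    sigma: float

    @property
    def area(self) -> float:
        return self.amplitude * self.sigma * math.sqrt(2.0 * math.pi)

    @property
    def fwhm(self) -> float:
        return GAUSS_FWHM * self.sigma


def _peak_mz(peak: PeakSpec, recipe: RunRecipe, targets_by_seq) -> float:
    if peak.sequence is not None and peak.sequence in targets_by_seq:
        base = targets_by_seq[peak.sequence].theoretical_mz
    elif peak.mz is not None:
        base = peak.mz
    else:
        raise ValueError(f"no m/z for peak {peak}")
    return base * (1.0 + (recipe.mass_offset_ppm + peak.mass_offset_ppm) * 1e-6)


def generate_run(recipe: RunRecipe) -> tuple[RunData, list[GroundTruthPeak]]:
    """Generate one synthetic acquisition plus its ground truth."""
    rng = np.random.default_rng(recipe.seed)
    targets_by_seq = {t.sequence: t for t in qc_panel(recipe.panel)}
    mzs = [_peak_mz(p, recipe, targets_by_seq) for p in recipe.peaks]
    truth = [
        GroundTruthPeak(
            sequence=p.sequence,
            mz=mzs[i],
            rt=p.rt + recipe.rt_shift,
            amplitude=p.amplitude,
            sigma=p.sigma,
        )
        for i, p in enumerate(recipe.peaks)
    ]
    grid = np.arange(0.0, recipe.gradient_length + 1e-9, recipe.scan_interval)

    if recipe.srm:
        return _generate_srm(recipe, truth, grid), truth

    panel_mzs = sorted(t.theoretical_mz for t in targets_by_seq.values())
    spectra: list[SpectrumMeta] = []
    index = 0
    ms2_cycle = 0
    for t in grid:
        mz_list: list[float] = []
        int_list: list[float] = []
        for peak, gt in zip(recipe.peaks, truth):
            if abs(t - gt.rt) > recipe.peak_support_sigmas * peak.sigma:
                continue
            inten = gt.amplitude * math.exp(-((t - gt.rt) ** 2) / (2.0 * peak.sigma**2))
            if recipe.noise_rel > 0:
                inten *= max(0.0, 1.0 + recipe.noise_rel * rng.standard_normal())
            if inten <= 0.0:
                continue
            mz_list.append(gt.mz)
            int_list.append(inten)
        for _ in range(recipe.baseline_peaks):
            mz_list.append(float(rng.uniform(300.0, 1500.0)))
            int_list.append(float(rng.uniform(0.0, recipe.baseline_level)))
        mz_arr, int_arr = _sorted_centroids(mz_list, int_list)
        it = max(0.1, float(rng.normal(*recipe.injection_ms1)))
        spectra.append(
            SpectrumMeta(
                index=index, ms_level=1, rt=float(t), tic=float(int_arr.sum()),
                injection_time=it, mz=mz_arr, intensity=int_arr,
            )
        )
        index += 1
        for k in range(recipe.ms2_per_ms1):
            prec = panel_mzs[ms2_cycle % len(panel_mzs)]
            ms2_cycle += 1
            frag_mz = np.sort(prec * np.array([0.35, 0.5, 0.65, 0.8, 1.2]))
            frag_int = rng.uniform(1e3, 1e4, size=frag_mz.size)
            it2 = max(0.1, float(rng.normal(*recipe.injection_ms2)))
            rt2 = float(t + (k + 1) * recipe.scan_interval / (recipe.ms2_per_ms1 + 1))
            spectra.append(
                SpectrumMeta(
                    index=index, ms_level=2, rt=rt2, tic=float(frag_int.sum()),
                    injection_time=it2, precursor_mz=float(prec),
                    mz=frag_mz, intensity=frag_int,
                )
            )
            index += 1

    run = RunData(
        spectra=spectra,
        instrument=recipe.instrument,
        qc_type=recipe.panel,
        acquired_at=recipe.acquired_at,
        source_name=recipe.source_name,
    )
    return run, truth


def _sorted_centroids(mz_list, int_list) -> tuple[np.ndarray, np.ndarray]:
    """Sort centroids by m/z, merging (summing) exact duplicates."""
    if not mz_list:
        return np.empty(0), np.empty(0)
    mz = np.asarray(mz_list, dtype=float)
    inten = np.asarray(int_list, dtype=float)
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    if np.any(np.diff(mz) == 0.0):
        umz, inverse = np.unique(mz, return_inverse=True)
        inten = np.bincount(inverse, weights=inten)
        mz = umz
    return mz, inten


def _generate_srm(recipe: RunRecipe, truth, grid) -> RunData:
    rng = np.random.default_rng(recipe.seed)
    chroms = []
    for peak, gt in zip(recipe.peaks, truth):
        inten = gt.amplitude * np.exp(-((grid - gt.rt) ** 2) / (2.0 * peak.sigma**2))
        inten[np.abs(grid - gt.rt) > recipe.peak_support_sigmas * peak.sigma] = 0.0
        if recipe.noise_rel > 0:
            inten = np.maximum(
                0.0, inten * (1.0 + recipe.noise_rel * rng.standard_normal(inten.size))
            )
        label = gt.sequence or f"mz{gt.mz:.4f}"
        chroms.append(
            Chromatogram(
                id=f"SRM SIC {label} Q1={gt.mz:.4f}",
                rt=grid.copy(),
                intensity=inten,
                precursor_mz=gt.mz,
            )
        )
    return RunData(
        spectra=[],
        chromatograms=chroms,
        instrument=recipe.instrument,
        qc_type=recipe.panel,
        acquired_at=recipe.acquired_at,
        source_name=recipe.source_name,
    )


# --- longitudinal series with programmed faults --------------------------------

FAULT_KINDS = ("mass_shift", "rt_drift", "sensitivity_drop", "carryover_peak")


@dataclass(frozen=True)
class Fault:
    """A programmed instrument fault starting at ``run_index``.

    * ``mass_shift``: calibration step, magnitude in ppm (stepwise).
    * ``rt_drift``: magnitude in s/run, accumulating run over run.
    * ``sensitivity_drop``: amplitudes multiplied by ``magnitude`` (< 1).
    * ``carryover_peak``: an off-panel peak of relative amplitude
      ``magnitude`` appears in the *following* run.
    """

    run_index: int
    kind: str
    magnitude: float

    def __post_init__(self) -> None:
        if self.kind not in FAULT_KINDS:
            raise ValueError(f"unknown fault kind {self.kind!r}")


@dataclass(frozen=True)
class SeriesRecipe:
    """A longitudinal series of runs with run-to-run variation and faults.

    Run-to-run variation emulates normal instrument behaviour: a global
    calibration jitter shared by all peptides in a run plus an independent
    per-peptide calibration jitter, and likewise a whole-gradient RT jitter
    plus an independent per-peptide elution jitter (peptides respond to
    column and solvent state individually, not only in lockstep).
    """

    base: RunRecipe
    n_runs: int = 30
    spacing: timedelta = timedelta(hours=1)
    faults: tuple[Fault, ...] = ()
    mass_jitter_ppm: float = 0.25
    peptide_mass_jitter_ppm: float = 0.2
    rt_jitter_s: float = 1.0
    peptide_rt_jitter_s: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("series needs at least one run")
        for f in self.faults:
            if not 0 <= f.run_index < self.n_runs:
                raise ValueError(f"fault index {f.run_index} outside series")


def generate_series(
    recipe: SeriesRecipe,
) -> tuple[list[tuple[RunData, list[GroundTruthPeak]]], list[dict]]:
    """Generate the series; returns (run, truth) pairs plus per-run labels.

    Each label records the run index, whether the run is in control, and
    the faults affecting it — the ground truth for validating control-chart
    classification.
    """
    rng = np.random.default_rng(recipe.seed)
    runs: list[tuple[RunData, list[GroundTruthPeak]]] = []
    labels: list[dict] = []
    base = recipe.base
    for i in range(recipe.n_runs):
        active: list[Fault] = []
        offset = base.mass_offset_ppm
        rt_shift = base.rt_shift
        sens = 1.0
        carryover: Optional[float] = None
        for f in recipe.faults:
            if f.kind == "mass_shift" and i >= f.run_index:
                offset += f.magnitude
                active.append(f)
            elif f.kind == "rt_drift" and i >= f.run_index:
                rt_shift += f.magnitude * (i - f.run_index + 1)
                active.append(f)
            elif f.kind == "sensitivity_drop" and i >= f.run_index:
                sens *= f.magnitude
                active.append(f)
            elif f.kind == "carryover_peak" and i == f.run_index + 1:
                carryover = f.magnitude
                active.append(f)
        offset += float(rng.normal(0.0, recipe.mass_jitter_ppm))
        rt_shift += float(rng.normal(0.0, recipe.rt_jitter_s))
        peaks = tuple(
            replace(
                p,
                amplitude=p.amplitude * sens,
                rt=p.rt + float(rng.normal(0.0, recipe.peptide_rt_jitter_s)),
                mass_offset_ppm=p.mass_offset_ppm
                + float(rng.normal(0.0, recipe.peptide_mass_jitter_ppm)),
            )
            for p in base.peaks
        )
        if carryover is not None:
            amp = carryover * max(p.amplitude for p in base.peaks)
            peaks = peaks + (
                PeakSpec(rt=0.5 * base.gradient_length, amplitude=amp,
                         sigma=2.0 * max(p.sigma for p in base.peaks), mz=522.5946),
            )
        run_recipe = replace(
            base,
            peaks=peaks,
            mass_offset_ppm=offset,
            rt_shift=rt_shift,
            acquired_at=base.acquired_at + i * recipe.spacing,
            run_label=f"run{i:03d}",
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        runs.append(generate_run(run_recipe))
        labels.append(
            {
                "run_index": i,
                "in_control": not active,
                "faults": tuple(f.kind for f in active),
                "source_name": run_recipe.source_name,
            }
        )
    return runs, labels


def write_truth(truth: Sequence[GroundTruthPeak], path: str | Path) -> None:
    """Write ground-truth peak parameters as a tab-separated table."""
    lines = ["sequence\tmz\trt\tamplitude\tsigma\tarea\tfwhm"]
    for gt in truth:
        lines.append(
            f"{gt.sequence or ''}\t{gt.mz!r}\t{gt.rt!r}\t{gt.amplitude!r}"
            f"\t{gt.sigma!r}\t{gt.area!r}\t{gt.fwhm!r}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
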