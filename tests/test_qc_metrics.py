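"""The QC metric set: formulas, availability rules and id-metric arithmetic."""

import statistics
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import lcmsqc
from lcmsqc.mzml_io import RunData, SpectrumMeta
from lcmsqc.peptide_chem import count_missed_cleavages, parse_peptide, qc_panel
from lcmsqc.qc_metrics import (
    IdResults,
    IdRow,
    MetricRecord,
    MetricSet,
    chromatographic_resolution,
    compute_all,
    id_metrics,
    mass_accuracy,
    median_injection_time,
    peak_capacity,
    peptide_area,
    read_id_table,
    rt_drift,
    spectra_counts,
    tic_metrics,
)
from lcmsqc.xic_features import Feature

QC2 = {t.sequence: t for t in qc_panel("QC2")}


def feature(seq, apex_rt=None, area=None, fwhm=None, observed_mz=None, found=True):
    target = QC2.get(seq) or qc_panel("QC1")[0]
    return Feature(
        target=target, found=found, apex_rt=apex_rt, area=area, fwhm=fwhm,
        height=1.0 if found else None,
        observed_mz=observed_mz if observed_mz is not None else target.theoretical_mz,
    )


def ms1(index, rt, tic, it=10.0):
    return SpectrumMeta(index=index, ms_level=1, rt=rt, tic=tic, injection_time=it)


class TestPeptideArea:
    def test_found_area_copied(self):
        records = peptide_area({"YAEAVTR": feature("YAEAVTR", area=1.0e7)})
        assert len(records) == 1
        assert records[0].value == 1.0e7
        assert records[0].target == "YAEAVTR"

    def test_not_found_leaves_gap(self):
        records = peptide_area({"YAEAVTR": feature("YAEAVTR", found=False)})
        assert records == []


class TestMassAccuracy:
    def test_zero_when_observed_equals_theoretical(self):
        f = feature("YAEAVTR")
        assert mass_accuracy(f).value == 0.0

    def test_plus_five_ppm(self):
        f = feature("YAEAVTR")
        f = replace(f, observed_mz=f.target.theoretical_mz * (1 + 5e-6))
        assert mass_accuracy(f).value == pytest.approx(5.0, abs=1e-9)

    def test_signed_formula(self):
        f = feature("YAEAVTR")
        theo = f.target.theoretical_mz
        f = replace(f, observed_mz=theo - theo * 3e-6)
        assert mass_accuracy(f).value == pytest.approx(-3.0, abs=1e-9)

    def test_absent_for_missing_feature(self):
        assert mass_accuracy(feature("YAEAVTR", found=False)) is None


class TestRtDrift:
    def test_signed_difference(self):
        records = rt_drift({"YAEAVTR": 1805.0}, {"YAEAVTR": 1800.0})
        assert records[0].value == pytest.approx(5.0)

    def test_no_previous_gives_no_record(self):
        assert rt_drift({"YAEAVTR": 1805.0}, {}) == []


class TestMedianInjectionTime:
    @pytest.mark.parametrize(
        "times, expected", [([10, 20, 30], 20.0), ([10, 20, 30, 100], 25.0)]
    )
    def test_median_rule(self, times, expected):
        run = RunData(spectra=[ms1(i, float(i), 1.0, it=t) for i, t in enumerate(times)])
        assert median_injection_time(run, 1).value == expected

    def test_absent_without_injection_times(self):
        run = RunData(spectra=[ms1(0, 0.0, 1.0, it=None)])
        assert median_injection_time(run, 1) is None

    @given(st.lists(st.floats(min_value=0.1, max_value=500.0), min_size=1, max_size=25))
    def test_agrees_with_statistics_median(self, times):
        run = RunData(spectra=[ms1(i, float(i), 1.0, it=t) for i, t in enumerate(times)])
        assert median_injection_time(run, 1).value == pytest.approx(
            statistics.median(times), rel=1e-12
        )


class TestChromatographicResolution:
    def test_formula(self):
        feats = {
            "SLADELALVDVLEDK": feature("SLADELALVDVLEDK", apex_rt=200.0, fwhm=10.0),
            "RFPGYDSESK": feature("RFPGYDSESK", apex_rt=100.0, fwhm=10.0),
        }
        records = chromatographic_resolution(feats)
        assert len(records) == 1
        assert records[0].value == pytest.approx(5.0, abs=1e-12)

    def test_coeluting_pair_gives_zero(self):
        feats = {
            "SLADELALVDVLEDK": feature("SLADELALVDVLEDK", apex_rt=150.0, fwhm=8.0),
            "RFPGYDSESK": feature("RFPGYDSESK", apex_rt=150.0, fwhm=12.0),
        }
        assert chromatographic_resolution(feats)[0].value == 0.0

    def test_dimensionless_under_time_rescaling(self):
        feats = {
            "SLADELALVDVLEDK": feature("SLADELALVDVLEDK", apex_rt=200.0, fwhm=10.0),
            "RFPGYDSESK": feature("RFPGYDSESK", apex_rt=100.0, fwhm=30.0),
        }
        v1 = chromatographic_resolution(feats)[0].value
        scaled = {
            seq: replace(f, apex_rt=f.apex_rt * 3.0, fwhm=f.fwhm * 3.0)
            for seq, f in feats.items()
        }
        assert chromatographic_resolution(scaled)[0].value == pytest.approx(v1, rel=1e-12)

    def test_missing_member_drops_pair(self):
        feats = {
            "SLADELALVDVLEDK": feature("SLADELALVDVLEDK", apex_rt=200.0, fwhm=10.0),
            "RFPGYDSESK": feature("RFPGYDSESK", found=False),
            "FEELNMDLFR": feature("FEELNMDLFR", apex_rt=300.0, fwhm=10.0),
            "LAVDEEENADNNTK": feature("LAVDEEENADNNTK", apex_rt=250.0, fwhm=10.0),
        }
        records = chromatographic_resolution(feats)
        assert [r.target for r in records] == ["FEELNMDLFR/LAVDEEENADNNTK"]


class TestPeakCapacity:
    def test_formula(self):
        feats = {
            "a": feature("YAEAVTR", apex_rt=100.0, fwhm=10.0),
            "b": feature("EVSTYIK", apex_rt=1000.0, fwhm=10.0),
        }
        assert peak_capacity(feats).value == pytest.approx(90.0, abs=1e-12)

    def test_single_feature_absent(self):
        assert peak_capacity({"a": feature("YAEAVTR", apex_rt=100.0, fwhm=10.0)}) is None

    def test_inside_feature_with_mean_fwhm_leaves_value(self):
        feats = {
            "a": feature("YAEAVTR", apex_rt=100.0, fwhm=10.0),
            "b": feature("EVSTYIK", apex_rt=1000.0, fwhm=10.0),
        }
        v1 = peak_capacity(feats).value
        feats["c"] = feature("EAALSTALSEK", apex_rt=500.0, fwhm=10.0)
        assert peak_capacity(feats).value == pytest.approx(v1, rel=1e-12)


class TestTicMetrics:
    def test_total_is_sum(self):
        run = RunData(spectra=[ms1(i, float(i), t) for i, t in enumerate([1e6, 2e6, 3e6])])
        records, _ = tic_metrics(run)
        total = next(r for r in records if r.metric_id == "total_ion_current")
        assert total.value == pytest.approx(6e6)

    def test_flat_trace_has_no_slump(self):
        run = RunData(spectra=[ms1(i, float(i), 5e5) for i in range(40)])
        records, _ = tic_metrics(run)
        slump = next(r for r in records if r.metric_id == "tic_slump")
        assert slump.value == pytest.approx(1.0)

    def test_half_intensity_final_quarter(self):
        tics = [1e6] * 30 + [5e5] * 10
        rts = np.linspace(0.0, 39.0, 40)
        run = RunData(spectra=[ms1(i, rts[i], tics[i]) for i in range(40)])
        records, _ = tic_metrics(run)
        slump = next(r for r in records if r.metric_id == "tic_slump")
        assert slump.value == pytest.approx(0.5)

    def test_trace_returned_for_inspection(self):
        run = RunData(spectra=[ms1(i, float(i), 1e6) for i in range(8)])
        _, (rts, tics) = tic_metrics(run)
        assert len(rts) == len(tics) == 8


class TestSpectraCounts:
    def test_counts_by_level(self, small_qc1):
        _, run, _ = small_qc1
        records = {r.metric_id: r.value for r in spectra_counts(run)}
        assert records["ms1_spectra_count"] == run.ms1_count
        assert records["ms2_spectra_count"] == run.ms2_count
        assert records["chromatogram_count"] == 0
        assert records["ms1_spectra_count"] + records["ms2_spectra_count"] == len(run.spectra)


def toy_run(n_spectra=10):
    return RunData(
        spectra=[
            SpectrumMeta(index=i, ms_level=2 if i % 2 else 1, rt=float(i), tic=1.0,
                         precursor_mz=500.0 if i % 2 else None)
            for i in range(n_spectra)
        ]
    )


def id_row(index, peptide, proteins, obs=None, theo=None, charge=2):
    if theo is None:
        theo = lcmsqc.mz(parse_peptide(peptide), charge)
    if obs is None:
        obs = theo
    return IdRow(spectrum_index=index, peptide=peptide, proteins=tuple(proteins),
                 observed_mz=obs, theoretical_mz=theo, charge=charge)


class TestIdMetrics:
    def test_toy_counts(self):
        ids = IdResults([
            id_row(1, "LVNELTEFAK", ["P1"]),
            id_row(3, "LVNELTEFAK", ["P1"]),
            id_row(5, "HLVDEPQNLIK", ["P1"]),
        ])
        values = {r.metric_id: r.value for r in id_metrics(toy_run(), ids)}
        assert values["total_psms"] == 3
        assert values["total_identified_peptides"] == 2
        assert values["total_uniquely_identified_peptides"] == 2
        assert values["total_identified_proteins"] == 1
        assert values["total_uniquely_identified_proteins"] == 1

    def test_empty_results(self):
        values = {r.metric_id: r.value for r in id_metrics(toy_run(), IdResults())}
        assert values["total_psms"] == 0
        assert values["id_ratio"] == 0.0
        assert "mean_delta_ppm" not in values

    def test_shared_peptide_not_unique(self):
        ids = IdResults([id_row(1, "LVNELTEFAK", ["P1", "P2"])])
        values = {r.metric_id: r.value for r in id_metrics(toy_run(), ids)}
        assert values["total_identified_peptides"] == 1
        assert values["total_uniquely_identified_peptides"] == 0
        assert values["total_identified_proteins"] == 2
        assert values["total_uniquely_identified_proteins"] == 0

    def test_id_ratio_uses_ms2_count(self):
        ids = IdResults([id_row(1, "LVNELTEFAK", ["P1"])])
        run = toy_run(10)  # 5 MS2 spectra
        values = {r.metric_id: r.value for r in id_metrics(run, ids)}
        assert values["id_ratio"] == pytest.approx(1 / 5)

    def test_delta_ppm_from_table_mz(self):
        ids = IdResults([
            id_row(1, "LVNELTEFAK", ["P1"], obs=500.0025, theo=500.0),
            id_row(3, "LVNELTEFAK", ["P1"], obs=500.0, theo=500.0),
        ])
        values = {r.metric_id: r.value for r in id_metrics(toy_run(), ids)}
        assert values["mean_delta_ppm"] == pytest.approx(2.5, abs=1e-6)
        assert values["median_delta_ppm"] == pytest.approx(2.5, abs=1e-6)

    def test_missed_cleavages_summed_over_psms(self):
        ids = IdResults([
            id_row(1, "AKAR", ["P1"]),
            id_row(3, "AKAR", ["P1"]),
            id_row(5, "AKPR", ["P2"]),
        ])
        values = {r.metric_id: r.value for r in id_metrics(toy_run(), ids)}
        assert values["total_missed_cleavages"] == 2

    def test_bad_spectrum_reference_names_row(self):
        ids = IdResults([id_row(99, "LVNELTEFAK", ["P1"])])
        with pytest.raises(ValueError, match="row 0"):
            id_metrics(toy_run(), ids)

    def test_random_tables_agree_with_brute_force_oracle(self):
        """Set arithmetic matches an independent exhaustive implementation."""
        rng = np.random.default_rng(42)
        peptides = ["AKAR", "LVNELTEFAK", "AKPR", "GGKA", "HLVDEPQNLIK", "RRK"]
        proteins = ["P1", "P2", "P3"]
        run = toy_run(20)
        for _ in range(300):
            n = int(rng.integers(0, 8))
            ids = IdResults([
                id_row(
                    int(rng.choice([1, 3, 5, 7, 9])),
                    str(rng.choice(peptides)),
                    list(rng.choice(proteins, size=int(rng.integers(1, 3)),
                                    replace=False)),
                    obs=500.0 * (1 + rng.normal(0, 2e-6)),
                )
                for _ in range(n)
            ])
            values = {r.metric_id: r.value for r in id_metrics(run, ids)}
            expected = _brute_force_id_counts(ids)
            for key, val in expected.items():
                assert values[key] == val, key

    def test_read_id_table(self, tmp_path):
        path = tmp_path / "ids.tsv"
        path.write_text(
            "spectrum_index\tpeptide\tproteins\tobserved_mz\ttheoretical_mz\tcharge\n"
            "1\tEAC(CAM)FAVEGPK\tP1;P2\t541.76\t541.75\t2\n"
        )
        ids = read_id_table(path)
        assert ids.rows[0].proteins == ("P1", "P2")
        assert ids.rows[0].charge == 2
        with pytest.raises(ValueError, match="missing columns"):
            bad = tmp_path / "bad.tsv"
            bad.write_text("a\tb\n1\t2\n")
            read_id_table(bad)


def _brute_force_id_counts(ids):
    """Exhaustive re-derivation of the id counts, element by element."""
    pep_to_prots = {}
    for row in ids.rows:
        for prot in row.proteins:
            pep_to_prots.setdefault(row.peptide, [])
            if prot not in pep_to_prots[row.peptide]:
                pep_to_prots[row.peptide].append(prot)
    unique_peps = [p for p in pep_to_prots if len(pep_to_prots[p]) == 1]
    all_prots = []
    for prots in pep_to_prots.values():
        for p in prots:
            if p not in all_prots:
                all_prots.append(p)
    unique_prots = []
    for prot in all_prots:
        for pep in unique_peps:
            if pep_to_prots[pep] == [prot] and prot not in unique_prots:
                unique_prots.append(prot)
    missed = 0
    for row in ids.rows:
        seq = parse_peptide(row.peptide).sequence
        for i in range(len(seq) - 1):
            if seq[i] in "KR" and seq[i + 1] != "P":
                missed += 1
    return {
        "total_psms": len(ids.rows),
        "total_identified_peptides": len(pep_to_prots),
        "total_uniquely_identified_peptides": len(unique_peps),
        "total_identified_proteins": len(all_prots),
        "total_uniquely_identified_proteins": len(unique_prots),
        "total_missed_cleavages": missed,
    }


class TestComputeAll:
    def test_qc1_without_ids(self, small_qc1):
        recipe, run, _ = small_qc1
        ms = compute_all(run, recipe.targets())
        ids_present = {r.metric_id for r in ms.records}
        assert "peptide_area" in ids_present
        assert "mass_accuracy" in ids_present
        assert "median_injection_time_ms1" in ids_present
        assert "peak_capacity" in ids_present
        assert "total_ion_current" in ids_present
        assert "ms1_spectra_count" in ids_present
        assert "total_psms" not in ids_present
        assert "chromatographic_resolution" not in ids_present  # QC1 panel
        assert "retention_time_drift" not in ids_present  # no previous run

    def test_qc2_with_ids_has_full_set(self):
        recipe = lcmsqc.RunRecipe.for_panel("QC2", seed=5, gradient_length=600.0,
                                            scan_interval=2.0, peak_sigma=8.0)
        run, _ = lcmsqc.generate_run(recipe)
        ms2_idx = [s.index for s in run.spectra if s.ms_level == 2]
        ids = IdResults([id_row(ms2_idx[0], "YAEAVTR", ["P1"])])
        ms = compute_all(run, recipe.targets(), ids=ids)
        present = {r.metric_id for r in ms.records}
        assert "chromatographic_resolution" in present
        assert "total_psms" in present
        assert len([r for r in ms.records if r.metric_id == "chromatographic_resolution"]) == 2

    def test_rt_drift_against_previous_metric_set(self, small_qc1):
        recipe, run, _ = small_qc1
        first = compute_all(run, recipe.targets())
        second = compute_all(run, recipe.targets(), previous=first)
        drifts = [r for r in second.records if r.metric_id == "retention_time_drift"]
        assert len(drifts) == 10
        assert all(r.value == 0.0 for r in drifts)  # identical run

    def test_no_duplicate_metric_target_pairs(self, small_qc1):
        recipe, run, _ = small_qc1
        ms = compute_all(run, recipe.targets())
        keys = [(r.metric_id, r.target) for r in ms.records]
        assert len(keys) == len(set(keys))

    def test_all_values_finite_and_absence_is_not_zero(self, small_qc1, tmp_path):
        recipe, run, _ = small_qc1
        ms = compute_all(run, recipe.targets())
        assert all(np.isfinite(r.value) for r in ms.records)
        # a not-found target must stay absent through serialization
        from lcmsqc.mzml_io import read_qcml, write_qcml

        assert ms.get("median_injection_time_ms3") is None
        path = tmp_path / "m.qcml.xml"
        write_qcml(ms, path)
        loaded = read_qcml(path)
        assert len(loaded.records) == len(ms.records)

    def test_duplicate_record_rejected(self):
        ms = MetricSet(run_id="r")
        ms.add(MetricRecord(metric_id="total_psms", value=1.0))
        with pytest.raises(ValueError, match="duplicate"):
            ms.add(MetricRecord(metric_id="total_psms", value=2.0))
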