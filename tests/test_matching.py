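"""Peak extraction, tier assignment, MRM matching, untargeted annotation."""

import numpy as np
import pytest

from lcoscan import (
    ChromatogramTrace,
    UntargetedSpectrum,
    build_transition_db,
    confidence_tier,
    extract_peaks,
    match_mrm,
    match_untargeted,
)
from lcoscan.matching import (
    read_spectra_csv,
    read_traces_csv,
    read_traces_mzml,
    write_traces_csv,
)


def gaussian_trace(prec, prod, centers, amplitudes, sigma=0.05, noise_sd=0.0, seed=0):
    t = np.arange(1.0, 11.0, 0.01)
    y = np.zeros_like(t)
    for c, a in zip(centers, amplitudes):
        y += a * np.exp(-((t - c) ** 2) / (2 * sigma**2))
    if noise_sd:
        y += np.random.default_rng(seed).normal(0, noise_sd, t.size)
    return ChromatogramTrace(prec, prod, t, np.clip(y, 0, None))


class TestExtractPeaks:
    def test_single_gaussian_apex(self):
        trace = gaussian_trace(628.0, 204.0, [5.0], [1000.0])
        peaks = extract_peaks(trace)
        assert len(peaks) == 1
        assert peaks[0].rt == pytest.approx(5.0, abs=0.011)
        assert peaks[0].intensity == pytest.approx(1000.0, rel=1e-3)

    def test_flat_trace_has_no_peaks(self):
        t = np.arange(1.0, 11.0, 0.01)
        trace = ChromatogramTrace(628.0, 204.0, t, np.zeros_like(t))
        assert extract_peaks(trace) == []

    def test_two_separated_gaussians(self):
        trace = gaussian_trace(628.0, 204.0, [4.0, 6.0], [800.0, 600.0])
        peaks = extract_peaks(trace)
        assert len(peaks) == 2
        assert peaks[0].rt == pytest.approx(4.0, abs=0.011)
        assert peaks[1].rt == pytest.approx(6.0, abs=0.011)

    def test_empty_trace_is_empty_result(self):
        trace = ChromatogramTrace(628.0, 204.0, np.array([]), np.array([]))
        assert extract_peaks(trace) == []

    def test_noisy_single_peak_still_found(self):
        trace = gaussian_trace(628.0, 204.0, [5.0], [1000.0], noise_sd=5.0, seed=3)
        peaks = extract_peaks(trace)
        assert any(abs(p.rt - 5.0) < 0.05 for p in peaks)

    def test_grid_must_increase(self):
        with pytest.raises(ValueError):
            ChromatogramTrace(628.0, 204.0, np.array([1.0, 1.0]), np.array([0.0, 0.0]))


class TestConfidenceTier:
    @pytest.mark.parametrize(
        "matched, at_rt, tier",
        [
            (3, False, "high"),
            (2, False, "high"),
            (1, True, "low"),
            (1, False, "none"),
            (0, False, "none"),
        ],
    )
    def test_tier_rules(self, matched, at_rt, tier):
        assert confidence_tier(matched, at_rt) == tier

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            confidence_tier(-1, False)


@pytest.fixture(scope="module")
def co_panel(co_structures):
    db = build_transition_db(co_structures)
    return db.with_expected_rt({"CO4": 5.0})


class TestMatchMrm:
    def test_three_coeluting_transitions_give_high(self, co_panel):
        records = co_panel.by_structure()["CO4"]
        traces = [
            gaussian_trace(r.precursor_mz, r.product_mz, [5.0], [500.0])
            for r in records
        ]
        calls = {c.structure: c for c in match_mrm(co_panel, traces)}
        assert calls["CO4"].tier == "high"
        assert calls["CO4"].matched_transitions == 3
        assert calls["CO4"].coelution_rt == pytest.approx(5.0, abs=0.02)

    def test_single_transition_at_expected_rt_gives_low(self, co_panel):
        record = co_panel.by_structure()["CO4"][0]
        traces = [gaussian_trace(record.precursor_mz, record.product_mz, [5.0], [500.0])]
        calls = {c.structure: c for c in match_mrm(co_panel, traces)}
        assert calls["CO4"].tier == "low"

    def test_single_transition_at_wrong_rt_gives_none(self, co_panel):
        record = co_panel.by_structure()["CO4"][0]
        traces = [gaussian_trace(record.precursor_mz, record.product_mz, [8.0], [500.0])]
        calls = {c.structure: c for c in match_mrm(co_panel, traces)}
        assert calls["CO4"].tier == "none"

    def test_no_traces_gives_none_for_all(self, co_panel):
        calls = match_mrm(co_panel, [])
        assert all(c.tier == "none" for c in calls)
        assert [c.structure for c in calls] == sorted(c.structure for c in calls)

    def test_non_coeluting_transitions_do_not_stack(self, co_panel):
        """Peaks at scattered RTs on different transitions stay unmatched."""
        records = co_panel.by_structure()["CO4"]
        traces = [
            gaussian_trace(r.precursor_mz, r.product_mz, [2.0 + 2.0 * i], [500.0])
            for i, r in enumerate(records)
        ]
        calls = {c.structure: c for c in match_mrm(co_panel, traces)}
        assert calls["CO4"].matched_transitions == 1

    def test_widening_tolerance_never_reduces_matches(self, co_panel):
        records = co_panel.by_structure()["CO4"]
        traces = [
            gaussian_trace(r.precursor_mz + 0.3, r.product_mz - 0.2, [5.0], [500.0])
            for r in records
        ]
        counts = [
            {c.structure: c.matched_transitions for c in
             match_mrm(co_panel, traces, mz_tolerance=tol)}
            for tol in (0.1, 0.35, 0.6, 1.0)
        ]
        for narrow, wide in zip(counts, counts[1:]):
            assert all(wide[s] >= narrow[s] for s in narrow)

    def test_ambiguous_trace_assigned_to_nearest(self, co_panel, caplog):
        record = co_panel.by_structure()["CO4"][0]
        trace = gaussian_trace(record.precursor_mz + 0.05, record.product_mz, [5.0], [500.0])
        with caplog.at_level("WARNING"):
            calls = {c.structure: c for c in
                     match_mrm(co_panel, [trace], mz_tolerance=650.0)}
        assert "assigning nearest" in caplog.text
        assert calls["CO4"].matched_transitions == 1

    def test_empty_panel_rejected(self):
        from lcoscan.transitions import TransitionDB

        with pytest.raises(ValueError):
            match_mrm(TransitionDB(), [])


@pytest.fixture(scope="module")
def db(co_structures):
    return build_transition_db(co_structures)


class TestMatchUntargeted:

    def test_co5_recovered_with_single_product(self, db):
        prec = db.by_structure()["CO5"][0].precursor_mz
        spectrum = UntargetedSpectrum("s1", prec, ((204.0867, 500.0),))
        hits = match_untargeted([spectrum], db, min_products=1)
        assert hits and hits[0].structure == "CO5" and hits[0].rank == 1

    def test_residue_range_excludes_long_backbones(self, co_structures):
        from lcoscan import COStructure

        db = build_transition_db(list(co_structures) + [COStructure(7)])
        prec = db.by_structure()["CO7"][0].precursor_mz
        spectrum = UntargetedSpectrum(
            "s1", prec, ((204.0867, 500.0), (407.1661, 300.0))
        )
        assert match_untargeted([spectrum], db, residue_range=(3, 6)) == []
        assert match_untargeted([spectrum], db, residue_range=(3, 7))

    def test_empty_spectra_list(self, db):
        assert match_untargeted([], db) == []

    def test_min_products_filters_weak_candidates(self, db):
        prec = db.by_structure()["CO5"][0].precursor_mz
        spectrum = UntargetedSpectrum("s1", prec, ((204.0867, 500.0),))
        assert match_untargeted([spectrum], db, min_products=2) == []

    def test_product_above_precursor_rejected(self):
        with pytest.raises(ValueError):
            UntargetedSpectrum("s1", 204.0, ((500.0, 10.0),))


class TestTraceIO:
    def test_csv_round_trip(self, tmp_path):
        traces = [
            gaussian_trace(628.256, 204.0867, [5.0], [500.0]),
            gaussian_trace(831.3354, 204.0867, [6.0], [300.0]),
        ]
        path = tmp_path / "traces.csv"
        write_traces_csv(traces, path)
        back = read_traces_csv(path)
        assert len(back) == 2
        keys = {t.key for t in back}
        assert (628.256, 204.0867) in keys
        for t in back:
            assert t.times.size == traces[0].times.size

    def test_mzml_chromatogram_reading(self, tmp_path):
        """Round-trip through a minimal handcrafted SRM mzML document."""
        import base64

        def encode(a):
            return base64.b64encode(np.asarray(a, dtype="<f8").tobytes()).decode()

        t = np.linspace(1, 3, 21)
        y = 100.0 * np.exp(-((t - 2.0) ** 2) / (2 * 0.05**2))
        path = tmp_path / "mini.mzML"
        path.write_text(f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <run id="r">
    <chromatogramList count="1" defaultDataProcessingRef="dp">
      <chromatogram index="0" id="SRM SIC Q1=628.256 Q3=204.0867" defaultArrayLength="{t.size}">
        <precursor><isolationWindow>
          <cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="628.256"/>
        </isolationWindow></precursor>
        <product><isolationWindow>
          <cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="204.0867"/>
        </isolationWindow></product>
        <binaryDataArrayList count="2">
          <binaryDataArray>
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>
            <cvParam cvRef="MS" accession="MS:1000595" name="time array" unitName="minute"/>
            <binary>{encode(t)}</binary>
          </binaryDataArray>
          <binaryDataArray>
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array"/>
            <binary>{encode(y)}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </chromatogram>
    </chromatogramList>
  </run>
</mzML>
""")
        traces = read_traces_mzml(path)
        assert len(traces) == 1
        assert traces[0].precursor_mz == pytest.approx(628.256)
        assert traces[0].product_mz == pytest.approx(204.0867)
        np.testing.assert_allclose(traces[0].times, t)
        np.testing.assert_allclose(traces[0].intensities, y)

    def test_spectra_csv_reader(self, tmp_path):
        path = tmp_path / "spectra.csv"
        path.write_text(
            "spectrum_id,precursor_mz,product_mz,intensity\n"
            "s1,1034.4147,204.0867,500\n"
            "s1,1034.4147,407.1661,300\n"
            "s2,628.2560,204.0867,900\n"
        )
        spectra = read_spectra_csv(path)
        assert [s.spectrum_id for s in spectra] == ["s1", "s2"]
        assert len(spectra[0].products) == 2
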