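"""ROI tracing, peak detection, feature grouping, gap filling."""

import numpy as np
import pytest

from mzsift import peaks as pk
from mzsift import simulate as sim
from mzsift.chem import ElementalFormula
from mzsift.peaks import EIC, Peak, detect_peaks, extract_rois, group_features
from mzsift.simulate import CompoundSpec, NoiseModel, Scenario, simulate_run


def make_run(compounds, noise=None, seed=0, group="Low"):
    sc = Scenario(compounds, noise=noise or NoiseModel.off())
    run, ledger = simulate_run(compounds, sample_id="s", group=group,
                               sample_type="incubation", injection_index=0,
                               scenario=sc, seed=seed)
    return run, ledger


def spec(name, mz, rt=200.0, abundance=1e6, **kw):
    kw.setdefault("multipliers", {"Low": 1.0})
    kw.setdefault("n_carbons", 0)
    return CompoundSpec(name, "parent", rt_apex=rt, base_abundance=abundance,
                        mz=mz, **kw)


def gaussian_eic(apex_rt=200.0, sigma=4.0, area=1e6, dt=0.5,
                 span=40.0, mz=300.0):
    rt = np.arange(apex_rt - span, apex_rt + span + dt / 2, dt)
    y = area * np.exp(-0.5 * ((rt - apex_rt) / sigma) ** 2) \
        / (sigma * np.sqrt(2 * np.pi))
    return EIC(target_mz=mz, ppm_halfwidth=5.0, rt=rt, intensity=y,
               mz=np.full_like(rt, mz))


class TestExtractRois:
    def test_single_species_single_roi(self):
        run, _ = make_run([spec("a", 300.0)])
        rois = extract_rois(run)
        assert len(rois) == 1
        assert rois[0].target_mz == pytest.approx(300.0, abs=1e-6)

    def test_species_50ppm_apart_stay_separate(self):
        mz = 300.0
        run, _ = make_run([spec("a", mz), spec("b", mz * (1 + 50e-6))])
        assert len(extract_rois(run, ppm_tol=5.0)) == 2

    def test_roi_mean_mz_within_2ppm_under_jitter(self):
        run, _ = make_run([spec("a", 218.15394)],
                          noise=NoiseModel(sigma_ppm=1.0, bio_cv=0, tech_cv=0,
                                           noise_per_scan=0,
                                           carryover_prob=0.0), seed=3)
        rois = extract_rois(run)
        assert len(rois) == 1
        err = abs(rois[0].target_mz - 218.15394) / 218.15394 * 1e6
        assert err <= 2.0

    def test_empty_run_gives_no_rois(self):
        run, _ = make_run([spec("a", 300.0)], group="Blank")
        assert extract_rois(run) == []


class TestDetectPeaks:
    def test_noise_free_gaussian_recovered(self):
        eic = gaussian_eic(sigma=4.0, area=1e6)
        found = detect_peaks(eic)
        assert len(found) == 1
        p = found[0]
        assert abs(p.apex_rt - 200.0) <= 0.5          # within one scan
        assert p.area == pytest.approx(1e6, rel=0.05)

    def test_flat_zero_trace_has_no_peaks(self):
        rt = np.arange(0, 50, 0.5)
        eic = EIC(300.0, 5.0, rt, np.zeros_like(rt), np.full_like(rt, 300.0))
        assert detect_peaks(eic) == []

    def test_two_gaussians_6_sigma_apart_split(self):
        a = gaussian_eic(apex_rt=200.0, sigma=4.0)
        b = gaussian_eic(apex_rt=224.0, sigma=4.0)
        rt = np.arange(160, 264, 0.5)
        y = np.interp(rt, a.rt, a.intensity, left=0, right=0) + \
            np.interp(rt, b.rt, b.intensity, left=0, right=0)
        eic = EIC(300.0, 5.0, rt, y, np.full_like(rt, 300.0))
        found = detect_peaks(eic)
        assert len(found) == 2
        assert sorted(round(p.apex_rt) for p in found) == [200, 224]

    def test_malformed_width_bounds_rejected(self):
        with pytest.raises(ValueError, match="width"):
            detect_peaks(gaussian_eic(), width_bounds_s=(60.0, 2.0))


def mkpeak(sample, mz, rt, area=100.0):
    return Peak(sample_id=sample, apex_rt=rt, rt_left=rt - 8, rt_right=rt + 8,
                mz=mz, area=area, snr=50.0, apex_intensity=area / 10)


class TestGroupFeatures:
    def test_one_species_in_20_runs_one_feature(self):
        plist = [mkpeak(f"s{i}", 300.0 + 1e-5 * np.sin(i), 200.0)
                 for i in range(20)]
        feats = group_features(plist)
        assert len(feats) == 1
        assert len(feats.attrs["abundance"][0]) == 20

    def test_rt_separation_splits(self):
        plist = [mkpeak("s1", 300.0, 100.0), mkpeak("s1", 300.0, 400.0)]
        assert len(group_features(plist, rt_tol_s=10.0)) == 2

    def test_isomer_pair_47s_apart_splits(self):
        # same m/z, RT 269 vs 316 s: the hydroxy-metabolite isomer pattern
        plist = [mkpeak("s1", 276.1954, 269.0), mkpeak("s1", 276.1954, 316.0),
                 mkpeak("s2", 276.1954, 269.0), mkpeak("s2", 276.1954, 316.0)]
        feats = group_features(plist, rt_tol_s=10.0)
        assert len(feats) == 2
        assert sorted(feats["rt"]) == [269.0, 316.0]

    def test_duplicate_sample_keeps_larger_area(self):
        plist = [mkpeak("s1", 300.0, 200.0, area=50.0),
                 mkpeak("s1", 300.0, 201.0, area=80.0)]
        feats = group_features(plist)
        assert len(feats) == 1
        assert feats.attrs["abundance"][0]["s1"] == 80.0

    def test_order_invariance(self):
        plist = [mkpeak(f"s{i}", mz, rt) for i in range(3)
                 for mz, rt in ((300.0, 100.0), (300.0, 400.0), (350.0, 100.0))]
        a = group_features(plist)
        b = group_features(plist[::-1])
        assert list(a.index) == list(b.index)


class TestFillMissing:
    def test_noise_off_filled_abundance_zero(self, quiet_scenario):
        study = sim.simulate_study(quiet_scenario, seed=0)
        table = pk.pick_study(study.runs, study.samples)
        blank_ids = table.group_columns("Blank")
        parent = [f for f in table.feature_names
                  if abs(table.features.loc[f, "mz"] - 218.15394) < 0.01]
        assert parent
        assert (table.abundance.loc[parent[0], blank_ids] == 0).all()

    def test_noise_on_blank_fill_integrates_noise(self, pipeline):
        table = pipeline.table_raw
        flags = table.abundance.attrs["fill_flags"]
        blank_ids = table.group_columns("Blank")
        parent = [f for f in table.feature_names
                  if abs(table.features.loc[f, "mz"] - 218.15394) < 0.005
                  and abs(table.features.loc[f, "rt"] - 216.0) < 5][0]
        assert flags.loc[parent, blank_ids].all()
        assert (table.abundance.loc[parent, blank_ids] > 0).all()

    def test_filled_matches_detected_for_present_species(self):
        # integrate the same window in a run where the peak WAS detected:
        # the filled value must match the detected area closely
        c = spec("a", 300.0)
        run, _ = make_run([c])
        peaks1 = pk.pick_sample(run)
        assert len(peaks1) == 1
        feats = group_features(peaks1)
        import pandas as pd
        samples = pd.DataFrame({"sample_id": ["s", "t"],
                                "group": ["Low", "Low"],
                                "sample_type": ["incubation", "incubation"],
                                "injection_index": [0, 1]}).set_index("sample_id")
        table = pk.build_table(feats, samples)
        run2 = make_run([c])[0]
        run2.sample_id = "t"
        filled = pk.fill_missing(table, [run, run2])
        a, b = filled.abundance.iloc[0]
        assert b == pytest.approx(a, rel=0.05)


class TestEndToEndRecovery:
    def test_recall_of_planted_species_above_noise(self, pipeline):
        """>= 95% of planted species with abundance above 10x the noise
        floor are recovered as features (5 ppm / 10 s ledger match)."""
        study = pipeline.study
        table = pipeline.table_raw
        mono = study.ledger[study.ledger.isotope_k == 0]
        per_species = mono.groupby(["species", "mz", "rt_apex"])[
            "planted_area"].max().reset_index()
        strong = per_species[per_species.planted_area >
                             10 * study.noise_floor]
        fmz = table.features["mz"].to_numpy()
        frt = table.features["rt"].to_numpy()
        hits = 0
        for row in strong.itertuples(index=False):
            ok = (np.abs(fmz - row.mz) / row.mz * 1e6 <= 5.0) & \
                 (np.abs(frt - row.rt_apex) <= 10.0)
            hits += bool(ok.any())
        assert hits / len(strong) >= 0.95

    def test_no_duplicate_abundance_per_sample(self, pipeline):
        table = pipeline.table_raw
        assert table.abundance.columns.is_unique
        assert table.abundance.index.is_unique
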