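"""Two-step global Langmuir fitting: aggregation, Imax, Kd, bootstrap, QC flags."""

import numpy as np
import pandas as pd
import pytest

from mrblepep.binding_fit import (
    LOW_SIGNAL,
    NON_SATURATING,
    NONSPECIFIC,
    UNTESTED,
    BindingSeries,
    FitResult,
    _fit_kd_single,
    aggregate_series,
    bootstrap_kd,
    estimate_background,
    estimate_peptide_concentration,
    fit_global_imax,
    fit_kds,
    flag_nonspecific,
    flag_saturation,
    results_from_csv,
    results_to_csv,
)
from mrblepep.decoding import decode_bead_table
from mrblepep.synthetic_data import (
    DEFAULT_CONCENTRATIONS,
    AssayDesign,
    langmuir_intensity,
    make_code_map,
    make_ground_truth,
    simulate_assay,
)

CONC = np.asarray(DEFAULT_CONCENTRATIONS)


def series_for(kd, imax=1000.0, name="pep", conc=CONC):
    return BindingSeries(
        variant_id=name,
        conc_nM=conc,
        median_intensity=langmuir_intensity(kd, imax, np.asarray(conc, float)),
        n_beads=np.full(len(conc), 50),
    )


class TestAggregateSeries:
    def test_single_bead_median_is_identity(self, code_map48, truth48, noiseless_design):
        design = AssayDesign(
            beads_per_code=1, intensity_sigma=0.0, ratio_sigma=0.0, background=0.0
        )
        beads = simulate_assay(code_map48, truth48, design)
        assignments = decode_bead_table(beads, code_map48)
        series = aggregate_series(beads, assignments, code_map48, by="code", min_beads=1)
        for s in series:
            expect = beads[beads["code_true"] == s.code_id].sort_values("conc_nM")
            assert np.allclose(s.median_intensity, expect["intensity"])

    def test_triplicate_codes_merge_into_pooled_peptide_series(self):
        peptides = [f"pep{i:03d}" for i in range(16) for _ in range(3)]  # 3 codes/peptide
        cm = make_code_map(48, peptides=peptides, seed=1)
        truth = make_ground_truth(sorted(set(peptides)), seed=1)
        beads = simulate_assay(cm, truth, AssayDesign(beads_per_code=10, seed=1))
        assignments = decode_bead_table(beads, cm)
        per_code = aggregate_series(beads, assignments, cm, by="code", min_beads=1)
        per_pep = aggregate_series(beads, assignments, cm, by="peptide", min_beads=1)
        assert len(per_code) == 48 and len(per_pep) == 16
        # pooled bead counts are the sum over the three codes
        counts = {s.variant_id: s.n_beads.sum() for s in per_pep}
        by_pep = {}
        for s in per_code:
            by_pep[s.variant_id] = by_pep.get(s.variant_id, 0) + s.n_beads.sum()
        assert counts == by_pep

    def test_median_matches_brute_force_sort_and_pick(self):
        rng = np.random.default_rng(0)
        rows = []
        for conc in (100.0, 200.0):
            for n, offset in ((7, 0), (8, 100)):  # odd and even counts
                for i in range(n):
                    rows.append(
                        {"bead_id": len(rows), "assay_id": "a", "conc_nM": conc + offset,
                         "intensity": float(rng.normal(500, 50))}
                    )
        beads = pd.DataFrame(rows)
        assignments = pd.DataFrame({"bead_id": beads["bead_id"], "code_id": "C000"})
        cm = make_code_map(1, levels_per_channel=1, peptides=["p"])
        series = aggregate_series(beads, assignments, cm, by="code", min_beads=1)[0]
        for conc, med in zip(series.conc_nM, series.median_intensity):
            vals = sorted(beads.loc[beads["conc_nM"] == conc, "intensity"])
            n = len(vals)
            brute = vals[n // 2] if n % 2 else 0.5 * (vals[n // 2 - 1] + vals[n // 2])
            assert med == pytest.approx(brute)

    def test_low_bead_count_flagged(self):
        beads = pd.DataFrame(
            {"bead_id": [0, 1], "assay_id": "a", "conc_nM": [100.0, 200.0],
             "intensity": [1.0, 2.0]}
        )
        assignments = pd.DataFrame({"bead_id": [0, 1], "code_id": "C000"})
        cm = make_code_map(1, levels_per_channel=1, peptides=["p"])
        series = aggregate_series(beads, assignments, cm, min_beads=5)[0]
        assert LOW_SIGNAL in series.flags


class TestGlobalImax:
    def test_noiseless_recovery_to_machine_precision(self):
        series = [series_for(kd, imax=1000.0, name=f"p{i}") for i, kd in
                  enumerate((50, 120, 300, 700, 1500, 2500))]
        imax = fit_global_imax(series)
        assert imax == pytest.approx(1000.0, rel=1e-6)

    def test_identical_series_match_joint_fit(self):
        series = [series_for(200.0, name=f"p{i}") for i in range(4)]
        assert fit_global_imax(series) == pytest.approx(1000.0, rel=1e-6)

    def test_top_fraction_choice_irrelevant_on_clean_data(self):
        series = [series_for(kd, name=f"p{i}") for i, kd in enumerate((60, 150, 400, 900, 2000))]
        a = fit_global_imax(series, top_fraction=0.8)
        b = fit_global_imax(series, top_fraction=1.0)
        assert a == pytest.approx(b, rel=1e-6)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            fit_global_imax([series_for(100.0)])
        short = series_for(100.0, conc=CONC[:2])
        with pytest.raises(ValueError):
            fit_global_imax([short, short])


class TestFitKds:
    def test_noiseless_kd_recovery(self):
        res = fit_kds([series_for(170.0)], imax_global=1000.0)[0]
        assert res.kd_nM == pytest.approx(170.0, rel=1e-6)

    def test_half_saturation_identity(self):
        # intensity Imax/2 at conc c (and consistent elsewhere) pins Kd = c
        res = fit_kds([series_for(500.0)], imax_global=1000.0)[0]
        assert res.kd_nM == pytest.approx(500.0, rel=1e-6)

    def test_fixed_imax_equals_joint_fit_on_noiseless_data(self):
        kds = (50.0, 300.0, 1200.0)
        series = [series_for(kd, name=f"p{i}") for i, kd in enumerate(kds)]
        imax = fit_global_imax(series, top_fraction=1.0)
        res = fit_kds(series, imax)
        for r, kd in zip(res, kds):
            assert r.kd_nM == pytest.approx(kd, rel=1e-6)

    def test_optimizer_matches_log_grid_oracle(self):
        rng = np.random.default_rng(42)
        grid = np.logspace(-2, 6, 10_000)
        step = grid[1] / grid[0]
        for _ in range(25):
            kd_true = 10 ** rng.uniform(1.2, 3.6)
            y = langmuir_intensity(kd_true, 1000.0, CONC) * np.exp(rng.normal(0, 0.1, len(CONC)))
            kd_opt, _ = _fit_kd_single(CONC, y, 1000.0)
            sse = ((1000.0 * CONC[None, :] / (grid[:, None] + CONC[None, :]) - y) ** 2).sum(1)
            kd_grid = grid[np.argmin(sse)]
            assert kd_grid / step <= kd_opt <= kd_grid * step

    def test_residuals_invariant_to_common_rescale(self):
        rng = np.random.default_rng(1)
        y = langmuir_intensity(300.0, 1000.0, CONC) * np.exp(rng.normal(0, 0.1, len(CONC)))
        s1 = BindingSeries("p", CONC, y, np.full(len(CONC), 10))
        s2 = BindingSeries("p", CONC, 5.0 * y, np.full(len(CONC), 10))
        r1 = fit_kds([s1], 1000.0)[0]
        r2 = fit_kds([s2], 5000.0)[0]
        assert r1.kd_nM == pytest.approx(r2.kd_nM, rel=1e-6)

    def test_all_background_series_reported_as_lower_bound(self):
        s = BindingSeries("p", CONC, np.full(len(CONC), 5.0), np.full(len(CONC), 10))
        res = fit_kds([s], 1000.0, background=10.0)[0]
        assert LOW_SIGNAL in res.flags
        assert res.kd_nM == CONC.max()

    def test_imax_must_be_positive(self):
        with pytest.raises(ValueError):
            fit_kds([series_for(100.0)], imax_global=0.0)


class TestBootstrap:
    @staticmethod
    def _beads(kd, n=60, sigma=0.15, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for conc in CONC:
            mean = langmuir_intensity(kd, 1000.0, conc)
            for v in mean * np.exp(rng.normal(0, sigma, n)):
                rows.append({"conc_nM": conc, "intensity": v})
        return pd.DataFrame(rows)

    def test_noiseless_data_gives_zero_width_interval(self):
        beads = self._beads(200.0, sigma=0.0)
        lo, hi = bootstrap_kd(beads, 1000.0, n_boot=100, seed=0)
        assert lo == pytest.approx(hi, rel=1e-6)
        assert lo == pytest.approx(200.0, rel=1e-6)

    def test_fixed_seed_reproducible(self):
        beads = self._beads(300.0, seed=1)
        a = bootstrap_kd(beads, 1000.0, n_boot=150, seed=5)
        b = bootstrap_kd(beads, 1000.0, n_boot=150, seed=5)
        assert a == b

    def test_interval_coverage_calibration(self):
        # true Kd should fall inside the 95% interval in nearly all replicates
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            beads = self._beads(400.0, n=50, seed=100 + rep)
            lo, hi = bootstrap_kd(beads, 1000.0, n_boot=150, seed=rep)
            hits += lo <= 400.0 <= hi
        assert hits / n_rep >= 0.85

    def test_single_bead_warns(self):
        beads = pd.DataFrame({"conc_nM": CONC, "intensity": langmuir_intensity(100, 1000, CONC)})
        with pytest.warns(UserWarning):
            bootstrap_kd(beads, 1000.0, n_boot=100, seed=0)

    def test_n_boot_floor(self):
        with pytest.raises(ValueError):
            bootstrap_kd(self._beads(100.0), 1000.0, n_boot=10)


class TestFlags:
    def _fit(self, kd=100.0):
        return FitResult(variant_id="p", kd_nM=kd, imax_global=1000.0)

    def test_background_level_controls_not_flagged(self):
        flags = flag_nonspecific(self._fit(), nir_median=12.0, antibody_median=9.0,
                                 background=10.0)
        assert NONSPECIFIC not in flags

    def test_sticky_peptide_flagged(self):
        flags = flag_nonspecific(self._fit(), nir_median=500.0, antibody_median=15.0,
                                 background=10.0)
        assert NONSPECIFIC in flags

    def test_vacuous_threshold_flags_nothing(self):
        flags = flag_nonspecific(self._fit(), nir_median=900.0, antibody_median=990.0,
                                 threshold_fraction=1.0)
        assert NONSPECIFIC not in flags

    def test_missing_controls_marked_untested(self):
        flags = flag_nonspecific(self._fit(), None, None)
        assert UNTESTED in flags and NONSPECIFIC not in flags

    @pytest.mark.parametrize(
        "kd,expect_flag",
        [
            (10 * CONC.max(), True),  # fraction bound 1/11
            (CONC.max() / 10, False),  # fraction bound 10/11
            (CONC.max(), False),  # boundary: fraction exactly 0.5, strict <
        ],
    )
    def test_saturation_flag(self, kd, expect_flag):
        flags = flag_saturation(self._fit(kd), series_for(kd))
        assert (NON_SATURATING in flags) == expect_flag


class TestHelpers:
    def test_background_estimate_is_control_median(self):
        ab = pd.DataFrame({"intensity": [8.0, 10.0, 12.0, 11.0, 9.0]})
        assert estimate_background(ab) == 10.0
        assert estimate_background(None) == 0.0

    def test_peptide_concentration_diagnostic(self):
        assert estimate_peptide_concentration(48) == pytest.approx(20.0 / 48)
        with pytest.raises(ValueError):
            estimate_peptide_concentration(0)

    def test_results_csv_round_trip(self, tmp_path):
        res = [
            FitResult("a", 120.0, 1000.0, kd_lo=100.0, kd_hi=150.0,
                      flags={NON_SATURATING}, residual_norm=3.0, code_id="C001", assay_id="x"),
            FitResult("b", 50.0, 1000.0),
        ]
        path = tmp_path / "fits.csv"
        results_to_csv(res, path)
        back = results_from_csv(path)
        assert back[0].variant_id == "a" and back[0].flags == {NON_SATURATING}
        assert back[1].kd_nM == pytest.approx(50.0)
        assert np.isnan(back[1].kd_lo)
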