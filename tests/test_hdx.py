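"""Uptake computation, significance differencing, and EX1 deconvolution."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sarmdyn.errors import InputError, InsufficientDataError
from sarmdyn.hdx import (
    DEUTERIUM_INCREMENT_DA,
    HdxConfig,
    PeptideRecord,
    SpectrumEnvelope,
    UptakeMeasurement,
    centroid_neutral_mass,
    compute_uptake,
    count_exchangeable,
    coverage_summary,
    diff_uptake,
    fit_bimodal,
    fit_transition_kinetics,
    classify_bimodality,
)
from sarmdyn.synthetic import (
    SyntheticConfig,
    ex1_open_fraction,
    simulate_envelope,
    simulate_ex1_series,
)


def flat_envelope(center_mz: float, charge: int = 1, **kw) -> SpectrumEnvelope:
    """Three equal-intensity points symmetric about center_mz."""
    defaults = dict(
        peptide_id="p", condition="c", timepoint_s=10.0, replicate=1, charge=charge
    )
    defaults.update(kw)
    return SpectrumEnvelope(
        mz=np.array([center_mz - 1, center_mz, center_mz + 1]),
        intensity=np.array([1.0, 1.0, 1.0]),
        **defaults,
    )


class TestCountExchangeable:
    @pytest.mark.parametrize(
        "seq,expected",
        [("APA", 1), ("AAAA", 3), ("APPPP", 0), ("A", 0), ("PA", 1), ("AAPA", 2)],
    )
    def test_rule(self, seq, expected):
        assert count_exchangeable(seq) == expected

    def test_unknown_letter_names_position(self):
        with pytest.raises(InputError, match="position 3"):
            count_exchangeable("AAXA")

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            count_exchangeable("")


class TestCentroid:
    def test_two_equal_points(self):
        env = SpectrumEnvelope(
            peptide_id="p", condition="c", timepoint_s=0, replicate=1, charge=1,
            mz=np.array([500.0, 501.0, 502.0]),
            intensity=np.array([1.0, 0.0, 1.0]),
        )
        # hand-computed: weighted mean 501 minus one proton
        assert centroid_neutral_mass(env) == pytest.approx(499.992724, abs=1e-6)

    def test_scale_invariance(self):
        env = flat_envelope(700.0)
        scaled = SpectrumEnvelope(
            peptide_id="p", condition="c", timepoint_s=10.0, replicate=1, charge=1,
            mz=env.mz, intensity=env.intensity * 10,
        )
        assert centroid_neutral_mass(env) == pytest.approx(
            centroid_neutral_mass(scaled), abs=1e-12
        )

    def test_charge_deconvolution(self):
        env = flat_envelope(400.0, charge=2)
        assert centroid_neutral_mass(env) == pytest.approx(
            2 * (400.0 - 1.007276), abs=1e-9
        )


class TestComputeUptake:
    def test_identical_envelopes_zero(self):
        pep = PeptideRecord("p", "AAAA", 1, 4)
        env = flat_envelope(500.0)
        m = compute_uptake(env, env, pep)
        assert m.uptake_da == pytest.approx(0.0, abs=1e-12)
        assert m.percent_d == pytest.approx(0.0, abs=1e-12)

    def test_half_max_uptake_percent(self):
        # 3 exchangeable amides; 1.509 Da is half the theoretical maximum
        pep = PeptideRecord("p", "AAAA", 1, 4)
        ref = flat_envelope(500.0)
        deut = flat_envelope(500.0 + 1.509)
        m = compute_uptake(deut, ref, pep)
        assert m.uptake_da == pytest.approx(1.509, abs=1e-9)
        assert m.percent_d == pytest.approx(50.0, abs=0.5)

    def test_generator_roundtrip(self, noiseless_cfg):
        pep = PeptideRecord("pep1", "A" * 21, 1, 21)
        env = simulate_envelope(noiseless_cfg, [3.0], [1.0])
        ref = simulate_envelope(noiseless_cfg, [0.0], [1.0])
        m = compute_uptake(env, ref, pep)
        assert m.uptake_da == pytest.approx(3.0, abs=0.02)

    def test_peptide_mismatch_rejected(self):
        pep = PeptideRecord("other", "AAAA", 1, 4)
        with pytest.raises(InputError, match="mismatch"):
            compute_uptake(flat_envelope(500.0), flat_envelope(500.0), pep)

    def test_zero_max_uptake_rejected(self):
        pep = PeptideRecord("p", "APPP", 1, 4)  # no exchangeable amides
        with pytest.raises(InputError, match="undefined|no exchangeable"):
            compute_uptake(flat_envelope(500.0), flat_envelope(500.0), pep)


def _meas(pid, t, uptake, rep=1, cond="a"):
    return UptakeMeasurement(pid, cond, t, rep, uptake, 0.0)


class TestDiffUptake:
    def test_above_threshold_significant_positive(self):
        df = diff_uptake([_meas("p", 10, 1.0)], [_meas("p", 10, 0.5, cond="b")])
        assert df.loc[0, "diff_da"] == pytest.approx(0.5)
        assert bool(df.loc[0, "significant"])

    def test_boundary_is_strict(self):
        df = diff_uptake([_meas("p", 10, 0.4)], [_meas("p", 10, 0.0, cond="b")])
        assert df.loc[0, "diff_da"] == pytest.approx(0.4)
        assert not bool(df.loc[0, "significant"])

    def test_replicates_averaged(self):
        a = [_meas("p", 10, 1.0, rep=1), _meas("p", 10, 2.0, rep=2)]
        b = [_meas("p", 10, 1.0, cond="b")]
        df = diff_uptake(a, b)
        assert df.loc[0, "mean_a"] == pytest.approx(1.5)
        assert df.loc[0, "n_a"] == 2

    def test_no_shared_keys_rejected(self):
        with pytest.raises(InputError, match="share no"):
            diff_uptake([_meas("p", 10, 1.0)], [_meas("q", 10, 1.0)])

    def test_ordering_n_to_c(self):
        peps = {
            "late": PeptideRecord("late", "AAAA", 50, 53),
            "early": PeptideRecord("early", "AAAA", 2, 5),
        }
        a = [_meas("late", 10, 1.0), _meas("early", 10, 1.0)]
        b = [_meas("late", 10, 0.0, cond="b"), _meas("early", 10, 0.0, cond="b")]
        df = diff_uptake(a, b, peptides=peps)
        assert list(df["peptide_id"]) == ["early", "late"]

    @settings(derandomize=True, max_examples=40)
    @given(
        diffs=st.lists(
            st.floats(min_value=-3, max_value=3, allow_nan=False), min_size=1, max_size=8
        )
    )
    def test_antisymmetry_property(self, diffs):
        a = [_meas(f"p{i}", 10, d) for i, d in enumerate(diffs)]
        b = [_meas(f"p{i}", 10, 0.0, cond="b") for i in range(len(diffs))]
        fwd = diff_uptake(a, b)
        rev = diff_uptake(b, a)
        np.testing.assert_allclose(fwd["diff_da"], -rev["diff_da"], atol=1e-12)
        assert list(fwd["significant"]) == list(rev["significant"])


class TestBimodalFit:
    def test_recovers_unequal_mixture(self, noiseless_cfg):
        env = simulate_envelope(noiseless_cfg, [4.0, 16.0], [0.3, 0.7])
        fit = fit_bimodal(env)
        assert fit.f_open == pytest.approx(0.7, abs=0.02)
        assert fit.mu_low < fit.mu_high and fit.sigma > 0

    def test_recovers_symmetric_mixture(self, noiseless_cfg):
        env = simulate_envelope(noiseless_cfg, [4.0, 16.0], [0.5, 0.5])
        assert fit_bimodal(env).f_open == pytest.approx(0.5, abs=0.02)

    @pytest.mark.parametrize("mean,expect_open", [(4.0, False), (16.0, True)])
    def test_pure_subpopulation_reports_extreme_fraction(
        self, noiseless_cfg, mean, expect_open
    ):
        env = simulate_envelope(noiseless_cfg, [mean], [1.0])
        fit = fit_bimodal(env)
        if expect_open:
            assert fit.f_open >= 0.95
        else:
            assert fit.f_open <= 0.05
        assert classify_bimodality(env)[0] == "unimodal"

    def test_f_open_invariant_to_intensity_scale(self, noiseless_cfg):
        env = simulate_envelope(noiseless_cfg, [4.0, 16.0], [0.4, 0.6])
        scaled = SpectrumEnvelope(
            peptide_id=env.peptide_id, condition=env.condition,
            timepoint_s=env.timepoint_s, replicate=env.replicate, charge=env.charge,
            mz=env.mz, intensity=env.intensity * 123.4,
        )
        assert fit_bimodal(env).f_open == pytest.approx(
            fit_bimodal(scaled).f_open, abs=1e-9
        )

    def test_area_sum_rule(self, noiseless_cfg):
        env = simulate_envelope(noiseless_cfg, [4.0, 16.0], [0.4, 0.6])
        fit = fit_bimodal(env)
        # envelope is normalised to unit area inside the fit
        assert fit.area_low + fit.area_high == pytest.approx(1.0, rel=0.05)

    def test_too_few_points_rejected(self):
        env = SpectrumEnvelope(
            peptide_id="p", condition="c", timepoint_s=0, replicate=1, charge=1,
            mz=np.array([500.0, 501, 502, 503]), intensity=np.ones(4),
        )
        with pytest.raises(InsufficientDataError):
            fit_bimodal(env)


class TestBimodalityCall:
    def test_well_separated_mixture_is_bimodal(self, noiseless_cfg):
        env = simulate_envelope(noiseless_cfg, [4.0, 16.0], [0.5, 0.5])
        label, score = classify_bimodality(env)
        assert label == "bimodal" and score > 0

    def test_single_component_is_unimodal(self, noiseless_cfg):
        env = simulate_envelope(noiseless_cfg, [10.0], [1.0])
        assert classify_bimodality(env)[0] == "unimodal"

    def test_unresolvable_separation_is_unimodal(self, noiseless_cfg):
        # means 0.5 subpopulation-widths apart cannot be resolved
        env = simulate_envelope(noiseless_cfg, [9.5, 10.5], [0.5, 0.5])
        assert classify_bimodality(env)[0] == "unimodal"


class TestKinetics:
    def test_flat_series(self):
        kin = fit_transition_kinetics([(10, 0.4), (60, 0.4), (300, 0.4)])
        t = np.array([10.0, 60.0, 300.0])
        np.testing.assert_allclose(kin.predict(t), 0.4, atol=1e-6)

    def test_noiseless_series_recovers_rate(self):
        cfg = SyntheticConfig(k_open=0.01, f0=0.05, f_inf=0.9)
        series = [(t, ex1_open_fraction(cfg, t)) for t in cfg.timepoints]
        kin = fit_transition_kinetics(series)
        assert kin.k_open == pytest.approx(0.01, rel=0.01)
        assert kin.rss < 1e-12

    def test_envelope_roundtrip_recovers_rate(self):
        cfg = SyntheticConfig(seed=2, intensity_noise_cv=0.0, k_open=0.01)
        series = [
            (e.timepoint_s, fit_bimodal(e).f_open) for e in simulate_ex1_series(cfg)
        ]
        kin = fit_transition_kinetics(series)
        assert kin.k_open == pytest.approx(0.01, rel=0.01)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_transition_kinetics([(10, 0.1), (30, 0.2)])

    def test_fitted_curve_stays_in_unit_interval(self):
        cfg = SyntheticConfig(k_open=0.005)
        t = np.array(cfg.timepoints)
        rng = np.random.default_rng(0)
        f = np.clip(
            [ex1_open_fraction(cfg, x) for x in t] + 0.05 * rng.standard_normal(len(t)),
            0, 1,
        )
        kin = fit_transition_kinetics(list(zip(t, f)))
        pred = kin.predict(t)
        assert np.all(pred >= -1e-9) and np.all(pred <= 1 + 1e-9)


class TestCoverage:
    def test_full_cover(self):
        protein = "ACDEFGHIKLMNQRSTVWYA"  # 20 residues, no proline
        peps = [PeptideRecord("p1", protein, 1, 20)]
        n, pct = coverage_summary(peps, protein)
        assert (n, pct) == (1, pytest.approx(100.0))

    def test_empty_list(self):
        assert coverage_summary([], "ACDEFG")[1] == 0.0

    def test_disjoint_peptides_set_union_oracle(self):
        protein = "ACDEFPHIKLMNQRSTVWYA"  # proline at position 6
        peps = [
            PeptideRecord("p1", protein[0:10], 1, 10),
            PeptideRecord("p2", protein[10:20], 11, 20),
        ]
        # independent oracle: explicit position sets
        protein_exch = {i for i in range(2, 21) if protein[i - 1] != "P"}
        covered = set()
        for pep in peps:
            for j, aa in enumerate(pep.sequence):
                if j >= 1 and aa != "P":
                    covered.add(pep.start_res + j)
        expected = 100.0 * len(covered & protein_exch) / len(protein_exch)
        _, pct = coverage_summary(peps, protein)
        assert pct == pytest.approx(expected)

    def test_out_of_range_names_peptide(self):
        with pytest.raises(InputError, match="bad_pep"):
            coverage_summary([PeptideRecord("bad_pep", "AAAA", 18, 21)], "A" * 20)


def test_hdx_config_rejects_nonpositive_threshold():
    with pytest.raises(InputError):
        HdxConfig(significance_threshold_da=0.0)
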