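"""Lineage, multinucleate and intensity simulators."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sizehom.simdata import (
    IntensitySimParams,
    MultinucSimParams,
    SimParams,
    adder_preset,
    simulate_lineages,
    simulate_multinucleate,
    simulate_nuclear_intensities,
    sizer_preset,
    timer_preset,
)


def _noise_free(control_model, **kw):
    base = dict(
        control_model=control_model,
        trigger_noise_sd=0.0,
        asym_sd=0.0,
        meas_noise_sd=0.0,
        frame_interval=0.0,
        founder_sd=0.0,
        founder_mean=7.0,
        n_founders=4,
        growth_rate=0.05,
    )
    base.update(kw)
    return SimParams(**base)


class TestLineages:
    def test_noise_free_sizer_steady_state(self):
        """Deterministic sizer from BL=7: every cycle is 7 -> 14 in 140 min."""
        df = simulate_lineages(_noise_free("sizer", target_length=14.0))
        assert np.allclose(df["birth_length_um"], 7.0)
        assert np.allclose(df["division_length_um"], 14.0)
        assert np.allclose(df["extension_um"], 7.0)
        assert np.allclose(df["cycle_time_min"], 140.0)

    def test_noise_free_adder_fixed_point(self):
        """Adder with Delta=7 from BL=7 sits at its fixed point D=14."""
        df = simulate_lineages(_noise_free("adder", increment=7.0))
        assert np.allclose(df["division_length_um"], 14.0)
        assert np.allclose(df["extension_um"], 7.0)

    def test_sizer_fixed_point_immediate(self):
        """A noise-free sizer corrects any founder size in one generation."""
        df = simulate_lineages(_noise_free("sizer", founder_mean=10.0))
        assert np.allclose(df["division_length_um"], 14.0, atol=1e-9)

    def test_adder_converges_geometrically(self):
        """A noise-free adder halves the deviation from D=2*Delta each
        generation (convergence is geometric, not immediate)."""
        df = simulate_lineages(_noise_free("adder", founder_mean=4.0))
        dev = (
            df.groupby("generation")["division_length_um"]
            .first()
            .sub(14.0)
            .abs()
            .to_numpy()
        )
        assert np.allclose(dev, [3.0, 1.5, 0.75], atol=1e-9)

    def test_extension_conservation_exact(self, sizer_records):
        ext = sizer_records["division_length_um"] - sizer_records["birth_length_um"]
        assert np.array_equal(ext.to_numpy(), sizer_records["extension_um"].to_numpy())

    def test_division_length_cv_matches_trigger_noise(self):
        """Sizer division lengths are L_T + eps, so CV(D) = sigma_T/L_T.

        Monte-Carlo CV should land within 3 SE of the analytic 8.0%.
        """
        params = sizer_preset(n_founders=200, asym_sd=0.0, founder_sd=0.0, seed=7)
        df = simulate_lineages(params)
        n = len(df)
        assert n >= 1000
        cv = 100 * df["division_length_um"].std(ddof=1) / df["division_length_um"].mean()
        expected = 100 * params.trigger_noise_sd / params.target_length
        se = expected / math.sqrt(2 * (n - 1))
        assert abs(cv - expected) < 3 * se

    def test_same_seed_bit_identical(self):
        p = sizer_preset(n_founders=20, seed=42)
        a = simulate_lineages(p)
        b = simulate_lineages(sizer_preset(n_founders=20, seed=42))
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_same_distribution(self):
        a = simulate_lineages(sizer_preset(n_founders=80, seed=1))
        b = simulate_lineages(sizer_preset(n_founders=80, seed=2))
        ks = stats.ks_2samp(
            a["division_length_um"][:500], b["division_length_um"][:500]
        )
        assert ks.pvalue > 0.01

    def test_generation_capped_and_positive_lengths(self, sizer_records):
        assert sizer_records["generation"].between(1, 3).all()
        assert (sizer_records["birth_length_um"] > 0).all()
        assert (sizer_records["division_length_um"] > 0).all()
        assert (sizer_records["extension_um"] > 0).all()  # sigma_m=0, dt=0

    def test_frame_sampling_quantization_bound(self):
        """Recorded cycle time >= true steady-state time minus 2 frames."""
        dt = 10.0
        df = simulate_lineages(
            _noise_free("sizer", frame_interval=dt, n_founders=6, founder_mean=6.3)
        )
        true_time = (14.0 - 7.0) / 0.05  # steady-state cycle, min
        later = df[df["generation"] >= 2]
        assert (later["cycle_time_min"] >= true_time - 2 * dt).all()
        assert (later["cycle_time_min"] % dt == 0).all()

    def test_timer_exponential_growth(self):
        """Noise-free timer under exponential growth doubles cells in rT=ln2."""
        t_dur = 100.0
        p = _noise_free(
            "timer",
            duration=t_dur,
            growth_rate=math.log(2) / t_dur,
            growth_model="exponential",
        )
        df = simulate_lineages(p)
        assert np.allclose(
            df["division_length_um"], 2 * df["birth_length_um"], rtol=1e-9
        )

    def test_trigger_satisfied_at_birth_is_flagged_not_dropped(self):
        """A founder born above the sizer target divides after the grace
        interval and is flagged."""
        df = simulate_lineages(
            _noise_free("sizer", founder_mean=20.0, target_length=14.0, n_founders=2)
        )
        founders = df[df["generation"] == 1]
        assert founders["flagged"].all()
        assert (founders["extension_um"] > 0).all()

    @pytest.mark.parametrize(
        "bad",
        [
            {"target_length": -1.0},
            {"control_model": "magic"},
            {"growth_rate": 0.0},
            {"trigger_noise_sd": -0.5},
            {"n_founders": 0},
        ],
    )
    def test_invalid_params_raise(self, bad):
        model = bad.pop("control_model", "sizer")
        with pytest.raises(ValueError):
            simulate_lineages(_noise_free(model, **bad))

    def test_daughter_fraction_clipping(self):
        """Huge asymmetry SD still never yields daughters outside 0.3-0.7 of D."""
        p = sizer_preset(asym_sd=5.0, n_founders=40, seed=3, max_generations=2)
        df = simulate_lineages(p)
        gen2 = df[df["generation"] == 2]
        # noise-free lengths: daughter BL must lie in [0.3, 0.7] x mother D
        mothers = df[df["generation"] == 1].set_index("lineage_id")
        for _, row in gen2.iterrows():
            d = mothers.loc[row["lineage_id"], "division_length_um"]
            assert 0.3 * d - 1e-9 <= row["birth_length_um"] <= 0.7 * d + 1e-9


class TestMultinucleate:
    def test_synchronous_doubling(self):
        df = simulate_multinucleate(
            MultinucSimParams(mode="synchronous", n_cycles=3, n_cells=50)
        )
        assert (df.loc[df["cycle"] == 3, "nuclei_count"] == 8).all()

    def test_independent_q1_equals_synchronous(self):
        df = simulate_multinucleate(
            MultinucSimParams(
                mode="independent", division_prob=1.0, n_cycles=3, n_cells=50
            )
        )
        assert (df.loc[df["cycle"] == 3, "nuclei_count"] == 8).all()

    def test_independent_matches_branching_enumeration(self):
        """q=0.5, 2 cycles: compare against brute-force enumeration of every
        per-nucleus division outcome."""
        # brute force: cycle 1 nucleus divides (prob q) or not; cycle 2 each
        # of the resulting nuclei divides independently.
        q = 0.5
        pmf: dict[int, float] = {}
        for first in (0, 1):  # did the founder nucleus divide in cycle 1
            n1 = 1 + first
            p1 = q if first else 1 - q
            for divs in range(n1 + 1):
                p2 = math.comb(n1, divs) * q**divs * (1 - q) ** (n1 - divs)
                pmf[n1 + divs] = pmf.get(n1 + divs, 0.0) + p1 * p2
        df = simulate_multinucleate(
            MultinucSimParams(
                mode="independent", division_prob=q, n_cycles=2, n_cells=20000, seed=9
            )
        )
        final = df.loc[df["cycle"] == 2, "nuclei_count"]
        for count, p in pmf.items():
            frac = (final == count).mean()
            se = math.sqrt(p * (1 - p) / len(final))
            assert abs(frac - p) < 3 * se, (count, frac, p)


class TestIntensities:
    def test_shape_contract(self):
        df = simulate_nuclear_intensities(
            IntensitySimParams(n_cells=5, nuclei_per_cell=4)
        )
        assert len(df) == 20
        assert df.groupby("cell_id").size().eq(4).all()

    def test_zero_within_cell_noise_gives_constant_cells(self):
        df = simulate_nuclear_intensities(
            IntensitySimParams(n_cells=10, within_cell_sd=0.0, seed=1)
        )
        spread = df.groupby("cell_id")["intensity_au"].agg(lambda v: v.max() - v.min())
        assert (spread == 0).all()

    def test_within_cell_cv_matches_noise_level(self):
        """between_cell_sd=0: per-cell CVs concentrate near
        100*within_cell_sd/mean."""
        p = IntensitySimParams(
            n_cells=400,
            nuclei_per_cell=4,
            between_cell_sd=0.0,
            within_cell_sd=5.0,
            mean_intensity=100.0,
            seed=2,
        )
        df = simulate_nuclear_intensities(p)
        cvs = df.groupby("cell_id")["intensity_au"].agg(
            lambda v: 100 * v.std(ddof=1) / v.mean()
        )
        # per-cell CV at n=4 is noisy; the population mean is close to the
        # analytic target (small-sample bias of SD ~ c4(4)=0.921)
        assert abs(cvs.mean() - 5.0 * 0.9213) < 0.3

    def test_intensities_positive(self):
        df = simulate_nuclear_intensities(
            IntensitySimParams(
                n_cells=100, within_cell_sd=200.0, between_cell_sd=200.0, seed=3
            )
        )
        assert (df["intensity_au"] > 0).all()
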