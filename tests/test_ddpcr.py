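"""Unit tests for the Bayesian ddPCR quantification model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonetrace.config import RunConfig
from clonetrace.ddpcr import (
    PG_PER_CELL,
    DropletAssay,
    GeneticContext,
    cells_from_dna_mass,
    lambdas_from_state,
    null_control_assay,
    positivity,
    posterior_mcf,
    quadrant_probs,
    tracing_eligible,
    vaf_to_mcf,
)
from clonetrace.simulate import simulate_ddpcr


class TestQuadrantProbs:
    def test_empty_droplets(self):
        assert np.allclose(quadrant_probs(0.0, 0.0), [1, 0, 0, 0])

    def test_closed_form_example(self):
        # e^{-0.6}, (1-e^{-0.1})e^{-0.5}, e^{-0.1}(1-e^{-0.5}), product
        got = quadrant_probs(0.1, 0.5)
        assert np.allclose(got, [0.5488, 0.0577, 0.3561, 0.0375], atol=5e-4)

    def test_saturation_limit(self):
        assert np.allclose(quadrant_probs(50.0, 50.0), [0, 0, 0, 1], atol=1e-12)

    @given(
        lm=st.floats(0, 20, allow_nan=False),
        lw=st.floats(0, 20, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_sums_to_one(self, lm, lw):
        p = quadrant_probs(lm, lw)
        assert abs(p.sum() - 1.0) < 1e-12
        assert (p >= 0).all()

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            quadrant_probs(-0.1, 0.5)
        with pytest.raises(ValueError):
            quadrant_probs(np.nan, 0.5)


class TestLambdas:
    def test_zero_theta(self):
        ctx = GeneticContext(ploidy=2)
        lm, lw = lambdas_from_state(0.0, 0.5, 1000, 14000, ctx)
        assert lm == 0
        assert lw == pytest.approx(1000 * 2 * 0.5 / 14000)

    def test_hemizygous_fully_mutant(self):
        ctx = GeneticContext(ploidy=1)
        lm, lw = lambdas_from_state(1.0, 0.5, 1000, 14000, ctx)
        assert lw == 0

    def test_bulk_dna_example(self):
        ctx = GeneticContext(ploidy=2)
        lm, lw = lambdas_from_state(0.05, 0.5, 9090, 14000, ctx)
        assert lm == pytest.approx(0.0162, abs=2e-4)
        assert lw == pytest.approx(0.633, abs=1e-3)


class TestGeneticContext:
    @pytest.mark.parametrize(
        "chrom,sex,ploidy",
        [
            ("autosome", "F", 2),
            ("autosome", "M", 2),
            ("X", "F", 2),
            ("X", "M", 1),
            ("Y", "M", 1),
        ],
    )
    def test_ploidy_resolution(self, chrom, sex, ploidy):
        assert GeneticContext.from_sample(chrom, sex).ploidy == ploidy

    def test_female_y_rejected(self):
        with pytest.raises(ValueError):
            GeneticContext.from_sample("Y", "F")


class TestPosterior:
    def test_no_mutant_evidence(self):
        a = DropletAssay(nn=8000, mut_only=0, wt_only=6000, double_pos=0, n_cells=2000)
        post = posterior_mcf(a)
        assert post.mean < 0.005
        assert post.ci_low < 1e-3  # lower bound pinned at the bottom of the grid
        assert abs(post.mass.sum() - 1) < 1e-9
        assert post.ci_low <= post.mean <= post.ci_high

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            DropletAssay(nn=0, mut_only=0, wt_only=0, double_pos=0, n_cells=100)

    def test_doubling_counts_narrows_interval(self):
        a = DropletAssay(nn=7000, mut_only=120, wt_only=5000, double_pos=80, n_cells=2000)
        b = DropletAssay(nn=14000, mut_only=240, wt_only=10000, double_pos=160, n_cells=4000)
        pa, pb = posterior_mcf(a), posterior_mcf(b)
        assert (pb.ci_high - pb.ci_low) < (pa.ci_high - pa.ci_low)

    def test_mean_monotone_in_mut_only(self):
        means = [
            posterior_mcf(
                DropletAssay(nn=9000, mut_only=m, wt_only=5000, double_pos=10, n_cells=2000)
            ).mean
            for m in (0, 5, 20, 80, 200)
        ]
        assert all(b >= a for a, b in zip(means, means[1:]))

    def test_point_recovery(self):
        a = simulate_ddpcr(0.10, 2000, 14000, 0.5, seed=1)
        post = posterior_mcf(a)
        assert post.mean == pytest.approx(0.10, abs=0.02)
        assert post.ci_low <= 0.10 <= post.ci_high


class TestPositivity:
    def test_identical_posteriors_negative(self):
        a = simulate_ddpcr(0.02, 2000, 14000, 0.5, seed=3)
        p = posterior_mcf(a)
        call = positivity(p, p)
        assert call.overlap == pytest.approx(1.0)
        assert call.label == "negative"

    def test_disjoint_supports_positive(self):
        hi = posterior_mcf(simulate_ddpcr(0.4, 2000, 14000, 0.5, seed=4))
        lo = posterior_mcf(simulate_ddpcr(0.0, 2000, 14000, 0.5, seed=5))
        call = positivity(hi, lo)
        assert call.overlap < 1e-6
        assert call.label == "positive"

    def test_threshold_bands(self):
        # synthetic posteriors with a controlled overlap
        grid = np.linspace(0, 1, 401)
        from clonetrace.ddpcr import PosteriorMCF

        def boxcar(lo, hi):
            mass = ((grid >= lo) & (grid < hi)).astype(float)
            mass /= mass.sum()
            mean = float((grid * mass).sum())
            return PosteriorMCF(grid=grid, mass=mass, mean=mean, ci_low=lo, ci_high=hi)

        a = boxcar(0.0, 0.25)
        b = boxcar(0.22, 0.47)  # 12% shared support
        call = positivity(a, b)
        assert 0.05 <= call.overlap < 0.20
        assert call.label == "likely_positive"

    def test_symmetry(self):
        a = posterior_mcf(simulate_ddpcr(0.05, 2000, 14000, 0.5, seed=6))
        b = posterior_mcf(simulate_ddpcr(0.02, 2000, 14000, 0.5, seed=7))
        assert positivity(a, b).overlap == pytest.approx(positivity(b, a).overlap)

    def test_detection_floor(self):
        """Wells at MCF 0.12% are called positive in a majority of replicates.

        Sorted-cell DNA is whole-genome amplified to the 60 ng ddPCR input
        (~9,090 genome equivalents), so template per sorted cell exceeds
        one; with 2,000 cells the effective efficiency is 9090/2000.
        """
        eff = 9090 / 2000
        hits = 0
        n_rep = 20
        for s in range(n_rep):
            a = simulate_ddpcr(0.0012, 2000, 14000, eff, seed=s)
            post = posterior_mcf(a)
            ctrl = posterior_mcf(null_control_assay(a))
            hits += positivity(post, ctrl).label in ("positive", "likely_positive")
        assert hits > n_rep / 2


class TestConversions:
    @pytest.mark.parametrize(
        "vaf,ploidy,expect",
        [(0.25, 2, 0.50), (0.25, 1, 0.25), (0.0, 2, 0.0), (0.8, 2, 1.0)],
    )
    def test_vaf_to_mcf(self, vaf, ploidy, expect):
        assert vaf_to_mcf(vaf, GeneticContext(ploidy=ploidy)) == expect

    def test_bulk_cell_number_convention(self):
        assert PG_PER_CELL == 6.6
        assert cells_from_dna_mass(60) == 9090
        assert cells_from_dna_mass(0.0066) == 1

    def test_mass_must_be_positive(self):
        with pytest.raises(ValueError):
            cells_from_dna_mass(0)

    @pytest.mark.parametrize(
        "mcf,driver,expect",
        [
            (0.025, True, True),
            (0.015, True, False),
            (0.012, False, True),
            (0.008, False, False),
            (0.02, True, True),  # boundary is inclusive
        ],
    )
    def test_tracing_eligibility(self, mcf, driver, expect):
        assert tracing_eligible(mcf, driver) is expect


def test_config_validation():
    with pytest.raises(ValueError):
        RunConfig(positivity_thresholds=(0.4, 0.2, 0.05))
    with pytest.raises(ValueError):
        RunConfig(n_permutations=0)
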