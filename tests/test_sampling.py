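import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import ndtr

from cellml_uq.errors import (DensityNormalizationError, InversionError,
                              NumericError)
from cellml_uq.fixtures import normal_pdf_lambda
from cellml_uq.mathml import Constant, Environment, Lambda, VariableRef
from cellml_uq.model import (DensitySpec, RealisationsSpec,
                             UncertaintyAssertion)
from cellml_uq.sampling import (NumericCdf, ParameterSampler, RngStream,
                                cdf_value, draw_parameter_set, invert_cdf,
                                sample_density, sample_realisations)

from conftest import exponential_pdf_lambda, uniform_pdf_lambda


class TestRngStream:
    def test_open_interval(self):
        rng = RngStream(0)
        draws = [rng.next_uniform() for _ in range(1000)]
        assert all(0.0 < u < 1.0 for u in draws)

    def test_seed_determinism(self):
        a = [RngStream(123).next_uniform() for _ in range(1)]
        seq1 = [RngStream(5).next_uniform() for _ in range(10)]
        rng = RngStream(5)
        seq2 = [rng.next_uniform() for _ in range(10)]
        assert seq1[0] != seq2[1]
        assert [RngStream(5).next_uniform() for _ in range(1)][0] == seq2[0]


class TestCdfValue:
    def test_standard_normal_at_zero(self, std_normal_cdf):
        assert cdf_value(std_normal_cdf, 0.0) == pytest.approx(0.5, abs=1e-7)

    def test_normalization_at_infinity(self, std_normal_cdf):
        assert cdf_value(std_normal_cdf, math.inf) == pytest.approx(1.0,
                                                                    abs=1e-6)

    def test_shifted_normal_phi_one(self):
        # oracle: Phi(1) via the error function
        cdf = NumericCdf(DensitySpec(normal_pdf_lambda(10.0, 1.0)))
        assert cdf_value(cdf, 11.0) == pytest.approx(float(ndtr(1.0)),
                                                     abs=1e-7)

    def test_invalid_density_rejected(self):
        NumericCdf(DensitySpec(normal_pdf_lambda(0.0, 1.0)))  # valid one is fine
        not_a_density = DensitySpec(uniform_pdf_lambda(0.0, 2.0))
        # uniform(0,2) written with height 1/2 integrates to 1; break it
        from cellml_uq.mathml import Apply
        bad = DensitySpec(Lambda(("x",), Apply(
            "times", (Constant(2.0, "dimensionless"),
                      uniform_pdf_lambda(0.0, 2.0).body))))
        with pytest.raises(DensityNormalizationError):
            NumericCdf(bad)

    def test_monotone_on_grid(self, std_normal_cdf):
        grid = np.linspace(-6.0, 6.0, 61)
        values = [cdf_value(std_normal_cdf, float(y)) for y in grid]
        assert all(b >= a - 1e-9 for a, b in zip(values, values[1:]))

    def test_env_constants_visible_in_density(self):
        mean = VariableRef("c", "mu")
        from cellml_uq.mathml import Apply
        body = Apply("times", (
            Apply("divide", (Constant(1.0, "dimensionless"), Apply(
                "root", (Constant(2.0, "dimensionless"),
                         Apply("times", (Constant(2.0, "dimensionless"),
                                         Constant(math.pi, "dimensionless"))))))),
            Apply("exp", (Apply("divide", (
                Apply("minus", (Apply("power", (
                    Apply("minus", (VariableRef(None, "x"), mean)),
                    Constant(2.0, "dimensionless"))),)),
                Constant(2.0, "dimensionless"))),))))
        cdf = NumericCdf(DensitySpec(Lambda(("x",), body)),
                         Environment({("c", "mu"): 3.0}))
        assert cdf.cdf_value(3.0) == pytest.approx(0.5, abs=1e-7)


class TestInvertCdf:
    def test_standard_normal_median(self, std_normal_cdf):
        assert invert_cdf(std_normal_cdf, 0.5) == pytest.approx(0.0, abs=1e-5)

    def test_uniform_identity_quantile(self):
        cdf = NumericCdf(DensitySpec(uniform_pdf_lambda(0.0, 1.0)))
        assert invert_cdf(cdf, 0.25) == pytest.approx(0.25, abs=1e-5)

    def test_normal_upper_tail(self, std_normal_cdf):
        # oracle: standard normal quantile
        expected = float(stats.norm.ppf(0.975))
        assert invert_cdf(std_normal_cdf, 0.975) == pytest.approx(
            expected, abs=1e-5)

    def test_z_outside_unit_interval(self, std_normal_cdf):
        with pytest.raises(InversionError):
            invert_cdf(std_normal_cdf, 1.5)

    def test_inverse_property_on_grid(self, std_normal_cdf):
        for x in np.linspace(-2.5, 2.5, 11):
            z = cdf_value(std_normal_cdf, float(x))
            assert invert_cdf(std_normal_cdf, z) == pytest.approx(
                float(x), abs=1e-5)

    def test_smallest_minimiser_on_zero_density_gap(self):
        # density with support [0,1] U [2,3]; F is flat on (1,2), so the
        # quantile at F=0.5 must land at the plateau's left edge (1.0)
        from cellml_uq.mathml import Apply
        x = VariableRef(None, "x")

        def between(lo, hi):
            return Apply("and", (
                Apply("geq", (x, Constant(lo, "dimensionless"))),
                Apply("leq", (x, Constant(hi, "dimensionless")))))
        from cellml_uq.mathml import Piecewise
        body = Piecewise(
            ((between(0.0, 1.0), Constant(0.5, "dimensionless")),
             (between(2.0, 3.0), Constant(0.5, "dimensionless"))),
            Constant(0.0, "dimensionless"))
        cdf = NumericCdf(DensitySpec(Lambda(("x",), body)))
        q = cdf.invert(0.5)
        assert q == pytest.approx(1.0, abs=1e-3)
        assert q <= 1.0 + 1e-3


class TestSampleDensity:
    def test_ks_against_normal_oracle(self, std_normal_cdf):
        rng = RngStream(2024)
        draws = [std_normal_cdf.sample(rng) for _ in range(1000)]
        stat, pvalue = stats.kstest(draws, "norm")
        assert pvalue > 0.01

    def test_mean_recovery_shifted_normal(self):
        cdf = NumericCdf(DensitySpec(normal_pdf_lambda(10.0, 1.0)))
        rng = RngStream(7)
        draws = [cdf.sample(rng) for _ in range(1000)]
        assert np.mean(draws) == pytest.approx(10.0, abs=3.0 / math.sqrt(1000))

    def test_same_seed_same_draws(self):
        spec = DensitySpec(normal_pdf_lambda(0.0, 1.0))
        cdf = NumericCdf(spec)
        a = [sample_density(spec, None, RngStream(11), cdf=cdf)
             for _ in range(3)]
        b = [sample_density(spec, None, RngStream(11), cdf=cdf)
             for _ in range(3)]
        assert a == b

    def test_consumes_exactly_one_deviate(self, std_normal_cdf):
        rng1, rng2 = RngStream(3), RngStream(3)
        std_normal_cdf.sample(rng1)
        rng2.next_uniform()
        assert rng1.next_uniform() == rng2.next_uniform()


@pytest.mark.parametrize("pdf,cdf_oracle", [
    (normal_pdf_lambda(0.0, 1.0), stats.norm.cdf),
    (uniform_pdf_lambda(0.0, 1.0), stats.uniform.cdf),
    (exponential_pdf_lambda(1.0), stats.expon.cdf),
])
def test_distributional_recovery_ks(pdf, cdf_oracle):
    cdf = NumericCdf(DensitySpec(pdf))
    rng = RngStream(99)
    draws = [cdf.sample(rng) for _ in range(2000)]
    stat, pvalue = stats.kstest(draws, cdf_oracle)
    assert pvalue > 0.01


class TestSampleRealisations:
    def test_single_element(self):
        spec = RealisationsSpec((7.0,))
        rng = RngStream(1)
        assert all(sample_realisations(spec, rng) == 7.0 for _ in range(5))

    def test_index_frequencies(self):
        spec = RealisationsSpec((0.0, 1.0))
        rng = RngStream(13)
        draws = [sample_realisations(spec, rng) for _ in range(10_000)]
        frac_one = np.mean(draws)
        assert 0.47 <= frac_one <= 0.53  # binomial 99% interval at n=10000

    def test_joint_tuples_never_decouple(self):
        spec = RealisationsSpec(((1.0, 10.0), (2.0, 20.0)))
        rng = RngStream(17)
        for _ in range(200):
            assert sample_realisations(spec, rng) in ((1.0, 10.0),
                                                      (2.0, 20.0))


class TestDrawParameterSet:
    def _assertions(self):
        return [
            UncertaintyAssertion(
                (VariableRef("c", "a"),),
                DensitySpec(normal_pdf_lambda(0.0, 1.0))),
            UncertaintyAssertion(
                (VariableRef("c", "b"), VariableRef("c", "d")),
                RealisationsSpec(((1.0, 10.0), (2.0, 20.0)))),
        ]

    def test_values_and_provenance(self):
        draw = draw_parameter_set(self._assertions(), None, RngStream(5))
        assert set(draw.values) == {("c", "a"), ("c", "b"), ("c", "d")}
        assert (draw.values[("c", "b")], draw.values[("c", "d")]) in \
            ((1.0, 10.0), (2.0, 20.0))
        assert [p["kind"] for p in draw.provenance] == ["density",
                                                        "realisations"]

    def test_empty_assertion_list(self):
        draw = draw_parameter_set([], None, RngStream(5))
        assert draw.values == {}

    def test_fixed_seed_reproducible(self):
        a = draw_parameter_set(self._assertions(), None, RngStream(5))
        b = draw_parameter_set(self._assertions(), None, RngStream(5))
        assert a.values == b.values

    def test_target_overlap_rejected(self):
        dup = [
            UncertaintyAssertion((VariableRef("c", "a"),),
                                 DensitySpec(normal_pdf_lambda(0.0, 1.0))),
            UncertaintyAssertion((VariableRef("c", "a"),),
                                 RealisationsSpec((1.0,))),
        ]
        with pytest.raises(NumericError, match="disjoint"):
            ParameterSampler(dup)

    def test_errors_tagged_with_target_names(self):
        from cellml_uq.mathml import Apply
        bad = [UncertaintyAssertion(
            (VariableRef("c", "badvar"),),
            DensitySpec(Lambda(("p",), Apply(
                "times", (Constant(3.0, "dimensionless"),
                          normal_pdf_lambda(0.0, 1.0).body)))))]
        with pytest.raises(DensityNormalizationError, match="badvar"):
            ParameterSampler(bad)

    def test_fixture_model_draw(self, example_model):
        draw = draw_parameter_set(example_model.uncertainty, None,
                                  RngStream(5))
        assert len(draw.values) == 4
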