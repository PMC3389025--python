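import math

import pytest

from cellml_uq.errors import (AlgebraicLoopError, ModelError,
                              UnderdeterminedModelError)
from cellml_uq.mathml import (Apply, Constant, CsymbolApply, Lambda,
                              VariableRef, VectorLiteral, parse_mathml,
                              parse_xml)
from cellml_uq.model import (DensitySpec, RealisationsSpec,
                             UncertaintyAssertion, classify_variables,
                             extract_uncertainty, load_cellml, write_cellml)

C11 = "http://www.cellml.org/cellml/1.1#"
M = "http://www.w3.org/1998/Math/MathML"
U = "http://www.cellml.org/uncertainty-1#"


def wrap_model(body, name="m"):
    return (f'<model xmlns="{C11}" xmlns:cellml="{C11}" '
            f'xmlns:m="{M}" name="{name}">{body}</model>')


MINIMAL = wrap_model("""
  <component name="main">
    <variable name="t" units="second"/>
    <variable name="x" units="metre" initial_value="1"/>
    <variable name="k" units="dimensionless" initial_value="2"/>
    <m:math>
      <m:apply><m:eq/>
        <m:apply><m:diff/><m:bvar><m:ci>t</m:ci></m:bvar><m:ci>x</m:ci></m:apply>
        <m:apply><m:times/><m:ci>k</m:ci><m:ci>x</m:ci></m:apply>
      </m:apply>
    </m:math>
  </component>
""")


class TestLoad:
    def test_minimal_decay_model(self):
        doc = load_cellml(MINIMAL)
        assert doc.name == "m"
        assert len(doc.assignments) == 1
        assert doc.uncertainty == []

    def test_fixture_model_has_four_assertions(self, fixture_paths):
        doc = load_cellml(fixture_paths["model"])
        assert len(doc.uncertainty) == 4
        kinds = [type(a.spec).__name__ for a in doc.uncertainty]
        assert kinds == ["DensitySpec"] * 3 + ["RealisationsSpec"]

    def test_import_rejected(self):
        with pytest.raises(ModelError, match="import"):
            load_cellml(wrap_model('<import xlink:href="other.xml" '
                                   'xmlns:xlink="http://www.w3.org/1999/xlink"/>'))

    def test_bogus_uncertainty_suffix(self):
        doc = wrap_model(f"""
          <component name="main">
            <variable name="v" units="metre"/>
            <m:math>
              <m:apply><m:csymbol definitionURL="{U}bogus"/>
                <m:ci>v</m:ci></m:apply>
            </m:math>
          </component>""")
        with pytest.raises(ModelError, match="bogus"):
            load_cellml(doc)

    def test_double_assignment_rejected(self):
        doc = wrap_model("""
          <component name="main">
            <variable name="a" units="metre"/>
            <m:math>
              <m:apply><m:eq/><m:ci>a</m:ci>
                <m:cn cellml:units="metre">1</m:cn></m:apply>
              <m:apply><m:eq/><m:ci>a</m:ci>
                <m:cn cellml:units="metre">2</m:cn></m:apply>
            </m:math>
          </component>""")
        with pytest.raises(ModelError, match="two assignments"):
            load_cellml(doc)

    def test_unresolved_connection(self):
        doc = wrap_model("""
          <component name="a"><variable name="v" units="metre"/></component>
          <connection>
            <map_components component_1="a" component_2="b"/>
            <map_variables variable_1="v" variable_2="w"/>
          </connection>""")
        with pytest.raises(ModelError, match="undeclared"):
            load_cellml(doc)

    def test_connection_collapses_variables(self):
        doc = load_cellml(wrap_model("""
          <component name="a">
            <variable name="v" units="metre"/>
            <m:math>
              <m:apply><m:eq/><m:ci>v</m:ci>
                <m:cn cellml:units="metre">3</m:cn></m:apply>
            </m:math>
          </component>
          <component name="b">
            <variable name="w" units="metre"/>
            <variable name="u" units="metre"/>
            <m:math>
              <m:apply><m:eq/><m:ci>u</m:ci><m:ci>w</m:ci></m:apply>
            </m:math>
          </component>
          <connection>
            <map_components component_1="a" component_2="b"/>
            <map_variables variable_1="v" variable_2="w"/>
          </connection>"""))
        assert doc.canonical(("b", "w")) == doc.canonical(("a", "v"))
        parts = classify_variables(doc)
        assert doc.canonical(("a", "v")) in parts["constants"]
        assert ("b", "u") in parts["algebraic"]


class TestExtractUncertainty:
    def _density_expr(self, var="v"):
        pdf = Lambda(("p",), Constant(1.0, "dimensionless"))
        return CsymbolApply(U + "uncertainParameterWithDistribution", (
            VariableRef("c", var),
            CsymbolApply(U + "distributionFromDensity", (pdf,))))

    def test_density_form(self):
        out = extract_uncertainty([self._density_expr()])
        assert len(out) == 1
        assert out[0].targets == (VariableRef("c", "v"),)
        assert isinstance(out[0].spec, DensitySpec)

    def test_realisations_joint_pairs(self):
        pairs = VectorLiteral(tuple(
            VectorLiteral((Constant(i, "m"), Constant(10.0 * i, "m")))
            for i in (1.0, 2.0, 3.0)))
        expr = CsymbolApply(U + "uncertainParameterWithDistribution", (
            VectorLiteral((VariableRef("c", "a"), VariableRef("c", "b"))),
            CsymbolApply(U + "distributionFromRealisations", (pairs,))))
        out = extract_uncertainty([expr])
        assert out[0].targets == (VariableRef("c", "a"),
                                  VariableRef("c", "b"))
        assert out[0].spec.realisations == ((1.0, 10.0), (2.0, 20.0),
                                            (3.0, 30.0))

    def test_mixed_scalars_and_pairs_rejected(self):
        mixed = VectorLiteral((
            Constant(1.0, "m"),
            VectorLiteral((Constant(2.0, "m"), Constant(3.0, "m")))))
        expr = CsymbolApply(U + "uncertainParameterWithDistribution", (
            VariableRef("c", "a"),
            CsymbolApply(U + "distributionFromRealisations", (mixed,))))
        with pytest.raises(ModelError, match="mixes"):
            extract_uncertainty([expr])

    def test_density_operand_count(self):
        expr = CsymbolApply(U + "uncertainParameterWithDistribution", (
            VariableRef("c", "v"),
            CsymbolApply(U + "distributionFromDensity", (
                Lambda(("p",), Constant(1.0, "dimensionless")),
                Constant(1.0, "dimensionless")))))
        with pytest.raises(ModelError, match="single argument"):
            extract_uncertainty([expr])

    def test_density_on_vector_target_rejected(self):
        pdf = Lambda(("p",), Constant(1.0, "dimensionless"))
        expr = CsymbolApply(U + "uncertainParameterWithDistribution", (
            VectorLiteral((VariableRef("c", "a"), VariableRef("c", "b"))),
            CsymbolApply(U + "distributionFromDensity", (pdf,))))
        with pytest.raises(ModelError, match="vector"):
            extract_uncertainty([expr])

    def test_two_bound_variables_rejected(self):
        pdf = Lambda(("p", "q"), Constant(1.0, "dimensionless"))
        expr = CsymbolApply(U + "uncertainParameterWithDistribution", (
            VariableRef("c", "v"),
            CsymbolApply(U + "distributionFromDensity", (pdf,))))
        with pytest.raises(ModelError, match="bound variable"):
            extract_uncertainty([expr])

    def test_order_preserved_and_idempotent(self):
        exprs = [self._density_expr("v1"), self._density_expr("v2")]
        out1 = extract_uncertainty(exprs)
        out2 = extract_uncertainty(exprs)
        assert [a.targets[0].variable for a in out1] == ["v1", "v2"]
        assert out1 == out2


class TestClassify:
    def test_fixture_partition(self, example_model):
        parts = classify_variables(example_model)
        names = {k: {v for _, v in keys} for k, keys in parts.items()}
        assert names["states"] == {"x", "y", "vx", "vy"}
        assert names["uncertain"] == {"x_init", "y_init", "vx_init",
                                      "vy_init"}
        assert names["bound"] == {"time"}
        assert names["constants"] == {"ax", "ay"}
        assert names["algebraic"] == set()

    def test_partition_exhaustive_and_disjoint(self, example_model):
        parts = classify_variables(example_model)
        union = set()
        total = 0
        for keys in parts.values():
            union |= keys
            total += len(keys)
        assert union == example_model.all_variable_keys()
        assert total == len(union)

    def test_algebraic_loop(self):
        doc = load_cellml(wrap_model("""
          <component name="main">
            <variable name="x" units="metre"/>
            <variable name="y" units="metre"/>
            <m:math>
              <m:apply><m:eq/><m:ci>x</m:ci><m:ci>y</m:ci></m:apply>
              <m:apply><m:eq/><m:ci>y</m:ci><m:ci>x</m:ci></m:apply>
            </m:math>
          </component>"""))
        with pytest.raises(AlgebraicLoopError):
            classify_variables(doc)

    def test_underdetermined(self):
        doc = load_cellml(wrap_model("""
          <component name="main">
            <variable name="ghost" units="metre"/>
          </component>"""))
        with pytest.raises(UnderdeterminedModelError, match="ghost"):
            classify_variables(doc)

    def test_empty_model(self):
        doc = load_cellml(wrap_model(""))
        parts = classify_variables(doc)
        assert all(len(v) == 0 for v in parts.values())


class TestRoundTrip:
    def test_fixture_round_trip(self, example_model, tmp_path):
        path = tmp_path / "model.cellml"
        write_cellml(example_model, path)
        again = load_cellml(path)
        assert again.name == example_model.name
        assert len(again.uncertainty) == len(example_model.uncertainty)
        for a, b in zip(again.uncertainty, example_model.uncertainty):
            assert [t.variable for t in a.targets] == \
                [t.variable for t in b.targets]
            assert type(a.spec) is type(b.spec)
        assert again.assignments == example_model.assignments
        assert again.units_definitions == example_model.units_definitions
        # write -> load -> write is a fixed point
        path2 = tmp_path / "model2.cellml"
        write_cellml(again, path2)
        assert path.read_text() == path2.read_text()

    def test_round_trip_preserves_realisation_order(self, example_model,
                                                    tmp_path):
        path = tmp_path / "model.cellml"
        write_cellml(example_model, path)
        again = load_cellml(path)
        assert again.uncertainty[3].spec.realisations == \
            example_model.uncertainty[3].spec.realisations

    def test_round_trip_preserves_density_values(self, example_model,
                                                 tmp_path):
        from cellml_uq.mathml import Environment, apply_lambda
        path = tmp_path / "model.cellml"
        write_cellml(example_model, path)
        again = load_cellml(path)
        for i in range(3):
            f0 = example_model.uncertainty[i].spec.pdf
            f1 = again.uncertainty[i].spec.pdf
            for v in (-1.0, 0.0, 2.5, 10.0):
                assert apply_lambda(f1, [v]) == \
                    pytest.approx(apply_lambda(f0, [v]), rel=1e-15)

    def test_write_to_unwritable_path(self, example_model, tmp_path):
        with pytest.raises(OSError):
            write_cellml(example_model,
                         tmp_path / "no_such_dir" / "model.cellml")
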