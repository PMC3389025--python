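"""SED-ML Level 1 subset: load, write, and execute experiment descriptions.

Supported: models, uniform time courses, tasks, single-variable identity
data generators, and reports.  A sampling sensitivity analysis is a
``uniformTimeCourse`` element carrying a ``numberOfSamples`` attribute in
the ``http://www.cellml.org/uncertainty-1#`` namespace (the serialization
of that attribute is a dialect decision; see README).  Running one with
``numberOfSamples = 1`` is bit-identical to the plain time course at the
same seed because both share a single code path and master stream.
"""

from __future__ import annotations

import os
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import NumericError, SedmlError, ValidationError
from .mathml import Environment, parse_xml
from .model import UNCERTAINTY_NS, load_cellml
from .sampling import ParameterSampler, QuadratureSettings, RngStream
from .simulation import (SolverSettings, TimeCourseSpec, compile_plan,
                         run_time_course)

SEDML_NS = "http://sed-ml.org/"
CELLML_LANGUAGE_URN = "urn:sedml:language:cellml"
_N_SAMPLES_ATTR = f"{{{UNCERTAINTY_NS}}}numberOfSamples"

# KiSAO ids we map onto solver methods; anything unknown falls back to RK45.
_KISAO_METHODS = {
    "KISAO:0000032": "RK45",   # explicit Runge-Kutta
    "KISAO:0000019": "LSODA",  # CVODE-like adaptive multistep
    "KISAO:0000088": "LSODA",
}
_DEFAULT_KISAO = "KISAO:0000032"


# ---------------------------------------------------------------------------
# Description types
# ---------------------------------------------------------------------------

@dataclass
class ModelRef:
    id: str
    source: str
    language: str = CELLML_LANGUAGE_URN


@dataclass
class UniformTimeCourse:
    id: str
    time_course: TimeCourseSpec
    algorithm: str = _DEFAULT_KISAO


@dataclass
class SamplingSensitivityAnalysis(UniformTimeCourse):
    number_of_samples: int = 1

    def __post_init__(self):
        if self.number_of_samples < 1:
            raise SedmlError("numberOfSamples must be >= 1, got "
                             f"{self.number_of_samples}")


@dataclass
class TaskRef:
    id: str
    model_reference: str
    simulation_reference: str


@dataclass
class DataSetSpec:
    label: str
    task_reference: str
    variable: str            # model variable name
    component: Optional[str] = None


@dataclass
class ReportSpec:
    id: str
    datasets: list = field(default_factory=list)


@dataclass
class ExperimentDescription:
    models: list = field(default_factory=list)
    simulations: list = field(default_factory=list)
    tasks: list = field(default_factory=list)
    outputs: list = field(default_factory=list)

    def model(self, ref: str) -> ModelRef:
        for m in self.models:
            if m.id == ref:
                return m
        raise SedmlError(f"task references undeclared model {ref!r}")

    def simulation(self, ref: str) -> UniformTimeCourse:
        for s in self.simulations:
            if s.id == ref:
                return s
        raise SedmlError(f"task references undeclared simulation {ref!r}")

    def validate(self):
        for t in self.tasks:
            self.model(t.model_reference)
            self.simulation(t.simulation_reference)


@dataclass
class EnsembleResult:
    task_id: str
    master_seed: int
    samples: list = field(default_factory=list)  # of (ParameterDraw, Trajectory)
    variables: Optional[list] = None             # report subset, None = all

    def __post_init__(self):
        if not self.samples:
            raise ValidationError("empty ensemble")


# ---------------------------------------------------------------------------
# Loading / writing
# ---------------------------------------------------------------------------

_TARGET_RE = re.compile(
    r"variable\[@name=['\"](?P<var>[^'\"]+)['\"]\]\s*$")
_COMPONENT_RE = re.compile(r"component\[@name=['\"](?P<comp>[^'\"]+)['\"]\]")


def _s(tag: str) -> str:
    return f"{{{SEDML_NS}}}{tag}"


def _float_attr(el, name, default=None):
    raw = el.get(name)
    if raw is None:
        if default is None:
            raise SedmlError(f"<{el.tag}> missing attribute {name!r}")
        return default
    try:
        return float(raw)
    except ValueError:
        raise SedmlError(f"attribute {name}={raw!r} is not numeric") from None


def load_sedml(source) -> ExperimentDescription:
    """Load a SED-ML document (path or XML string)."""
    root = parse_xml(source)
    if root.tag != _s("sedML"):
        raise SedmlError(f"not a SED-ML document (root {root.tag!r})")
    exp = ExperimentDescription()

    for m in root.iter(_s("model")):
        mid, src = m.get("id"), m.get("source")
        if mid is None or src is None:
            raise SedmlError("model requires id and source attributes")
        exp.models.append(ModelRef(mid, src,
                                   m.get("language", CELLML_LANGUAGE_URN)))

    for sim in root.iter(_s("uniformTimeCourse")):
        sid = sim.get("id")
        if sid is None:
            raise SedmlError("simulation requires an id attribute")
        tc = TimeCourseSpec(
            initial_time=_float_attr(sim, "initialTime"),
            output_start=_float_attr(sim, "outputStartTime"),
            output_end=_float_attr(sim, "outputEndTime"),
            number_of_points=int(_float_attr(sim, "numberOfPoints")))
        algo_el = sim.find(_s("algorithm"))
        algorithm = (algo_el.get("kisaoID", _DEFAULT_KISAO)
                     if algo_el is not None else _DEFAULT_KISAO)
        raw_n = sim.get(_N_SAMPLES_ATTR)
        if raw_n is not None:
            try:
                n = int(raw_n)
            except ValueError:
                raise SedmlError(
                    f"numberOfSamples={raw_n!r} is not an integer") from None
            exp.simulations.append(SamplingSensitivityAnalysis(
                sid, tc, algorithm, number_of_samples=n))
        else:
            exp.simulations.append(UniformTimeCourse(sid, tc, algorithm))

    # a samplingSensitivityAnalysis element must carry numberOfSamples
    for sim in root.iter(_s("samplingSensitivityAnalysis")):
        raise SedmlError(
            "samplingSensitivityAnalysis simulation is missing its "
            "numberOfSamples attribute"
            if sim.get(_N_SAMPLES_ATTR) is None else
            "samplingSensitivityAnalysis must be written as a "
            "uniformTimeCourse carrying the extension attribute")

    for t in root.iter(_s("task")):
        tid = t.get("id")
        mref, sref = t.get("modelReference"), t.get("simulationReference")
        if not (tid and mref and sref):
            raise SedmlError("task requires id, modelReference and "
                             "simulationReference")
        exp.tasks.append(TaskRef(tid, mref, sref))

    generators = {}
    for dg in root.iter(_s("dataGenerator")):
        var_el = dg.find(f"{_s('listOfVariables')}/{_s('variable')}")
        if var_el is None:
            continue
        target = var_el.get("target", "")
        match = _TARGET_RE.search(target)
        name = match.group("var") if match else var_el.get("name")
        if name is None:
            raise SedmlError(
                f"dataGenerator {dg.get('id')!r}: cannot resolve variable "
                f"from target {target!r}")
        cmatch = _COMPONENT_RE.search(target)
        generators[dg.get("id")] = (
            var_el.get("taskReference"), name,
            cmatch.group("comp") if cmatch else None)

    for rep in root.iter(_s("report")):
        spec = ReportSpec(rep.get("id", "report"))
        for ds in rep.iter(_s("dataSet")):
            ref = ds.get("dataReference")
            if ref not in generators:
                raise SedmlError(
                    f"dataSet references unknown dataGenerator {ref!r}")
            task_ref, var, comp = generators[ref]
            spec.datasets.append(
                DataSetSpec(ds.get("label", var), task_ref, var, comp))
        exp.outputs.append(spec)

    exp.validate()
    return exp


def write_sedml(exp: ExperimentDescription, path) -> None:
    """Serialize an experiment description to a SED-ML Level 1 file."""
    ET.register_namespace("", SEDML_NS)
    ET.register_namespace("uncert", UNCERTAINTY_NS)
    root = ET.Element(_s("sedML"), {"level": "1", "version": "1"})

    sims_el = ET.SubElement(root, _s("listOfSimulations"))
    for sim in exp.simulations:
        tc = sim.time_course
        attrs = {
            "id": sim.id,
            "initialTime": repr(tc.initial_time),
            "outputStartTime": repr(tc.output_start),
            "outputEndTime": repr(tc.output_end),
            "numberOfPoints": str(tc.number_of_points),
        }
        if isinstance(sim, SamplingSensitivityAnalysis):
            attrs[_N_SAMPLES_ATTR] = str(sim.number_of_samples)
        el = ET.SubElement(sims_el, _s("uniformTimeCourse"), attrs)
        ET.SubElement(el, _s("algorithm"), {"kisaoID": sim.algorithm})

    models_el = ET.SubElement(root, _s("listOfModels"))
    for m in exp.models:
        ET.SubElement(models_el, _s("model"),
                      {"id": m.id, "language": m.language, "source": m.source})

    tasks_el = ET.SubElement(root, _s("listOfTasks"))
    for t in exp.tasks:
        ET.SubElement(tasks_el, _s("task"),
                      {"id": t.id, "modelReference": t.model_reference,
                       "simulationReference": t.simulation_reference})

    gens_el = ET.SubElement(root, _s("listOfDataGenerators"))
    outs_el = ET.SubElement(root, _s("listOfOutputs"))
    for rep in exp.outputs:
        rep_el = ET.SubElement(outs_el, _s("report"), {"id": rep.id})
        ds_list = ET.SubElement(rep_el, _s("listOfDataSets"))
        for i, ds in enumerate(rep.datasets):
            gid = f"dg_{rep.id}_{i}"
            dg = ET.SubElement(gens_el, _s("dataGenerator"), {"id": gid})
            lov = ET.SubElement(dg, _s("listOfVariables"))
            comp_part = (f"/cellml:component[@name='{ds.component}']"
                         if ds.component else "/cellml:component")
            ET.SubElement(lov, _s("variable"), {
                "id": f"{gid}_v", "taskReference": ds.task_reference,
                "name": ds.variable,
                "target": f"/cellml:model{comp_part}"
                          f"/cellml:variable[@name='{ds.variable}']"})
            ET.SubElement(ds_list, _s("dataSet"),
                          {"id": f"ds_{rep.id}_{i}", "dataReference": gid,
                           "label": ds.label})

    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="UTF-8", xml_declaration=True)


# ---------------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------------

def run_experiment(exp: ExperimentDescription, master_seed: int,
                   base_dir: str = ".",
                   model_sources: Optional[dict] = None,
                   quadrature: Optional[QuadratureSettings] = None,
                   solver: Optional[SolverSettings] = None) -> dict:
    """Execute every task; returns ``{task id: EnsembleResult}``.

    ``model_sources`` overrides model source locations by model id (the CLI
    uses it to point at an explicit file).  One master stream drives all
    draws of a task, in sample order; a failed sample fails the whole
    ensemble, reporting how many samples completed.
    """
    exp.validate()
    results = {}
    for task in exp.tasks:
        mref = exp.model(task.model_reference)
        source = (model_sources or {}).get(mref.id, mref.source)
        if not os.path.isabs(source) and not os.path.exists(source):
            source = os.path.join(base_dir, source)
        model = load_cellml(source)
        plan = compile_plan(model)
        sampler = ParameterSampler(model.uncertainty, Environment(),
                                   quadrature)
        sim = exp.simulation(task.simulation_reference)
        tc = sim.time_course
        if solver is not None:
            tc = TimeCourseSpec(tc.initial_time, tc.output_start,
                                tc.output_end, tc.number_of_points, solver)
        elif sim.algorithm in _KISAO_METHODS:
            tc = TimeCourseSpec(
                tc.initial_time, tc.output_start, tc.output_end,
                tc.number_of_points,
                SolverSettings(method=_KISAO_METHODS[sim.algorithm]))
        n = (sim.number_of_samples
             if isinstance(sim, SamplingSensitivityAnalysis) else 1)
        rng = RngStream(master_seed)
        samples = []
        for i in range(n):
            try:
                draw = sampler.draw(rng)
                samples.append((draw, run_time_course(plan, draw, tc)))
            except NumericError as exc:
                raise type(exc)(
                    f"task {task.id!r}, sample {i}: {exc} "
                    f"({len(samples)} of {n} samples completed)") from exc
        variables = None
        for rep in exp.outputs:
            requested = [ds.variable for ds in rep.datasets
                         if ds.task_reference == task.id]
            if requested:
                variables = requested
        results[task.id] = EnsembleResult(task.id, master_seed, samples,
                                          variables)
    return results


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_report(result: EnsembleResult, path) -> str:
    """Write the ensemble as long-format CSVs.

    ``<path>`` gets rows (sample_index, time, variable, value); a companion
    ``<stem>_draws.csv`` gets (sample_index, parameter, value).  Returns the
    companion path.  Row order is deterministic: sample, then time, then
    the trajectory's column order.
    """
    if not result.samples:
        raise ValidationError("empty ensemble")
    rows = []
    for idx, (draw, traj) in enumerate(result.samples):
        time_col = traj.columns[0]
        names = [c for c in traj.columns[1:]
                 if result.variables is None or c in result.variables]
        for ti, t in enumerate(traj.times):
            for name in names:
                rows.append((idx, t, name,
                             traj.values[ti, traj.columns.index(name)]))
    pd.DataFrame(rows, columns=["sample_index", "time", "variable", "value"]
                 ).to_csv(path, index=False)

    draw_rows = []
    for idx, (draw, _traj) in enumerate(result.samples):
        for (comp, var), value in sorted(draw.values.items()):
            draw_rows.append((idx, var, value))
    stem, ext = os.path.splitext(str(path))
    draws_path = f"{stem}_draws{ext or '.csv'}"
    pd.DataFrame(draw_rows, columns=["sample_index", "parameter", "value"]
                 ).to_csv(draws_path, index=False)
    return draws_path


def summarize_endpoint(result: EnsembleResult, variable: str,
                       time: float) -> dict:
    """Across-sample summary of one variable at one output grid time."""
    values = []
    for _draw, traj in result.samples:
        hits = np.isclose(traj.times, time, rtol=1e-9, atol=1e-12)
        if not hits.any():
            raise ValidationError(f"time {time!r} is not on the output grid")
        values.append(traj.column(variable)[hits][0])
    values = np.asarray(values)
    qs = np.percentile(values, [2.5, 25, 50, 75, 97.5])
    return {
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
        "quantiles": {"2.5": float(qs[0]), "25": float(qs[1]),
                      "50": float(qs[2]), "75": float(qs[3]),
                      "97.5": float(qs[4])},
        "n": int(values.size),
    }
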