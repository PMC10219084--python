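"""Case- and cohort-level orchestration and evaluation.

``run_case`` executes the full chain for one scenario -- domain build,
healing simulation, bridging classification, mRUST trajectory -- and
``evaluate_cohort`` tallies predicted against true outcomes into a
confusion matrix.

Label convention (documented prominently because the source literature is
inconsistent): *union* (consolidation) is the positive class.
``true_positive`` = predicted union and truly union; ``false_negative`` =
predicted union but truly non-union; ``true_negative`` = predicted
non-union and truly non-union; ``false_positive`` = predicted non-union
but truly union.  Accuracy = (TP + TN) / total.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__ as _version
from .cohort import (CohortParams, ConfigurationError, Scenario)
from .grid import GeometryParams, build_domain
from .healing import RuleSet, simulate_healing
from .mechanics import LoadCoefficients, MaterialTable
from .outcome import (BridgingReport, classify_outcome, score_mrust,
                      MIN_BRIDGED_QUADRANTS, UNION_WINDOW_DAYS)

__all__ = [
    "SimulationConfig",
    "OutcomeReport",
    "ConfusionMatrix",
    "RunManifest",
    "run_case",
    "evaluate_cohort",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All tunables of a pipeline run, loadable from one YAML/JSON file
    with blocks {cohort, geometry, materials, load, rules, classify,
    output}."""

    cohort: CohortParams = field(default_factory=CohortParams)
    voxel_size: float = 2.0  # mm
    segment_length: float = 72.0  # mm
    envelope_axial_margin: float = 10.0  # mm
    materials: MaterialTable = field(default_factory=MaterialTable)
    load: LoadCoefficients = field(default_factory=LoadCoefficients)
    rules: RuleSet = field(default_factory=RuleSet)
    max_days: int = 280
    window: int = UNION_WINDOW_DAYS
    min_quadrants: int = MIN_BRIDGED_QUADRANTS
    bridge_threshold: float = 0.70
    mrust_every: int = 28  # days between mRUST evaluations
    solver: str = "auto"
    rtol: float = 1e-8
    mechanics_interval: int = 1  # days between elastic re-solves
    output_dir: str | None = None

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        text = path.read_text()
        try:
            doc = yaml.safe_load(text) or {}
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"{path}: cannot parse ({exc})") from exc
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "SimulationConfig":
        kwargs = {}
        if "cohort" in doc:
            kwargs["cohort"] = CohortParams(**doc["cohort"])
        geometry = doc.get("geometry", {})
        for key in ("voxel_size", "segment_length", "envelope_axial_margin"):
            if key in geometry:
                kwargs[key] = geometry[key]
        if "materials" in doc:
            kwargs["materials"] = MaterialTable(**doc["materials"])
        if "load" in doc:
            kwargs["load"] = LoadCoefficients(**doc["load"])
        if "rules" in doc:
            kwargs["rules"] = RuleSet(**doc["rules"])
        classify = doc.get("classify", {})
        for key in ("window", "min_quadrants", "bridge_threshold"):
            if key in classify:
                kwargs[key] = classify[key]
        sim = doc.get("simulation", {})
        for key in ("max_days", "mrust_every", "solver", "rtol",
                    "mechanics_interval"):
            if key in sim:
                kwargs[key] = sim[key]
        output = doc.get("output", {})
        if "dir" in output:
            kwargs["output_dir"] = output["dir"]
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigurationError(f"config: {exc}") from exc

    def to_dict(self) -> dict:
        d = asdict(self)
        d["materials"]["moduli"] = dict(d["materials"]["moduli"])
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class OutcomeReport:
    """Per-case outcome: bridging days, union call, mRUST trajectory."""

    case_id: str
    outcome: str  # "union" or "non_union"
    consolidation_day: int | None
    bridge_days: dict  # quadrant name -> day or None
    mrust_trajectory: list  # [(day, total score), ...]
    mrust_final: int
    days_simulated: int
    truth: str | None = None  # ground-truth label if known
    config_hash: str = ""

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "OutcomeReport":
        d = dict(d)
        d["mrust_trajectory"] = [tuple(pair) for pair in d["mrust_trajectory"]]
        return cls(**d)


def run_case(scenario: Scenario, config: SimulationConfig = SimulationConfig(),
             out_dir=None) -> OutcomeReport:
    """Execute the full pipeline for one scenario.

    Builds the patient-scaled domain, runs the healing simulation, derives
    the bridging report and the mRUST trajectory, and (if ``out_dir`` or
    the config's output dir is set) writes a JSON report plus an HDF5 state
    file.  Deterministic: identical scenario + config give identical
    reports.
    """
    patient = scenario.patient
    geom = GeometryParams.from_patient(patient, segment_length=config.segment_length)
    domain = build_domain(geom, scenario.fracture, scenario.nail,
                          voxel_size=config.voxel_size, side=patient.side,
                          envelope_axial_margin=config.envelope_axial_margin)
    traj = simulate_healing(
        domain, patient, scenario.nail, rules=config.rules,
        materials=config.materials, load_coefficients=config.load,
        max_days=config.max_days, snapshot_every=config.mrust_every,
        bridge_threshold=config.bridge_threshold, solver=config.solver,
        rtol=config.rtol, mechanics_interval=config.mechanics_interval)
    bridging: BridgingReport = classify_outcome(
        traj.bridge_days, window=config.window,
        min_quadrants=config.min_quadrants)
    mrust_traj = [(day, score_mrust(st, domain).total)
                  for day, st in traj.snapshots]
    report = OutcomeReport(
        case_id=patient.id,
        outcome=bridging.outcome,
        consolidation_day=bridging.consolidation_day,
        bridge_days=dict(traj.bridge_days),
        mrust_trajectory=mrust_traj,
        mrust_final=score_mrust(traj.final_state, domain).total,
        days_simulated=traj.days_simulated,
        truth="non_union" if scenario.compromised else "union",
        config_hash=config.content_hash(),
    )
    out_dir = out_dir or config.output_dir
    if out_dir is not None:
        from .io import write_report_json, write_trajectory_h5
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report_json(report, out / f"{patient.id}.json")
        write_trajectory_h5(domain, traj, out / f"{patient.id}.h5")
        traj.summary_frame().to_csv(out / f"{patient.id}_daily.csv")
    return report


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 outcome tally; union is the positive class (see module docs)."""

    true_positive: int  # predicted union, truly union
    false_negative: int  # predicted union, truly non-union
    true_negative: int  # predicted non-union, truly non-union
    false_positive: int  # predicted non-union, truly union

    @property
    def total(self) -> int:
        return (self.true_positive + self.false_negative
                + self.true_negative + self.false_positive)

    @property
    def accuracy(self) -> float:
        return (self.true_positive + self.true_negative) / self.total


def evaluate_cohort(reports, truths: dict) -> ConfusionMatrix:
    """Tally predicted vs. true outcomes.

    ``reports`` is a list of :class:`OutcomeReport` (or of ``(case_id,
    outcome)`` pairs); ``truths`` maps case ids to "union"/"non_union".
    Raises on an empty cohort (accuracy undefined) and on id mismatches.
    """
    pairs = []
    for rep in reports:
        if isinstance(rep, OutcomeReport):
            pairs.append((rep.case_id, rep.outcome))
        else:
            cid, out = rep
            pairs.append((cid, out))
    if not pairs:
        raise ValueError("empty cohort: accuracy is undefined")
    missing = [cid for cid, _ in pairs if cid not in truths]
    extra = sorted(set(truths) - {cid for cid, _ in pairs})
    if missing or extra:
        raise ValueError(
            f"case id mismatch between reports and truths: "
            f"reports without truth {missing}; truths without report {extra}")
    for _, out in pairs:
        if out not in ("union", "non_union"):
            raise ValueError(f"unknown outcome label {out!r}")
    for cid in truths:
        if truths[cid] not in ("union", "non_union"):
            raise ValueError(f"unknown truth label {truths[cid]!r} for {cid}")
    tp = sum(1 for cid, out in pairs if out == "union" and truths[cid] == "union")
    fn = sum(1 for cid, out in pairs if out == "union" and truths[cid] == "non_union")
    tn = sum(1 for cid, out in pairs if out == "non_union" and truths[cid] == "non_union")
    fp = sum(1 for cid, out in pairs if out == "non_union" and truths[cid] == "union")
    return ConfusionMatrix(true_positive=tp, false_negative=fn,
                           true_negative=tn, false_positive=fp)


@dataclass
class RunManifest:
    """Reproducibility record: config, seed and per-case outcome rows."""

    config: dict
    config_hash: str
    seed: int
    version: str = _version
    cases: list = field(default_factory=list)  # row dicts

    @classmethod
    def for_run(cls, config: SimulationConfig) -> "RunManifest":
        return cls(config=config.to_dict(), config_hash=config.content_hash(),
                   seed=config.cohort.seed)

    def add(self, report: OutcomeReport) -> None:
        self.cases.append({
            "case_id": report.case_id,
            "outcome": report.outcome,
            "consolidation_day": report.consolidation_day,
            "mrust_final": report.mrust_final,
            "truth": report.truth,
        })

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)
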