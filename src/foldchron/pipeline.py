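"""End-to-end pipeline: census (real or simulated) -> characters -> tree
-> node-distance ages -> geological ages -> pathway atlas, with a
machine-readable JSON run report.

Every stage writes plain-text artifacts into the output directory and the
whole run is reproducible bit-for-bit from the seed and config.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import networkx as nx
import pandas as pd

from . import atlas, io
from .chronology import CLOCKS, MolecularClock, calibrate_clock
from .fixtures import load_purine_fixture
from .model import FoldChronology
from .parsimony import SearchConfig
from .simulate import SimulationConfig, simulate_domain_evolution


@dataclasses.dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Exactly one census source is used: ``matrix_path``, ``simulation``
    (generate a synthetic census), or ``fixture_only`` (skip inference and
    use the packaged purine ages).  ``clock`` is ``"fold"``, ``"FSF"``,
    ``"calibrate"`` (fit to ``calibration_path``) or a custom
    :class:`MolecularClock`.
    """

    out_dir: str | Path = "foldchron_out"
    seed: int = 0
    matrix_path: str | Path | None = None
    simulation: SimulationConfig | None = None
    fixture_only: bool = False
    network_path: str | Path | None = None
    use_fixture_network: bool = False
    calibration_path: str | Path | None = None
    scale: str = "log"
    normalization: str = "minmax"
    search: SearchConfig = dataclasses.field(default_factory=SearchConfig)
    clock: str | MolecularClock = "fold"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        search = SearchConfig(**raw.pop("search", {}))
        sim = raw.pop("simulation", None)
        simulation = SimulationConfig(**sim) if sim else None
        return cls(search=search, simulation=simulation, **raw)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _resolve_clock(config: PipelineConfig):
    if isinstance(config.clock, MolecularClock):
        return config.clock, None
    if config.clock == "calibrate":
        if config.calibration_path is None:
            raise ValueError("clock='calibrate' requires calibration_path")
        pairs = io.read_calibration_tsv(config.calibration_path)
        cal = calibrate_clock(pairs[["nd", "age_gy"]], level="calibrated")
        return cal.clock, cal
    if config.clock in CLOCKS:
        return CLOCKS[config.clock], None
    raise ValueError(f"unknown clock {config.clock!r}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured pipeline and return the JSON-serializable report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "config": {
            "scale": config.scale,
            "normalization": config.normalization,
            "clock": config.clock if isinstance(config.clock, str) else "custom",
            "search": dataclasses.asdict(config.search),
            "fixture_only": config.fixture_only,
        },
        "outputs": {},
    }

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # surface the failing stage by name
                raise StageError(name, exc) from exc

        return wrap

    clock, calibration = stage("clock")(lambda: _resolve_clock(config))
    report["clock"] = {"slope": clock.slope, "intercept": clock.intercept, "level": clock.level}
    if calibration is not None:
        report["clock"]["r"] = calibration.r_value
        report["clock"]["p"] = calibration.p_value

    fixture_ages, fixture_net = load_purine_fixture()

    if config.fixture_only:
        ages = fixture_ages
        report["ages_source"] = "packaged_fixture"
    else:
        def census():
            if config.matrix_path is not None:
                return io.read_abundance_tsv(config.matrix_path)
            if config.simulation is not None:
                sim = dataclasses.replace(config.simulation, seed=config.seed)
                matrix, truth = simulate_domain_evolution(sim)
                io.write_abundance_tsv(matrix, out / "abundance.tsv")
                pd.DataFrame(
                    {
                        "family": truth.family_ids,
                        "birth_time": truth.birth_time,
                        "birth_rank": truth.birth_rank,
                    }
                ).to_csv(out / "truth.tsv", sep="\t", index=False)
                report["outputs"]["abundance"] = "abundance.tsv"
                report["outputs"]["truth"] = "truth.tsv"
                from .coding import drop_empty_proteomes

                kept = drop_empty_proteomes(matrix)
                report["n_empty_proteomes_dropped"] = (
                    len(matrix.proteome_ids) - len(kept.proteome_ids)
                )
                return kept
            raise ValueError("no census source: set matrix_path, simulation or fixture_only")

        matrix = stage("census")(census)

        def encode():
            model = FoldChronology(matrix, config.scale)
            io.write_nexus(model.character_matrix, out / "characters.nex")
            report["outputs"]["characters"] = "characters.nex"
            return model

        model = stage("encode")(encode)

        def infer():
            search = dataclasses.replace(config.search, seed=config.seed)
            res = model.fit(search=search, normalization=config.normalization)
            io.write_newick(res.tree, out / "tree.nwk")
            report["outputs"]["tree"] = "tree.nwk"
            report["tree_score"] = res.score
            report["n_cooptimal"] = res.n_cooptimal
            return res

        results = stage("infer")(infer)
        ages = results.ages
        report["ages_source"] = "inferred_tree"

    stage("ages")(lambda: io.write_age_table(ages, out / "ages.tsv"))
    report["outputs"]["ages"] = "ages.tsv"

    net = None
    if config.network_path is not None:
        net = stage("network")(lambda: atlas.EnzymeNetwork.from_tsv(config.network_path))
    elif config.use_fixture_network or config.fixture_only:
        net = fixture_net

    if net is not None:
        def map_pathways():
            timelines = atlas.build_timeline(net, ages, clock)
            atlas.timeline_dataframe(timelines).to_csv(out / "timeline.csv", index=False)
            curves = []
            for pw, tl in timelines.items():
                for nd, count in tl.accumulation:
                    curves.append({"pathway": pw, "nd": nd, "cumulative_ffs": count})
            pd.DataFrame(curves).to_csv(out / "accumulation.csv", index=False)
            events = atlas.classify_recruitment(net, ages)
            pd.DataFrame(
                {
                    "ff": [e.ff for e in events],
                    "nd": [e.nd for e in events],
                    "class": [e.recruitment_class for e in events],
                    "pathways": [",".join(sorted(e.pathways_sharing)) for e in events],
                    "steps": [",".join(sorted(e.steps_sharing)) for e in events],
                }
            ).to_csv(out / "recruitment.csv", index=False)
            g = atlas.paint_network(net, ages)
            (out / "network.dot").write_text(atlas.to_dot(g))
            nx.write_graphml(g, out / "network.graphml")
            report["outputs"].update(
                {
                    "timeline": "timeline.csv",
                    "accumulation": "accumulation.csv",
                    "recruitment": "recruitment.csv",
                    "network_dot": "network.dot",
                    "network_graphml": "network.graphml",
                }
            )
            report["pathways"] = {
                pw: {
                    "first_nd": tl.first_nd,
                    "completion_nd": tl.completion_nd,
                    "first_age_gy": tl.first_age_gy,
                    "completion_age_gy": tl.completion_age_gy,
                }
                for pw, tl in timelines.items()
            }

        stage("map")(map_pathways)

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
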