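"""End-to-end colony analysis pipeline.

Runs the full analysis surface for one colony — network construction,
modularity (with null-model significance), nestedness, module network,
individual specialization scores, day/night mixing and the age analyses — and
writes a summary row mirroring the standard colony table (ants, behaviour
nodes, total weight, links, modules, connectance, modularity, normalized
modularity, nestedness, with significance stars), plus per-stage CSV/JSON
outputs and a run manifest. Outputs are deterministic for a fixed config and
seed.
"""

from __future__ import annotations

import json

import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .community import maximize_modularity, modularity_pvalue
from .io_network import build_network, connectance, read_metadata, read_observations
from .module_metrics import module_network, score_correlation, specialization_scores
from .nestedness import wnodf_pvalue
from .synthetic_data import SyntheticColonyConfig, generate_colony
from .temporal_age import (
    DEFAULT_PERIOD_MAP,
    age_module_comparison,
    age_regression,
    behaviour_proportions,
    period_mixing,
)




@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (seed mandatory for stochastic stages)."""

    seed: int
    observations: str | None = None  # CSV path; exclusive with `synthetic`
    metadata: str | None = None
    synthetic: SyntheticColonyConfig | None = None
    column_scheme: str = "behaviour_by_day"
    n_restarts: int = 20
    null_restarts: int = 2
    n_null: int = 1000
    alpha: float = 0.05
    exclude_queen: bool = False
    output_dir: str = "polyethnet_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(open(path)) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticColonyConfig(**raw["synthetic"])
        return cls(**raw)

    def validate(self) -> None:
        if (self.observations is None) == (self.synthetic is None):
            raise ValueError("config needs exactly one of `observations` or `synthetic`")


@dataclass
class ColonySummary:
    """One colony's network-level metrics (a colony-table row with p-values)."""

    colony_id: str
    n_ants: int
    n_behaviour_nodes: int
    sum_weights: int
    n_links: int
    n_modules: int
    connectance: float
    modularity: float
    modularity_p: float
    normalized_modularity: float
    nestedness: float
    nestedness_p: float

    def formatted_row(self, alpha: float = 0.05) -> dict:
        """Report-rounded row: 3 d.p. for connectance/modularity, 2 d.p. for
        nestedness, significance stars at the given alpha."""
        star = lambda v, p: f"{v}{'*' if p < alpha else ''}"
        return {
            "colony_id": self.colony_id,
            "n_ants": self.n_ants,
            "n_behaviour_nodes": self.n_behaviour_nodes,
            "sum_weights": self.sum_weights,
            "n_links": self.n_links,
            "n_modules": self.n_modules,
            "connectance": f"{self.connectance:.3f}",
            "modularity": star(f"{self.modularity:.3f}", self.modularity_p),
            "normalized_modularity": f"{self.normalized_modularity:.3f}",
            "nestedness": star(f"{self.nestedness:.2f}", self.nestedness_p),
        }


def _alluvial_table(records: pd.DataFrame, metadata: pd.DataFrame | None) -> pd.DataFrame:
    """Plot-ready long table (ant, age in months, behaviour, aggregate weight)."""
    counts = (
        records.groupby(["ant_id", "behaviour"]).size().reset_index(name="weight")
    )
    if metadata is not None:
        ages = metadata.set_index("ant_id")["age_days"]
        counts["age_months"] = (counts["ant_id"].map(ages) / 30.0).round(1)
    return counts


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle into ``config.output_dir``.

    Returns a dict with the in-memory results (summary, partition, scores,
    mixing, age analyses). On any stage failure the partial outputs written by
    this run are removed and the error re-raised with the stage name.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    timings: dict[str, float] = {}
    stage = "setup"

    def _write_csv(df: pd.DataFrame, name: str, **kw) -> None:
        path = outdir / name
        df.to_csv(path, **kw)
        written.append(path)

    def _write_json(obj, name: str) -> None:
        path = outdir / name
        path.write_text(json.dumps(obj, indent=1, default=_jsonable))
        written.append(path)

    try:
        t0 = time.perf_counter()
        stage = "load"
        if config.synthetic is not None:
            colony = generate_colony(config.synthetic)
            records, metadata = colony.records, colony.metadata
            colony_id = colony.colony_id
        else:
            records = read_observations(config.observations)
            metadata = read_metadata(config.metadata) if config.metadata else None
            ids = records["colony_id"].unique()
            colony_id = str(ids[0]) if len(ids) == 1 else "multi"
        timings[stage] = time.perf_counter() - t0

        t0 = time.perf_counter()
        stage = "network"
        net = build_network(
            records,
            column_scheme=config.column_scheme,
            metadata=metadata,
            exclude_queen=config.exclude_queen,
            period_map=DEFAULT_PERIOD_MAP
            if config.column_scheme == "behaviour_by_period"
            else None,
        )
        net.to_edgelist(outdir / "network_edges.csv")
        written += [outdir / "network_edges.csv", outdir / "network_edges.csv.json"]
        timings[stage] = time.perf_counter() - t0

        t0 = time.perf_counter()
        stage = "modularity"
        mod = modularity_pvalue(
            net,
            n_null=config.n_null,
            n_restarts=config.n_restarts,
            null_restarts=config.null_restarts,
            seed=config.seed,
        )
        part = mod.partition
        part_df = pd.DataFrame(
            {
                "node": net.row_labels + net.col_labels,
                "node_class": ["individual"] * net.r + ["behaviour"] * net.s,
                "module": np.concatenate([part.row_modules, part.col_modules]),
            }
        )
        _write_csv(part_df, "partition.csv", index=False)
        timings[stage] = time.perf_counter() - t0

        t0 = time.perf_counter()
        stage = "nestedness"
        nest = wnodf_pvalue(net, n_null=config.n_null, seed=config.seed)
        timings[stage] = time.perf_counter() - t0

        t0 = time.perf_counter()
        stage = "module_network"
        modnet = module_network(net, part)
        q_df = pd.DataFrame(
            modnet.q,
            index=[f"module_{m}" for m in range(1, part.n_modules + 1)],
            columns=[f"module_{m}" for m in range(1, part.n_modules + 1)],
        )
        _write_csv(q_df, "module_network.csv")
        timings[stage] = time.perf_counter() - t0

        t0 = time.perf_counter()
        stage = "scores"
        scores = specialization_scores(net, part)
        _write_csv(scores, "scores.csv")
        try:
            r_cd, p_cd = score_correlation(scores)
        except ValueError:
            r_cd, p_cd = float("nan"), float("nan")
        timings[stage] = time.perf_counter() - t0

        t0 = time.perf_counter()
        stage = "daynight"
        day_net = build_network(
            records, column_scheme="behaviour_by_period", period_map=DEFAULT_PERIOD_MAP
        )
        day_mod = maximize_modularity(
            day_net, n_restarts=config.n_restarts, seed=config.seed
        )
        mixing = period_mixing(day_net, day_mod.partition)
        _write_json(
            {
                "co_modular": mixing.co_modular,
                "mixed_module_fraction": mixing.mixed_module_fraction,
                "excluded_behaviours": mixing.excluded,
                "n_modules": day_mod.partition.n_modules,
            },
            "daynight.json",
        )
        timings[stage] = time.perf_counter() - t0

        t0 = time.perf_counter()
        stage = "age"
        age_out: dict = {}
        if metadata is not None and metadata["age_days"].notna().sum() >= 3:
            ages = metadata.set_index("ant_id")["age_days"]
            props = behaviour_proportions(records)
            regs = {}
            for b in props.columns.drop("n_scans"):
                try:
                    regs[b] = age_regression(props, ages, b)
                except ValueError:
                    continue
            reg_df = pd.DataFrame(
                {
                    b: {
                        "slope": r.slope,
                        "intercept": r.intercept,
                        "r_squared": r.r_squared,
                        "p_value": r.p_value,
                        "n": r.n,
                    }
                    for b, r in regs.items()
                }
            ).T
            _write_csv(reg_df, "age_regressions.csv", index_label="behaviour")
            part_map = pd.Series(part.row_modules, index=net.row_labels)
            try:
                ages_cmp = age_module_comparison(
                    ages, part_map, alpha=config.alpha, seed=config.seed
                )
                _write_csv(ages_cmp.pairwise, "age_module_tests.csv", index=False)
                age_out = {
                    "letters": {str(k): v for k, v in ages_cmp.letters.items()},
                    "dropped_modules": [str(m) for m in ages_cmp.dropped],
                    "regressions": {b: regs[b].slope for b in regs},
                }
            except ValueError as exc:
                age_out = {"skipped": str(exc), "regressions": {b: regs[b].slope for b in regs}}
            _write_json(age_out, "age_summary.json")
        timings[stage] = time.perf_counter() - t0

        stage = "summary"
        summary = ColonySummary(
            colony_id=colony_id,
            n_ants=net.r,
            n_behaviour_nodes=net.s,
            sum_weights=net.M,
            n_links=int(np.count_nonzero(net.A)),
            n_modules=part.n_modules,
            connectance=connectance(net),
            modularity=mod.Q_W,
            modularity_p=mod.p_value,
            normalized_modularity=mod.Q_norm,
            nestedness=nest.WNODF,
            nestedness_p=nest.p_value,
        )
        row = summary.formatted_row(alpha=config.alpha)
        row["scheme"] = config.column_scheme
        _write_csv(pd.DataFrame([row]), "summary.csv", index=False)
        _write_csv(
            _alluvial_table(records, metadata), "alluvial_table.csv", index=False
        )

        stage = "consistency"
        edges = pd.read_csv(outdir / "network_edges.csv")
        assert int(edges["weight"].sum()) == summary.sum_weights
        assert len(edges) == summary.n_links
        assert abs(len(edges) / (net.r * net.s) - summary.connectance) < 1e-12

        stage = "manifest"
        manifest = {
            "polyethnet_version": __version__,
            "seed": config.seed,
            "column_scheme": config.column_scheme,
            "n_restarts": config.n_restarts,
            "null_restarts": config.null_restarts,
            "n_null": config.n_null,
            "alpha": config.alpha,
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
            "synthetic": asdict(config.synthetic) if config.synthetic else None,
            "outputs": sorted(p.name for p in written),
        }
        _write_json(manifest, "manifest.json")
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {
        "summary": summary,
        "modularity": mod,
        "nestedness": nest,
        "partition": part,
        "module_network": modnet,
        "scores": scores,
        "score_correlation": (r_cd, p_cd),
        "daynight": mixing,
        "age": age_out,
        "network": net,
        "output_dir": outdir,
    }


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
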