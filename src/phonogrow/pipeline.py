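"""End-to-end run: ingest -> networks -> growth metrics -> models -> report.

Every run is deterministic given its configuration and inputs; the report is
plain JSON (plus TSV/CSV intermediates) stamped with a hash of the resolved
configuration so any number in it can be recomputed from the artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import growth_metrics, network_build, stats_models
from .growth_metrics import GrowthTrajectory
from .lexicon_io import IOConfig, read_word_lists, round_display
from .network_build import AssortativityUndefined, PhonNetwork, WeightFn
from .phonetics import FeatureTable, default_feature_table
from .synthetic_data import GeneratorConfig, generate
from .types import N_STAGES, StagedLexicon


class PipelineError(RuntimeError):
    def __init__(self, stage_name: str, cause: Exception):
        super().__init__(f"pipeline stage {stage_name!r} failed: {cause}")
        self.stage_name = stage_name
        self.cause = cause


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    word_list_paths: Sequence[str] = ()
    synthetic: GeneratorConfig | None = None
    out_dir: str = "phonogrow_run"
    models: Sequence[str] = ("degree", "saturation", "weighted")
    feature_table_path: str | None = None
    wd_mode: str = "cumulative"
    seed: int = 0

    def resolved(self) -> dict:
        d = {
            "word_list_paths": list(self.word_list_paths),
            "synthetic": asdict(self.synthetic) if self.synthetic else None,
            "models": list(self.models),
            "feature_table_path": self.feature_table_path,
            "wd_mode": self.wd_mode,
            "seed": self.seed,
        }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    body: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"config_hash": self.config_hash, **self.body}, indent=1)


def _tidy_fit(fit: stats_models.FitResult) -> dict:
    out = {
        "model_type": fit.model_type,
        "dv": fit.dv,
        "n": fit.nobs,
        "dispersion": fit.dispersion,
        "mcfadden_r2": fit.mcfadden_r2,
        "vif": fit.vif,
        "coefficients": fit.coefficients.round(6).to_dict(orient="records"),
        "std_odds_ratios": fit.std_odds_ratios.round(4).to_dict(orient="records")
        if fit.std_odds_ratios is not None
        else None,
    }
    if fit.zero_coefficients is not None:
        out["zero_coefficients"] = fit.zero_coefficients.round(6).to_dict(orient="records")
    return out


def summarize_growth(
    lexicon: StagedLexicon,
    networks: Mapping[int, PhonNetwork],
    trajectories: Sequence[GrowthTrajectory],
) -> dict:
    """Per-stage network statistics and per-spurt growth summaries."""
    final = networks[N_STAGES]
    per_stage = {}
    for s in range(1, N_STAGES + 1):
        net = networks[s]
        try:
            assort = round(network_build.assortativity_degree(net), 4)
        except AssortativityUndefined:
            assort = None
        new = lexicon.new_at_stage(s)
        per_stage[s] = {
            "vocabulary_size": net.n_nodes,
            "unique_words": len(new),
            "edges": net.n_edges,
            "assortativity": assort,
            "hermit_fraction": round(network_build.hermit_fraction(lexicon, s, final), 4)
            if new
            else None,
        }

    growing = [t for t in trajectories if t.final_degree > 0]
    mean_gain_by_spurt: dict[int, float] = {}
    counts: dict[int, int] = {}
    for t in growing:
        for j in range(1, t.n_spurts + 1):
            g = growth_metrics.proportional_degree_gain(t, j)
            mean_gain_by_spurt[j] = mean_gain_by_spurt.get(j, 0.0) + g
            counts[j] = counts.get(j, 0) + 1
    mean_gain_by_spurt = {j: round(v / counts[j], 2) for j, v in mean_gain_by_spurt.items()}

    sat_by_aoa: dict[int, list[float]] = {}
    for t in growing:
        l1 = lexicon.entry(t.phon).l1_density
        if l1 > 0:
            sat_by_aoa.setdefault(t.aoa, []).append(
                growth_metrics.saturation(t, l1, t.n_spurts)
            )
    mean_sat_by_aoa = {a: round(sum(v) / len(v), 2) for a, v in sorted(sat_by_aoa.items())}

    patterns: dict[str, int] = {}
    for t in growing:
        if t.n_spurts >= 3:
            patterns[growth_metrics.classify_growth_pattern(t).value] = (
                patterns.get(growth_metrics.classify_growth_pattern(t).value, 0) + 1
            )

    return {
        "per_stage": per_stage,
        "n_words": len(lexicon),
        "n_growing_words": len(growing),
        "mean_prop_degree_gain_by_spurt_pct": mean_gain_by_spurt,
        "mean_final_saturation_by_aoa_pct": mean_sat_by_aoa,
        "growth_pattern_counts": patterns,
    }


def run_all(
    config: RunConfig,
    lexicon: StagedLexicon | None = None,
    io_config: IOConfig | None = None,
    ft: FeatureTable | None = None,
    weight_fn: WeightFn | None = None,
) -> RunReport:
    """Execute the full analysis and write artifacts under ``config.out_dir``.

    A lexicon may be passed directly (e.g. the worked-example fixture);
    otherwise it is read from ``word_list_paths`` or generated from the
    synthetic configuration.  Any stage failure aborts with the failing stage
    named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ft = ft or default_feature_table()
    report = RunReport(config_hash=config.config_hash())
    report.body["config"] = config.resolved()

    stage = "ingest"
    try:
        if lexicon is None:
            if config.synthetic is not None:
                syn = generate(config.synthetic)
                syn.write(out / "synthetic")
                lexicon = syn.lexicon
                report.body["synthetic_pool_size"] = syn.pool_size
            elif config.word_list_paths:
                io_config = io_config or IOConfig(inventory=ft.inventory)
                lexicon, drops = read_word_lists(config.word_list_paths, io_config)
                (out / "drop_report.json").write_text(drops.to_json())
                report.body["rows_read"] = drops.n_rows
                report.body["rows_dropped"] = drops.n_dropped
            else:
                raise ValueError("no lexicon, word lists, or synthetic config provided")

        stage = "networks"
        networks = network_build.build_all_networks(lexicon, ft, weight_fn)
        network_build.write_edge_list(networks[N_STAGES], out / "edges_stage6.tsv")

        stage = "growth"
        trajectories = growth_metrics.compute_all_trajectories(networks)
        traj_rows = []
        for t in trajectories:
            for j, sp in enumerate(t.spurts, start=1):
                traj_rows.append(
                    {
                        "word": "".join(t.phon),
                        "aoa": t.aoa,
                        "spurt": j,
                        "added": sp.neighbors_added,
                        "cumulative": sp.cumulative_degree,
                        "added_weight": sp.added_weight,
                        "avg_wd": round(
                            growth_metrics.avg_weighted_degree_new(t, j, config.wd_mode), 4
                        ),
                    }
                )
        pd.DataFrame(traj_rows).to_csv(out / "trajectories.tsv", sep="\t", index=False)
        report.body["growth"] = summarize_growth(lexicon, networks, trajectories)

        stage = "model_table"
        l1 = {t.phon: lexicon.entry(t.phon).l1_density for t in trajectories}
        fl = {t.phon: lexicon.entry(t.phon).freq_log for t in trajectories}
        ln = {t.phon: lexicon.entry(t.phon).length for t in trajectories}
        table = growth_metrics.build_model_table(trajectories, l1, fl, ln, config.wd_mode)
        table.to_csv(out / "model_table.csv", index=False)
        report.body["model_table_rows"] = len(table)

        stage = "models"
        fits = {}
        if "degree" in config.models:
            fit = stats_models.fit_proportional_model(table, "degree_gain")
            fits["degree"] = fit
            report.body.setdefault("models", {})["degree_gain"] = _tidy_fit(fit)
            report.body["models"]["degree_gain"]["spurt_contrasts"] = (
                stats_models.pairwise_spurt_contrasts(fit).round(6).to_dict(orient="records")
            )
        if "saturation" in config.models:
            fit = stats_models.fit_proportional_model(table, "saturation_gain")
            fits["saturation"] = fit
            report.body.setdefault("models", {})["saturation_gain"] = _tidy_fit(fit)
            report.body["models"]["saturation_gain"]["spurt_contrasts"] = (
                stats_models.pairwise_spurt_contrasts(fit).round(6).to_dict(orient="records")
            )
        if "weighted" in config.models:
            fit = stats_models.fit_zinb_model(table)
            fits["weighted"] = fit
            report.body.setdefault("models", {})["weighted_degree"] = _tidy_fit(fit)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(stage, exc) from exc

    (out / "report.json").write_text(report.to_json())
    return report


def run_worked_example(out_dir: str | Path = "phonogrow_worked_example") -> RunReport:
    """Run the pipeline on the hand-built worked-example fixture.

    Model fitting is skipped: the fixture is far too small for the regression
    models and exists to exercise the growth metrics end to end.
    """
    from .synthetic_data import fixture_weight_fn, make_worked_example_fixture

    cfg = RunConfig(out_dir=str(out_dir), models=())
    return run_all(cfg, lexicon=make_worked_example_fixture(), weight_fn=fixture_weight_fn)


def worked_example_numbers() -> dict:
    """The worked growth numbers, recomputed from the fixture via the pipeline.

    Returns display-rounded values for the three designated trajectories:
    proportional degree gains of the degree-16 word, the saturation ladder of
    the density-15 word, the per-neighbor weighted-degree averages of the
    seven-to-twelve-neighbor word, and the homophone frequency average.
    """
    from .lexicon_io import merge_homophones, RawRow
    from .synthetic_data import fixture_weight_fn, make_worked_example_fixture

    lex = make_worked_example_fixture()
    networks = network_build.build_all_networks(lex, weight_fn=fixture_weight_fn)
    bad = growth_metrics.compute_trajectory(tuple("bad"), networks)
    eni = growth_metrics.compute_trajectory(tuple("eni"), networks)
    bi = growth_metrics.compute_trajectory(tuple("bi"), networks)
    g1 = growth_metrics.proportional_degree_gain(bad, 1)
    g2 = growth_metrics.proportional_degree_gain(bad, 2)
    merged = merge_homophones(
        [
            RawRow("plain", tuple("plen"), 3, 21.8, 18),
            RawRow("plane", tuple("plen"), 3, 95.5, 18),
        ]
    )
    return {
        "degree_gain_spurt1_pct": round_display(g1),
        "degree_gain_spurt2_pct": round_display(g2),
        "cumulative_gain_after_spurt2_pct": round_display(g1 + g2),
        "saturation_spurt1_pct": growth_metrics.saturation(eni, 15, 1),
        "saturation_spurt2_pct": growth_metrics.saturation(eni, 15, 2),
        "saturation_spurt3_pct": growth_metrics.saturation(eni, 15, 3),
        "saturation_max_pct": growth_metrics.saturation(eni, 15, eni.n_spurts),
        "avg_weighted_degree_spurt1": round_display(
            growth_metrics.avg_weighted_degree_new(bi, 1)
        ),
        "avg_weighted_degree_spurt2": round_display(
            growth_metrics.avg_weighted_degree_new(bi, 2)
        ),
        "avg_weighted_degree_spurt3": round_display(
            growth_metrics.avg_weighted_degree_new(bi, 3)
        ),
        "homophone_mean_freq": round_display(merged.freq_raw),
    }
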