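"""End-to-end modelling pipeline.

Orchestrates the full workflow in three phases: (I) bootstrap the input
table into a pseudopopulation and validate predictor subsets with the
MLP, (II) fit the dummy-coded OLS model on the validated subset, (III)
fit the possibilistic fuzzy regression on the same subset and render its
central/lower/upper boundary equations.  A single master seed derives
every per-stage seed, so identical configurations give byte-identical
outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import bootstrap as bt
from . import fuzzy as fz
from . import linear as lm
from . import mlp as nn
from . import synthetic as syn
from .data import ConfigurationError, DesignMatrix, ObservationTable, encode_dummies, load_table

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


def _stage_seeds(master: int, n: int) -> list[int]:
    # per-stage seeds below 2**31, reproducibly derived from the master seed
    state = np.random.SeedSequence(master).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


@dataclass(frozen=True)
class PipelineConfig:
    """Full run configuration; exactly one of ``input_path`` / ``generator`` is set."""

    input_path: str | None = None
    generator: syn.GeneratorConfig | None = None
    n_replicates: int = 1000
    mlp: nn.MLPConfig = field(default_factory=nn.MLPConfig)
    h_level: float = 0.0
    fuzzy_mode: str = "symmetric"
    output_dir: str | None = None
    seed: int = 0
    force_full_model: bool = False
    fit_on: str = "mega"  # "mega" | "original"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.generator is None):
            raise ConfigurationError("supply exactly one of input_path or generator")
        if self.fit_on not in ("mega", "original"):
            raise ConfigurationError("fit_on must be 'mega' or 'original'")


@dataclass(frozen=True)
class RunReport:
    """Three-phase result with provenance.

    Phases II and III are fit on exactly the predictor subset chosen in
    phase I.
    """

    subset_scores: list[nn.SubsetScore]
    chosen_subset: tuple[str, ...]
    ols_report: lm.CoefficientReport
    fuzzy_model: fz.FuzzyModel
    equations: tuple[str, str, str]
    provenance: dict = field(default_factory=dict)


def _load_input(config: PipelineConfig, seed: int) -> ObservationTable:
    if config.input_path is not None:
        return load_table(config.input_path)
    gen = config.generator
    if gen.seed != seed:
        gen = syn.GeneratorConfig(**{**gen.__dict__, "seed": seed})
    return syn.generate(gen)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute load/generate -> encode -> bootstrap -> MLP validation -> OLS -> fuzzy.

    Artifacts (subset ranking, coefficient tables, equations, run config)
    are written to ``config.output_dir`` when it is set.
    """
    t0 = time.time()
    gen_seed, boot_seed, mlp_seed = _stage_seeds(config.seed, 3)

    table = _load_input(config, gen_seed)
    logger.info("input table: %d rows (%d dropped)", len(table), table.n_dropped)

    design_orig = encode_dummies(table)
    boot = bt.resample(table, bt.BootstrapConfig(n_replicates=config.n_replicates, seed=boot_seed))
    design_mega = encode_dummies(boot.mega_table)
    design_fit: DesignMatrix = design_mega if config.fit_on == "mega" else design_orig

    mlp_cfg = nn.MLPConfig(**{**config.mlp.__dict__, "seed": mlp_seed})
    candidates = list(design_fit.groups)
    scores = nn.select_variables(design_fit, candidates, mlp_cfg)
    chosen = tuple(candidates) if config.force_full_model else scores[0].subset

    sub = design_fit.subset(list(chosen))
    ols = lm.fit_ols(sub)
    fuz = fz.fit_possibilistic(sub, h_level=config.h_level, mode=config.fuzzy_mode)
    equations = fz.format_model_equations(fuz)

    provenance = {
        "seed": config.seed,
        "stage_seeds": {"generate": gen_seed, "bootstrap": boot_seed, "mlp": mlp_seed},
        "n_input_rows": len(table),
        "n_dropped_rows": table.n_dropped,
        "n_replicates": config.n_replicates,
        "n_fit_rows": sub.n_rows,
        "fit_on": config.fit_on,
        "h_level": config.h_level,
        "fuzzy_mode": config.fuzzy_mode,
        "chosen_subset": list(chosen),
        "elapsed_s": round(time.time() - t0, 3),
    }
    report = RunReport(
        subset_scores=scores,
        chosen_subset=chosen,
        ols_report=ols,
        fuzzy_model=fuz,
        equations=equations,
        provenance=provenance,
    )
    if config.output_dir is not None:
        _write_artifacts(report, table, boot, Path(config.output_dir))
    logger.info("pipeline done in %.2fs; chosen subset %s", time.time() - t0, chosen)
    return report


def _write_artifacts(
    report: RunReport, table: ObservationTable, boot: bt.BootstrapResult, outdir: Path
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "input_table.csv")
    boot.to_csv(outdir / "bootstrap_mega.csv")
    with open(outdir / "subset_ranking.csv", "w") as fh:
        fh.write("subset,train_mse,test_mse\n")
        for s in report.subset_scores:
            fh.write(f"{'+'.join(s.subset)},{s.train_mse!r},{s.test_mse!r}\n")
    report.ols_report.to_csv(outdir / "ols_report.csv")
    report.fuzzy_model.to_csv(outdir / "fuzzy_model.csv")
    with open(outdir / "equations.txt", "w") as fh:
        for label, eq in zip(("Central tendency", "Lower boundary", "Upper boundary"),
                             report.equations):
            fh.write(f"{label}: {eq}\n")
    with open(outdir / "run_provenance.json", "w") as fh:
        json.dump(report.provenance, fh, indent=2, sort_keys=True)


def format_summary(report: RunReport) -> str:
    """Plain-text three-phase summary of a pipeline run."""
    lines = ["=== Phase I: MLP predictor validation ==="]
    for s in report.subset_scores:
        lines.append(
            f"  {'+'.join(s.subset):<30s} train MSE {s.train_mse:10.4f}  test MSE {s.test_mse:10.4f}"
        )
    lines.append(f"  chosen subset: {', '.join(report.chosen_subset)}")
    lines.append("=== Phase II: multiple linear regression ===")
    lines.append(report.ols_report.to_frame().to_string(index=False))
    lines.append(
        f"  r-squared {report.ols_report.r_squared:.4f} "
        f"(adjusted {report.ols_report.adj_r_squared:.4f}), "
        f"residual df {report.ols_report.residual_df}"
    )
    lines.append("=== Phase III: possibilistic fuzzy regression ===")
    lines.append(report.fuzzy_model.to_frame().to_string(index=False))
    for label, eq in zip(("Central tendency", "Lower boundary", "Upper boundary"),
                         report.equations):
        lines.append(f"  {label}: {eq}")
    return "\n".join(lines)
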