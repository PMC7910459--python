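"""End-to-end orchestration: simulate -> count -> fc -> score -> call -> report.

Every stage writes its TSV artifact together with a JSON provenance sidecar
(parameters, seeds, SHA-256 checksums of the inputs), so identical
configuration and inputs reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .library import GuideLibrary, load_library, write_library
from .model import PairedScreen, PairedScreenResults
from .quantify import CountMatrix
from .simulate import SimulationConfig, TrueEffects, simulate_screen

__all__ = ["RunConfig", "run_pipeline", "write_report", "PipelineError"]

log = logging.getLogger("pairscreen")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Declarative configuration for a full pipeline run."""

    outdir: str = "pairscreen_run"
    # inputs: either simulate=True, or library+counts paths
    simulate: bool = True
    library_path: str | None = None
    counts_path: str | None = None
    samples_path: str | None = None
    essential_list_path: str | None = None
    # stage parameters
    normalization: str = "median_ratio"
    pseudocount: float = 1.0
    min_baseline_count: int = 30
    screen_timepoint: int = 28
    essential_timepoint: int | None = 14
    span: float = 0.75
    degree: int = 2
    bin_size: int = 200
    divisor: str = "variance"
    alpha: float = 0.10
    n_perm: int = 10_000
    threshold: float = 0.1
    correction: str = "bonferroni"
    seed: int = 0
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    def validate(self) -> None:
        if self.bin_size < 10:
            raise ValueError("bin_size must be >= 10")
        if not (0 < self.alpha <= 0.5):
            raise ValueError("alpha must lie in (0, 0.5]")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if not self.simulate:
            for name in ("library_path", "counts_path", "samples_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"{name} required when simulate=false")
                if not Path(p).exists():
                    raise ValueError(f"{name}: no such file {p!r}")
        self.sim.validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        if "timepoints" in sim_raw:
            sim_raw["timepoints"] = tuple(sim_raw["timepoints"])
        return cls(**raw, sim=SimulationConfig(**sim_raw))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["timepoints"] = list(d["sim"]["timepoints"])
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_with_provenance(write, path: Path, params: dict,
                           inputs: list[Path]) -> None:
    partial = path.with_suffix(path.suffix + ".partial")
    write(partial)
    partial.rename(path)
    sidecar = {"artifact": path.name, "parameters": params,
               "inputs": {p.name: _sha256(p) for p in inputs if p.exists()}}
    path.with_suffix(path.suffix + ".prov.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(cfg: RunConfig) -> dict[str, str]:
    """Execute every enabled stage in order; returns the artifact manifest.

    A stage failure raises :class:`PipelineError` naming the stage; partial
    outputs keep a ``.partial`` suffix.
    """
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    params = cfg.to_dict()
    truth: TrueEffects | None = None

    stage = "inputs"
    try:
        if cfg.simulate:
            sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.seed)
            lib, truth, counts = simulate_screen(sim_cfg)
            _write_with_provenance(lambda p: write_library(lib, p),
                                   out / "library.tsv", params, [])
            _write_with_provenance(
                lambda p: counts.to_tsv(p, out / "samples.tsv"),
                out / "counts.tsv", params, [])
            _write_with_provenance(
                lambda p: truth.write_tsv(p, out / "pair_interaction.tsv"),
                out / "gene_fitness.tsv", params, [])
            manifest.update(library=str(out / "library.tsv"),
                            counts=str(out / "counts.tsv"),
                            samples=str(out / "samples.tsv"),
                            truth=str(out / "gene_fitness.tsv"))
        else:
            lib = load_library(cfg.library_path)
            counts = CountMatrix.from_tsv(cfg.counts_path, cfg.samples_path)
            manifest.update(library=str(cfg.library_path),
                            counts=str(cfg.counts_path))

        external = None
        if cfg.essential_list_path:
            external = {line.strip() for line
                        in Path(cfg.essential_list_path).read_text().split()
                        if line.strip()}

        stage = "score"
        model = PairedScreen(counts, lib,
                             screen_timepoint=cfg.screen_timepoint,
                             essential_timepoint=cfg.essential_timepoint,
                             normalization=cfg.normalization,
                             pseudocount=cfg.pseudocount,
                             min_baseline_count=cfg.min_baseline_count)
        res = model.fit(span=cfg.span, degree=cfg.degree,
                        bin_size=cfg.bin_size, divisor=cfg.divisor,
                        alpha=cfg.alpha, n_perm=cfg.n_perm,
                        threshold=cfg.threshold, correction=cfg.correction,
                        external_essential=external, seed=cfg.seed)

        stage = "write"
        inputs = [out / "counts.tsv", out / "library.tsv"]
        _write_with_provenance(res.fold_change_table.to_tsv,
                               out / "fold_changes.tsv", params, inputs)
        _write_with_provenance(res.residual_table.to_tsv,
                               out / "residuals.tsv", params, inputs)
        _write_with_provenance(
            lambda p: res.pair_results.to_csv(p, sep="\t", index=False),
            out / "results.tsv", params, inputs)
        _write_with_provenance(res.essential_genes.to_tsv,
                               out / "essential_genes.tsv", params, inputs)
        manifest.update(fold_changes=str(out / "fold_changes.tsv"),
                        residuals=str(out / "residuals.tsv"),
                        results=str(out / "results.tsv"),
                        essential=str(out / "essential_genes.tsv"))

        stage = "report"
        report = write_report(res, truth, out / "report.txt")
        manifest["report"] = str(report)
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001 - annotate with the failing stage
        raise PipelineError(stage, str(e)) from e
    log.info("pipeline complete: %d artifacts in %s", len(manifest), out)
    return manifest


def write_report(res: PairedScreenResults, truth: TrueEffects | None,
                 path) -> Path:
    """Human-readable run report; adds a confusion table when ground truth
    from a simulation is available."""
    lines = [res.summary()]
    if truth is not None:
        c = res.confusion(truth)
        lines += [
            "",
            "Ground-truth evaluation (simulation)",
            "-" * 54,
            f"{'True SL pairs':34s}{c['n_true_sl']:>20d}",
            f"{'Called hits':34s}{c['n_called']:>20d}",
            f"{'True positives':34s}{c['true_positives']:>20d}",
            f"{'False positives':34s}{c['false_positives']:>20d}",
            f"{'Sensitivity':34s}{c['sensitivity']:>20.3f}",
            f"{'Empirical FDP':34s}{c['fdp']:>20.3f}",
        ]
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path
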