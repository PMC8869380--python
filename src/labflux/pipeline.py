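"""Pipeline orchestration: run the analysis stages with one config.

Stages run in dependency order — growth simulation (fba), GAM fitting,
nutrient omission, carbon scan, reporter metabolites — each writing a TSV
whose header records the seed and the configuration hash, plus a
machine-readable JSON summary. Re-running with an unchanged configuration is
a no-op unless forced, so a pipeline directory is reproducible and
self-describing.

The model may be a file path or the literal ``mini-lab``, in which case the
synthetic fixture (with its canonical panel, media and composition) is
generated in place and the pipeline is fully self-contained.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy

from . import __version__
from .carbon import DEFAULT_UPTAKE_LEVELS, scan_carbons
from .errors import LabfluxError
from .fba import fit_gam, solve_fba
from .io import load_model, save_model
from .medium import (
    MediumSpec, apply_medium, carbon_scan_background, load_medium_tsv,
    omission_medium, validation_medium,
)
from .omission import NutrientPanel, double_omission, single_omission
from .reporter import read_deg_table, reporter_scores, summarize_routes
from .synthetic import (
    MiniLabSpec, make_deg_table, make_mini_lab, mini_lab_composition,
    mini_lab_nutrient_classes, mini_lab_panel,
)

__all__ = ["RunConfig", "run_pipeline"]

STAGES = ("fba", "fit-gam", "omit", "scan", "reporter")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Thresholds are the conventional cutoffs: preferable-growth 0.005 h^-1,
    DEG expression FPKM >= 1, |log2FC| >= 1.5, FDR < 0.05.
    """

    model: str = "mini-lab"
    out_dir: str = "labflux_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    medium_tsv: str | None = None       # external models: validation medium
    panel_tsv: str | None = None        # external models: omission panel
    deg_tsv: str | None = None          # external DEG table for the reporter stage
    carbon_exchange: str | None = None  # carbon used by fba / fit-gam
    carbon_uptake: float = 6.634
    measured_growth: float | None = None
    gam_bounds: tuple[float, float] = (0.0, 100.0)
    growth_threshold: float = 0.005
    fpkm_min: float = 1.0
    abs_lfc_min: float = 1.5
    fdr_max: float = 0.05
    force: bool = False

    def validate(self) -> None:
        bad = sorted(set(self.stages) - set(STAGES))
        if bad:
            raise LabfluxError(f"unknown stages: {bad}")
        for name in ("growth_threshold", "fpkm_min", "abs_lfc_min", "fdr_max"):
            if getattr(self, name) <= 0:
                raise LabfluxError(f"threshold {name} must be positive")

    def hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("force")
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


class _Run:
    def __init__(self, config: RunConfig):
        config.validate()
        self.config = config
        self.out = Path(config.out_dir)
        self.header = (
            f"# labflux {__version__}\n# seed={config.seed}\n"
            f"# config_hash={config.hash()}\n"
        )
        self.outputs: dict[str, str] = {}
        self._setup_inputs()

    def _setup_inputs(self) -> None:
        cfg = self.config
        if cfg.model == "mini-lab":
            spec = MiniLabSpec(seed=cfg.seed)
            self.model, self.truth = make_mini_lab(spec)
            classes = mini_lab_nutrient_classes(spec)
            self.panel = mini_lab_panel()
            self.composition = mini_lab_composition(spec)
            carbon = cfg.carbon_exchange or "EX_glc_e"
            self.validation = validation_medium(classes, carbon, cfg.carbon_uptake)
            self.omission_base = omission_medium(classes, "EX_glc_e")
            self.scan_background = carbon_scan_background(classes)
            self.scan_carbons = list(classes.carbons)
            self.carbon = carbon
        else:
            path = Path(cfg.model)
            if not path.exists():
                raise LabfluxError(f"model path does not exist: {path}")
            self.model = load_model(path)
            self.truth = None
            self.composition = None
            if cfg.medium_tsv is None:
                raise LabfluxError("external models require --medium (TSV)")
            self.validation = load_medium_tsv(cfg.medium_tsv)
            self.omission_base = self.validation
            self.scan_background = self.validation
            if cfg.panel_tsv:
                ids = tuple(
                    line.split("\t")[0]
                    for line in Path(cfg.panel_tsv).read_text().splitlines()
                    if line.strip() and not line.startswith("#")
                )
                self.panel = NutrientPanel(ids)
            else:
                self.panel = None
            self.scan_carbons = list(cfg.carbon_exchange.split(",")) if cfg.carbon_exchange else []
            self.carbon = self.scan_carbons[0] if self.scan_carbons else None

    def _write(self, stage: str, name: str, body: str) -> None:
        path = self.out / name
        path.write_text(self.header + body)
        self.outputs[stage] = name

    def stage_fba(self) -> None:
        sol = solve_fba(apply_medium(self.model, self.validation))
        lines = [f"status\t{sol.status}", f"growth_rate\t{sol.growth_rate!r}"]
        for rid, v in sorted(sol.fluxes.items()):
            if abs(v) > 1e-9:
                lines.append(f"flux\t{rid}\t{v:.10g}")
        self._write("fba", "fba.tsv", "\n".join(lines) + "\n")

    def stage_fit_gam(self) -> None:
        cfg = self.config
        if self.composition is None or cfg.measured_growth is None:
            _log("fit-gam: skipped (needs a biomass composition and --measured)")
            return
        gam = fit_gam(self.model, self.composition, self.validation,
                      cfg.measured_growth, bounds=cfg.gam_bounds)
        self._write("fit-gam", "gam.tsv",
                    f"gam_mmol_atp_per_gDCW\t{gam!r}\n"
                    f"measured_growth\t{cfg.measured_growth!r}\n")

    def stage_omit(self) -> None:
        if self.panel is None:
            _log("omit: skipped (no panel)")
            return
        singles = single_omission(self.model, self.panel, self.omission_base)
        doubles = double_omission(self.model, self.panel, self.omission_base,
                                  singles=singles)
        lines = ["omitted\tgrowth_rate\tclassification\tsynthetic_essential"]
        for o in list(singles) + list(doubles):
            lines.append(
                f"{'+'.join(sorted(o.omitted))}\t{o.growth_rate:.6g}\t"
                f"{o.classification}\t{int(o.synthetic_essential)}"
            )
        self._write("omit", "omission.tsv", "\n".join(lines) + "\n")

    def stage_scan(self) -> None:
        if not self.scan_carbons:
            _log("scan: skipped (no carbons)")
            return
        matrix = scan_carbons(self.model, self.scan_carbons,
                              DEFAULT_UPTAKE_LEVELS, self.scan_background)
        lines = ["carbon\t" + "\t".join(f"{u:g}" for u in matrix.uptake_levels)]
        for i, carbon in enumerate(matrix.carbons):
            row = "\t".join(f"{v:.6g}" for v in matrix.growth[i])
            lines.append(f"{carbon}\t{row}")
        self._write("scan", "carbon_scan.tsv", "\n".join(lines) + "\n")

    def stage_reporter(self) -> None:
        cfg = self.config
        if cfg.deg_tsv is not None:
            degs = read_deg_table(cfg.deg_tsv)
        elif cfg.model == "mini-lab":
            degs, _ = make_deg_table(
                self.model,
                ("Starch and sucrose metabolism", "Sugar transport"),
                n_null_genes=100, seed=cfg.seed,
            )
        else:
            _log("reporter: skipped (no DEG table)")
            return
        gene_p = dict(zip(degs["gene"], degs["p"]))
        scores = reporter_scores(self.model, gene_p, seed=cfg.seed)
        table = summarize_routes(scores, self.model, top_n=len(scores))
        body = table.to_csv(sep="\t", index=False)
        self._write("reporter", "reporter.tsv", body)

    def execute(self) -> dict:
        cfg = self.config
        summary_path = self.out / "summary.json"
        if summary_path.exists() and not cfg.force:
            previous = json.loads(summary_path.read_text())
            if previous.get("config_hash") == cfg.hash():
                _log("unchanged config: nothing to do (use --force to re-run)")
                return previous
        self.out.mkdir(parents=True, exist_ok=True)
        if cfg.model == "mini-lab":
            save_model(self.model, self.out / "model.json")
        handlers = {
            "fba": self.stage_fba, "fit-gam": self.stage_fit_gam,
            "omit": self.stage_omit, "scan": self.stage_scan,
            "reporter": self.stage_reporter,
        }
        for stage in STAGES:
            if stage not in cfg.stages:
                continue
            start = time.perf_counter()
            try:
                handlers[stage]()
            except Exception as exc:
                raise LabfluxError(f"stage {stage!r} failed: {exc}") from exc
            _log(f"{stage}: {time.perf_counter() - start:.2f}s")
        summary = {
            "labflux_version": __version__,
            "numpy_version": np.__version__,
            "scipy_version": scipy.__version__,
            "seed": cfg.seed,
            "config_hash": cfg.hash(),
            "config": dataclasses.asdict(cfg),
            "outputs": self.outputs,
        }
        summary_path.write_text(json.dumps(summary, indent=1, default=str, sort_keys=True) + "\n")
        return summary


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the run summary."""
    return _Run(config).execute()
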