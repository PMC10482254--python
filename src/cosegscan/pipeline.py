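"""End-to-end orchestration: simulate (or load) -> scan -> filter -> report.

A run consumes one hierarchical YAML config, executes the stages in the
cascade's order, and writes ``regions.bed``, ``survivors.vcf``,
``trace.tsv``, ``report.tsv`` and ``manifest.json`` into the output
directory.  The manifest snapshots the config, seed and input digests, so
a rerun with the same manifest reproduces ``trace.tsv`` and ``report.tsv``
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from . import io as cio
from .cascade import CascadeConfig, run_cascade, trace_to_frame
from .linkage import MarkerGenotypeMatrix, ScanParams, scan_regions
from .model import DataError
from .report import (
    ExpressionMatrix,
    developmental_window_flag,
    read_annotations,
    write_report,
)
from .simulate import ChromosomeSpec, SimulationConfig, simulate_family

log = logging.getLogger("cosegscan")

PathLike = Union[str, Path]


@dataclass
class InputPaths:
    vcf: Optional[str] = None
    ped: Optional[str] = None
    matrix: Optional[str] = None
    regions: Optional[str] = None
    annotations: Optional[str] = None
    expression: Optional[str] = None


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: Optional[SimulationConfig] = None
    inputs: InputPaths = field(default_factory=InputPaths)
    scan: ScanParams = field(default_factory=ScanParams)
    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    expression_window: tuple = (0.1, 2.4)
    expression_z_threshold: float = 1.0

    @classmethod
    def from_yaml(cls, path: PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        sim = None
        if raw.get("simulate") is not None:
            sim_raw = dict(raw["simulate"])
            if "chromosomes" in sim_raw:
                sim_raw["chromosomes"] = tuple(
                    ChromosomeSpec(str(c[0]), int(c[1]), float(c[2]))
                    for c in sim_raw["chromosomes"]
                )
            if "causal_locus" in sim_raw and isinstance(sim_raw["causal_locus"], list):
                sim_raw["causal_locus"] = (
                    str(sim_raw["causal_locus"][0]),
                    int(sim_raw["causal_locus"][1]),
                )
            for key in ("rare_af_range", "common_af_range", "marker_maf_range"):
                if key in sim_raw:
                    sim_raw[key] = tuple(sim_raw[key])
            sim = SimulationConfig(**sim_raw)
        cascade_raw = dict(raw.get("cascade", {}))
        if "allowed_consequences" in cascade_raw:
            cascade_raw["allowed_consequences"] = frozenset(
                cascade_raw["allowed_consequences"]
            )
        return cls(
            seed=int(raw.get("seed", 0)),
            simulate=sim,
            inputs=InputPaths(**raw.get("inputs", {})),
            scan=ScanParams(**raw.get("scan", {})),
            cascade=CascadeConfig(**cascade_raw),
            expression_window=tuple(raw.get("expression_window", (0.1, 2.4))),
            expression_z_threshold=float(raw.get("expression_z_threshold", 1.0)),
        )

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        if out.get("cascade"):
            out["cascade"]["allowed_consequences"] = sorted(
                self.cascade.allowed_consequences
            )
        if self.simulate is not None:
            out["simulate"]["chromosomes"] = [
                [c.label, c.length_bp, c.map_length_cm]
                for c in self.simulate.chromosomes
            ]
            if isinstance(self.simulate.causal_locus, tuple):
                out["simulate"]["causal_locus"] = list(self.simulate.causal_locus)
        out["expression_window"] = list(self.expression_window)
        return out


def default_config_yaml() -> str:
    """The full default configuration, as YAML (for ``config init``)."""
    cfg = PipelineConfig(simulate=SimulationConfig())
    return yaml.safe_dump(cfg.to_dict(), sort_keys=False)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig, out_dir: PathLike
) -> dict:
    """Run the full pipeline; returns the manifest dictionary.

    With a ``simulate`` block the family is generated; otherwise the
    ``inputs`` paths supply the pedigree, variants and (optionally) marker
    matrix or precomputed regions.  All referenced inputs are checked
    before any stage runs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    input_paths = {
        name: Path(p)
        for name, p in dataclasses.asdict(config.inputs).items()
        if p is not None
    }
    missing = [f"{k}: {v}" for k, v in input_paths.items() if not v.exists()]
    if missing:
        raise DataError("missing inputs: " + "; ".join(missing))
    if config.simulate is None and ("vcf" not in input_paths or "ped" not in input_paths):
        raise DataError("need either a simulate block or vcf+ped inputs")

    manifest: dict = {
        "seed": config.seed,
        "config": config.to_dict(),
        "inputs": {k: _digest(v) for k, v in input_paths.items()},
        "stages": {},
        "timings_s": {},
    }

    def timed(stage):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                manifest["timings_s"][stage] = round(
                    time.perf_counter() - self.t0, 4
                )

        return _Timer()

    # --- acquire inputs ----------------------------------------------------
    truth = None
    with timed("acquire"):
        if config.simulate is not None:
            sim = simulate_family(config.simulate, seed=config.seed)
            pedigree, matrix, records = sim.pedigree, sim.matrix, sim.variants
            truth = sim.truth
            cio.write_ped(pedigree, out / "fam.ped")
            matrix.to_tsv(out / "markers.tsv")
            cio.write_vcf(records, out / "variants.vcf")
            manifest["truth"] = {
                "causal": list(truth.causal_key),
                "carriers": truth.carriers,
            }
        else:
            pedigree = cio.read_ped(input_paths["ped"])
            records = cio.read_vcf(input_paths["vcf"], pedigree)
            matrix = (
                MarkerGenotypeMatrix.from_tsv(input_paths["matrix"])
                if "matrix" in input_paths
                else None
            )
    log.info("inputs: %d variants, %d pedigree members", len(records), len(pedigree))

    # --- region scan -------------------------------------------------------
    with timed("scan"):
        if "regions" in input_paths:
            dialect = (
                "table1_tsv"
                if input_paths["regions"].suffix in (".tsv", ".txt")
                else "bed"
            )
            regions = cio.read_regions(input_paths["regions"], dialect=dialect)
        elif matrix is not None:
            regions = scan_regions(matrix, pedigree, config.scan)
        else:
            raise DataError("no regions input and no marker matrix to scan")
        cio.write_regions(regions, out / "regions.bed", dialect="bed")
    manifest["stages"]["scan"] = {"regions": len(regions)}
    log.info("scan: %d linked regions", len(regions))

    # --- filter cascade ----------------------------------------------------
    with timed("filter"):
        survivors, trace = run_cascade(records, pedigree, regions, config.cascade)
        cio.write_vcf(survivors, out / "survivors.vcf", samples=sorted(
            {s for r in records for s in r.calls}
        ))
        trace_to_frame(trace).to_csv(out / "trace.tsv", sep="\t", index=False)
    funnel = trace.survivors_per_stage()
    manifest["stages"]["filter"] = {
        "input": len(records),
        "funnel": funnel,
        "survivors": len(survivors),
    }
    for stage, count in funnel.items():
        log.info("filter funnel: %-22s %d", stage, count)

    # --- report ------------------------------------------------------------
    with timed("report"):
        annotations = {}
        if "annotations" in input_paths:
            annotations = read_annotations(input_paths["annotations"])
            genes = {r.gene for r in survivors}
            annotations = {g: a for g, a in annotations.items() if g in genes}
        flags = {}
        if "expression" in input_paths:
            expr = ExpressionMatrix.from_tsv(input_paths["expression"])
            for rec in survivors:
                if rec.gene and rec.gene in expr.values.index:
                    flags[rec.gene] = developmental_window_flag(
                        expr,
                        rec.gene,
                        window_years=tuple(config.expression_window),
                        z_threshold=config.expression_z_threshold,
                    )
        write_report(survivors, annotations, flags, out / "report.tsv", trace)
    manifest["stages"]["report"] = {"rows": len(survivors)}
    if truth is not None:
        manifest["stages"]["report"]["causal_recovered"] = any(
            rec.key == truth.causal_key for rec in survivors
        )

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
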