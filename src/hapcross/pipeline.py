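"""End-to-end orchestration: simulate -> QC/blocks -> trace -> scan -> screen.

A run is driven by a single mapping (usually loaded from YAML), executes the
stages in dependency order into an output directory, and records a manifest
with the seed, stage timings and input checksums.  Stages only append files
to the run directory; nothing is mutated after it is written.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .blocks import HaplotypeBlockFinder, QCParams, qc_filter
from .gwas import MixedModelScan
from .origin import OriginClassifier, exotic_specific_blocks
from .screen import RareHaplotypeScreen, class_profiles, consistency_matrix
from .simulate import (
    PlantedScenario,
    SimConfig,
    planted_scenario,
)

__all__ = ["RunConfig", "run", "load_config"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated run settings; see ``load_config`` for the YAML layout."""

    simulate: dict | None = None
    inputs: dict | None = None
    qc: dict = field(default_factory=dict)
    blocks: dict = field(default_factory=dict)
    gwas: dict = field(default_factory=dict)
    screen: dict = field(default_factory=dict)
    target_trait: str = "grain_yield"
    seed: int = 0

    def validate(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError(
                "config must provide exactly one of 'simulate' or 'inputs'")
        if self.inputs is not None:
            for key in ("genotypes", "map", "phenotypes", "crosses",
                        "membership"):
                if key not in self.inputs:
                    raise ValueError(f"inputs.{key} is required")
                if not Path(self.inputs[key]).exists():
                    raise FileNotFoundError(self.inputs[key])


def load_config(path: str | Path) -> RunConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig(**{k: v for k, v in raw.items()
                       if k in RunConfig.__dataclass_fields__})
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: RunConfig, out_dir: str | Path, seed: int | None = None) -> Path:
    """Execute the full pipeline; returns the run directory."""
    config.validate()
    seed = config.seed if seed is None else seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": int(seed), "version": __version__,
                      "stages": {}, "inputs": {}}

    def stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(name, str(exc)) from exc
                manifest["stages"][name] = round(
                    time.perf_counter() - self_inner.t0, 3)
        return _Timer()

    # ---- acquire data ------------------------------------------------
    with stage("data"):
        if config.simulate is not None:
            sim_kwargs = dict(config.simulate)
            planted = sim_kwargs.pop("planted", True)
            sc_kwargs = {k: sim_kwargs.pop(k) for k in
                         ("effect_sd", "donor_crosses", "segment_markers",
                          "residual_var", "polygenic_var")
                         if k in sim_kwargs}
            sim_cfg = SimConfig(**sim_kwargs) if sim_kwargs else None
            if not planted:
                raise ValueError("only planted simulation runs are bundled")
            sc: PlantedScenario = planted_scenario(
                seed, config=sim_cfg, **sc_kwargs)
            G, gmap, traits = sc.genotypes, sc.gmap, sc.phenotypes
            registry, parents = sc.registry, sc.founders
            io.write_genotypes(G, out / "genotypes.hapmap.tsv",
                               genetic_map=gmap)
            io.write_genotypes(parents, out / "parents.hapmap.tsv",
                               genetic_map=gmap)
            io.write_map(gmap, out / "map.tsv")
            io.write_phenotypes(traits, out / "phenotypes.csv")
            io.write_crosses(registry, out / "crosses.csv",
                             out / "membership.csv")
            manifest["planted_markers"] = list(sc.planted_markers)
            manifest["planted_class"] = sc.planted_class
        else:
            paths = config.inputs
            for key in ("genotypes", "map", "phenotypes", "crosses",
                        "membership"):
                manifest["inputs"][key] = _sha256(Path(paths[key]))
            G = io.read_genotypes(paths["genotypes"],
                                  paths.get("format", "hapmap_tsv"))
            gmap = io.read_map(paths["map"])
            traits = io.read_phenotypes(paths["phenotypes"])
            registry = io.read_crosses(paths["crosses"], paths["membership"])
            parents = (io.read_genotypes(paths["parents"],
                                         paths.get("format", "hapmap_tsv"))
                       if "parents" in paths else G)

    # ---- QC ----------------------------------------------------------
    with stage("qc"):
        params = QCParams(**config.qc) if config.qc else QCParams()
        Gf, report = qc_filter(G, gmap, params)
        report.to_csv(out / "qc_report.tsv", sep="\t", index=False)

    # ---- blocks ------------------------------------------------------
    with stage("blocks"):
        finder = HaplotypeBlockFinder(
            ld_window_cm=params.ld_window_cm, **config.blocks)
        blocks = finder.fit(Gf, gmap).blocks_
        io.write_blocks(blocks, out / "blocks.tsv")
        io.write_block_assignments(blocks, out / "block_assignments.csv")

    # ---- origin tracing ---------------------------------------------
    with stage("trace"):
        clf = OriginClassifier().fit(parents, G, registry)
        io.write_origin_matrix(clf.origin_, out / "origin_matrix.csv")
        summary = clf.transform(gmap, registry)
        summary.per_line.to_csv(out / "contribution_per_line.tsv", sep="\t")
        summary.panel.to_frame("value").to_csv(
            out / "contribution_panel.tsv", sep="\t")
        exo_ids = [p for p in registry.exotic_parents()
                   if p in parents.line_ids]
        eli_ids = [p for p in registry.elite_parents()
                   if p in parents.line_ids]
        flagged, imprint = exotic_specific_blocks(
            blocks, parents.subset(lines=exo_ids),
            parents.subset(lines=eli_ids))
        manifest["exotic_specific_blocks"] = [b.name for b in flagged]
        manifest["exotic_imprint_fraction"] = (
            None if np.isnan(imprint) else imprint)
        exotic_flag = {b.name: (b in flagged) for b in blocks}

    # ---- GWAS --------------------------------------------------------
    with stage("gwas"):
        scan = MixedModelScan(**config.gwas).fit(blocks, Gf, traits)
        io.write_associations(scan.results_, out / "associations.tsv")
        consistency_matrix(scan.results_).to_csv(
            out / "consistency_matrix.tsv", sep="\t")

    # ---- screen ------------------------------------------------------
    with stage("screen"):
        profiles = class_profiles(blocks, traits)
        screen = RareHaplotypeScreen(**config.screen)
        screen.fit(profiles, scan.results_, config.target_trait, traits,
                   exotic_specific=exotic_flag)
        pd.DataFrame([asdict(c) for c in screen.candidates_]).to_csv(
            out / "candidates.tsv", sep="\t", index=False)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
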