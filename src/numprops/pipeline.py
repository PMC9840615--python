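"""One-command driver: generate → simulate → extract → prep → analyze.

The pipeline materializes a full synthetic study under one output root::

    out/
      stimuli/<style>/   rendered PNGs + stimlist_<style>.csv
      trials/            simulated trial tables
      features/          extracted feature tables
      behavior/          per-stimulus aggregates + exclusion logs
      results/           correlations.csv, r2_grid.csv, delta_r2_grid.csv,
                         heatmaps, run log
      MANIFEST.json      config, seed, package version, SHA-256 of outputs

Every stage derives its random stream from the single run seed, so two runs
with the same configuration produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .behavior_prep import aggregate, exclude_outliers
from .behavior_sim import sample_participants, simulate_trials
from .features import extract_dataset
from .io import write_table
from .stats import run_validation
from .stimgen import GeometryConfig, generate_dataset, render_dataset

__all__ = ["RunConfig", "pipeline_run"]

log = logging.getLogger("numprops")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run (serializes losslessly)."""

    seed: int = 0
    styles: tuple[str, ...] = ("D1", "D2", "D3", "D4", "D5")
    n_participants: int = 200
    weber_median: float = 0.25
    panel_width: int = 400
    panel_height: int = 400
    total_area: float = 8000.0
    min_gap: float = 2.0
    dispersion: float = 0.3
    paper_mode: bool = True
    out_root: str = "numprops_run"

    def geometry(self) -> GeometryConfig:
        return GeometryConfig(panel_width=self.panel_width,
                              panel_height=self.panel_height,
                              total_area=self.total_area,
                              min_gap=self.min_gap,
                              dispersion=self.dispersion)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["styles"] = list(self.styles)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "styles" in d:
            d["styles"] = tuple(d["styles"])
        return cls(**d)


def _child_seed(seed: int, *key: int) -> int:
    """Deterministic per-stage sub-seed below 2**31."""
    return int(np.random.SeedSequence([seed, *key]).generate_state(1)[0]
               % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def pipeline_run(config: RunConfig) -> Path:
    """Execute all stages; returns the output root.

    Any stage failure raises with the stage name; outputs written so far
    stay on disk for inspection.
    """
    root = Path(config.out_root)
    root.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "version": __version__}
    geometry = config.geometry()
    style_index = {s: i for i, s in enumerate(
        ("D1", "D2", "D3", "D4", "D5"))}
    features, behavior = {}, {}
    try:
        for style in config.styles:
            stage = f"generate[{style}]"
            sseed = _child_seed(config.seed, 1, style_index[style])
            log.info("stage %s (seed %d)", stage, sseed)
            pairs = generate_dataset(style, sseed, geometry)
            pics = root / "stimuli" / style
            stimlist = render_dataset(pairs, pics, seed=sseed)
            write_table(stimlist, root / "stimuli" / f"stimlist_{style}.csv",
                        meta)

            stage = f"extract[{style}]"
            log.info("stage %s", stage)
            feats = extract_dataset(stimlist, pics)
            if feats["seg_mismatch"].any():
                log.warning("%s: %d segmentation mismatches", style,
                            int(feats["seg_mismatch"].sum()))
            write_table(feats, root / "features" / f"features_{style}.csv",
                        meta)
            features[style] = feats

            stage = f"simulate[{style}]"
            bseed = _child_seed(config.seed, 2, style_index[style])
            log.info("stage %s (seed %d)", stage, bseed)
            rng = np.random.default_rng(bseed)
            participants = sample_participants(
                config.n_participants, rng, weber_median=config.weber_median)
            trials = simulate_trials(stimlist, participants, rng)
            write_table(trials, root / "trials" / f"trials_{style}.csv", meta)

            stage = f"prep[{style}]"
            log.info("stage %s", stage)
            kept, excluded = exclude_outliers(trials)
            if len(excluded):
                log.warning("%s: excluded %d participants", style,
                            len(excluded))
            agg = aggregate(kept)
            write_table(agg, root / "behavior" / f"behavior_{style}.csv",
                        meta)
            write_table(excluded,
                        root / "behavior" / f"exclusions_{style}.csv", meta)
            behavior[style] = agg

        stage = "analyze"
        log.info("stage %s", stage)
        paper_mode = config.paper_mode and len(config.styles) == 5
        run_validation(features, behavior, out_dir=root / "results",
                       paper_mode=paper_mode)
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed ({exc}); partial outputs "
            f"remain under {root}") from exc

    manifest = {
        "config": config.to_dict(),
        "version": __version__,
        "hashes": {str(p.relative_to(root)): _sha256(p)
                   for p in sorted(root.rglob("*"))
                   if p.is_file() and p.name != "MANIFEST.json"},
    }
    (root / "MANIFEST.json").write_text(json.dumps(manifest, indent=1,
                                                   sort_keys=True))
    return root
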