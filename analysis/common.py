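"""Shared configuration for the numbered analysis scripts: one default
synthetic study landscape (200×200 km at 1 km, 29 regions, four decadal
epochs) rebuilt deterministically from the seed in every script."""

import argparse
from pathlib import Path

from ecoserv.pipeline import PipelineConfig
from ecoserv.synthetic import LandscapeSpec


def parse_args(description: str) -> argparse.Namespace:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--rows", type=int, default=200)
    ap.add_argument("--cols", type=int, default=200)
    return ap.parse_args()


def default_config(args: argparse.Namespace) -> PipelineConfig:
    spec = LandscapeSpec(grid_rows=args.rows, grid_cols=args.cols,
                         n_regions=29, seed=int(args.seed) % (2**31))
    return PipelineConfig(spec=spec, out_dir=args.out / "pipeline",
                          seed=spec.seed)
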