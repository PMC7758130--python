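"""Shared plumbing for the numbered analysis drivers: locate the synthetic
data directory, load it, and recompute the DE tables the later stages need."""

from __future__ import annotations

import argparse
from pathlib import Path

from mircrosstalk import pipeline, synthdata

DEFAULT_DATA = Path("results/data")
DEFAULT_OUT = Path("results")


def parse_args(description: str, need_data: bool = True) -> argparse.Namespace:
    ap = argparse.ArgumentParser(description=description)
    if need_data:
        ap.add_argument("--data", type=Path, default=DEFAULT_DATA,
                        help="directory written by 01_simulate.py")
    ap.add_argument("--out", type=Path, default=DEFAULT_OUT)
    ap.add_argument("--seed", type=int, default=1)
    return ap.parse_args()


def load_all(data_dir: Path):
    bundle, truth = synthdata.read_study(data_dir)
    ann = synthdata.read_annotations(data_dir)
    return bundle, truth, ann


def de_tables(bundle):
    return pipeline.stage_differential(
        bundle, pipeline.diffexpr.P_CUT, pipeline.diffexpr.LFC_CUT
    )
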