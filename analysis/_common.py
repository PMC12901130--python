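"""Shared argument handling for the numbered analysis drivers.

``--fast`` runs a reduced cohort (5 devices x 4 studies, 80^3 voxels) that
finishes in about a minute; the default reproduces the reference scale
(15 devices x 10 studies, 128^3, 2000 votes) in roughly a quarter hour.
"""

from __future__ import annotations

import argparse

from flairqc.pipeline import RunConfig


def parse_args(description: str) -> tuple[argparse.Namespace, RunConfig]:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--outdir", default="results/run", help="pipeline output directory")
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--fast", action="store_true", help="reduced cohort for quick runs")
    ap.add_argument("--ingest-votes", default=None, help="external vote CSV (03 only)")
    args = ap.parse_args()
    if args.fast:
        cfg = RunConfig(
            n_devices=5, studies_per_device=4, matrix_size=(80, 80, 80),
            voxel_spacing_mm=(2.0, 2.0, 2.0), n_votes=600, seed=args.seed,
        )
    else:
        cfg = RunConfig(seed=args.seed)
    return args, cfg
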