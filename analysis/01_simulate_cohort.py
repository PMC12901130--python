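"""Simulate the multi-scanner 3D-FLAIR phantom cohort.

Writes one NIfTI volume + ground-truth masks + JSON sidecar per study and
a cohort manifest keyed by device, with the latent device quality that
will later drive both the image degradations and the simulated observer.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import parse_args

from flairqc.pipeline import read_table, stage_simulate


def main() -> None:
    args, cfg = parse_args(__doc__)
    manifest_path = stage_simulate(cfg, args.outdir)
    manifest = read_table(manifest_path, cfg.hash())
    per_dev = manifest.groupby("device_id")["latent_quality"].agg(["size", "mean"])
    print(f"simulated {len(manifest)} studies on {per_dev.shape[0]} devices -> {manifest_path}")
    print(per_dev.rename(columns={"size": "n_studies", "mean": "latent_quality"}).round(3))


if __name__ == "__main__":
    main()
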