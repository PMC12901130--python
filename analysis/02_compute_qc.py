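"""Extract the technical QC parameters from every simulated study.

Produces the cohort QC table (contrast, noise, CNR, QI, per-axis
MTF50/MTF10 with edge counts) plus per-study MTF curves as JSON.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import parse_args

from flairqc.pipeline import read_table, stage_qc


def main() -> None:
    args, cfg = parse_args(__doc__)
    qc_path = stage_qc(cfg, args.outdir)
    qc = read_table(qc_path, cfg.hash())
    cols = ["contrast", "noise_sd", "cnr", "qi", "mtf50_fh", "mtf10_ap"]
    print(f"QC complete for {len(qc)} studies -> {qc_path}")
    print(qc.groupby("device_id")[cols].median().round(3))
    flagged = qc[qc["flags"].notna() & (qc["flags"] != "")]
    if len(flagged):
        print(f"{len(flagged)} studies carry flags (partial results)")


if __name__ == "__main__":
    main()
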