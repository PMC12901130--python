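"""Device-level statistics and the quality-vs-QC correlation tables.

Shapiro-Wilk normality of P per device, one-way ANOVA of P across
devices, Tukey HSD pairwise matrix, and R^2 between P and each QC
parameter by study and by device median.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _common import parse_args

from flairqc.pipeline import stage_stats


def main() -> None:
    args, cfg = parse_args(__doc__)
    stats_dir = stage_stats(cfg, args.outdir)
    print(f"statistics written to {stats_dir}")
    anova = pd.read_csv(stats_dir / "anova_by_device.csv", comment="#")
    print(f"device ANOVA: F = {anova['f_statistic'][0]:.2f}, p = {anova['p_value'][0]:.2g}")
    r2 = pd.read_csv(stats_dir / "r2_table.csv", comment="#", index_col=0)
    print("R^2 of estimate P vs QC parameters:")
    print(r2.round(2))


if __name__ == "__main__":
    main()
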