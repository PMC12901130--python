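"""Turn the vote log into per-study quality estimates.

For each study: N_s comparisons won of N_t total, estimate P = N_s/N_t and
its binomial SD = sqrt(P(1-P)/N_t).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import parse_args

from flairqc.pipeline import read_table, stage_rate


def main() -> None:
    args, cfg = parse_args(__doc__)
    ratings_path = stage_rate(cfg, args.outdir)
    ratings = read_table(ratings_path, cfg.hash())
    print(f"rated {len(ratings)} studies -> {ratings_path}")
    print(
        f"comparisons per study: {ratings['n_total'].min()}-{ratings['n_total'].max()} "
        f"(mean {ratings['n_total'].mean():.1f}); max SD {ratings['sd'].max():.3f}"
    )


if __name__ == "__main__":
    main()
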