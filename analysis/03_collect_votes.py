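"""Run the blinded forced-choice session with the simulated observer.

Random pairs of volumes (self-comparison forbidden) are judged by a
logistic observer driven by each study's latent quality; alternatively an
external vote log is ingested with --ingest-votes.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import parse_args

from flairqc.forced_choice import read_votes
from flairqc.pipeline import stage_vote


def main() -> None:
    args, cfg = parse_args(__doc__)
    votes_path = stage_vote(cfg, args.outdir, ingest_votes=args.ingest_votes)
    votes = read_votes(votes_path)
    print(f"collected {len(votes)} forced-choice votes -> {votes_path}")


if __name__ == "__main__":
    main()
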