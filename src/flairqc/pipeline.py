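"""Experiment orchestration: simulate -> qc -> vote -> rate -> stats.

Each stage is idempotent, individually re-runnable, and writes tables that
carry the run's configuration hash in a leading ``#`` comment line; mixing
artifacts produced under different configurations is rejected at read
time.  All randomness derives from the master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort_stats import build_report, build_table, write_report
from .forced_choice import (
    ObserverModel,
    compute_ratings,
    read_votes,
    schedule_pairs,
    simulate_votes,
    write_votes,
)
from .phantom import default_cohort_spec, iter_cohort, read_study, write_study
from .qc_metrics import QCConfig, compute_qc, qc_row

log = logging.getLogger("flairqc")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full experiment.

    Defaults reproduce the reference scale: 15 devices x 10 studies and
    2000 forced-choice votes by one simulated observer.
    """

    n_devices: int = 15
    studies_per_device: int = 10
    matrix_size: tuple[int, int, int] = (128, 128, 128)
    voxel_spacing_mm: tuple[float, float, float] = (1.5, 1.5, 1.5)
    supersample: int = 2
    n_votes: int = 2000
    observer_tau: float = 0.35
    seed: int = 0
    qc: QCConfig = field(default_factory=QCConfig)

    def hash(self) -> str:
        payload = json.dumps(_as_jsonable(self), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (tuple, list)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    return obj


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from a YAML/JSON file plus keyword overrides."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
    data.update({k: v for k, v in overrides.items() if v is not None})
    qc = data.pop("qc", None)
    for key in ("matrix_size", "voxel_spacing_mm"):
        if key in data:
            data[key] = tuple(data[key])
    cfg = RunConfig(**data) if qc is None else RunConfig(**data, qc=_qc_from_dict(qc))
    return cfg


def _qc_from_dict(d: dict) -> QCConfig:
    from .mtf import MTFConfig

    mtf = d.pop("mtf", None)
    return QCConfig(**d) if mtf is None else QCConfig(**d, mtf=MTFConfig(**mtf))


# ---------------------------------------------------------------------------
# hashed-table I/O


def _header(cfg_hash: str, seed: int) -> str:
    return f"# flairqc config_hash={cfg_hash} seed={seed}\n"


def write_table(df: pd.DataFrame, path: Path, cfg_hash: str, seed: int) -> None:
    with open(path, "w") as f:
        f.write(_header(cfg_hash, seed))
        df.to_csv(f, index=False, float_format="%.8g", lineterminator="\n")


def read_table(path: Path, expect_hash: str | None = None, producer: str = "") -> pd.DataFrame:
    if not Path(path).exists():
        hint = f"; run `flairqc {producer}` first" if producer else ""
        raise FileNotFoundError(f"missing upstream table {path}{hint}")
    with open(path) as f:
        first = f.readline()
        if not first.startswith("# flairqc"):
            raise ValueError(f"{path}: missing provenance header")
        found = dict(tok.split("=") for tok in first.split()[2:])
        if expect_hash is not None and found.get("config_hash") != expect_hash:
            raise ValueError(
                f"{path}: config_hash {found.get('config_hash')} does not match "
                f"the current run configuration ({expect_hash}); artifacts from "
                "different runs must not be mixed"
            )
        return pd.read_csv(io.StringIO(f.read()))


def _write_run_manifest(cfg: RunConfig, outdir: Path) -> None:
    manifest = {
        "config": _as_jsonable(cfg),
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "versions": {"flairqc": __version__, "numpy": np.__version__, "pandas": pd.__version__},
    }
    (outdir / "run.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: RunConfig, outdir: str | Path) -> Path:
    """Generate the phantom cohort and its manifest."""
    outdir = Path(outdir)
    studies_dir = outdir / "studies"
    studies_dir.mkdir(parents=True, exist_ok=True)
    _write_run_manifest(cfg, outdir)
    spec = default_cohort_spec(
        n_devices=cfg.n_devices,
        studies_per_device=cfg.studies_per_device,
        seed=cfg.seed,
        matrix_size=cfg.matrix_size,
        voxel_spacing_mm=cfg.voxel_spacing_mm,
        supersample=cfg.supersample,
    )
    rows = []
    for rec in iter_cohort(spec):
        path = write_study(rec.volume, rec.truth, studies_dir, rec.study_id, rec.device_id)
        rows.append(
            {
                "study_id": rec.study_id,
                "device_id": rec.device_id,
                "path": str(path.relative_to(outdir)),
                "latent_quality": rec.truth.latent_quality,
                "true_noise_sd": rec.truth.true_noise_sd,
                "true_contrast": rec.truth.true_contrast,
                "true_blur_sigma_fh": rec.truth.true_blur_sigma_mm[0],
                "true_blur_sigma_ap": rec.truth.true_blur_sigma_mm[1],
                "true_blur_sigma_rl": rec.truth.true_blur_sigma_mm[2],
            }
        )
        log.info("simulated %s", rec.study_id)
    manifest = outdir / "manifest.csv"
    write_table(pd.DataFrame(rows), manifest, cfg.hash(), cfg.seed)
    return manifest


def stage_qc(cfg: RunConfig, outdir: str | Path) -> Path:
    """Run the QC battery on every study in the manifest."""
    outdir = Path(outdir)
    manifest = read_table(outdir / "manifest.csv", cfg.hash(), producer="simulate")
    curves_dir = outdir / "mtf_curves"
    curves_dir.mkdir(exist_ok=True)
    rows = []
    for rec in manifest.itertuples():
        vol, masks, meta = read_study(outdir / rec.path)
        result = compute_qc(vol, masks, cfg.qc)
        rows.append(qc_row(rec.study_id, rec.device_id, result))
        (curves_dir / f"{rec.study_id}_mtf.json").write_text(
            json.dumps(result.mtf_curves, sort_keys=True)
        )
        log.info("qc %s done (flags: %s)", rec.study_id, result.flags or "none")
    qc_path = outdir / "qc.csv"
    write_table(pd.DataFrame(rows), qc_path, cfg.hash(), cfg.seed)
    return qc_path


def stage_vote(
    cfg: RunConfig, outdir: str | Path, ingest_votes: str | Path | None = None
) -> Path:
    """Simulate forced-choice votes (or ingest an external vote log)."""
    outdir = Path(outdir)
    votes_path = outdir / "votes.csv"
    if ingest_votes is not None:
        votes = read_votes(ingest_votes)
        write_votes(votes, votes_path)
        return votes_path
    manifest = read_table(outdir / "manifest.csv", cfg.hash(), producer="simulate")
    ids = manifest["study_id"].tolist()
    quality = dict(zip(manifest["study_id"], manifest["latent_quality"]))
    ss = np.random.SeedSequence((cfg.seed, 0xF0))
    s_pairs, s_obs = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    pairs = schedule_pairs(ids, cfg.n_votes, s_pairs)
    votes = simulate_votes(pairs, ObserverModel(quality, tau=cfg.observer_tau, seed=s_obs))
    with open(votes_path, "w", newline="") as f:
        f.write(_header(cfg.hash(), cfg.seed))
    with open(votes_path, "a", newline="") as f:
        import csv

        w = csv.writer(f)
        w.writerow(["study_left", "study_right", "winner", "observer_id", "vote_index"])
        for v in votes:
            w.writerow([v.study_left, v.study_right, v.winner, v.observer_id, v.vote_index])
    return votes_path


def stage_rate(cfg: RunConfig, outdir: str | Path) -> Path:
    """Compute estimate P and binomial SD per study from the vote log."""
    outdir = Path(outdir)
    votes_file = outdir / "votes.csv"
    if not votes_file.exists():
        raise FileNotFoundError(f"missing vote log {votes_file}; run `flairqc vote` first")
    votes = read_votes(votes_file)
    manifest = read_table(outdir / "manifest.csv", cfg.hash(), producer="simulate")
    rated, unrated = compute_ratings(votes, manifest["study_id"].tolist())
    device_of = dict(zip(manifest["study_id"], manifest["device_id"]))
    df = pd.DataFrame(
        [
            {
                "study_id": r.study_id,
                "device_id": device_of.get(r.study_id, "NA"),
                "n_superior": r.n_superior,
                "n_total": r.n_total,
                "p": r.p,
                "sd": r.sd,
            }
            for r in rated
        ]
    )
    if unrated:
        log.warning("%d unrated studies excluded: %s", len(unrated), unrated)
    ratings_path = outdir / "ratings.csv"
    write_table(df, ratings_path, cfg.hash(), cfg.seed)
    return ratings_path


def stage_stats(cfg: RunConfig, outdir: str | Path) -> Path:
    """Cohort statistics from ratings + QC tables."""
    outdir = Path(outdir)
    ratings = read_table(outdir / "ratings.csv", cfg.hash(), producer="rate")
    qc = read_table(outdir / "qc.csv", cfg.hash(), producer="qc")
    table = build_table(ratings, qc)
    report = build_report(table)
    stats_dir = outdir / "stats"
    write_report(report, stats_dir, header=_header(cfg.hash(), cfg.seed))
    return stats_dir


def run_all(cfg: RunConfig, outdir: str | Path) -> Path:
    """Full experiment in stage order."""
    stage_simulate(cfg, outdir)
    stage_qc(cfg, outdir)
    stage_vote(cfg, outdir)
    stage_rate(cfg, outdir)
    return stage_stats(cfg, outdir)
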