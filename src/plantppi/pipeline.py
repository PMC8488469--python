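"""End-to-end orchestration and the command-line interface.

Chains profiles -> condensation -> feature transform -> SVD reduction ->
pair assembly -> classification -> cross-validated evaluation behind one
flat configuration, with full seed propagation so a run is a pure
function of its inputs and config.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import click
import numpy as np
import pandas as pd

from . import evaluation, io_formats, synthetic
from .io_formats import Profile, ProteinRecord
from .model import DNNConfig
from .profiles import PsiBlastConfig, logistic_normalize, run_psiblast
from .synthetic import SynthConfig
from .transforms import extract_descriptor

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat configuration binding every stage's documented defaults."""

    features_kind: str = "dht"
    features_energy: str = "modulus"
    features_ac_lag: int = 5
    condense_mode: str = "crossproduct"
    profile_normalize: bool = False
    svd_k: int = 300
    svd_paper_mode: bool = False
    pair_symmetrize: bool = False
    classifier: str = "dnn"
    knn_k: int = 5
    rf_trees: int = 500
    cv_folds: int = 5
    cv_seed: int = 7
    cv_stratified: bool = True
    dnn: DNNConfig = field(default_factory=DNNConfig)
    synthetic: SynthConfig = field(default_factory=SynthConfig)

    _KEYMAP = {
        "features.kind": ("features_kind", str),
        "features.energy": ("features_energy", str),
        "features.ac_lag": ("features_ac_lag", int),
        "condense.mode": ("condense_mode", str),
        "profile.normalize": ("profile_normalize", lambda s: s.lower() == "true"),
        "svd.k": ("svd_k", int),
        "svd.paper_mode": ("svd_paper_mode", lambda s: s.lower() == "true"),
        "pair.symmetrize": ("pair_symmetrize", lambda s: s.lower() == "true"),
        "classifier": ("classifier", str),
        "baseline.knn.k": ("knn_k", int),
        "baseline.rf.trees": ("rf_trees", int),
        "cv.k": ("cv_folds", int),
        "cv.seed": ("cv_seed", int),
        "cv.stratified": ("cv_stratified", lambda s: s.lower() == "true"),
    }
    _DNN_KEYS = {
        "dnn.architecture": ("architecture", str),
        "dnn.hidden": ("hidden", lambda s: tuple(int(x) for x in s.split(","))),
        "dnn.dropout": ("dropout", float),
        "dnn.learning_rate": ("learning_rate", float),
        "dnn.epochs": ("epochs", int),
        "dnn.batch_size": ("batch_size", int),
        "dnn.seed": ("seed", int),
    }

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a flat ``section.key = value`` text config."""
        cfg = cls()
        dnn_kwargs: dict = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key in cls._KEYMAP:
                attr, conv = cls._KEYMAP[key]
                setattr(cfg, attr, conv(raw))
            elif key in cls._DNN_KEYS:
                attr, conv = cls._DNN_KEYS[key]
                dnn_kwargs[attr] = conv(raw)
            else:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        if dnn_kwargs:
            cfg.dnn = DNNConfig(**{**dataclasses.asdict(cfg.dnn), **dnn_kwargs})
        return cfg


def run_features(
    records: list[ProteinRecord],
    profiles: Mapping[str, Profile],
    cfg: RunConfig,
    cache_path: str | Path | None = None,
) -> pd.DataFrame:
    """Per-protein descriptor table (rows keyed by protein id).

    When ``cache_path`` exists it is loaded instead of recomputing; the
    cache round-trips at full float precision so cached and cold runs
    are identical.
    """
    ids = [r.id for r in records]
    if cache_path is not None and Path(cache_path).exists():
        table = pd.read_csv(cache_path, index_col=0, float_precision="round_trip")
        if list(table.index) == ids:
            logger.info("feature cache hit: %s", cache_path)
            return table
    missing = [r.id for r in records if r.id not in profiles]
    if missing:
        raise ValueError(f"missing profiles for: {missing}")
    rows = []
    for rec in records:
        profile = profiles[rec.id]
        if cfg.profile_normalize:
            profile = logistic_normalize(profile)
        desc = extract_descriptor(
            profile,
            kind=cfg.features_kind,
            condense_mode=cfg.condense_mode,
            energy=cfg.features_energy,
            ac_lag=cfg.features_ac_lag,
        )
        rows.append(desc.values)
    table = pd.DataFrame(np.array(rows), index=ids)
    logger.info(
        "features: %d proteins x %d dims (kind=%s)",
        table.shape[0], table.shape[1], cfg.features_kind,
    )
    if cache_path is not None:
        table.to_csv(cache_path, float_format="%.17g")
    return table


def _load_dataset(
    cfg: RunConfig,
    fasta: str | None,
    pairs_path: str | None,
    pssm_dir: str | None,
) -> tuple[list[ProteinRecord], dict[str, Profile], list]:
    if fasta is None:
        return synthetic.gen_dataset(cfg.synthetic)
    records = io_formats.read_fasta(fasta)
    pairs = io_formats.read_pair_list(pairs_path)
    profiles = {
        r.id: io_formats.parse_ascii_pssm(Path(pssm_dir) / f"{r.id}.pssm")
        for r in records
    }
    return records, profiles, pairs


def run_experiment(
    cfg: RunConfig,
    fasta: str | None = None,
    pairs_path: str | None = None,
    pssm_dir: str | None = None,
    out_dir: str | Path | None = None,
) -> evaluation.CVReport:
    """Full cross-validated experiment; synthetic data unless paths given.

    Writes ``report.txt`` and per-fold ROC CSVs under ``out_dir`` when
    provided.
    """
    records, profiles, pairs = _load_dataset(cfg, fasta, pairs_path, pssm_dir)
    table = run_features(records, profiles, cfg)
    features = {pid: table.loc[pid].to_numpy() for pid in table.index}
    report = evaluation.run_cv(
        features,
        pairs,
        classifier=cfg.classifier,
        svd_k=cfg.svd_k,
        folds=cfg.cv_folds,
        seed=cfg.cv_seed,
        stratified=cfg.cv_stratified,
        paper_mode=cfg.svd_paper_mode,
        symmetrize=cfg.pair_symmetrize,
        dnn=cfg.dnn,
        baseline_params={"k": cfg.knn_k, "trees": cfg.rf_trees},
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io_formats.write_report(report, out / "report.txt")
        for i, points in enumerate(report.roc, start=1):
            io_formats.write_roc(points, out / f"roc_fold{i}.csv")
    return report


# ---------------------------------------------------------------------------
# CLI


@click.group()
def main() -> None:
    """Sequence-based plant protein-protein interaction prediction."""
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")


def _cfg_from(config: str | None, seed: int | None) -> RunConfig:
    cfg = RunConfig.from_file(config) if config else RunConfig()
    if seed is not None:
        cfg.cv_seed = seed
        cfg.synthetic = dataclasses.replace(cfg.synthetic, seed=seed)
    return cfg


@main.command()
@click.option("--out", required=True, type=click.Path(), help="output directory")
@click.option("--seed", type=int, default=7, show_default=True)
@click.option("--n-proteins", type=int, default=60, show_default=True)
@click.option("--n-pos", type=int, default=150, show_default=True)
@click.option("--n-neg", type=int, default=150, show_default=True)
@click.option("--strength", type=float, default=2.0, show_default=True)
def simulate(out, seed, n_proteins, n_pos, n_neg, strength):
    """Write a synthetic dataset: FASTA, pair TSV and ASCII PSSM fixtures."""
    cfg = SynthConfig(
        n_proteins=n_proteins, n_pos=n_pos, n_neg=n_neg,
        signal_strength=strength, seed=seed,
    )
    records, profiles, pairs = synthetic.gen_dataset(cfg)
    out = Path(out)
    (out / "pssm").mkdir(parents=True, exist_ok=True)
    io_formats.write_fasta(records, out / "proteins.fasta")
    io_formats.write_pair_list(pairs, out / "pairs.tsv")
    for rec in records:
        synthetic.emit_ascii_pssm(profiles[rec.id], rec, out / "pssm" / f"{rec.id}.pssm")
    click.echo(f"wrote {len(records)} proteins and {len(pairs)} pairs to {out}")


@main.command()
@click.option("--fasta", required=True, type=click.Path(exists=True))
@click.option("--db", required=True, help="formatted protein database path")
@click.option("--out-dir", required=True, type=click.Path())
@click.option("--executable", default="psiblast", show_default=True)
@click.option("--iterations", type=int, default=3, show_default=True)
@click.option("--evalue", type=float, default=0.001, show_default=True)
def pssm(fasta, db, out_dir, executable, iterations, evalue):
    """Run PSI-BLAST for every FASTA record, writing ASCII PSSMs."""
    records = io_formats.read_fasta(fasta)
    pcfg = PsiBlastConfig(
        db_path=db, iterations=iterations, evalue=evalue, executable=executable
    )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in records:
        profile = run_psiblast(rec, pcfg)
        synthetic.emit_ascii_pssm(
            Profile(np.round(profile.values), source=profile.source),
            rec, out / f"{rec.id}.pssm",
        )
    click.echo(f"wrote {len(records)} PSSMs to {out}")


@main.command()
@click.option("--fasta", required=True, type=click.Path(exists=True))
@click.option("--pssm-dir", required=True, type=click.Path(exists=True))
@click.option("--out", required=True, type=click.Path())
@click.option("--kind", default="dht", show_default=True,
              type=click.Choice(["dht", "dct", "fft", "dwt", "ac"]))
@click.option("--config", type=click.Path(exists=True))
def features(fasta, pssm_dir, out, kind, config):
    """Compute the per-protein descriptor table as CSV."""
    cfg = _cfg_from(config, None)
    cfg.features_kind = kind
    records = io_formats.read_fasta(fasta)
    profiles = {
        r.id: io_formats.parse_ascii_pssm(Path(pssm_dir) / f"{r.id}.pssm")
        for r in records
    }
    table = run_features(records, profiles, cfg, cache_path=out)
    click.echo(f"wrote {table.shape[0]} x {table.shape[1]} feature table to {out}")


@main.command()
@click.option("--fasta", type=click.Path(exists=True))
@click.option("--pairs", "pairs_path", type=click.Path(exists=True))
@click.option("--pssm-dir", type=click.Path(exists=True))
@click.option("--out", required=True, type=click.Path())
@click.option("--config", type=click.Path(exists=True))
@click.option("--seed", type=int, default=None)
@click.option("--classifier", default="dnn", show_default=True,
              type=click.Choice(["dnn", "knn", "rf"]))
def train(fasta, pairs_path, pssm_dir, out, config, seed, classifier):
    """Train on the full dataset and serialise the model (DNN only)."""
    from .model import save_model, train_dnn
    from .reduction import fit_projector, project

    cfg = _cfg_from(config, seed)
    cfg.classifier = classifier
    records, profiles, pairs = _load_dataset(cfg, fasta, pairs_path, pssm_dir)
    table = run_features(records, profiles, cfg)
    feats = {pid: table.loc[pid].to_numpy() for pid in table.index}
    projector = fit_projector(table.to_numpy(), k=cfg.svd_k)
    reduced = {pid: project(projector, v) for pid, v in feats.items()}
    X = np.array(
        [np.concatenate([reduced[p.id_a], reduced[p.id_b]]) for p in pairs]
    )
    y = np.array([p.label for p in pairs])
    if classifier != "dnn":
        raise click.UsageError("model serialisation is only supported for the DNN")
    state = train_dnn(X, y, dataclasses.replace(cfg.dnn, seed=cfg.cv_seed))
    save_model(state, out)
    click.echo(f"trained on {len(pairs)} pairs; final loss {state.loss_trace[-1]:.4f}")


@main.command()
@click.option("--fasta", type=click.Path(exists=True))
@click.option("--pairs", "pairs_path", type=click.Path(exists=True))
@click.option("--pssm-dir", type=click.Path(exists=True))
@click.option("--out", required=True, type=click.Path())
@click.option("--config", type=click.Path(exists=True))
@click.option("--seed", type=int, default=None)
@click.option("--classifier", default="dnn", show_default=True,
              type=click.Choice(["dnn", "knn", "rf"]))
@click.option("--features", "features_kind", default="dht", show_default=True,
              type=click.Choice(["dht", "dct", "fft", "dwt", "ac"]))
@click.option("--svd-k", type=int, default=None)
@click.option("--paper-mode", is_flag=True, help="fit the SVD on all data, not per fold")
def evaluate(fasta, pairs_path, pssm_dir, out, config, seed, classifier,
             features_kind, svd_k, paper_mode):
    """Five-fold cross-validation; writes report.txt and ROC CSVs."""
    cfg = _cfg_from(config, seed)
    cfg.classifier = classifier
    cfg.features_kind = features_kind
    if svd_k is not None:
        cfg.svd_k = svd_k
    if paper_mode:
        cfg.svd_paper_mode = True
    report = run_experiment(cfg, fasta, pairs_path, pssm_dir, out_dir=out)
    mean, sd = report.mean, report.sd
    click.echo(
        f"mean Acc {100 * mean['acc']:.2f} ± {100 * sd['acc']:.2f} %, "
        f"AUC {mean['auc']:.4f} ± {sd['auc']:.4f}"
    )


@main.command()
@click.option("--out", required=True, type=click.Path())
@click.option("--seed", type=int, default=7, show_default=True)
@click.option("--classifiers", default="dnn,knn,rf", show_default=True)
@click.option("--descriptors", default="dht,dct,fft,dwt,ac", show_default=True)
def compare(out, seed, classifiers, descriptors):
    """Descriptor x classifier grid on the synthetic dataset."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    for kind in descriptors.split(","):
        for clf in classifiers.split(","):
            cfg = _cfg_from(None, seed)
            cfg.features_kind = kind
            cfg.classifier = clf
            report = run_experiment(cfg)
            io_formats.write_report(report, out / f"report_{kind}_{clf}.txt")
            click.echo(
                f"{kind:>4} + {clf:<3}: AUC {report.mean['auc']:.4f} "
                f"± {report.sd['auc']:.4f}"
            )


if __name__ == "__main__":
    main()
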