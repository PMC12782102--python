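"""End-to-end orchestration: dataset -> splits -> features -> model -> report.

The full procedure mirrors the method's architecture diagram: cluster-aware
6:2:2 splitting, negative down-sampling of training residues, per-branch
feature construction (embedding + PCA, AAindex windows, PSSM
standardization) with all statistics fitted on the training split only,
simulated-annealing accession selection, attention-fusion model training,
and residue-level evaluation on the untouched class distribution.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import io_formats as io
from . import model as mdl
from . import selection as sel
from .evaluation import EvalReport, evaluate_scores

log = logging.getLogger("slimfuse")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything a pipeline run needs; defaults follow the method's values."""

    # dataset paths (resolved against data_dir when relative)
    data_dir: str = "."
    fasta: str = "sequences.fasta"
    labels: str = "labels.tsv"
    pssm_dir: str = "pssm"
    aaindex: str = "aaindex.txt"
    clusters: str = "clusters.clstr"

    # feature settings
    k: int = 128
    windows: tuple[int, ...] = (7, 11)
    top_k: int = 54
    scale_aaindex: bool = True
    blocks: tuple[str, ...] = ("seqfea", "pssm", "phy")
    backend: str = "synthetic"
    backend_dim: int = 1024
    backend_seed: int = 7
    backend_signal: float = 1.0

    # selection settings
    accessions_file: str | None = None
    sa: sel.SAConfig = field(default_factory=sel.SAConfig)
    sweep_windows: tuple[int, ...] = (5, 7, 9, 11, 21, 41)
    subset_sizes: tuple[int, ...] = (10, 20)
    sa_max_residues: int = 2000

    # training / evaluation
    train: mdl.TrainConfig = field(default_factory=mdl.TrainConfig)
    variant: str = "matmul"
    heads: int = 4
    eval_targets: tuple[float, ...] = (0.2, 0.3, 0.4)
    split_ratio: tuple[float, float, float] = (6, 2, 2)
    seed: int = 0

    def path(self, name: str) -> Path:
        p = Path(getattr(self, name))
        return p if p.is_absolute() else Path(self.data_dir) / p

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("windows", "blocks", "sweep_windows", "subset_sizes",
                    "eval_targets", "split_ratio"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sa" in d and isinstance(d["sa"], dict):
            d["sa"] = sel.SAConfig(**d["sa"])
        if "train" in d and isinstance(d["train"], dict):
            d["train"] = mdl.TrainConfig(**d["train"])
        for key in ("windows", "blocks", "sweep_windows", "subset_sizes",
                    "eval_targets", "split_ratio"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# dataset loading
# ---------------------------------------------------------------------------


@dataclass
class Dataset:
    records: list[io.ProteinRecord]
    clusters: io.ClusterAssignment
    profiles: dict[str, io.PSSMProfile]
    table: io.AAindexTable


def load_dataset(cfg: RunConfig) -> Dataset:
    records = io.read_fasta(cfg.path("fasta"))
    records = io.read_labels(cfg.path("labels"), records)
    clusters = io.read_cdhit_clusters(cfg.path("clusters"))
    table = io.read_aaindex1(cfg.path("aaindex"))
    profiles: dict[str, io.PSSMProfile] = {}
    pssm_dir = cfg.path("pssm_dir")
    for rec in records:
        p = pssm_dir / f"{rec.id}.pssm"
        if not p.exists():
            raise FileNotFoundError(f"missing PSSM profile for sequence {rec.id!r}: {p}")
        profiles[rec.id] = io.read_ascii_pssm(p, seq_id=rec.id)
    return Dataset(records, clusters, profiles, table)


# ---------------------------------------------------------------------------
# feature building
# ---------------------------------------------------------------------------


@dataclass
class FeatureBuilder:
    """Fitted feature transformers shared by training and inference."""

    backend: feat.EmbeddingBackend
    table: io.AAindexTable
    selected: list[str]
    windows: tuple[int, ...] = (7, 11)
    scale: bool = True
    blocks: tuple[str, ...] = ("seqfea", "pssm", "phy")
    pca: feat.PCAModel | None = None
    normalizer: feat.PSSMNormalizer | None = None

    def fit(
        self,
        train_records: list[io.ProteinRecord],
        train_profiles: dict[str, io.PSSMProfile],
        k: int = 128,
    ) -> "FeatureBuilder":
        if "seqfea" in self.blocks:
            mats = feat.embed_sequences(self.backend, train_records)
            self.pca = feat.fit_pca(mats, k=k)
            log.info(
                "PCA fitted: %d -> %d dims, top-5 explained variance %s",
                self.pca.dim, self.pca.k,
                np.round(self.pca.explained_variance[:5], 3).tolist(),
            )
        if "pssm" in self.blocks:
            self.normalizer = feat.fit_pssm_normalizer(
                [train_profiles[r.id] for r in train_records]
            )
        return self

    def build(
        self,
        records: list[io.ProteinRecord],
        profiles: dict[str, io.PSSMProfile],
        loss_masks: dict[str, np.ndarray] | None = None,
    ) -> list[mdl.SequenceFeatures]:
        wspecs = tuple(feat.WindowSpec(N) for N in self.windows)
        out = []
        for rec in records:
            blocks: dict[str, np.ndarray] = {}
            if "seqfea" in self.blocks:
                emb = feat.embed_sequences(self.backend, [rec])[0]
                blocks["seqfea"] = feat.apply_pca(self.pca, emb, rec.id).values
            if "pssm" in self.blocks:
                if rec.id not in profiles:
                    raise KeyError(f"no PSSM profile for {rec.id!r}")
                blocks["pssm"] = feat.build_pssm_features(
                    profiles[rec.id], self.normalizer
                ).values
            if "phy" in self.blocks:
                blocks["phy"] = feat.build_phyfea(
                    rec.seq, self.table, self.selected, wspecs,
                    scale=self.scale, seq_id=rec.id,
                ).values
            out.append(
                mdl.SequenceFeatures(
                    seq_id=rec.id,
                    blocks=blocks,
                    labels=rec.labels,
                    loss_idx=None if loss_masks is None else loss_masks.get(
                        rec.id, np.array([], dtype=np.int64)
                    ),
                )
            )
        return out

    # -- persistence --------------------------------------------------------

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = {
            "windows": list(self.windows),
            "scale": self.scale,
            "blocks": list(self.blocks),
            "backend": {
                "name": self.backend.name,
                "dim": self.backend.dim,
                "seed": getattr(self.backend, "seed", None),
                "context_weight": getattr(self.backend, "context_weight", None),
                "signal_strength": getattr(self.backend, "signal_strength", None),
            },
        }
        (out / "builder.json").write_text(json.dumps(meta, indent=2))
        sel.write_accessions(self.selected, out / "accessions.txt")
        from .synthetic import write_aaindex1

        write_aaindex1(self.table, out / "aaindex.txt")
        if self.pca is not None:
            np.savez(
                out / "pca.npz",
                mean=self.pca.mean,
                components=self.pca.components,
                explained_variance=self.pca.explained_variance,
            )
        if self.normalizer is not None:
            (out / "pssm_norm.json").write_text(
                json.dumps(
                    {"mean": self.normalizer.mean.tolist(),
                     "std": self.normalizer.std.tolist()}
                )
            )

    @classmethod
    def load(cls, in_dir: str | Path) -> "FeatureBuilder":
        in_dir = Path(in_dir)
        meta = json.loads((in_dir / "builder.json").read_text())
        b = meta["backend"]
        if b["name"] != "synthetic":
            backend = feat.get_backend(b["name"])
        else:
            backend = feat.get_backend(
                "synthetic", dim=b["dim"], seed=b["seed"],
                context_weight=b["context_weight"],
                signal_strength=b["signal_strength"],
            )
        table = io.read_aaindex1(in_dir / "aaindex.txt")
        selected = sel.read_accessions(in_dir / "accessions.txt")
        builder = cls(
            backend=backend, table=table, selected=selected,
            windows=tuple(meta["windows"]), scale=meta["scale"],
            blocks=tuple(meta["blocks"]),
        )
        pca_path = in_dir / "pca.npz"
        if pca_path.exists():
            d = np.load(pca_path)
            builder.pca = feat.PCAModel(
                mean=d["mean"], components=d["components"],
                explained_variance=d["explained_variance"],
            )
        norm_path = in_dir / "pssm_norm.json"
        if norm_path.exists():
            d = json.loads(norm_path.read_text())
            builder.normalizer = feat.PSSMNormalizer(
                mean=np.array(d["mean"]), std=np.array(d["std"])
            )
        return builder


# ---------------------------------------------------------------------------
# pipeline commands
# ---------------------------------------------------------------------------


def _make_backend(cfg: RunConfig) -> feat.EmbeddingBackend:
    if cfg.backend == "synthetic":
        return feat.get_backend(
            "synthetic", dim=cfg.backend_dim, seed=cfg.backend_seed,
            signal_strength=cfg.backend_signal,
        )
    return feat.get_backend(cfg.backend)


def select_accessions(
    cfg: RunConfig, dataset: Dataset, train_records: list[io.ProteinRecord]
) -> tuple[list[str], dict]:
    """SA sweep over (window, subset size) pairs + frequency consensus."""
    results, tally = sel.run_window_sweep(
        train_records, dataset.table,
        windows=cfg.sweep_windows, subset_sizes=cfg.subset_sizes,
        config=cfg.sa, top_k=min(cfg.top_k, len(dataset.table)),
        max_residues=cfg.sa_max_residues, scale=cfg.scale_aaindex,
    )
    summary = {
        f"N={N},size={s}": round(res.best_score, 4)
        for (N, s), res in results.items()
    }
    log.info("SA sweep best scores: %s", summary)
    top_k = min(cfg.top_k, len(tally.counts))
    selected = tally.selected[:top_k]
    return selected, summary


def train_pipeline(cfg: RunConfig, out_dir: str | Path) -> tuple[Path, list[dict]]:
    """Run the full training procedure and persist the model directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset = load_dataset(cfg)

    splits = io.assign_splits(dataset.clusters, ratio=cfg.split_ratio, seed=cfg.seed)
    io.write_splits(splits, out / "splits.tsv")
    train_records = splits.subset(dataset.records, "train")
    val_records = splits.subset(dataset.records, "validation")
    log.info(
        "split sizes: train=%d validation=%d test=%d",
        len(train_records), len(val_records),
        len(splits.subset(dataset.records, "test")),
    )
    loss_masks = io.downsample_negatives(train_records, seed=cfg.seed)

    if cfg.accessions_file:
        selected = sel.read_accessions(cfg.path("accessions_file"))
        sweep_summary: dict = {}
    elif "phy" in cfg.blocks:
        selected, sweep_summary = select_accessions(cfg, dataset, train_records)
    else:
        selected, sweep_summary = [], {}

    # the fused width must divide the head count; drop the lowest-ranked
    # consensus accessions if an undersized pool left it indivisible
    if "phy" in cfg.blocks and selected:
        other = (cfg.k if "seqfea" in cfg.blocks else 0) + (
            20 if "pssm" in cfg.blocks else 0
        )
        while selected and (other + len(selected) * len(cfg.windows)) % cfg.heads:
            dropped = selected.pop()
            log.info("dropping accession %s to align fused width with heads", dropped)

    builder = FeatureBuilder(
        backend=_make_backend(cfg), table=dataset.table, selected=selected,
        windows=cfg.windows, scale=cfg.scale_aaindex, blocks=cfg.blocks,
    ).fit(train_records, dataset.profiles, k=cfg.k)

    train_feats = builder.build(train_records, dataset.profiles, loss_masks)
    val_feats = builder.build(val_records, dataset.profiles)

    dims = {name: train_feats[0].blocks[name].shape[1] for name in cfg.blocks}
    bundle = mdl.init_bundle(
        seqfea_dim=dims.get("seqfea", 0), phy_dim=dims.get("phy", 0),
        pssm_dim=dims.get("pssm", 0), heads=cfg.heads, variant=cfg.variant,
        config=cfg.train, blocks=cfg.blocks,
    )
    bundle.meta["sweep_summary"] = sweep_summary
    bundle, history = mdl.train(bundle, train_feats, val_feats or None, cfg.train)
    for row in history:
        log.info(
            "epoch %3d  train_loss %.4f  val_auc %.4f",
            row["epoch"], row["train_loss"], row["val_auc"],
        )

    bundle.save(out)
    builder.save(out)
    cfg.save(out / "config.yaml")
    pd.DataFrame(history).to_csv(out / "history.csv", index=False)
    return out, history


def load_model_dir(model_dir: str | Path) -> tuple[mdl.ModelBundle, FeatureBuilder]:
    return mdl.ModelBundle.load(model_dir), FeatureBuilder.load(model_dir)


def predict_records(
    model_dir: str | Path,
    records: list[io.ProteinRecord],
    profiles: dict[str, io.PSSMProfile],
) -> dict[str, np.ndarray]:
    bundle, builder = load_model_dir(model_dir)
    feats = builder.build(records, profiles)
    return {f.seq_id: mdl.predict(bundle, f) for f in feats}


def evaluate_pipeline(
    model_dir: str | Path,
    cfg: RunConfig,
    split: str = "test",
    targets: tuple[float, ...] | None = None,
    allow_train: bool = False,
) -> EvalReport:
    """Score a data split with a trained model directory.

    Training-split evaluation is refused unless ``allow_train`` because the
    balanced training distribution gives optimistically biased metrics.
    """
    if split == "train" and not allow_train:
        raise ValueError(
            "refusing to evaluate on the balanced training split; "
            "pass allow_train=True to override"
        )
    dataset = load_dataset(cfg)
    model_dir = Path(model_dir)
    splits = io.read_splits(model_dir / "splits.tsv")
    records = splits.subset(dataset.records, split)
    if not records:
        raise ValueError(f"split {split!r} holds no sequences")
    preds = predict_records(model_dir, records, dataset.profiles)
    scores = np.concatenate([preds[r.id] for r in records])
    labels = np.concatenate([r.labels for r in records])
    return evaluate_scores(scores, labels, targets or cfg.eval_targets)
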