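"""End-to-end orchestration: embed -> train -> predict -> evaluate.

Each stage reads/writes plain-text artifacts under the run's output
directory and records a manifest (config hash, gene-index checksum, stage
parameters) so downstream stages can detect stale upstream outputs, and a
run can be reproduced bit-for-bit from its manifest. Embeddings are content-
addressed by the hash of the parameters that determine them, since they are
the expensive stage and get reused across classifier sweeps.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cascade import (
    CascadeConfig,
    CascadeModel,
    fit_cascade,
    predict_proba,
    threshold_predict,
)
from .diffusion import FeatureMatrix, concat_embeddings, embed_network
from .evaluation import EvalReport, cross_validate
from .network_io import (
    LabelMatrix,
    gene_index_checksum,
    load_annotations,
    load_gene_index,
    load_network,
    symmetrize,
)

__all__ = ["RunConfig", "run_embed", "run_train", "run_predict", "run_evaluate"]


class StaleArtifactError(RuntimeError):
    """An upstream artifact no longer matches the current configuration."""


@dataclass
class RunConfig:
    """Everything a pipeline run needs; serialisable to/from YAML."""

    network_files: list[str]
    gene_index: str
    annotations: str
    labels: list[str] = field(default_factory=list)
    alpha: float = 0.5
    d: int = 100
    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    folds: int = 5
    threshold: float = 0.5
    seed: int = 0
    out_dir: str = "difforest_run"

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if isinstance(self.cascade, dict):
            self.cascade = CascadeConfig(**self.cascade)

    def validate_paths(self) -> None:
        missing = [
            p
            for p in [*self.network_files, self.gene_index, self.annotations]
            if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def embed_hash(self) -> str:
        """Content hash of everything that determines the feature matrix."""
        key = json.dumps(
            {
                "networks": [Path(p).name for p in self.network_files],
                "alpha": self.alpha,
                "d": self.d,
            },
            sort_keys=True,
        )
        return hashlib.sha256(key.encode()).hexdigest()[:16]


def _label_set(cfg: RunConfig, id_map) -> list[str]:
    if cfg.labels:
        return cfg.labels
    seen: dict[str, None] = {}
    for line in Path(cfg.annotations).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            seen.setdefault(line.split()[1])
    return sorted(seen)


def run_embed(cfg: RunConfig) -> FeatureMatrix:
    """Embed every network and write the concatenated features + manifest."""
    cfg.validate_paths()
    id_map = load_gene_index(cfg.gene_index)
    embeddings = []
    for path in cfg.network_files:
        g = symmetrize(load_network(path, id_map))
        embeddings.append(embed_network(g, alpha=cfg.alpha, d=cfg.d))
    feats = concat_embeddings(embeddings)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes = sorted(id_map, key=id_map.__getitem__)
    header = "#gene\t" + "\t".join(
        f"{name}_dim{i}"
        for name, w in zip(feats.network_order, feats.block_widths)
        for i in range(w)
    )
    lines = [header] + [
        gid + "\t" + "\t".join(f"{v:.10g}" for v in row)
        for gid, row in zip(genes, feats.X_full)
    ]
    (out / "features.tsv").write_text("\n".join(lines) + "\n")
    manifest = {
        "stage": "embed",
        "embed_hash": cfg.embed_hash(),
        "gene_index_sha256": gene_index_checksum(id_map),
        "alpha": cfg.alpha,
        "d": cfg.d,
        "networks": feats.network_order,
        "block_widths": feats.block_widths,
    }
    (out / "embed_manifest.json").write_text(json.dumps(manifest, indent=2))
    return feats


def _load_features(cfg: RunConfig) -> tuple[np.ndarray, list[str]]:
    out = Path(cfg.out_dir)
    manifest = json.loads((out / "embed_manifest.json").read_text())
    if manifest["embed_hash"] != cfg.embed_hash():
        raise StaleArtifactError(
            "embedding manifest does not match the current configuration; "
            "rerun the embed stage"
        )
    id_map = load_gene_index(cfg.gene_index)
    if manifest["gene_index_sha256"] != gene_index_checksum(id_map):
        raise StaleArtifactError("gene index changed since embeddings were built")
    genes: list[str] = []
    rows: list[list[float]] = []
    for line in (out / "features.tsv").read_text().splitlines():
        if line.startswith("#"):
            continue
        parts = line.split("\t")
        genes.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    return np.array(rows), genes


def _load_labels(cfg: RunConfig) -> tuple[LabelMatrix, dict[str, int]]:
    id_map = load_gene_index(cfg.gene_index)
    labels = load_annotations(cfg.annotations, id_map, _label_set(cfg, id_map))
    return labels, id_map


def run_train(cfg: RunConfig, val_fraction: float = 0.2) -> CascadeModel:
    """Fit the cascade on all annotated genes (internal validation split)."""
    from sklearn.model_selection import train_test_split

    X, _ = _load_features(cfg)
    labels, _ = _load_labels(cfg)
    Y = np.asarray(labels.Y)
    annotated = np.flatnonzero(Y.sum(axis=1) > 0)
    fit_idx, val_idx = train_test_split(
        annotated, test_size=val_fraction, random_state=cfg.seed
    )
    model = fit_cascade(X[fit_idx], Y[fit_idx], X[val_idx], Y[val_idx], cfg.cascade)
    model_dir = Path(cfg.out_dir) / "model"
    model.save(model_dir)
    (model_dir / "labels.json").write_text(json.dumps(labels.label_names))
    return model


def run_predict(cfg: RunConfig) -> Path:
    """Score every gene; write ranked per-gene label probabilities.

    Output rows are sorted by probability descending within each gene (the
    ranked-candidate-function view used for case studies), with the binary
    call at the configured threshold alongside.
    """
    X, genes = _load_features(cfg)
    model_dir = Path(cfg.out_dir) / "model"
    model = CascadeModel.load(model_dir)
    label_names = json.loads((model_dir / "labels.json").read_text())
    P = predict_proba(model, X).P
    V = threshold_predict(P, cfg.threshold).V
    lines = ["#gene\trank\tlabel\tprobability\tpredicted"]
    for i, gid in enumerate(genes):
        order = np.argsort(-P[i], kind="stable")
        for rank, c in enumerate(order, start=1):
            lines.append(
                f"{gid}\t{rank}\t{label_names[c]}\t{P[i, c]:.6f}\t{V[i, c]}"
            )
    path = Path(cfg.out_dir) / "predictions.tsv"
    path.write_text("\n".join(lines) + "\n")
    return path


def run_evaluate(cfg: RunConfig) -> EvalReport:
    """Cross-validated evaluation over the configured networks."""
    cfg.validate_paths()
    id_map = load_gene_index(cfg.gene_index)
    networks = [
        symmetrize(load_network(p, id_map)) for p in cfg.network_files
    ]
    labels, _ = _load_labels(cfg)
    report = cross_validate(
        networks,
        labels,
        cfg.cascade,
        alpha=cfg.alpha,
        d=cfg.d,
        n_folds=cfg.folds,
        threshold=cfg.threshold,
        seed=cfg.seed,
    )
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.to_tsv(out / "evaluation.tsv")
    report.to_json(out / "evaluation.json")
    return report
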