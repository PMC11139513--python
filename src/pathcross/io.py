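"""Readers, writers and run configuration shared across the pipeline.

The matrix dialect is TSV with a header row and feature ids in the first
column (gzip transparently supported via pandas).  Mappings are
``feature<TAB>gene[<TAB>weight][<TAB>position]``; background gene networks
are two-column edge lists.  Coordinates arriving from BED-derived mappings
are converted to the internal 0-based convention at parse time.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .embedding import EmbeddingConfig, ModalityInput
from .simulate import SimConfig
from .training import CVPlan, TrainConfig
from .transformer import AttentionConfig

logger = logging.getLogger(__name__)

__all__ = ["read_matrix_tsv", "write_matrix_tsv", "read_mapping_tsv",
           "read_labels_tsv", "read_edge_list", "load_modality",
           "write_network_tsv", "write_mask_triplets", "RunConfig",
           "validate_config", "write_manifest"]


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Feature-by-sample matrix; first column = feature ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"{path}: duplicate feature ids, e.g. {dup}")
    return df


def write_matrix_tsv(df: pd.DataFrame, path: str | Path,
                     float_format: str = "%.8g") -> None:
    df.rename_axis("feature").to_csv(path, sep="\t",
                                     float_format=float_format)


def read_mapping_tsv(path: str | Path, one_based_positions: bool = False
                     ) -> tuple[dict, dict | None, dict | None]:
    """feature->gene mapping with optional weight and position columns."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "feature" not in cols or "gene" not in cols:
        raise ValueError(f"{path}: mapping needs 'feature' and 'gene' columns")
    mapping = dict(zip(df[cols["feature"]].astype(str),
                       df[cols["gene"]].astype(str)))
    weights = None
    if "weight" in cols:
        weights = dict(zip(df[cols["feature"]].astype(str),
                           df[cols["weight"]].astype(float)))
    positions = None
    if "position" in cols:
        pos = df[cols["position"]].astype(int)
        if one_based_positions:
            logger.info("%s: converting 1-based positions to 0-based", path)
            pos = pos - 1
        positions = dict(zip(df[cols["feature"]].astype(str), pos))
    return mapping, weights, positions


def read_labels_tsv(path: str | Path) -> pd.Series:
    """Sample labels: two columns (sample, label); labels integer-coded."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns (sample, label)")
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str))
    if not np.issubdtype(s.dtype, np.integer):
        codes, uniques = pd.factorize(s, sort=True)
        logger.info("%s: labels coded as %s", path,
                    dict(enumerate(uniques.tolist())))
        s = pd.Series(codes, index=s.index)
    return s


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: edge list needs two columns")
    return list(zip(df[0].astype(str), df[1].astype(str)))


def mapping_from_bed(bed_path: str | Path, annotation_path: str | Path
                     ) -> tuple[dict, dict]:
    """Derive a feature->gene mapping from a BED file of features and a gene
    annotation TSV (gene, chrom, start, end; 1-based inclusive coordinates,
    converted to the internal 0-based half-open convention at parse time).

    A feature maps to the first annotated gene whose interval overlaps it
    (annotation order decides ties).  Returns (feature_to_gene,
    feature_position) with the position measured from the gene start.
    """
    bed = pd.read_csv(bed_path, sep="\t", header=None, comment="#")
    if bed.shape[1] < 4:
        raise ValueError(f"{bed_path}: BED needs chrom, start, end, name")
    bed.columns = ["chrom", "start", "end", "name"] + [
        f"x{i}" for i in range(bed.shape[1] - 4)]
    ann = pd.read_csv(annotation_path, sep="\t")
    need = {"gene", "chrom", "start", "end"}
    if not need <= set(ann.columns):
        raise ValueError(f"{annotation_path}: annotation needs columns "
                         f"{sorted(need)}")
    ann = ann.assign(start=ann["start"].astype(int) - 1,  # 1-based -> 0-based
                     end=ann["end"].astype(int))
    logger.info("%s: converted 1-based inclusive annotation coordinates to "
                "0-based half-open", annotation_path)
    mapping: dict[str, str] = {}
    position: dict[str, int] = {}
    by_chrom = {c: g.sort_values("start") for c, g in ann.groupby("chrom")}
    for row in bed.itertuples(index=False):
        genes = by_chrom.get(row.chrom)
        if genes is None:
            continue
        hit = genes[(genes["start"] < row.end) & (genes["end"] > row.start)]
        if len(hit):
            g = hit.iloc[0]
            mapping[str(row.name)] = str(g["gene"])
            position[str(row.name)] = int(row.start) - int(g["start"])
    if not mapping:
        raise ValueError("no BED feature overlaps any annotated gene")
    return mapping, position


def load_modality(name: str, level: str, matrix_path: str | Path,
                  mapping_path: str | Path | None = None,
                  transform: str = "none") -> ModalityInput:
    values = read_matrix_tsv(matrix_path)
    mapping = weights = positions = None
    if mapping_path is not None:
        mapping, weights, positions = read_mapping_tsv(mapping_path)
    return ModalityInput(name=name, level=level, values=values,
                         feature_to_gene=mapping, feature_weights=weights,
                         feature_position=positions, transform=transform)


def write_network_tsv(matrix: np.ndarray, ids: list[str], path: str | Path,
                      triplets: bool = True) -> None:
    """Crosstalk network as sparse triplets (default) or a dense matrix."""
    if triplets:
        i, j = np.nonzero(np.triu(matrix, k=1))
        pd.DataFrame({"pathway_a": [ids[a] for a in i],
                      "pathway_b": [ids[b] for b in j],
                      "weight": matrix[i, j]}) \
            .to_csv(path, sep="\t", index=False, float_format="%.8g")
    else:
        pd.DataFrame(matrix, index=ids, columns=ids) \
            .rename_axis("pathway").to_csv(path, sep="\t",
                                           float_format="%.8g")


def write_mask_triplets(mask, path: str | Path) -> None:
    g, p = np.nonzero(mask.matrix)
    pd.DataFrame({"gene": [mask.gene_universe[i] for i in g],
                  "pathway": [mask.pathway_ids[j] for j in p]}) \
        .to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------- config

@dataclasses.dataclass
class RunConfig:
    """Validated pipeline configuration (paths + stage settings)."""

    gmt: str | None = None
    modalities: list[dict] = dataclasses.field(default_factory=list)
    labels: str | None = None
    gene_network: str | None = None
    output_dir: str = "pathcross_out"
    seed: int = 0
    verbosity: str = "info"
    embedding: EmbeddingConfig = dataclasses.field(
        default_factory=EmbeddingConfig)
    attention: AttentionConfig = dataclasses.field(
        default_factory=AttentionConfig)
    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    cv: CVPlan = dataclasses.field(default_factory=CVPlan)
    sim: SimConfig | None = None

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        if self.sim is None:
            out.pop("sim")
        return out


_SECTION_TYPES = {"embedding": EmbeddingConfig, "attention": AttentionConfig,
                  "train": TrainConfig, "cv": CVPlan, "sim": SimConfig}


def validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML/JSON run configuration (strict keys)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs: dict = {}
    for key, value in raw.items():
        if key in _SECTION_TYPES:
            cls = _SECTION_TYPES[key]
            sect_fields = {f.name for f in dataclasses.fields(cls)}
            bad = set(value) - sect_fields
            if bad:
                raise ValueError(f"{path}: unknown keys in '{key}': "
                                 f"{sorted(bad)}")
            for tup in ("genes_per_pathway", "sites_per_gene"):
                if tup in value and isinstance(value[tup], list):
                    value[tup] = tuple(value[tup])
            kwargs[key] = cls(**value)
        else:
            kwargs[key] = value
    cfg = RunConfig(**kwargs)
    for field_name in ("gmt", "labels", "gene_network"):
        p = getattr(cfg, field_name)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"config field '{field_name}': "
                                    f"{p} does not exist")
    for m in cfg.modalities:
        for k in ("path", "mapping"):
            if m.get(k) and not Path(m[k]).exists():
                raise FileNotFoundError(f"modality {m.get('name')}: "
                                        f"{m[k]} does not exist")
    logger.info("config loaded: %s", json.dumps(cfg.to_dict(), default=str))
    return cfg


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: str | Path, stage: str, inputs: list[str | Path],
                   config: dict, seed: int,
                   outputs: list[str | Path] | None = None,
                   status: str = "complete") -> Path:
    """Record stage provenance: input hashes, config hash, seed, versions."""
    import pathcross
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "status": status,
        "seed": seed,
        "inputs": {str(p): _hash_file(Path(p)) for p in inputs
                   if Path(p).exists()},
        "outputs": [str(p) for p in (outputs or [])],
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "versions": {"pathcross": pathcross.__version__,
                     "numpy": np.__version__, "pandas": pd.__version__},
    }
    path = outdir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
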