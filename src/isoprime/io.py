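"""Tab-separated I/O for feature tables, sample sheets and config files.

TSV (tab-delimited, UTF-8, '.' decimal, header row) is the canonical
dialect.  Feature tables are written with phylotypes as rows, libraries as
columns, and an optional trailing ``taxonomy`` column; the sample sheet is
a sidecar TSV keyed by library id.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import (
    GeneratorConfig,
    GradientConfig,
    QpcrConfig,
    Treatment,
)
from .table import FeatureTable, FeatureTableError


def write_feature_table(table: FeatureTable, counts_path, samples_path=None) -> None:
    out = table.counts.copy()
    out.index.name = "phylotype_id"
    if table.taxonomy is not None:
        out["taxonomy"] = table.taxonomy
    out.to_csv(counts_path, sep="\t")
    if samples_path is not None:
        sheet = table.samples.copy()
        sheet.index.name = "library_id"
        sheet.to_csv(samples_path, sep="\t")


def read_feature_table(counts_path, samples_path=None,
                       taxonomy_column: str = "taxonomy") -> FeatureTable:
    """Read a phylotype x library TSV (+ optional sample sheet).

    Counts must be integers unless the file stores a normalized table;
    duplicated phylotype or library ids raise.
    """
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    taxonomy = None
    if taxonomy_column in df.columns:
        taxonomy = df.pop(taxonomy_column)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FeatureTableError(f"duplicated phylotype ids: {dups}")
    arr = df.to_numpy()
    try:
        numeric = arr.astype(float)
    except (ValueError, TypeError) as exc:
        raise FeatureTableError(f"non-numeric counts in {counts_path}: {exc}") from exc
    if not np.array_equal(numeric, np.round(numeric)):
        raise FeatureTableError(f"non-integer counts in {counts_path}")
    counts = df.astype(np.int64)
    counts.index.name = None
    counts.columns.name = None
    if taxonomy is not None:
        taxonomy.index.name = None
    if samples_path is not None:
        samples = pd.read_csv(samples_path, sep="\t", index_col=0)
        samples.index.name = None
    else:
        samples = pd.DataFrame(index=counts.columns)
    return FeatureTable(counts=counts, samples=samples, taxonomy=taxonomy)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


# ---------------------------------------------------------------------------
# generator-config (de)serialization
# ---------------------------------------------------------------------------


def config_to_dict(config: GeneratorConfig) -> dict:
    d = dataclasses.asdict(config)
    # tuples -> lists for clean YAML
    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        return obj
    return _clean(d)


def config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    treatments = tuple(Treatment(**t) for t in d.pop("treatments", []))
    gradient = d.pop("gradient", {})
    if gradient:
        gradient = dict(gradient)
        if "pooling" in gradient:
            gradient["pooling"] = tuple(tuple(p) for p in gradient["pooling"])
        if "gc_bounds" in gradient:
            gradient["gc_bounds"] = tuple(gradient["gc_bounds"])
        gradient = GradientConfig(**gradient)
    else:
        gradient = GradientConfig()
    qpcr = d.pop("qpcr", {})
    if qpcr:
        qpcr = dict(qpcr)
        if "standard_copies" in qpcr:
            qpcr["standard_copies"] = tuple(qpcr["standard_copies"])
        qpcr = QpcrConfig(**qpcr)
    else:
        qpcr = QpcrConfig()
    for key in ("sampling_times", "ecoplots"):
        if key in d:
            d[key] = tuple(d[key])
    cfg = GeneratorConfig(treatments=treatments, gradient=gradient, qpcr=qpcr, **d)
    cfg.validate()
    return cfg


def write_config(config: GeneratorConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def read_config(path) -> GeneratorConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))
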