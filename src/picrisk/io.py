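"""Delimited-table and tree file readers/writers used by the CLI."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .tree import Phylogeny


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a comma- or tab-delimited UTF-8 table with a header row."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else None
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if df.empty:
        raise ValueError(f"{path}: empty table")
    return df


def read_tree(path: str | Path, tree_id: str | None = None) -> Phylogeny:
    text = Path(path).read_text()
    return Phylogeny.from_newick(text, tree_id=tree_id or Path(path).stem)


def read_config(path: str | Path) -> dict:
    """Read the nested key-value run configuration (YAML)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg
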