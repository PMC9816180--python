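"""Readers and writers for the plain-text exchange formats of the pipeline.

All tables are tab-separated with a header row.  Gene sets travel as GMT lines
(name, description, then one gene per column).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene": str}, keep_default_na=False, na_values=[""])


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file into ``{set_name: genes}``.

    Duplicate genes within a line collapse to one membership; empty gene sets
    are kept (membership simply contributes nothing downstream).
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            name = fields[0]
            genes = {g for g in fields[2:] if g}
            sets[name] = genes
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name in sets:
            desc = (descriptions or {}).get(name, "na")
            genes = sorted(set(sets[name]))
            fh.write("\t".join([name, desc, *genes]) + "\n")
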