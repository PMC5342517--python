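"""TSV/JSON interchange helpers.

All tabular outputs are UTF-8 TSV with a header row, ``NA`` for missing
values, and optional ``#``-prefixed metadata lines (config hash, seed) above
the header.  Readers skip ``#`` lines.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

NA_REP = "NA"


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    meta: Mapping[str, Any] | None = None,
    index: bool = False,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", na_rep=NA_REP, index=index, lineterminator="\n")


def read_tsv(path: str | Path, index_col: int | str | None = None) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", na_values=[NA_REP], index_col=index_col
    )


def write_json(obj: Any, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path) -> Any:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
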