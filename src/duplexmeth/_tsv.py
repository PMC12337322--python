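"""Tab-separated I/O helpers shared by all stages.

Every tabular output the pipeline writes carries leading ``#`` comment lines
naming the tool version and the configuration hash of the run; readers skip
them transparently.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable

import pandas as pd


def _opener(path: Path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_table(df: pd.DataFrame, path, comments: Iterable[str] = ()) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with _opener(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path, **kwargs) -> pd.DataFrame:
    with _opener(Path(path), "r") as fh:
        return pd.read_csv(fh, sep="\t", comment="#", **kwargs)
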