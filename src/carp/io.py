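"""Reading and writing response matrices (CSV/TSV) and item banks (JSON)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .irt_sim import ItemBank

__all__ = ["read_scores", "write_scores", "read_bank", "write_bank"]


def read_scores(path) -> np.ndarray:
    """Read an N x J binary score matrix from a headered CSV or TSV file."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=sep)
    values = frame.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise InvalidInputError(f"{path} contains non-binary entries")
    return values.astype(np.int8)


def write_scores(x, path) -> None:
    """Write a score matrix with header ``item1..itemJ``."""
    x = np.asarray(x)
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    columns = [f"item{k + 1}" for k in range(x.shape[1])]
    pd.DataFrame(x, columns=columns).to_csv(path, sep=sep, index=False)


def read_bank(path) -> ItemBank:
    return ItemBank.from_json(Path(path).read_text())


def write_bank(bank: ItemBank, path) -> None:
    Path(path).write_text(bank.to_json())
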