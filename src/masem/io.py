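"""Plain-text exchange formats for study sets and results.

A StudySet is stored as a directory of 4x4 correlation CSV files (header
row with the variable names) plus a ``manifest.json`` listing, per study,
the sample size, the matrix file, and the population label.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import VAR_NAMES
from .simulate import StudySet

__all__ = ["write_studyset", "read_studyset", "write_population_csv"]


def write_population_csv(matrix: np.ndarray, path: str | Path) -> None:
    """Write a 4x4 correlation matrix as CSV with variable-name header/index."""
    pd.DataFrame(matrix, index=VAR_NAMES, columns=VAR_NAMES).to_csv(path)


def _read_matrix_csv(path: Path) -> np.ndarray:
    df = pd.read_csv(path, index_col=0)
    R = df.to_numpy(dtype=float)
    if R.shape != (4, 4):
        raise ValueError(f"{path}: expected a 4x4 matrix, got {R.shape}")
    return R


def write_studyset(studies: StudySet, directory: str | Path) -> Path:
    """Serialize a StudySet to a directory of CSVs plus manifest.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, (n, R, label) in enumerate(zip(studies.sizes, studies.matrices, studies.labels)):
        fname = f"study_{i:03d}.csv"
        pd.DataFrame(R, index=VAR_NAMES, columns=VAR_NAMES).to_csv(directory / fname)
        entries.append({"n": int(n), "file": fname, "label": label})
    (directory / "manifest.json").write_text(json.dumps({"studies": entries}, indent=2))
    return directory


def read_studyset(directory: str | Path) -> StudySet:
    """Load a StudySet from a directory written by write_studyset."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    sizes, matrices, labels = [], [], []
    for entry in manifest["studies"]:
        sizes.append(int(entry["n"]))
        matrices.append(_read_matrix_csv(directory / entry["file"]))
        labels.append(entry.get("label", "sigma"))
    return StudySet(sizes=sizes, matrices=matrices, labels=labels)
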