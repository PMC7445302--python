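"""Plain-text I/O: multi-frame XYZ conformations and CSV results tables.

Coordinates are written with 6 decimal places (fixed-precision round-trip
contract); result CSVs carry the effective configuration and package version
as ``#``-prefixed header comment lines.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sampler import Conformation

__all__ = ["write_xyz", "read_xyz", "write_results", "read_results", "RESULT_COLUMNS"]

#: canonical column order of ensemble-result tables
RESULT_COLUMNS = [
    "fc", "fr", "n", "M", "n_conf",
    "rg2", "rg2_err", "rhinv", "rhinv_err", "rho", "rho_err", "seed",
]


def write_xyz(
    confs: Sequence[Conformation],
    path: str | Path,
    seed: int | None = None,
) -> None:
    """Write conformations as a standard multi-frame XYZ file.

    Atom-count line, then a comment line carrying fc/fr/n/seed/frame, then one
    ``<element> x y z`` line per bead.  The core (bead 0) is labeled ``N`` for
    visibility, all other beads ``C``.
    """
    if not confs:
        raise ValueError("no conformations to write")
    path = Path(path)
    with path.open("w") as fh:
        for frame, conf in enumerate(confs):
            t = conf.topology
            fh.write(f"{conf.n_beads}\n")
            fh.write(
                f"fc={t.f_c} fr={t.f_r} n={t.n_per_arm} "
                f"seed={'none' if seed is None else seed} frame={frame}\n"
            )
            for i, row in enumerate(conf.coords):
                label = "N" if i == 0 else "C"
                fh.write(label + " " + " ".join(f"{v:.6f}" for v in row) + "\n")


def read_xyz(path: str | Path) -> list[tuple[str, np.ndarray]]:
    """Read a multi-frame XYZ file; returns (comment, coords) per frame."""
    frames: list[tuple[str, np.ndarray]] = []
    lines = Path(path).read_text().splitlines()
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        count = int(lines[pos])
        comment = lines[pos + 1]
        rows = [
            [float(v) for v in lines[pos + 2 + i].split()[1:]]
            for i in range(count)
        ]
        frames.append((comment, np.asarray(rows)))
        pos += 2 + count
    return frames


def _version() -> str:
    from . import __version__

    return __version__


def write_results(
    records: Sequence[Mapping],
    path: str | Path,
    config: Mapping | None = None,
) -> None:
    """Write homogeneous result records as CSV with a config comment header."""
    path = Path(path)
    df = pd.DataFrame(list(records))
    if len(df) and set(RESULT_COLUMNS) <= set(df.columns):
        df = df[RESULT_COLUMNS + [c for c in df.columns if c not in RESULT_COLUMNS]]
    elif not len(df):
        df = pd.DataFrame(columns=RESULT_COLUMNS)
    with path.open("w") as fh:
        fh.write(f"# rosette version {_version()}\n")
        for key, value in (config or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results CSV written by :func:`write_results`."""
    return pd.read_csv(path, comment="#")
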