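"""Stable on-disk formats: TSV count tables and JSON configuration/results.

Count tables are TSV with columns ``cell_id, copies, group, generation``
(TSV rather than CSV to sidestep locale decimal separators). Every file
written carries a ``#`` header comment with the tool version and a short
hash of the configuration that produced it. All sub-seeds are derived
deterministically from one global seed via :func:`derive_seed`.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .initsort import CopyNumberSample

__all__ = ["read_counts", "write_counts", "write_snapshots", "derive_seed", "config_hash"]

REQUIRED_COLUMNS = ("cell_id", "copies", "group", "generation")


def config_hash(config: dict) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def derive_seed(global_seed: int, module: str) -> int:
    """Deterministic sub-seed for a named module from one global seed.

    Uses numpy's SeedSequence spawn-key mechanism with a stable hash of the
    module name; the result is always below 2**31.
    """
    tag = int.from_bytes(hashlib.sha256(module.encode()).digest()[:4], "big")
    ss = np.random.SeedSequence([int(global_seed), tag])
    return int(ss.generate_state(1)[0] % (2**31))


def write_counts(
    samples,
    path,
    config: dict | None = None,
    version: str | None = None,
) -> None:
    """Write one or more CopyNumberSamples as a TSV count table."""
    from . import __version__

    if isinstance(samples, CopyNumberSample):
        samples = [samples]
    rows = []
    cell_id = 0
    for s in samples:
        for k in s.counts:
            rows.append((cell_id, int(k), s.group, s.generation))
            cell_id += 1
    df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# ecdnasim {version or __version__} config={config_hash(config or {})}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_snapshots(snapshots, path, config: dict | None = None) -> None:
    """Write simulator snapshots as TSV: generation, time_h, cell_index, copies."""
    from . import __version__

    rows = []
    for s in snapshots:
        for i, k in enumerate(s.copies):
            rows.append((s.generation, s.time, i, int(k)))
    df = pd.DataFrame(rows, columns=["generation", "time_h", "cell_index", "copies"])
    with open(Path(path), "w") as fh:
        fh.write(f"# ecdnasim {__version__} config={config_hash(config or {})}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_counts(path) -> Dict[Tuple[str, int], CopyNumberSample]:
    """Read a TSV count table into one sample per (group, generation) stratum.

    Raises on a missing column (naming it), on negative or non-integer
    copy values (citing the offending line), and on a table with no rows.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"count table {path} is missing required column {col!r}")
    if len(df) == 0:
        raise ValueError(f"count table {path} contains a header but no rows")
    with open(path) as fh:
        header_offset = 0
        for line in fh:
            if not line.startswith("#"):
                break
            header_offset += 1
    copies = np.empty(len(df), dtype=np.int64)
    for i, raw in enumerate(df["copies"]):
        line_no = header_offset + 2 + i  # 1-based, past header
        try:
            val = int(raw)
        except (TypeError, ValueError):
            raise ValueError(f"{path}:{line_no}: copies value {raw!r} is not an integer") from None
        if val < 0:
            raise ValueError(f"{path}:{line_no}: copies value {val} is negative")
        copies[i] = val
    df = df.assign(_copies=copies, _gen=df["generation"].astype(int))
    out: Dict[Tuple[str, int], CopyNumberSample] = {}
    for (group, gen), sub in df.groupby(["group", "_gen"], sort=True):
        out[(str(group), int(gen))] = CopyNumberSample(
            counts=sub["_copies"].to_numpy(), group=str(group), generation=int(gen), source=str(path)
        )
    return out
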