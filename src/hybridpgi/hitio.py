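"""Plain-text file formats: hit streams, manifests, profiles, result tables.

The hit-stream format is delimited text (CSV) with '#'-prefixed comment
lines and a versioned header; columns are
(event_id, imager, layer, crystal_index, x_mm, y_mm, z_mm, energy_keV,
time_ns).  Readers tolerate arbitrary comment lines.  All outputs carry
provenance comments (format version, seed when known).
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .transport import HIT_COLUMNS

__all__ = [
    "write_hits", "read_hits", "write_manifest", "read_manifest",
    "write_profile", "read_profile", "write_table", "read_table",
]

FORMAT_VERSION = 1


def write_hits(path, hits: pd.DataFrame, manifest: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# hybridpgi hit stream v{FORMAT_VERSION}\n")
        if manifest is not None and "seed" in manifest:
            fh.write(f"# seed {manifest['seed']}\n")
        fh.write("# columns: " + ",".join(HIT_COLUMNS) + "\n")
        hits.to_csv(fh, index=False, columns=list(HIT_COLUMNS),
                    float_format="%.6f")


def read_hits(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing hit columns {sorted(missing)}")
    return df


def write_manifest(path, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_profile(path, positions, values, meta: dict | None = None) -> None:
    """Two-column delimited text profile with a '#' header."""
    header = [f"hybridpgi profile v{FORMAT_VERSION}", "x_mm value"]
    for k, v in (meta or {}).items():
        header.append(f"{k} {v}")
    np.savetxt(path, np.column_stack([positions, values]),
               header="\n".join(header))


def read_profile(path) -> tuple:
    data = np.loadtxt(path)
    return data[:, 0], data[:, 1]


def write_table(path, table: pd.DataFrame, meta: dict | None = None) -> None:
    """Tidy delimited result table with provenance comments."""
    with open(path, "w") as fh:
        fh.write(f"# hybridpgi table v{FORMAT_VERSION}\n")
        for k, v in (meta or {}).items():
            fh.write(f"# {k} {v}\n")
        table.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
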