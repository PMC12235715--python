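"""Readers and writers for the pipeline's tabular artifacts.

Sample tables and abundance matrices travel as CSV/TSV (delimiter sniffed
from the file extension), gene sets as GMT, run configuration as YAML.
All readers validate type invariants and report offending rows/cells rather
than silently coercing.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import Z_CUTOFF

logger = logging.getLogger("bwproteo")

SAMPLE_COLUMNS = [
    "participant_id",
    "visit",
    "gestational_age",
    "group",
    "birth_weight_z",
    "bmi",
    "nulliparous",
    "sex",
]


class ValidationError(ValueError):
    """Raised when an input artifact violates a type invariant."""


def _sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def validate_sample_table(df: pd.DataFrame) -> None:
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"sample table missing columns: {missing}")
    if len(df) == 0:
        raise ValidationError("no samples in table")
    dup = df.duplicated(subset=["participant_id", "visit"])
    if dup.any():
        rows = list(df.index[dup])
        raise ValidationError(f"duplicate (participant, visit) pairs at rows {rows}")
    bad_visit = ~df["visit"].isin([1, 2, 3])
    if bad_visit.any():
        raise ValidationError(f"visit outside {{1,2,3}} at rows {list(df.index[bad_visit])}")
    z = df["birth_weight_z"].to_numpy(float)
    grp = df["group"].to_numpy()
    expected = np.where(z > Z_CUTOFF, "LGA", np.where(z < -Z_CUTOFF, "SGA", "AGA"))
    bad = expected != grp
    if bad.any():
        offenders = [
            f"row {i}: group={g} but z={v:.3g}" for i, g, v in
            zip(df.index[bad], grp[bad], z[bad])
        ]
        raise ValidationError("group/z-score mismatch: " + "; ".join(offenders))


def read_sample_table(path) -> pd.DataFrame:
    """Read and validate a per-sample clinical/design table."""
    try:
        df = pd.read_csv(path, sep=_sep(path))
    except pd.errors.EmptyDataError:
        raise ValidationError(f"no samples in {path}") from None
    if len(df) == 0 or df.shape[1] == 0:
        raise ValidationError(f"no samples in {path}")
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    validate_sample_table(df)
    if "sample_id" not in df.index.names or df.index.name != "sample_id":
        df.index = df["participant_id"].astype(str) + "_v" + df["visit"].astype(str)
        df.index.name = "sample_id"
    df["nulliparous"] = df["nulliparous"].astype(bool)
    return df


def write_sample_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep=_sep(path), index=True, index_label="sample_id")


def read_protein_matrix(path) -> pd.DataFrame:
    """Read a samples × proteins abundance matrix (first column = sample id).

    Non-numeric or non-positive cells and duplicated protein ids are
    rejected with coordinates.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(_sep(path))[1:]
    dups = sorted({name for i, name in enumerate(header) if name in header[:i]})
    if dups:
        raise ValidationError(f"duplicated protein ids in header: {dups}")
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    vals = df.apply(pd.to_numeric, errors="coerce")
    bad = vals.isna() | ~np.isfinite(vals) | (vals <= 0)
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"non-numeric or non-positive value at sample {df.index[r]!r}, "
            f"protein {df.columns[c]!r}: {df.iat[r, c]!r}"
        )
    return vals


def write_protein_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep=_sep(path), index=True, index_label="sample_id")


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. GO Biological Process terms from a GMT export)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str]

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, set_id: str) -> set[str]:
        return self.sets[set_id]

    def ids(self) -> list[str]:
        return list(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: per line, set id, description, then member genes."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}:{lineno}: GMT line has <3 tab-separated fields")
            set_id, desc = fields[0], fields[1]
            if set_id in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            members = {m for m in fields[2:] if m}
            if not members:
                raise ValidationError(f"{path}:{lineno}: set {set_id!r} has no members")
            sets[set_id] = members
            descriptions[set_id] = desc
    if not sets:
        raise ValidationError(f"{path}: no gene sets")
    return GeneSetCollection(sets, descriptions)


def collapse_duplicate_proteins(df: pd.DataFrame) -> pd.DataFrame:
    """Keep the first column per duplicated gene-name id, with a warning.

    Aptamer panels can carry multiple reagents per gene; identifiers here are
    gene names, so duplicates are collapsed at read time.
    """
    if df.columns.duplicated().any():
        dups = sorted(set(df.columns[df.columns.duplicated()]))
        warnings.warn(f"collapsing duplicated protein ids (keeping first): {dups}")
        df = df.loc[:, ~df.columns.duplicated()]
    return df


def write_results_table(rows: pd.DataFrame, path, sort_by: list[str] | None = None) -> None:
    """Write a results table as TSV with floats at 6 significant digits.

    Row order is deterministic: ``sort_by`` if given, else (q, protein) when
    present, else the incoming order.
    """
    df = rows.copy()
    if sort_by is None and {"q", "protein"} <= set(df.columns):
        sort_by = ["q", "protein"]
    if sort_by:
        df = df.sort_values(sort_by, kind="stable")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def log_run(out_dir, config_path=None, seed=None, artifacts=()) -> None:
    """Append resolved run metadata (seed, artifact checksums) to a run log."""
    import datetime
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "run_log.txt", "a") as fh:
        fh.write(f"time={datetime.datetime.now().isoformat()} seed={seed} config={config_path}\n")
        for art in artifacts:
            fh.write(f"  {art}\tsha256={file_checksum(art)}\n")
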