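"""Table and gene-set file I/O with schema validation.

Tables are plain UTF-8 CSV/TSV with a mandatory header row and "." decimal
separator; the delimiter is chosen from the file extension (.tsv/.tab ->
tab, anything else -> comma).  Pathway membership uses the GMT convention:
one set per line, ``name<TAB>description<TAB>member1<TAB>member2...``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import GmtFormatError, ParseError, SchemaError

log = logging.getLogger("tcqe")

# column -> dtype ("str" or "float") per input table kind
COMPOUND_SCHEMA = {"id": "str", "name": "str", "ob": "float", "dl": "float"}
PREDICTION_SCHEMA = {"compound_id": "str", "target_id": "str", "probability": "float"}
DISEASE_GENE_SCHEMA = {"gene_id": "str", "relevance": "float"}
PLATE_SCHEMA = {
    "batch": "str",
    "dose": "float",
    "replicate": "str",
    "signal": "float",
    "well_role": "str",
}


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_table(path: str | Path, schema: dict[str, str]) -> pd.DataFrame:
    """Read a CSV/TSV file and validate it against ``schema``.

    Mandatory columns are coerced to the schema dtype; row order is
    preserved; unknown columns are retained but logged.

    Raises
    ------
    SchemaError
        if a mandatory column is missing.
    ParseError
        if a numeric column holds a non-numeric value (the 0-based row
        index is named in the message).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path), dtype=str, keep_default_na=False)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing mandatory column(s) {missing}")
    extra = [c for c in df.columns if c not in schema]
    if extra:
        log.info("%s: retaining %d unknown column(s): %s", path.name, len(extra), extra)
    for col, kind in schema.items():
        if kind == "float":
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & (df[col].str.strip() != "")
            if bad.any():
                row = int(bad.idxmax())
                raise ParseError(
                    f"{path.name}: non-numeric value {df[col][row]!r} "
                    f"in column '{col}' at row {row}"
                )
            df[col] = coerced
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table; ``read_table(write_table(df))`` round-trips values."""
    path = Path(path)
    df.to_csv(path, sep=_delimiter_for(path), index=False, lineterminator="\n")


@dataclass
class GeneSetCollection:
    """Named member sets plus an optional explicit background universe."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: set[str] | None = None

    def members(self, name: str) -> set[str]:
        return set(self.sets[name])

    def default_universe(self) -> set[str]:
        """Union of all members, unless an explicit universe was given."""
        if self.universe is not None:
            return set(self.universe)
        out: set[str] = set()
        for members in self.sets.values():
            out.update(members)
        return out

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    Duplicate members within a set are dropped (first occurrence kept);
    a line with fewer than three fields, or with no non-empty members,
    raises :class:`GmtFormatError` naming the 1-based line number.
    """
    path = Path(path)
    coll = GeneSetCollection()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtFormatError(
                    f"{path.name}:{lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc = fields[0], fields[1]
            seen: dict[str, None] = {}
            for m in fields[2:]:
                m = m.strip()
                if m:
                    seen.setdefault(m)
            if not seen:
                raise GmtFormatError(f"{path.name}:{lineno}: set '{name}' is empty")
            coll.sets[name] = list(seen)
            coll.descriptions[name] = desc
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in coll.sets.items():
            desc = coll.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")
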