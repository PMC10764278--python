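"""Reading, writing and grouping of helical particle metadata tables.

Particle tables are loop-based STAR text files, one row per extracted
filament segment ("particle").  Each particle carries the micrograph it was
picked from, the helical tube (filament) it belongs to within that
micrograph, and the 2D class it was assigned to in a reference-free 2D
classification.  The pair (micrograph, tube) identifies a filament; tube IDs
are *not* assumed unique across micrographs.

Column labels are configurable through :class:`StarDialect`; the defaults
are the RELION conventions (``_rlnMicrographName``, ``_rlnHelicalTubeID``,
``_rlnClassNumber``).  Columns the dialect does not name are preserved
verbatim per record so that a read/write cycle round-trips the file.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from gemmi import cif

__all__ = [
    "StarDialect",
    "ParticleRecord",
    "FilamentProfile",
    "StarFormatError",
    "StarParseError",
    "read_particles",
    "write_particles",
    "group_filaments",
    "class_distribution_matrix",
    "profiles_to_table",
]


class StarFormatError(ValueError):
    """Structural problem with a STAR table (missing block or column)."""


class StarParseError(ValueError):
    """A cell could not be parsed; the message carries the 1-based row."""


@dataclass(frozen=True)
class StarDialect:
    """Mapping from semantic roles to STAR column labels.

    ``block`` selects the data block by name; ``None`` accepts the first
    block that contains a loop (covering both ``data_particles`` and
    unnamed ``data_`` blocks).
    """

    micrograph: str = "_rlnMicrographName"
    tube: str = "_rlnHelicalTubeID"
    class_number: str = "_rlnClassNumber"
    coord_x: str = "_rlnCoordinateX"
    coord_y: str = "_rlnCoordinateY"
    block: str | None = None

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "StarDialect":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise StarFormatError(f"unknown dialect keys: {sorted(unknown)}")
        return cls(**dict(mapping))


@dataclass
class ParticleRecord:
    """One extracted helical segment and its 2D class assignment.

    ``class_id`` is 1-based; non-positive values mark particles whose class
    assignment is unusable (e.g. picking false positives removed by an
    initial classification round).  Such particles are excluded from
    filament profiles but still count towards picked-particle totals.
    """

    micrograph_id: str
    tube_id: int
    class_id: int
    x: float | None = None
    y: float | None = None
    source_row: int = -1
    extras: "OrderedDict[str, str]" = field(default_factory=OrderedDict)

    @property
    def filament_key(self) -> tuple[str, int]:
        return (self.micrograph_id, self.tube_id)

    @property
    def usable(self) -> bool:
        return self.class_id >= 1


@dataclass(frozen=True)
class FilamentProfile:
    """A filament's normalised distribution over 2D classes."""

    filament_key: tuple[str, int]
    n_particles: int
    distribution: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distribution, dtype=float)
        object.__setattr__(self, "distribution", d)
        if self.n_particles <= 0:
            raise ValueError("profile requires at least one particle")
        if np.any(d < 0) or abs(d.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"distribution of {self.filament_key} is not a probability vector"
            )


def _find_block(doc: cif.Document, dialect: StarDialect) -> cif.Block:
    if dialect.block is not None:
        blk = doc.find_block(dialect.block)
        if blk is None:
            raise StarFormatError(f"no data block named {dialect.block!r}")
        return blk
    for blk in doc:
        if any(item.loop is not None for item in blk):
            return blk
    raise StarFormatError("no data block with a loop_ found")


def _parse_int(raw: str, column: str, row: int) -> int:
    try:
        return int(float(raw))
    except ValueError:
        raise StarParseError(
            f"row {row}: cannot parse {raw!r} in column {column} as integer"
        ) from None


def _parse_float(raw: str, column: str, row: int) -> float:
    try:
        return float(raw)
    except ValueError:
        raise StarParseError(
            f"row {row}: cannot parse {raw!r} in column {column} as number"
        ) from None


def read_particles(
    path: str | Path, dialect: StarDialect | None = None
) -> list[ParticleRecord]:
    """Read a STAR particle table into an ordered list of records.

    Raises :class:`StarFormatError` if a required column (micrograph, tube,
    class) is absent and :class:`StarParseError` on malformed numeric cells.
    Unknown columns are kept as raw strings in each record's ``extras`` so
    that :func:`write_particles` can re-emit them unchanged.
    """
    dialect = dialect or StarDialect()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = cif.read_file(str(path))
    blk = _find_block(doc, dialect)
    loop = next(item.loop for item in blk if item.loop is not None)
    tags = list(loop.tags)

    required = {
        "micrograph": dialect.micrograph,
        "tube": dialect.tube,
        "class": dialect.class_number,
    }
    for role, tag in required.items():
        if tag not in tags:
            raise StarFormatError(
                f"required column {tag!r} ({role} identifier) not found; "
                f"present: {tags}"
            )
    col = {tag: i for i, tag in enumerate(tags)}
    known = {dialect.micrograph, dialect.tube, dialect.class_number,
             dialect.coord_x, dialect.coord_y}
    extra_tags = [t for t in tags if t not in known]

    records: list[ParticleRecord] = []
    width = loop.width()
    values = loop.values
    for r in range(loop.length()):
        row = values[r * width : (r + 1) * width]
        rec = ParticleRecord(
            micrograph_id=cif.as_string(row[col[dialect.micrograph]]),
            tube_id=_parse_int(row[col[dialect.tube]], dialect.tube, r + 1),
            class_id=_parse_int(row[col[dialect.class_number]],
                                dialect.class_number, r + 1),
            x=(_parse_float(row[col[dialect.coord_x]], dialect.coord_x, r + 1)
               if dialect.coord_x in col else None),
            y=(_parse_float(row[col[dialect.coord_y]], dialect.coord_y, r + 1)
               if dialect.coord_y in col else None),
            source_row=r,
            extras=OrderedDict((t, row[col[t]]) for t in extra_tags),
        )
        records.append(rec)
    return records


def write_particles(
    records: Sequence[ParticleRecord],
    path: str | Path,
    dialect: StarDialect | None = None,
    allow_empty: bool = False,
) -> None:
    """Write records to a STAR particle table (inverse of :func:`read_particles`)."""
    dialect = dialect or StarDialect()
    if not records and not allow_empty:
        raise ValueError("refusing to write an empty table (pass allow_empty=True)")

    has_xy = bool(records) and records[0].x is not None and records[0].y is not None
    extra_tags = list(records[0].extras) if records else []
    tags = [dialect.micrograph, dialect.tube, dialect.class_number]
    if has_xy:
        tags += [dialect.coord_x, dialect.coord_y]
    tags += extra_tags

    if not records:
        # gemmi omits zero-row loops on write; emit the header-only table
        block_name = dialect.block or "particles"
        Path(path).write_text(
            f"data_{block_name}\n\nloop_\n" + "\n".join(tags) + "\n"
        )
        return

    doc = cif.Document()
    blk = doc.add_new_block(dialect.block or "particles")
    loop = blk.init_loop("", tags)
    for rec in records:
        row = [cif.quote(rec.micrograph_id), str(rec.tube_id), str(rec.class_id)]
        if has_xy:
            row += [repr(float(rec.x)), repr(float(rec.y))]
        row += [rec.extras.get(t, ".") for t in extra_tags]
        loop.add_row(row)
    doc.write_file(str(path))


def group_filaments(
    records: Iterable[ParticleRecord],
) -> "OrderedDict[tuple[str, int], list[ParticleRecord]]":
    """Group particles into filaments keyed by (micrograph_id, tube_id).

    Keys are ordered lexicographically by micrograph, then numerically by
    tube, so downstream leaf indices are deterministic.
    """
    groups: dict[tuple[str, int], list[ParticleRecord]] = {}
    for rec in records:
        groups.setdefault(rec.filament_key, []).append(rec)
    return OrderedDict(sorted(groups.items()))


def class_distribution_matrix(
    groups: Mapping[tuple[str, int], Sequence[ParticleRecord]],
    n_classes: int,
) -> list[FilamentProfile]:
    """Build per-filament class-assignment distributions.

    Entry ``c`` of a filament's distribution is the fraction of its usable
    particles assigned to class ``c+1``.  Particles with non-positive class
    IDs are skipped; a filament with no usable particle is omitted.
    Raises ``ValueError`` naming the filament if a class exceeds ``n_classes``.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    profiles: list[FilamentProfile] = []
    for key, recs in groups.items():
        counts = np.zeros(n_classes, dtype=float)
        n = 0
        for rec in recs:
            if not rec.usable:
                continue
            if rec.class_id > n_classes:
                raise ValueError(
                    f"filament {key}: class_id {rec.class_id} exceeds "
                    f"n_classes={n_classes}"
                )
            counts[rec.class_id - 1] += 1
            n += 1
        if n == 0:
            continue
        profiles.append(FilamentProfile(key, n, counts / n))
    return profiles


def profiles_to_table(profiles: Sequence[FilamentProfile]):
    """Long-format DataFrame export of profiles (one row per filament)."""
    import pandas as pd

    if not profiles:
        return pd.DataFrame(columns=["micrograph", "tube", "n_particles"])
    k = len(profiles[0].distribution)
    rows = []
    for p in profiles:
        row = {"micrograph": p.filament_key[0], "tube": p.filament_key[1],
               "n_particles": p.n_particles}
        row.update({f"class_{c + 1}": p.distribution[c] for c in range(k)})
        rows.append(row)
    return pd.DataFrame(rows)
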