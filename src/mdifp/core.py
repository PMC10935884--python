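"""Core data model and I/O for per-frame interaction fingerprints.

An interaction fingerprint (IFP) encodes one MD trajectory frame as a bit
vector: one bit per (ligand, residue, interaction-type) column, 1 when the
interaction is present in that frame.  Fingerprints are computed upstream
(e.g. with ProLIF) at residue level and arrive as wide Boolean tables with
one row per frame; this module loads those tables, maps Boolean values to
bits, and provides the column-space operations (dropping interaction types,
concatenating replicates, merging two sets onto a common column space) that
the aggregation and comparison stages build on.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "INTERACTION_TYPES",
    "InteractionKey",
    "FingerprintFrameSet",
    "FingerprintFormatError",
    "load_fingerprint_table",
    "write_fingerprint_table",
    "drop_interaction_types",
    "concat_replicates",
    "merge_column_spaces",
]

#: Closed enumeration of residue-level interaction types (ProLIF vocabulary).
INTERACTION_TYPES: tuple[str, ...] = (
    "Anionic",
    "CationPi",
    "Cationic",
    "EdgeToFace",
    "FaceToFace",
    "HBAcceptor",
    "HBDonor",
    "Hydrophobic",
    "Interaction",
    "MetalAcceptor",
    "MetalDonor",
    "PiCation",
    "PiStacking",
    "XBAcceptor",
    "XBDonor",
    "VdWContact",
)

_RESIDUE_RE = re.compile(r"^([A-Za-z]+)(\d+)")


class FingerprintFormatError(ValueError):
    """Raised when a fingerprint table header cannot be interpreted."""


@dataclass(frozen=True, order=False)
class InteractionKey:
    """One fingerprint column: a ligand/residue pair plus interaction type.

    The residue label combines three-letter residue name and sequence number
    (e.g. ``"TYR272"``); the interaction type must come from the closed
    :data:`INTERACTION_TYPES` enumeration.
    """

    ligand: str
    residue: str
    interaction_type: str

    def __post_init__(self) -> None:
        if self.interaction_type not in INTERACTION_TYPES:
            raise ValueError(
                f"unknown interaction type {self.interaction_type!r}; "
                f"expected one of {sorted(INTERACTION_TYPES)}"
            )

    @property
    def residue_number(self) -> int:
        """Residue sequence number parsed from the label (0 if absent)."""
        m = _RESIDUE_RE.match(self.residue)
        return int(m.group(2)) if m else 0

    @property
    def residue_name(self) -> str:
        m = _RESIDUE_RE.match(self.residue)
        return m.group(1) if m else self.residue

    def sort_key(self) -> tuple:
        return (self.residue_number, self.residue_name, self.interaction_type, self.ligand)

    def __str__(self) -> str:  # flat-header serialisation
        return f"{self.ligand}|{self.residue}|{self.interaction_type}"

    @classmethod
    def from_string(cls, token: str) -> "InteractionKey":
        parts = token.split("|")
        if len(parts) != 3:
            raise FingerprintFormatError(
                f"malformed column header {token!r}: expected "
                "'LIGAND|RESIDUE|TYPE' with two '|' separators"
            )
        return cls(*parts)


@dataclass
class FingerprintFrameSet:
    """Ordered per-frame bit matrix over interaction columns.

    Attributes
    ----------
    columns:
        Ordered, unique :class:`InteractionKey` list (one per matrix column).
    frames:
        ``(n, 2)`` integer array of ``(replicate_id, frame_number)`` rows;
        frame numbers are strictly increasing within a replicate.
    bits:
        ``(n, len(columns))`` matrix of 0/1 values (uint8).
    """

    columns: tuple[InteractionKey, ...]
    frames: np.ndarray
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.columns = tuple(self.columns)
        self.frames = np.asarray(self.frames, dtype=np.int64).reshape(-1, 2)
        self.bits = np.ascontiguousarray(np.asarray(self.bits, dtype=np.uint8))
        if self.bits.ndim != 2:
            self.bits = self.bits.reshape(len(self.frames), len(self.columns))
        if self.bits.shape != (len(self.frames), len(self.columns)):
            raise ValueError(
                f"bit matrix shape {self.bits.shape} does not match "
                f"{len(self.frames)} frames x {len(self.columns)} columns"
            )
        if self.bits.size and not np.isin(self.bits, (0, 1)).all():
            raise ValueError("bit matrix entries must be 0 or 1")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("duplicate interaction columns")
        for rep in np.unique(self.frames[:, 0]):
            nums = self.frames[self.frames[:, 0] == rep, 1]
            if np.any(np.diff(nums) <= 0):
                raise ValueError(
                    f"frame numbers not strictly increasing in replicate {rep}"
                )

    # -- basic accessors ---------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.bits.shape[0]

    @property
    def n_columns(self) -> int:
        return self.bits.shape[1]

    @property
    def replicate_ids(self) -> np.ndarray:
        return np.unique(self.frames[:, 0])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FingerprintFrameSet):
            return NotImplemented
        return (
            self.columns == other.columns
            and np.array_equal(self.frames, other.frames)
            and np.array_equal(self.bits, other.bits)
        )

    @classmethod
    def from_bits(
        cls,
        bits: np.ndarray,
        columns: Sequence[InteractionKey],
        replicate_id: int = 0,
    ) -> "FingerprintFrameSet":
        """Build a single-replicate set with frame numbers 0..n-1."""
        bits = np.asarray(bits, dtype=np.uint8)
        n = bits.shape[0] if bits.ndim == 2 else 0
        frames = np.column_stack(
            [np.full(n, replicate_id, dtype=np.int64), np.arange(n, dtype=np.int64)]
        )
        return cls(tuple(columns), frames, bits.reshape(n, len(columns)))

    def to_dataframe(self) -> pd.DataFrame:
        """Wide DataFrame with a (ligand, residue, interaction) column
        MultiIndex and a (replicate, frame) row MultiIndex."""
        cols = pd.MultiIndex.from_tuples(
            [(k.ligand, k.residue, k.interaction_type) for k in self.columns],
            names=["ligand", "residue", "interaction"],
        )
        idx = pd.MultiIndex.from_arrays(
            [self.frames[:, 0], self.frames[:, 1]], names=["replicate", "frame"]
        )
        return pd.DataFrame(self.bits, index=idx, columns=cols)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_TRUE = {"true", "1", "1.0"}
_FALSE = {"false", "0", "0.0", ""}


def _parse_bit(raw: str, row: int, col: str) -> int:
    token = str(raw).strip().lower()
    if token in _TRUE:
        return 1
    if token in _FALSE:
        return 0
    raise ValueError(
        f"non-Boolean cell {raw!r} at data row {row}, column {col!r}: "
        "expected True/False or 1/0"
    )


def _looks_like_data(cells: Sequence[str]) -> bool:
    """Data rows hold only numbers/Booleans; header rows carry labels."""
    for c in cells:
        token = c.strip().lower()
        if not token or token in _TRUE | _FALSE:
            continue
        try:
            float(token)
        except ValueError:
            return False
    return True


def _frames_from_meta(meta_names: list[str], meta_rows: list[list[str]]) -> np.ndarray:
    n = len(meta_rows)
    names = [m.strip().lower() for m in meta_names]
    if "frame" in names:
        frame = np.array([int(float(r[names.index("frame")])) for r in meta_rows])
    else:
        frame = np.arange(n, dtype=np.int64)
    if "replicate" in names:
        rep = np.array([int(float(r[names.index("replicate")])) for r in meta_rows])
    else:
        rep = np.zeros(n, dtype=np.int64)
    return np.column_stack([rep, frame])


def _load_flat_csv(path: Path) -> FingerprintFrameSet:
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r]
    if not rows:
        raise FingerprintFormatError(f"{path}: empty file")
    header = rows[0]
    meta_names = [h for h in header if "|" not in h]
    keys = []
    for h in header[len(meta_names):]:
        if "|" not in h:
            raise FingerprintFormatError(
                f"{path}: metadata column {h!r} after fingerprint columns"
            )
        keys.append(InteractionKey.from_string(h))
    n_meta = len(meta_names)
    meta_rows, bits = [], []
    for i, row in enumerate(rows[1:]):
        meta_rows.append(row[:n_meta])
        bits.append(
            [_parse_bit(v, i, str(keys[j])) for j, v in enumerate(row[n_meta:])]
        )
    frames = _frames_from_meta(meta_names, meta_rows)
    bitmat = np.array(bits, dtype=np.uint8).reshape(len(meta_rows), len(keys))
    return FingerprintFrameSet(tuple(keys), frames, bitmat)


def _load_multi_csv(path: Path) -> FingerprintFrameSet:
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r]
    if not rows:
        raise FingerprintFormatError(f"{path}: empty file")
    # header rows precede the first row whose payload cells are all Boolean
    n_header = 0
    while n_header < len(rows) and not _looks_like_data(rows[n_header][1:]):
        n_header += 1
    if n_header < 2:
        raise FingerprintFormatError(
            f"{path}: header lacks an interaction-type level (found "
            f"{n_header} header row(s); need residue and interaction rows)"
        )
    if n_header > 3:
        raise FingerprintFormatError(f"{path}: too many header rows ({n_header})")
    header_rows = rows[:n_header]
    width = len(header_rows[0])
    # leading metadata columns are named in the first header row and blank below
    n_meta = 0
    while n_meta < width and all(
        not header_rows[lvl][n_meta].strip() for lvl in range(1, n_header)
    ):
        n_meta += 1
    meta_names = [header_rows[0][j] for j in range(n_meta)]
    keys = []
    for j in range(n_meta, width):
        levels = [header_rows[lvl][j].strip() for lvl in range(n_header)]
        if n_header == 2:
            ligand, (residue, itype) = "LIG", levels
        else:
            ligand, residue, itype = levels
        try:
            keys.append(InteractionKey(ligand, residue, itype))
        except ValueError as exc:
            raise FingerprintFormatError(
                f"{path}: bad header for column {j}: {exc}"
            ) from exc
    meta_rows, bits = [], []
    for i, row in enumerate(rows[n_header:]):
        meta_rows.append(row[:n_meta])
        bits.append(
            [_parse_bit(v, i, str(keys[j])) for j, v in enumerate(row[n_meta:])]
        )
    frames = _frames_from_meta(meta_names, meta_rows)
    bitmat = np.array(bits, dtype=np.uint8).reshape(len(meta_rows), len(keys))
    return FingerprintFrameSet(tuple(keys), frames, bitmat)


def _load_parquet(path: Path) -> FingerprintFrameSet:
    df = pd.read_parquet(path)
    meta_names = [c for c in df.columns if "|" not in str(c)]
    keys = tuple(
        InteractionKey.from_string(str(c)) for c in df.columns if "|" in str(c)
    )
    vals = df[[str(k) for k in keys]].to_numpy()
    bad = ~np.isin(vals.astype(float), (0.0, 1.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-Boolean cell {vals[i, j]!r} at data row {i}, column {keys[j]}"
        )
    meta_rows = df[meta_names].astype(str).to_numpy().tolist() if meta_names else [
        [] for _ in range(len(df))
    ]
    frames = _frames_from_meta(meta_names, meta_rows)
    return FingerprintFrameSet(keys, frames, vals.astype(np.uint8))


def load_fingerprint_table(path, dialect: str | None = None) -> FingerprintFrameSet:
    """Load a wide fingerprint table into a :class:`FingerprintFrameSet`.

    Parameters
    ----------
    path:
        Delimited-text (CSV) or parquet file.  CSV headers may be flat
        (``"LIG1|TYR272|Hydrophobic"`` per column) or multi-row
        (ligand / residue / interaction rows, ligand row optional).
        Optional leading ``replicate`` / ``frame`` metadata columns are
        recognised; otherwise frames are numbered 0..n-1 in replicate 0.
    dialect:
        ``"flat"``, ``"multi"``, ``"parquet"`` or ``None`` to auto-detect
        from the file extension and first line.

    Boolean cells may be spelled ``True``/``False`` or ``1``/``0``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        if path.suffix in {".parquet", ".pq"}:
            dialect = "parquet"
        else:
            with open(path, newline="") as fh:
                first = fh.readline()
            dialect = "flat" if "|" in first else "multi"
    if dialect == "parquet":
        return _load_parquet(path)
    if dialect == "flat":
        return _load_flat_csv(path)
    if dialect == "multi":
        return _load_multi_csv(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_fingerprint_table(fset: FingerprintFrameSet, path, dialect: str | None = None) -> None:
    """Write a fingerprint set as flat CSV, multi-row-header CSV or parquet."""
    path = Path(path)
    if dialect is None:
        dialect = "parquet" if path.suffix in {".parquet", ".pq"} else "flat"
    if dialect == "parquet":
        df = pd.DataFrame(fset.bits, columns=[str(k) for k in fset.columns])
        df.insert(0, "frame", fset.frames[:, 1])
        df.insert(0, "replicate", fset.frames[:, 0])
        df.to_parquet(path, index=False)
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        if dialect == "flat":
            writer.writerow(["replicate", "frame"] + [str(k) for k in fset.columns])
        elif dialect == "multi":
            writer.writerow(["replicate", "frame"] + [k.ligand for k in fset.columns])
            writer.writerow(["", ""] + [k.residue for k in fset.columns])
            writer.writerow(["", ""] + [k.interaction_type for k in fset.columns])
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
        for (rep, frame), row in zip(fset.frames, fset.bits):
            writer.writerow([rep, frame] + row.tolist())


# ---------------------------------------------------------------------------
# Column-space operations
# ---------------------------------------------------------------------------


def drop_interaction_types(
    fset: FingerprintFrameSet, types: Iterable[str]
) -> FingerprintFrameSet:
    """Remove all columns of the given interaction types.

    Typical use is dropping ``VdWContact``, which subsumes more specific
    interactions when enabled upstream.
    """
    types = list(types)
    unknown = [t for t in types if t not in INTERACTION_TYPES]
    if unknown:
        raise ValueError(f"unknown interaction type(s): {unknown}")
    keep = [i for i, k in enumerate(fset.columns) if k.interaction_type not in types]
    return FingerprintFrameSet(
        tuple(fset.columns[i] for i in keep), fset.frames.copy(), fset.bits[:, keep]
    )


def _union_columns(column_lists: Sequence[Sequence[InteractionKey]]) -> tuple[InteractionKey, ...]:
    seen: dict[InteractionKey, None] = {}
    for cols in column_lists:
        for k in cols:
            seen.setdefault(k)
    return tuple(sorted(seen, key=InteractionKey.sort_key))


def _reindex_bits(
    bits: np.ndarray, columns: Sequence[InteractionKey], target: Sequence[InteractionKey]
) -> np.ndarray:
    out = np.zeros((bits.shape[0], len(target)), dtype=np.uint8)
    pos = {k: j for j, k in enumerate(target)}
    for j, k in enumerate(columns):
        out[:, pos[k]] = bits[:, j]
    return out


def concat_replicates(sets: Sequence[FingerprintFrameSet]) -> FingerprintFrameSet:
    """Stack replicate fingerprint sets into one set, in the given order.

    Replicates of the same system are treated as a single entity downstream;
    each input set's replicates receive fresh consecutive replicate ids.
    Column lists are unioned (deterministically ordered) with absent
    interactions filled as 0 when the inputs disagree; identical column
    lists are preserved as-is.
    """
    sets = list(sets)
    if not sets:
        raise ValueError("concat_replicates requires at least one input set")
    first_cols = sets[0].columns
    if all(s.columns == first_cols for s in sets):
        columns = first_cols
    else:
        columns = _union_columns([s.columns for s in sets])
    bit_blocks, frame_blocks = [], []
    next_rep = 0
    for s in sets:
        bit_blocks.append(
            s.bits if s.columns == columns else _reindex_bits(s.bits, s.columns, columns)
        )
        frames = s.frames.copy()
        remap = {old: next_rep + i for i, old in enumerate(np.unique(frames[:, 0]))}
        frames[:, 0] = np.array([remap[r] for r in frames[:, 0]], dtype=np.int64)
        next_rep += len(remap)
        frame_blocks.append(frames)
    return FingerprintFrameSet(
        columns, np.vstack(frame_blocks), np.vstack(bit_blocks)
    )


def merge_column_spaces(a, b):
    """Re-express two fingerprint sets over the union of their columns.

    Interactions absent from one set are added as all-zero columns so the
    two sets become directly comparable (a "merged" pair).  Works on
    :class:`FingerprintFrameSet` and on aggregated sets (any object with
    ``columns`` and a ``with_columns(columns, bits)`` constructor hook).
    The union is ordered by (residue number, residue name, interaction
    type); inputs that already share an identical column list are returned
    unchanged, which makes the operation idempotent.
    """
    if tuple(a.columns) == tuple(b.columns):
        return a, b
    union = _union_columns([a.columns, b.columns])

    def rebuild(obj):
        mat = obj.bits if isinstance(obj, FingerprintFrameSet) else obj.ifps
        new = _reindex_bits(mat, obj.columns, union)
        if isinstance(obj, FingerprintFrameSet):
            return FingerprintFrameSet(union, obj.frames.copy(), new)
        return obj.with_columns(union, new)

    return rebuild(a), rebuild(b)
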