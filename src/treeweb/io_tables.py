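"""Tabular I/O for the pipeline: OTU count tables, sample metadata, guild maps.

TSV is the canonical interchange format (wide count tables, long result
tables); BIOM 2.1 (HDF5) count tables are accepted read-only.  All label
matching is exact and case-sensitive, and validation is strict: a malformed
cell is reported with its OTU and sample label rather than silently coerced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "SampleRecord",
    "GuildMap",
    "GUILDS",
    "ValidationError",
    "read_count_table",
    "read_sample_metadata",
    "read_guild_map",
    "write_table",
]

logger = logging.getLogger(__name__)

#: Closed set of fungal functional groups recognised by the pipeline.
GUILDS = frozenset(
    {
        "saprotroph",
        "ectomycorrhizal",
        "arbuscular_mycorrhizal",
        "plant_pathogen",
        "unknown",
        "other",
    }
)

ALLOWED_RICHNESS = frozenset({1, 2, 4, 8, 16})


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValidationError(f"duplicated {what} label: {lab!r}")
        seen.add(lab)


@dataclass
class CountTable:
    """An OTU x sample matrix of non-negative integer read counts.

    Rows are OTUs, columns are samples; both carry ordered, unique string
    labels.  The matrix is stored as an int64 numpy array.
    """

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValidationError(
                f"shape {self.counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        _check_unique(self.otu_ids, "OTU")
        _check_unique(self.sample_ids, "sample")
        if not np.issubdtype(self.counts.dtype, np.integer):
            frac = self.counts != np.floor(self.counts)
            if np.any(frac):
                i, j = np.argwhere(frac)[0]
                raise ValidationError(
                    f"non-integer count {self.counts[i, j]!r} at "
                    f"OTU {self.otu_ids[i]!r}, sample {self.sample_ids[j]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count {self.counts[i, j]} at "
                f"OTU {self.otu_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        self.counts = self.counts.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        """Column subset in the given order."""
        idx = [self.sample_index(s) for s in sample_ids]
        return CountTable(list(self.otu_ids), list(sample_ids), self.counts[:, idx])

    def select_otus(self, otu_ids: Sequence[str]) -> "CountTable":
        pos = {o: i for i, o in enumerate(self.otu_ids)}
        idx = [pos[o] for o in otu_ids]
        return CountTable(list(otu_ids), list(self.sample_ids), self.counts[idx, :])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.otu_ids == other.otu_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass(frozen=True)
class SampleRecord:
    """One soil sample: where it was taken and under which tree."""

    sample_id: str
    plot_id: str
    tree_species: str
    plot_richness: int
    replicate: int

    def __post_init__(self) -> None:
        if self.plot_richness not in ALLOWED_RICHNESS:
            raise ValidationError(
                f"sample {self.sample_id!r}: plot_richness {self.plot_richness} "
                f"not in {sorted(ALLOWED_RICHNESS)}"
            )
        if not 1 <= self.replicate <= 5:
            raise ValidationError(
                f"sample {self.sample_id!r}: replicate {self.replicate} outside 1-5"
            )


@dataclass
class GuildMap:
    """otu_id -> functional guild; absent OTUs resolve to ``unknown``."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {g for g in self.mapping.values() if g not in GUILDS}
        if bad:
            raise ValidationError(f"guild values outside the closed set: {sorted(bad)}")

    def __getitem__(self, otu_id: str) -> str:
        return self.mapping.get(otu_id, "unknown")

    def get(self, otu_id: str) -> str:
        return self[otu_id]

    def __len__(self) -> int:
        return len(self.mapping)


def read_count_table(path: str | Path, format_hint: str | None = None) -> CountTable:
    """Read a wide count table (TSV, or BIOM 2.1 HDF5 with hint ``"biom"``).

    TSV layout: first column holds OTU ids, header row holds sample ids.
    Row and column order of the file is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format_hint or ("biom" if path.suffix == ".biom" else "tsv")
    if fmt == "biom":
        return _read_biom(path)
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    otu_ids = [str(x) for x in df.index]
    sample_ids = [str(x) for x in df.columns]
    mat = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col].to_numpy()):
            try:
                val = int(raw)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"non-integer count {raw!r} at OTU {otu_ids[i]!r}, "
                    f"sample {sample_ids[j]!r}"
                ) from None
            mat[i, j] = val
    return CountTable(otu_ids, sample_ids, mat)


def _read_biom(path: Path) -> CountTable:
    # BIOM 2.1 stores the matrix in CSR layout under observation/matrix.
    import h5py
    from scipy import sparse

    with h5py.File(path, "r") as f:
        otu_ids = [x.decode() for x in f["observation/ids"][:]]
        sample_ids = [x.decode() for x in f["sample/ids"][:]]
        data = f["observation/matrix/data"][:]
        indices = f["observation/matrix/indices"][:]
        indptr = f["observation/matrix/indptr"][:]
    mat = sparse.csr_matrix(
        (data, indices, indptr), shape=(len(otu_ids), len(sample_ids))
    ).toarray()
    return CountTable(otu_ids, sample_ids, mat)


_META_COLUMNS = ["sample_id", "plot_id", "tree_species", "plot_richness", "replicate"]


def read_sample_metadata(path: str | Path) -> list[SampleRecord]:
    """Read the sample metadata TSV and validate the design constraints."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"metadata missing columns {missing}; expected header {_META_COLUMNS}"
        )
    records = []
    seen: set[tuple[str, str, str]] = set()
    for row in df.itertuples(index=False):
        rec = SampleRecord(
            sample_id=str(row.sample_id),
            plot_id=str(row.plot_id),
            tree_species=str(row.tree_species),
            plot_richness=int(row.plot_richness),
            replicate=int(row.replicate),
        )
        key = (rec.plot_id, rec.tree_species, str(rec.replicate))
        if key in seen:
            raise ValidationError(
                f"duplicate (plot, species, replicate) triple: {key}"
            )
        seen.add(key)
        records.append(rec)
    return records


def read_guild_map(path: str | Path) -> GuildMap:
    """Read otu_id -> guild; strings outside the closed set become ``other``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("otu_id", "guild") if c not in df.columns]
    if missing:
        raise ValidationError(f"guild table missing columns {missing}")
    mapping: dict[str, str] = {}
    for row in df.itertuples(index=False):
        guild = str(row.guild)
        if guild not in GUILDS:
            logger.warning("guild %r for OTU %r not recognised; coerced to 'other'",
                           guild, row.otu_id)
            guild = "other"
        mapping[str(row.otu_id)] = guild
    return GuildMap(mapping)


def _format_value(v: object) -> str:
    if isinstance(v, (bool, np.bool_)):
        return str(bool(v))
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        # 6 significant digits keeps outputs byte-stable across runs
        return f"{float(v):.6g}"
    return str(v)


def write_table(
    path: str | Path,
    rows: Sequence[Mapping[str, object]],
    schema: Sequence[str],
) -> None:
    """Write rows as TSV with a fixed column order and 6-significant-digit floats."""
    path = Path(path)
    lines = ["\t".join(schema)]
    for k, row in enumerate(rows):
        extra = set(row) - set(schema)
        missing = set(schema) - set(row)
        if extra or missing:
            raise ValidationError(
                f"row {k} does not conform to schema: "
                f"missing {sorted(missing)}, unexpected {sorted(extra)}"
            )
        lines.append("\t".join(_format_value(row[c]) for c in schema))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_count_table(path: str | Path, table: CountTable) -> None:
    """Write a CountTable in the canonical wide TSV layout."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("otu_id\t" + "\t".join(table.sample_ids) + "\n")
        for otu, row in zip(table.otu_ids, table.counts):
            fh.write(otu + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
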