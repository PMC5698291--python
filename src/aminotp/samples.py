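"""Domain types and delimited-file I/O for isotope sample tables.

A sample is one individual's hair measurements: bulk-tissue carbon and
nitrogen isotope values (d13C vs VPDB, d15N vs AIR, in per mil) and,
optionally, compound-specific nitrogen isotope values of glutamic acid
(a trophic amino acid) and phenylalanine (a source amino acid).
Amino-acid values carry a per-sample 1-sigma measurement uncertainty,
0.5 per mil by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .errors import PlausibilityWarning, SchemaError, ValidationError

#: Per-mil values outside this band are almost certainly unit or transcription
#: errors for natural hair keratin, but are kept (with a warning) because the
#: bounds are heuristic.
PLAUSIBLE_RANGE = (-60.0, 60.0)

#: Default 1-sigma uncertainty on amino-acid d15N values, per mil.
DEFAULT_AA_SIGMA = 0.5

MANDATORY_COLUMNS = ("sample_id", "species", "d13c_bulk", "d15n_bulk")
OPTIONAL_COLUMNS = ("guild", "d15n_glu", "d15n_phe", "sigma_glu", "sigma_phe")

# Common header spellings seen in museum / lab exports, mapped to canonical
# snake_case names. Matching is case-insensitive after stripping whitespace.
_HEADER_ALIASES = {
    "id": "sample_id",
    "sampleid": "sample_id",
    "sample": "sample_id",
    "taxon": "species",
    "feeding_guild": "guild",
    "d13c": "d13c_bulk",
    "d13c_bulk": "d13c_bulk",
    "delta13c": "d13c_bulk",
    "d15n": "d15n_bulk",
    "d15n_bulk": "d15n_bulk",
    "delta15n": "d15n_bulk",
    "d15n_glu": "d15n_glu",
    "glu": "d15n_glu",
    "d15nglu": "d15n_glu",
    "d15n_phe": "d15n_phe",
    "phe": "d15n_phe",
    "d15nphe": "d15n_phe",
    "sigma_glu": "sigma_glu",
    "sd_glu": "sigma_glu",
    "sigma_phe": "sigma_phe",
    "sd_phe": "sigma_phe",
}


def _canonical_header(name: str) -> str:
    key = name.strip().lower().replace("δ", "d").replace("‰", "").strip("_ ")
    return _HEADER_ALIASES.get(key, key)


@dataclass
class IsotopeSample:
    """One individual's bulk and amino-acid isotope measurements."""

    sample_id: str
    species: str
    d13c_bulk: float
    d15n_bulk: float
    guild: str = ""
    d15n_glu: float | None = None
    d15n_phe: float | None = None
    sigma_glu: float = DEFAULT_AA_SIGMA
    sigma_phe: float = DEFAULT_AA_SIGMA

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if not self.species:
            raise ValidationError(f"sample {self.sample_id!r}: species must be non-empty")
        for name in ("d13c_bulk", "d15n_bulk"):
            value = getattr(self, name)
            if value is None or not math.isfinite(value):
                raise ValidationError(f"sample {self.sample_id!r}: {name} must be finite")
        for name in ("d15n_glu", "d15n_phe"):
            value = getattr(self, name)
            if value is not None and not math.isfinite(value):
                raise ValidationError(f"sample {self.sample_id!r}: {name} must be finite if present")
        if self.sigma_glu < 0 or self.sigma_phe < 0:
            raise ValidationError(f"sample {self.sample_id!r}: sigma_glu/sigma_phe must be >= 0")
        lo, hi = PLAUSIBLE_RANGE
        for name in ("d13c_bulk", "d15n_bulk", "d15n_glu", "d15n_phe"):
            value = getattr(self, name)
            if value is not None and not lo <= value <= hi:
                warnings.warn(
                    f"sample {self.sample_id!r}: {name} = {value} per mil is outside "
                    f"the plausible range [{lo}, {hi}]",
                    PlausibilityWarning,
                    stacklevel=2,
                )

    @property
    def has_aa(self) -> bool:
        """True when both glutamic-acid and phenylalanine values are present."""
        return self.d15n_glu is not None and self.d15n_phe is not None


@dataclass
class Dataset:
    """Ordered collection of samples with unique ids."""

    samples: list[IsotopeSample] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        for s in self.samples:
            seen[s.sample_id] = seen.get(s.sample_id, 0) + 1
        dupes = sorted(k for k, v in seen.items() if v > 1)
        if dupes:
            raise ValidationError(f"duplicate sample_id values: {dupes}")

    def __iter__(self) -> Iterator[IsotopeSample]:
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    def __getitem__(self, i: int) -> IsotopeSample:
        return self.samples[i]

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with canonical column names; absent AA values become NaN."""
        cols = MANDATORY_COLUMNS + OPTIONAL_COLUMNS
        return pd.DataFrame([{c: getattr(s, c) for c in cols} for s in self.samples])


def read_samples(
    path: str | Path,
    *,
    delimiter: str = ",",
    header_map: Mapping[str, str] | None = None,
    provenance: str | None = None,
) -> Dataset:
    """Read a sample table from a delimited text file.

    The header must contain (possibly via aliases or ``header_map``)
    ``sample_id``, ``species``, ``d13c_bulk`` and ``d15n_bulk``. Rows lacking
    amino-acid values are kept with those fields absent; malformed numeric
    cells are collected and reported with their row numbers.

    Raises
    ------
    SchemaError
        if a mandatory column is missing.
    ValidationError
        listing every offending row for duplicate ids or unparseable numbers.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    rename: dict[str, str] = {}
    extra = {k.strip().lower(): v for k, v in (header_map or {}).items()}
    for col in raw.columns:
        key = col.strip().lower()
        rename[col] = extra.get(key, _canonical_header(col))
    table = raw.rename(columns=rename)

    missing = [c for c in MANDATORY_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing mandatory column(s): {missing}")

    numeric_required = ("d13c_bulk", "d15n_bulk")
    numeric_optional = ("d15n_glu", "d15n_phe", "sigma_glu", "sigma_phe")
    problems: list[str] = []
    samples: list[IsotopeSample] = []
    for idx, row in table.iterrows():
        rownum = int(idx) + 2  # 1-based, counting the header line
        kwargs: dict[str, object] = {
            "sample_id": str(row["sample_id"]).strip(),
            "species": str(row["species"]).strip(),
            "guild": str(row["guild"]).strip() if "guild" in table.columns else "",
        }
        ok = True
        for col in numeric_required:
            cell = str(row[col]).strip()
            try:
                kwargs[col] = float(cell)
            except ValueError:
                problems.append(f"row {rownum}: column {col!r}: cannot parse {cell!r}")
                ok = False
        for col in numeric_optional:
            if col not in table.columns:
                continue
            cell = str(row[col]).strip()
            if cell == "":
                continue  # absent is fine; defaults apply for sigmas
            try:
                kwargs[col] = float(cell)
            except ValueError:
                problems.append(f"row {rownum}: column {col!r}: cannot parse {cell!r}")
                ok = False
        if ok:
            try:
                samples.append(IsotopeSample(**kwargs))  # type: ignore[arg-type]
            except ValidationError as exc:
                problems.append(f"row {rownum}: {exc}")
    if problems:
        raise ValidationError(f"{path.name}: {len(problems)} problem(s):\n" + "\n".join(problems))
    return Dataset(samples, provenance=provenance if provenance is not None else str(path))


def write_samples(path: str | Path, dataset: Dataset, *, ndigits: int = 6) -> None:
    """Write a dataset back to CSV (inverse of :func:`read_samples` at 6 dp)."""
    frame = dataset.to_frame()
    frame.to_csv(path, index=False, float_format=f"%.{ndigits}f", na_rep="")


def write_results(path: str | Path, rows: Sequence[Mapping] | pd.DataFrame, *, ndigits: int = 6) -> None:
    """Write result records to CSV with numeric fields at fixed precision.

    NaN / None values are serialized as empty cells so they read back as
    absent. Raises :class:`ValidationError` on empty or ragged input.
    """
    if isinstance(rows, pd.DataFrame):
        frame = rows
        if frame.empty:
            raise ValidationError("write_results: rows must be non-empty")
    else:
        if not rows:
            raise ValidationError("write_results: rows must be non-empty")
        keys = list(rows[0].keys())
        for i, r in enumerate(rows):
            if list(r.keys()) != keys:
                raise ValidationError(f"write_results: row {i} fields differ from row 0")
        frame = pd.DataFrame(list(rows), columns=keys)
    frame.to_csv(path, index=False, float_format=f"%.{ndigits}f", na_rep="")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results CSV written by :func:`write_results` (empty cells -> NaN)."""
    return pd.read_csv(path)
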