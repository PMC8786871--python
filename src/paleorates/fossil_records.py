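"""Curation of fossil occurrence tables into analysis-ready datasets.

A fossil occurrence is the presence of a taxon at one stratigraphic level of
one fossil locality, dated with an uncertainty window ``[min_age, max_age]``
in Ma before present (larger = older).  This module reads delimited occurrence
tables, applies the standard curation filters (taxonomic-qualifier exclusion,
dating-uncertainty cap), restructures the records into four dataset variants
(species occurrences, fossil specimens, stage-dated occurrences, genus-level
occurrences), and draws age-randomised replicate datasets in which every
occurrence age is resampled uniformly within its window.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd


class Rank(str, Enum):
    SPECIES = "species"
    GENUS = "genus"


class Qualifier(str, Enum):
    NONE = "none"
    CF = "cf"
    AFF = "aff"
    QUESTIONABLE = "questionable"


class DatasetMode(str, Enum):
    SPECIES_OCCURRENCE = "species_occurrence"
    FOSSIL_SPECIMEN = "fossil_specimen"
    AGE_STAGE = "age_stage"
    GENUS = "genus"


class SchemaError(ValueError):
    """A required column is missing from the input file."""


class ValidationError(ValueError):
    """A row violates an occurrence-record invariant."""


#: regexes that detect open-nomenclature qualifiers embedded in taxon names
_QUALIFIER_PATTERNS = (
    (re.compile(r"\bcf\.?(\s|$)", re.IGNORECASE), Qualifier.CF),
    (re.compile(r"\baff\.?(\s|$)", re.IGNORECASE), Qualifier.AFF),
    (re.compile(r"\?"), Qualifier.QUESTIONABLE),
)

_QUALIFIER_ALIASES = {
    "": Qualifier.NONE,
    "none": Qualifier.NONE,
    "cf": Qualifier.CF,
    "cf.": Qualifier.CF,
    "aff": Qualifier.AFF,
    "aff.": Qualifier.AFF,
    "?": Qualifier.QUESTIONABLE,
    "questionable": Qualifier.QUESTIONABLE,
}


def parse_qualifier(name: str) -> Qualifier:
    """Detect an open-nomenclature qualifier (cf., aff., ?) in a taxon name."""
    for pattern, qual in _QUALIFIER_PATTERNS:
        if pattern.search(name):
            return qual
    return Qualifier.NONE


def strip_qualifier(name: str) -> str:
    """Remove qualifier tokens from a taxon name, normalising whitespace."""
    out = name
    for pattern, _ in _QUALIFIER_PATTERNS:
        out = pattern.sub(" ", out)
    return " ".join(out.split())


@dataclass(frozen=True)
class OccurrenceRecord:
    """One fossil occurrence/specimen row.

    Ages are Ma before present, so ``max_age >= min_age >= 0`` and larger
    values are older.
    """

    taxon_name: str
    min_age: float
    max_age: float
    rank: Rank = Rank.SPECIES
    qualifier: Qualifier = Qualifier.NONE
    locality: str = ""
    stratum: str = ""
    specimen_id: Optional[str] = None
    clade: str = ""

    def __post_init__(self) -> None:
        if not self.taxon_name or not self.taxon_name.strip():
            raise ValidationError("taxon_name must be non-empty")
        if not (0.0 <= self.min_age <= self.max_age):
            raise ValidationError(
                f"require max_age >= min_age >= 0, got "
                f"[{self.min_age}, {self.max_age}] for {self.taxon_name!r}"
            )
        if self.rank is Rank.SPECIES and len(self.taxon_name.split()) < 2:
            raise ValidationError(
                f"species-rank name must contain genus and epithet: "
                f"{self.taxon_name!r}"
            )

    @property
    def genus(self) -> str:
        return self.taxon_name.split()[0]

    @property
    def age_range(self) -> float:
        return self.max_age - self.min_age


@dataclass
class OccurrenceTable:
    """Ordered collection of occurrence records with provenance metadata."""

    records: Sequence[OccurrenceRecord]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon": [r.taxon_name for r in self.records],
                "rank": [r.rank.value for r in self.records],
                "qualifier": [r.qualifier.value for r in self.records],
                "min_age": [r.min_age for r in self.records],
                "max_age": [r.max_age for r in self.records],
                "locality": [r.locality for r in self.records],
                "stratum": [r.stratum for r in self.records],
                "specimen_id": [r.specimen_id or "" for r in self.records],
                "clade": [r.clade for r in self.records],
            }
        )


@dataclass
class StageTable:
    """Mapping from stage name to (lower_bound, upper_bound) in Ma.

    ``lower_bound`` is the older boundary, so ``lower_bound > upper_bound``.
    """

    stages: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.stages.items():
            if not lo > hi >= 0:
                raise ValidationError(
                    f"stage {name!r}: require lower_bound > upper_bound >= 0, "
                    f"got ({lo}, {hi})"
                )

    def find(self, min_age: float, max_age: float) -> Optional[str]:
        """Return the stage whose bounds contain [min_age, max_age], if any.

        Falls back to the stage containing the window midpoint when no stage
        fully contains the window.
        """
        for name, (lo, hi) in self.stages.items():
            if lo >= max_age and hi <= min_age:
                return name
        mid = 0.5 * (min_age + max_age)
        for name, (lo, hi) in self.stages.items():
            if hi <= mid <= lo:
                return name
        return None


@dataclass
class AnalysisDataset:
    """Point-of-analysis dataset: one row per (taxon_key, age window)."""

    mode: DatasetMode
    rows: pd.DataFrame  # columns: taxon_key, min_age, max_age
    stage_table_used: Optional[StageTable] = None

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_taxa(self) -> int:
        return self.rows["taxon_key"].nunique()


@dataclass
class ReplicateSet:
    """Age-randomised replicate datasets (taxon_key, age)."""

    replicates: Sequence[pd.DataFrame]
    seed: int
    n_replicates: int = 20

    def __post_init__(self) -> None:
        if len(self.replicates) != self.n_replicates:
            raise ValidationError(
                f"expected {self.n_replicates} replicates, got "
                f"{len(self.replicates)}"
            )


_DEFAULT_SCHEMA = {
    "taxon": "taxon",
    "min_age": "min_age",
    "max_age": "max_age",
    "rank": "rank",
    "qualifier": "qualifier",
    "locality": "locality",
    "stratum": "stratum",
    "specimen_id": "specimen_id",
    "clade": "clade",
}

_REQUIRED = ("taxon", "min_age", "max_age")


def read_occurrence_table(
    path: Union[str, Path, io.IOBase],
    schema: Optional[Mapping[str, str]] = None,
    sep: Optional[str] = None,
) -> OccurrenceTable:
    """Read a delimited occurrence table into an :class:`OccurrenceTable`.

    Parameters
    ----------
    path
        CSV/TSV file (or open text buffer).  The delimiter is sniffed unless
        ``sep`` is given.
    schema
        Maps canonical field names (``taxon``, ``min_age``, ``max_age``, and
        optionally ``rank``, ``qualifier``, ``locality``, ``stratum``,
        ``specimen_id``, ``clade``) to the file's column names.  Defaults to
        identity.

    Raises
    ------
    SchemaError
        if a required mapped column is absent.
    ValidationError
        if a row violates the age or naming invariants (message cites the
        1-based data row number).
    """
    colmap = dict(_DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str)
    for key in _REQUIRED:
        if colmap[key] not in df.columns:
            raise SchemaError(f"missing required column {colmap[key]!r}")
    # an explicitly mapped column must exist even if it is optional
    for key, col in (schema or {}).items():
        if col not in df.columns:
            raise SchemaError(f"missing mapped column {col!r} (field {key})")

    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))
        name = str(rowd[colmap["taxon"]]).strip()
        try:
            min_age = float(rowd[colmap["min_age"]])
            max_age = float(rowd[colmap["max_age"]])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"row {i}: unparseable age: {exc}") from exc

        def _opt(key: str, default: str = "") -> str:
            col = colmap[key]
            if col in df.columns and pd.notna(rowd[col]):
                return str(rowd[col]).strip()
            return default

        rank_str = _opt("rank", Rank.SPECIES.value).lower()
        try:
            rank = Rank(rank_str)
        except ValueError as exc:
            raise ValidationError(f"row {i}: unknown rank {rank_str!r}") from exc

        qual_str = _opt("qualifier", "").lower()
        if qual_str in _QUALIFIER_ALIASES:
            qualifier = _QUALIFIER_ALIASES[qual_str]
        else:
            raise ValidationError(f"row {i}: unknown qualifier {qual_str!r}")
        if qualifier is Qualifier.NONE:
            qualifier = parse_qualifier(name)
        name = strip_qualifier(name)

        try:
            records.append(
                OccurrenceRecord(
                    taxon_name=name,
                    min_age=min_age,
                    max_age=max_age,
                    rank=rank,
                    qualifier=qualifier,
                    locality=_opt("locality"),
                    stratum=_opt("stratum"),
                    specimen_id=_opt("specimen_id") or None,
                    clade=_opt("clade"),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc

    src = str(path) if isinstance(path, (str, Path)) else "<buffer>"
    return OccurrenceTable(records=records, provenance=f"read from {src}")


def write_occurrence_table(table: OccurrenceTable, path: Union[str, Path]) -> None:
    """Write a table back to CSV (round-trips through read_occurrence_table)."""
    table.to_frame().to_csv(path, index=False)


def filter_taxonomy(
    table: OccurrenceTable, target_rank: Rank = Rank.SPECIES
) -> OccurrenceTable:
    """Drop taxonomically uncertain and under-identified records.

    Records carrying an open-nomenclature qualifier (cf., aff., ?) are
    removed, as are records identified below ``target_rank`` (genus-rank rows
    when species are required).  Relative order is preserved.
    """
    keep = []
    for rec in table.records:
        if rec.qualifier is not Qualifier.NONE:
            continue
        if target_rank is Rank.SPECIES and rec.rank is not Rank.SPECIES:
            continue
        keep.append(rec)
    return OccurrenceTable(records=keep, provenance=table.provenance)


def filter_age_uncertainty(
    table: OccurrenceTable, max_range: float = 15.0
) -> OccurrenceTable:
    """Drop records whose dating window is not strictly narrower than
    ``max_range`` Ma (default 15; the boundary case is removed)."""
    if max_range <= 0:
        raise ValueError(f"max_range must be positive, got {max_range}")
    keep = [r for r in table.records if r.age_range < max_range]
    return OccurrenceTable(records=keep, provenance=table.provenance)


def build_dataset(
    table: OccurrenceTable,
    mode: Union[DatasetMode, str],
    stage_table: Optional[StageTable] = None,
) -> AnalysisDataset:
    """Restructure a curated table into one of the four dataset variants.

    * ``species_occurrence`` — deduplicate by (species, locality, stratum);
      one row per occurrence.
    * ``fossil_specimen`` — one row per specimen, no deduplication.
    * ``age_stage`` — species occurrences, with each window replaced by the
      bounds of its stage.
    * ``genus`` — deduplicate by (genus, locality, stratum).
    """
    mode = DatasetMode(mode)
    if mode is DatasetMode.AGE_STAGE and stage_table is None:
        raise ValueError("age_stage mode requires a stage table")

    rows: list[tuple[str, float, float]] = []
    if mode is DatasetMode.FOSSIL_SPECIMEN:
        rows = [(r.taxon_name, r.min_age, r.max_age) for r in table.records]
    else:
        seen: set[tuple[str, str, str]] = set()
        for rec in table.records:
            key_taxon = rec.genus if mode is DatasetMode.GENUS else rec.taxon_name
            key = (key_taxon, rec.locality, rec.stratum)
            if key in seen:
                continue
            seen.add(key)
            if mode is DatasetMode.AGE_STAGE:
                assert stage_table is not None
                stage = stage_table.find(rec.min_age, rec.max_age)
                if stage is None:
                    raise ValidationError(
                        f"occurrence {rec.taxon_name!r} "
                        f"[{rec.min_age}, {rec.max_age}] matches no stage"
                    )
                lo, hi = stage_table.stages[stage]
                rows.append((key_taxon, hi, lo))
            else:
                rows.append((key_taxon, rec.min_age, rec.max_age))

    df = pd.DataFrame(rows, columns=["taxon_key", "min_age", "max_age"])
    return AnalysisDataset(mode=mode, rows=df, stage_table_used=stage_table)


def resample_replicates(
    dataset: AnalysisDataset, n: int = 20, seed: int = 0
) -> ReplicateSet:
    """Draw ``n`` point-dated replicates, each occurrence age uniform within
    its ``[min_age, max_age]`` window.  Deterministic given ``seed``."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    lo = dataset.rows["min_age"].to_numpy(float)
    hi = dataset.rows["max_age"].to_numpy(float)
    if not np.all(np.isfinite(lo)) or not np.all(np.isfinite(hi)):
        raise ValidationError("age windows must be finite for resampling")
    reps = []
    for _ in range(n):
        ages = lo + rng.random(len(lo)) * (hi - lo)
        reps.append(
            pd.DataFrame(
                {"taxon_key": dataset.rows["taxon_key"].to_numpy(), "age": ages}
            )
        )
    return ReplicateSet(replicates=reps, seed=seed, n_replicates=n)


def summarize_counts(dataset: AnalysisDataset) -> tuple[int, int]:
    """Return (number of distinct taxa, number of dataset rows)."""
    return dataset.n_taxa, dataset.n_rows


def write_replicates(
    reps: ReplicateSet, outdir: Union[str, Path], prefix: str = "replicate"
) -> list[Path]:
    """Write one delimited file per replicate (columns taxon_key, age)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, df in enumerate(reps.replicates, start=1):
        p = outdir / f"{prefix}_{i:02d}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths.append(p)
    return paths


def replicate_to_species_data(replicate: pd.DataFrame) -> dict[str, np.ndarray]:
    """Group a point-dated replicate into per-species fossil-age arrays,
    sorted oldest-first (the shape downstream likelihoods expect)."""
    out: dict[str, np.ndarray] = {}
    for taxon, grp in replicate.groupby("taxon_key", sort=True):
        out[str(taxon)] = np.sort(grp["age"].to_numpy(float))[::-1]
    return out
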