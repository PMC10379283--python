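"""Reading, validating and summarising locality tables of observed heterozygosity.

Each row of a locality table is one sampled population of *Rattus rattus* or
*R. norvegicus*: where it was sampled, which study reported it, its observed
heterozygosity (Ho) from nuclear markers, and whether the site is insular or
continental.  Ho is the one diversity metric comparable across compiled
studies, and only nuclear markers (microsatellites, SNPs, RAD-seq) are
admitted — mitochondrial records are rejected at parse time because their
Ho is not commensurable with diploid nuclear Ho.
"""

from __future__ import annotations

import csv
import logging
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

SPECIES = ("rattus", "norvegicus")
INSULARITY = ("island", "mainland")
NUCLEAR_MARKERS = ("microsatellite", "SNP", "RADseq")

#: canonical column names; a config mapping may rename file headers to these
REQUIRED_COLUMNS = (
    "species",
    "study_id",
    "site",
    "lon",
    "lat",
    "ho",
    "insularity",
    "marker",
)


@dataclass(frozen=True)
class LocalityRecord:
    """One sampled population with coordinates, species, Ho and insularity."""

    species: str
    study_id: str
    site: str
    lon: float
    lat: float
    ho: float
    insularity: str
    marker: str

    def validate(self) -> Optional[str]:
        """Return a rejection reason, or None if the record is admissible."""
        if self.species not in SPECIES:
            return f"unknown species {self.species!r}"
        if self.marker not in NUCLEAR_MARKERS:
            return "non-nuclear marker"
        if not (math.isfinite(self.ho) and 0.0 <= self.ho <= 1.0):
            return "ho out of range"
        if not (math.isfinite(self.lon) and -180.0 <= self.lon <= 180.0):
            return "lon out of range"
        if not (math.isfinite(self.lat) and -90.0 <= self.lat <= 90.0):
            return "lat out of range"
        if self.insularity not in INSULARITY:
            return f"unknown insularity {self.insularity!r}"
        return None


class MissingColumnError(ValueError):
    """A required column is absent from the locality file header."""


@dataclass
class ParseReport:
    """Bookkeeping from one read_localities call."""

    n_read: int = 0
    n_kept: int = 0
    rejected: Counter = None  # reason -> count
    n_duplicates: int = 0

    def __post_init__(self):
        if self.rejected is None:
            self.rejected = Counter()


def _coerce(row: Mapping[str, str]) -> LocalityRecord:
    def num(key: str) -> float:
        raw = row[key].strip()
        try:
            return float(raw)
        except ValueError:
            return math.nan

    return LocalityRecord(
        species=row["species"].strip(),
        study_id=row["study_id"].strip(),
        site=row["site"].strip(),
        lon=num("lon"),
        lat=num("lat"),
        ho=num("ho"),
        insularity=row["insularity"].strip(),
        marker=row["marker"].strip(),
    )


def read_localities(
    path: str | Path,
    species_filter: Optional[str] = None,
    columns: Optional[Mapping[str, str]] = None,
) -> tuple[list[LocalityRecord], ParseReport]:
    """Read a locality CSV, keeping only rows that satisfy the invariants.

    Parameters
    ----------
    path
        CSV file (UTF-8, comma separated, header row).
    species_filter
        If given, only records of this species are returned; other species
        do not count as rejections.
    columns
        Optional mapping from canonical column names to the headers actually
        used in the file, so externally compiled tables can be ingested
        without editing (config key ``localities.columns``).

    Returns
    -------
    (records, report)
        Valid records in file order, plus counts of rejected rows by reason.
        Duplicate (species, lon, lat) rows are retained but counted.

    Raises
    ------
    MissingColumnError
        If a required column is missing from the header.
    """
    path = Path(path)
    rename = dict(columns or {})
    report = ParseReport()
    records: list[LocalityRecord] = []
    seen: set[tuple] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for canonical in REQUIRED_COLUMNS:
            src = rename.get(canonical, canonical)
            if src not in header:
                raise MissingColumnError(
                    f"required column {canonical!r} (file header {src!r}) "
                    f"not found in {path}"
                )
        for raw in reader:
            report.n_read += 1
            row = {c: raw[rename.get(c, c)] for c in REQUIRED_COLUMNS}
            rec = _coerce(row)
            reason = rec.validate()
            if reason is not None:
                report.rejected[reason] += 1
                logger.info("rejected row %d: %s", report.n_read, reason)
                continue
            if species_filter is not None and rec.species != species_filter:
                continue
            key = (rec.species, rec.lon, rec.lat)
            if key in seen:
                report.n_duplicates += 1
                logger.info("duplicate (species, lon, lat): %s", key)
            seen.add(key)
            records.append(rec)
            report.n_kept += 1
    return records, report


def write_localities(records: Iterable[LocalityRecord], path: str | Path) -> None:
    """Serialise records to CSV with the canonical header (round-trip safe)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(REQUIRED_COLUMNS)
        for r in records:
            writer.writerow(
                [r.species, r.study_id, r.site, repr(r.lon), repr(r.lat),
                 repr(r.ho), r.insularity, r.marker]
            )


def summarize_ho(
    records: Sequence[LocalityRecord], species: str
) -> tuple[float, float, int]:
    """Mean, sample standard deviation (n-1) and count of Ho for one species.

    For a single record the sd is defined as 0 rather than NaN so summary
    tables stay numeric.
    """
    values = [r.ho for r in records if r.species == species]
    n = len(values)
    if n == 0:
        raise ValueError(f"no records for species {species!r}")
    mean = sum(values) / n
    if n == 1:
        return mean, 0.0, 1
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var), n
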