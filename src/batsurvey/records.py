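"""Detection-record data model, delimited-text I/O, and record filtering.

A *detection record* is one identified echolocation call sequence (a bat
pass) with spatial, temporal, and taxonomic attributes.  All timestamps are
expressed in minutes from the start of the 8-hour recording window
(21:30-05:30 local time), so every valid timestamp lies in ``[0, 480)``.

The module also implements the taxon-grouping rules used for richness
analyses (acoustically inseparable congeners collapsed into a single
taxon), guild assignment (short-/middle-/long-range echolocators), and the
temporal/spatial filters that define a sampling scheme.
"""

from __future__ import annotations

import csv
import enum
import io
import warnings
from dataclasses import dataclass, replace
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "NIGHT_MINUTES",
    "Microhabitat",
    "TemporalPattern",
    "TaxonLevel",
    "Guild",
    "DetectionRecord",
    "SamplingScheme",
    "FormatError",
    "read_records",
    "write_records",
    "parse_clock_time",
    "collapse_taxa",
    "filter_temporal",
    "filter_design",
    "summarize_identification",
    "identification_summary_from_counts",
    "IdentificationSummary",
    "round_half_up",
    "DEFAULT_TAXON_GROUPS",
    "DEFAULT_GUILDS",
]

#: Length of the nightly recording window in minutes (21:30-05:30).
NIGHT_MINUTES = 480

#: Minutes from midnight at which the recording window opens (21:30).
WINDOW_START_MINUTE_OF_DAY = 21 * 60 + 30


class Microhabitat(str, enum.Enum):
    """Sampling stratum within a forest plot."""

    GROUND = "GR"
    CANOPY = "CA"
    GAP = "GA"

    @classmethod
    def parse(cls, text: str) -> "Microhabitat":
        key = str(text).strip().upper()
        aliases = {
            "GR": cls.GROUND, "GROUND": cls.GROUND, "FOREST GROUND": cls.GROUND,
            "CA": cls.CANOPY, "CANOPY": cls.CANOPY,
            "GA": cls.GAP, "GAP": cls.GAP, "FOREST GAP": cls.GAP,
        }
        try:
            return aliases[key]
        except KeyError:
            raise ValueError(f"unknown microhabitat {text!r}") from None


class TemporalPattern(str, enum.Enum):
    """Within-night recording window of a sampling scheme.

    ``FULL_NIGHT``
        the whole 8-hour window, ``[0, 480)`` minutes.
    ``FIRST_4H``
        the first 4 hours after sunset (21:30-01:30), ``[0, 240)``.
    ``SPLIT_2H_2H``
        2 hours after sunset plus 2 hours before sunrise
        (21:30-23:30 and 03:30-05:30), ``[0, 120) U [360, 480)``.
    """

    FULL_NIGHT = "full_night"
    FIRST_4H = "first_4h"
    SPLIT_2H_2H = "split_2h_2h"

    @property
    def windows(self) -> tuple[tuple[float, float], ...]:
        """Half-open kept intervals in minutes from night start."""
        if self is TemporalPattern.FULL_NIGHT:
            return ((0.0, 480.0),)
        if self is TemporalPattern.FIRST_4H:
            return ((0.0, 240.0),)
        return ((0.0, 120.0), (360.0, 480.0))

    def contains(self, t: float) -> bool:
        return any(lo <= t < hi for lo, hi in self.windows)


class TaxonLevel(str, enum.Enum):
    SPECIES = "species"
    SPECIES_GROUP = "species_group"
    GENUS = "genus"
    GENUS_GROUP = "genus_group"
    ORDER = "order"


class Guild(str, enum.Enum):
    """Echolocation guild: short-, middle-, or long-range echolocators."""

    SRE = "SRE"
    MRE = "MRE"
    LRE = "LRE"
    UNKNOWN = "UNKNOWN"


#: Congeners whose calls cannot be reliably separated acoustically are
#: collapsed to a genus-level group and counted as one taxon downstream.
DEFAULT_TAXON_GROUPS: Mapping[str, str] = {
    "Plecotus auritus": "Plecotus sp.",
    "Plecotus austriacus": "Plecotus sp.",
    "Nyctalus noctula": "Nyctalus sp.",
    "Nyctalus leisleri": "Nyctalus sp.",
    "Eptesicus serotinus": "Eptesicus sp.",
    "Eptesicus nilssoni": "Eptesicus sp.",
}

#: Default guild membership for the taxa of a central-European lowland
#: forest bat assemblage (clutter resistance / echolocation range classes).
DEFAULT_GUILDS: Mapping[str, Guild] = {
    "Eptesicus sp.": Guild.LRE,
    "Nyctalus sp.": Guild.LRE,
    "Vespertilio murinus": Guild.LRE,
    "Hypsugo savii": Guild.MRE,
    "Pipistrellus kuhlii": Guild.MRE,
    "Pipistrellus nathusii": Guild.MRE,
    "Pipistrellus pipistrellus": Guild.MRE,
    "Pipistrellus pygmaeus": Guild.MRE,
    "Myotis brandtii": Guild.SRE,
    "Myotis bechsteinii": Guild.SRE,
    "Myotis daubentonii": Guild.SRE,
    "Myotis emarginatus": Guild.SRE,
    "Myotis myotis": Guild.SRE,
    "Myotis mystacinus": Guild.SRE,
    "Myotis nattereri": Guild.SRE,
    "Plecotus sp.": Guild.SRE,
    # pre-collapse species map to the guild of their group
    "Plecotus auritus": Guild.SRE,
    "Plecotus austriacus": Guild.SRE,
    "Nyctalus noctula": Guild.LRE,
    "Nyctalus leisleri": Guild.LRE,
    "Eptesicus serotinus": Guild.LRE,
    "Eptesicus nilssoni": Guild.LRE,
}


class FormatError(ValueError):
    """Raised when an input file violates the expected tabular format."""


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention used in report tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(slots=True)
class DetectionRecord:
    """One identified echolocation sequence.

    Parameters
    ----------
    night_id:
        Label of the calendar night (the evening date the night starts).
    timestamp:
        Minutes from the start of the recording window; in ``[0, 480)``.
    cell_id, plot_id, site_id:
        Spatial hierarchy: 1-km2 cell > forest plot > microhabitat site.
    microhabitat:
        Which of the three strata the site samples.
    taxon:
        Label at the best identified taxonomic level.
    taxon_level:
        Resolution of the identification.
    guild:
        Echolocation guild; ``UNKNOWN`` only for order-level records.
    n_calls:
        Number of single calls in the sequence (metadata only).
    """

    night_id: str
    timestamp: float
    cell_id: str
    plot_id: str
    site_id: str
    microhabitat: Microhabitat
    taxon: str
    taxon_level: TaxonLevel
    guild: Guild
    n_calls: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.timestamp < NIGHT_MINUTES:
            raise ValueError(
                f"timestamp {self.timestamp} outside the recording window "
                f"[0, {NIGHT_MINUTES}) minutes"
            )
        if self.guild is Guild.UNKNOWN and self.taxon_level is not TaxonLevel.ORDER:
            raise ValueError(
                "guild may be UNKNOWN only for order-level identifications "
                f"(taxon {self.taxon!r} at level {self.taxon_level.value})"
            )
        if self.n_calls < 0:
            raise ValueError("n_calls must be nonnegative")


@dataclass(frozen=True)
class SamplingScheme:
    """Spatial design (microhabitat subset) x temporal pattern."""

    design: frozenset[Microhabitat]
    pattern: TemporalPattern

    def __post_init__(self) -> None:
        if not self.design:
            raise ValueError("design must be a nonempty set of microhabitats")
        object.__setattr__(self, "design", frozenset(self.design))

    @property
    def n_detectors_per_plot(self) -> int:
        """One detector per sampled microhabitat of a plot."""
        return len(self.design)

    @property
    def label(self) -> str:
        order = [Microhabitat.GAP, Microhabitat.GROUND, Microhabitat.CANOPY]
        mics = "+".join(m.value for m in order if m in self.design)
        return f"{mics} {self.pattern.value}"


def parse_clock_time(text: str) -> float:
    """Convert a clock time to minutes from the 21:30 window start.

    Accepts ``HH:MM`` / ``HH:MM:SS`` wall-clock strings (times after
    midnight belong to the same night) or a plain number already in
    minutes-from-window-start.
    """
    s = str(text).strip()
    if ":" in s:
        parts = s.split(":")
        if len(parts) not in (2, 3):
            raise ValueError(f"cannot parse clock time {text!r}")
        h, m = int(parts[0]), int(parts[1])
        sec = float(parts[2]) if len(parts) == 3 else 0.0
        minute_of_day = h * 60 + m + sec / 60.0
        return (minute_of_day - WINDOW_START_MINUTE_OF_DAY) % (24 * 60)
    return float(s)


REQUIRED_COLUMNS = ("night_id", "time", "cell", "plot", "site", "microhabitat", "taxon", "level")


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_records(
    path: str | Path,
    *,
    delimiter: str | None = None,
    column_map: Mapping[str, str] | None = None,
    strict: bool = False,
    guild_map: Mapping[str, Guild] | None = None,
) -> list[DetectionRecord]:
    """Read detection records from a delimited-text file.

    The file must have a header naming the required columns (``night_id``,
    ``time``, ``cell``, ``plot``, ``site``, ``microhabitat``, ``taxon``,
    ``level``; optional ``guild`` and ``n_calls``).  ``column_map`` maps
    required names to the file's actual header names.  Rows that fail
    validation (e.g. a timestamp outside the 21:30-05:30 window) are
    rejected with a line-numbered warning, or raise in ``strict`` mode.
    Missing required columns always raise :class:`FormatError`.
    """
    path = Path(path)
    text = path.read_text()
    if delimiter is None:
        delimiter = _sniff_delimiter(text[:4096])
    colmap = dict(column_map or {})
    guilds = dict(DEFAULT_GUILDS)
    if guild_map:
        guilds.update(guild_map)

    reader = csv.DictReader(io.StringIO(text), delimiter=delimiter)
    header = reader.fieldnames or []
    resolved = {req: colmap.get(req, req) for req in REQUIRED_COLUMNS}
    missing = [src for src in resolved.values() if src not in header]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")
    guild_col = colmap.get("guild", "guild") if colmap.get("guild", "guild") in header else None
    ncalls_col = colmap.get("n_calls", "n_calls") if colmap.get("n_calls", "n_calls") in header else None

    records: list[DetectionRecord] = []
    for lineno, row in enumerate(reader, start=2):
        try:
            missing_vals = [req for req, src in resolved.items() if not (row.get(src) or "").strip()]
            if missing_vals:
                raise FormatError(f"missing value(s) for {missing_vals}")
            t = parse_clock_time(row[resolved["time"]])
            level = TaxonLevel(row[resolved["level"]].strip().lower())
            taxon = row[resolved["taxon"]].strip()
            if guild_col and (row.get(guild_col) or "").strip():
                guild = Guild(row[guild_col].strip().upper())
            elif level is TaxonLevel.ORDER:
                guild = Guild.UNKNOWN
            elif taxon in guilds:
                guild = guilds[taxon]
            else:
                raise FormatError(f"no guild known for taxon {taxon!r}")
            rec = DetectionRecord(
                night_id=row[resolved["night_id"]].strip(),
                timestamp=t,
                cell_id=row[resolved["cell"]].strip(),
                plot_id=row[resolved["plot"]].strip(),
                site_id=row[resolved["site"]].strip(),
                microhabitat=Microhabitat.parse(row[resolved["microhabitat"]]),
                taxon=taxon,
                taxon_level=level,
                guild=guild,
                n_calls=int(row[ncalls_col]) if ncalls_col and (row.get(ncalls_col) or "").strip() else 1,
            )
        except (ValueError, FormatError) as exc:
            msg = f"{path.name}:{lineno}: {exc}"
            if strict or isinstance(exc, FormatError):
                raise FormatError(msg) from exc
            warnings.warn(f"rejected row — {msg}", stacklevel=2)
            continue
        records.append(rec)
    return records


def write_records(records: Iterable[DetectionRecord], path: str | Path, *, delimiter: str = ",") -> None:
    """Write records in the same delimited-text layout ``read_records`` accepts."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(list(REQUIRED_COLUMNS) + ["guild", "n_calls"])
        for r in records:
            w.writerow([
                r.night_id, f"{r.timestamp:g}", r.cell_id, r.plot_id, r.site_id,
                r.microhabitat.value, r.taxon, r.taxon_level.value, r.guild.value, r.n_calls,
            ])


def collapse_taxa(
    records: Sequence[DetectionRecord],
    mapping: Mapping[str, str] | None = None,
) -> list[DetectionRecord]:
    """Collapse acoustically inseparable species into genus-level groups.

    Each group counts as one taxon in all downstream richness analyses.
    The operation is idempotent: group labels map to themselves.
    """
    table = dict(DEFAULT_TAXON_GROUPS if mapping is None else mapping)
    out = []
    for r in records:
        if r.taxon in table:
            out.append(replace(r, taxon=table[r.taxon], taxon_level=TaxonLevel.SPECIES_GROUP))
        else:
            out.append(r)
    return out


def filter_temporal(
    records: Sequence[DetectionRecord], pattern: TemporalPattern
) -> list[DetectionRecord]:
    """Keep records whose timestamp falls inside the pattern's windows."""
    return [r for r in records if pattern.contains(r.timestamp)]


def filter_design(
    records: Sequence[DetectionRecord], design: Iterable[Microhabitat]
) -> list[DetectionRecord]:
    """Keep records from the microhabitats of the given spatial design."""
    design = frozenset(design)
    if not design:
        raise ValueError("design must contain at least one microhabitat")
    return [r for r in records if r.microhabitat in design]


@dataclass
class IdentificationSummary:
    """Identification-effort summary: counts and percentages.

    ``by_level`` reports one row per taxonomic level with its share of the
    grand total (1 decimal, ties rounded up).  ``by_taxon`` reports one row
    per guild-assignable taxon with its share of the guild-assignable total
    (order-level sequences excluded; 2 decimals), the convention used for
    community tables.
    """

    by_level: pd.DataFrame
    by_taxon: pd.DataFrame
    total: int = 0
    total_guild_assignable: int = 0


def identification_summary_from_counts(
    level_counts: Mapping[TaxonLevel, int],
    taxon_counts: Mapping[str, int],
    order_level_taxa: Iterable[str] = ("Chiroptera",),
) -> IdentificationSummary:
    """Build an :class:`IdentificationSummary` from pre-tabulated counts.

    ``taxon_counts`` should exclude order-level catch-all labels (any label
    in ``order_level_taxa`` is dropped defensively).
    """
    total = int(sum(level_counts.values()))
    lv_rows = []
    for level in TaxonLevel:
        n = int(level_counts.get(level, 0))
        if n == 0 and level not in level_counts:
            continue
        pct = round_half_up(100.0 * n / total, 1) if total else 0.0
        lv_rows.append({"level": level.value, "count": n, "pct_of_total": pct})
    by_level = pd.DataFrame(lv_rows, columns=["level", "count", "pct_of_total"])

    tx = {t: int(n) for t, n in taxon_counts.items() if t not in set(order_level_taxa)}
    denom = sum(tx.values())
    tx_rows = [
        {"taxon": t, "count": n, "pct_of_guild_assignable": round_half_up(100.0 * n / denom, 2) if denom else 0.0}
        for t, n in sorted(tx.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    by_taxon = pd.DataFrame(tx_rows, columns=["taxon", "count", "pct_of_guild_assignable"])
    return IdentificationSummary(by_level=by_level, by_taxon=by_taxon, total=total, total_guild_assignable=denom)


def summarize_identification(records: Sequence[DetectionRecord]) -> IdentificationSummary:
    """Tabulate identification counts and percentages from records."""
    level_counts: dict[TaxonLevel, int] = {}
    taxon_counts: dict[str, int] = {}
    for r in records:
        level_counts[r.taxon_level] = level_counts.get(r.taxon_level, 0) + 1
        if r.taxon_level is not TaxonLevel.ORDER:
            taxon_counts[r.taxon] = taxon_counts.get(r.taxon, 0) + 1
    return identification_summary_from_counts(level_counts, taxon_counts)
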