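"""Nightly activity indices.

Because one bat foraging around a microphone can trigger hundreds of
recordings, raw sequence counts overstate activity.  The activity index
used here instead counts the number of distinct 5-minute intervals of a
night that contain at least one sequence of the taxon (or guild) of
interest.  With an 8-hour recording window the index ranges from 0 to 96.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .records import DetectionRecord, Guild, NIGHT_MINUTES

__all__ = ["BIN_MINUTES", "N_BINS", "activity_index", "guild_activity_table", "ActivityTable"]

BIN_MINUTES = 5
N_BINS = NIGHT_MINUTES // BIN_MINUTES  # 96 bins of 5 min


def activity_index(
    records: Sequence[DetectionRecord],
    taxon: str | Guild | None = None,
) -> int:
    """Number of occupied 5-min bins for one site-night.

    ``taxon`` selects by taxon label, by :class:`Guild` (matching every
    record assignable to that guild, at any taxonomic level), or ``None``
    for all records.  All records must belong to a single site-night.
    """
    keys = {(r.site_id, r.night_id) for r in records}
    if len(keys) > 1:
        raise ValueError(f"records span {len(keys)} site-nights; expected one")
    if isinstance(taxon, Guild):
        sel = (r for r in records if r.guild is taxon)
    elif taxon is not None:
        sel = (r for r in records if r.taxon == taxon)
    else:
        sel = iter(records)
    bins = {int(r.timestamp // BIN_MINUTES) for r in sel}
    return len(bins)


@dataclass
class ActivityTable:
    """Per-night guild activity indices plus per-microhabitat summaries."""

    per_night: pd.DataFrame  # guild, microhabitat, cell, plot, site, night, index
    summary: pd.DataFrame    # guild, microhabitat, mean, sd, n_site_nights


def guild_activity_table(
    records: Sequence[DetectionRecord],
    exclude_taxa: Iterable[str] = (),
) -> ActivityTable:
    """Guild activity index for every sampled site-night.

    ``exclude_taxa`` removes hyper-dominant taxa (a species present in
    nearly every interval swamps its guild's signal) before counting.
    Order-level records carry no guild and never contribute.  Site-nights
    are taken from the input record set; each yields a row for all three
    guilds, zero where the guild was absent.
    """
    excl = set(exclude_taxa)
    site_nights: dict[tuple[str, str], dict] = {}
    bins: dict[tuple[str, str, Guild], set[int]] = {}
    for r in records:
        key = (r.site_id, r.night_id)
        site_nights.setdefault(
            key,
            {"cell": r.cell_id, "plot": r.plot_id, "microhabitat": r.microhabitat.value},
        )
        if r.taxon in excl or r.guild is Guild.UNKNOWN:
            continue
        bins.setdefault((r.site_id, r.night_id, r.guild), set()).add(int(r.timestamp // BIN_MINUTES))

    rows = []
    for (site, night), meta in sorted(site_nights.items()):
        for guild in (Guild.SRE, Guild.MRE, Guild.LRE):
            rows.append(
                {
                    "guild": guild.value,
                    "microhabitat": meta["microhabitat"],
                    "cell": meta["cell"],
                    "plot": meta["plot"],
                    "site": site,
                    "night": night,
                    "index": len(bins.get((site, night, guild), ())),
                }
            )
    per_night = pd.DataFrame(
        rows, columns=["guild", "microhabitat", "cell", "plot", "site", "night", "index"]
    )
    if per_night.empty:
        summary = pd.DataFrame(columns=["guild", "microhabitat", "mean", "sd", "n_site_nights"])
    else:
        summary = (
            per_night.groupby(["guild", "microhabitat"])["index"]
            .agg(mean="mean", sd="std", n_site_nights="size")
            .reset_index()
        )
    return ActivityTable(per_night=per_night, summary=summary)
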