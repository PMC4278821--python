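from __future__ import annotations

import numpy as np
import pytest

from batsurvey.records import (
    DetectionRecord,
    Guild,
    Microhabitat,
    TaxonLevel,
)


def make_record(
    timestamp: float = 30.0,
    night_id: str = "n01",
    site_id: str = "C01-P1-GA",
    plot_id: str = "C01-P1",
    cell_id: str = "C01",
    microhabitat: Microhabitat = Microhabitat.GAP,
    taxon: str = "Pipistrellus pipistrellus",
    taxon_level: TaxonLevel = TaxonLevel.SPECIES,
    guild: Guild = Guild.MRE,
) -> DetectionRecord:
    return DetectionRecord(
        night_id=night_id,
        timestamp=timestamp,
        cell_id=cell_id,
        plot_id=plot_id,
        site_id=site_id,
        microhabitat=microhabitat,
        taxon=taxon,
        taxon_level=taxon_level,
        guild=guild,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20130604)


@pytest.fixture
def records_csv(tmp_path):
    """A small, well-formed records file covering all microhabitats."""
    path = tmp_path / "records.csv"
    path.write_text(
        "night_id,time,cell,plot,site,microhabitat,taxon,level\n"
        "n01,21:30,C01,C01-P1,C01-P1-GA,GA,Pipistrellus pipistrellus,species\n"
        "n01,05:29,C01,C01-P1,C01-P1-GR,GR,Myotis myotis,species\n"
        "n01,22:00,C01,C01-P1,C01-P1-CA,CA,Nyctalus sp.,species_group\n"
        "n02,02:00,C01,C01-P1,C01-P1-GA,GA,Plecotus auritus,species\n"
        "n02,04:00,C01,C01-P1,C01-P1-GR,GR,Chiroptera,order\n"
    )
    return path
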