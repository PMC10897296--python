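"""Italian administrative reference partition: 106 provinces in 20 regions.

Public reference data: the official 2016 Istat province list (two-letter
vehicle codes) grouped by administrative region, with the province of Sud
Sardegna (SU) merged into Cagliari (CA) so that the same 106 nodes are
compatible across mobility, census and health datasets.  Used as the
benchmark partition when scoring data-driven community structures against
the administrative subdivision of the country.
"""

from __future__ import annotations

from .gmc import Partition

#: Region -> province vehicle codes (2016 list, SU merged into CA).
PROVINCES_BY_REGION: dict[str, tuple[str, ...]] = {
    "Piemonte": ("TO", "VC", "NO", "CN", "AT", "AL", "BI", "VB"),
    "Valle d'Aosta": ("AO",),
    "Lombardia": (
        "VA", "CO", "SO", "MI", "BG", "BS", "PV", "CR", "MN", "LC", "LO", "MB",
    ),
    "Trentino-Alto Adige": ("BZ", "TN"),
    "Veneto": ("VR", "VI", "BL", "TV", "VE", "PD", "RO"),
    "Friuli-Venezia Giulia": ("UD", "GO", "TS", "PN"),
    "Liguria": ("IM", "SV", "GE", "SP"),
    "Emilia-Romagna": ("PC", "PR", "RE", "MO", "BO", "FE", "RA", "FC", "RN"),
    "Toscana": ("MS", "LU", "PT", "FI", "LI", "PI", "AR", "SI", "GR", "PO"),
    "Umbria": ("PG", "TR"),
    "Marche": ("PU", "AN", "MC", "AP", "FM"),
    "Lazio": ("VT", "RI", "RM", "LT", "FR"),
    "Abruzzo": ("AQ", "TE", "PE", "CH"),
    "Molise": ("CB", "IS"),
    "Campania": ("CE", "BN", "NA", "AV", "SA"),
    "Puglia": ("FG", "BA", "TA", "BR", "LE", "BT"),
    "Basilicata": ("PZ", "MT"),
    "Calabria": ("CS", "CZ", "KR", "VV", "RC"),
    "Sicilia": ("TP", "PA", "ME", "AG", "CL", "EN", "CT", "RG", "SR"),
    "Sardegna": ("SS", "NU", "CA", "OR"),
}


def province_labels() -> tuple[str, ...]:
    """The 106 province codes, ordered region by region."""
    return tuple(
        code for provinces in PROVINCES_BY_REGION.values() for code in provinces
    )


def region_partition() -> Partition:
    """Partition of the 106 provinces into the 20 administrative regions."""
    labels = [
        region
        for region, provinces in PROVINCES_BY_REGION.items()
        for _ in provinces
    ]
    return Partition.from_labels(labels, province_labels())
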