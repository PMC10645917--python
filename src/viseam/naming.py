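"""Product filename convention for the reconstructed VI tiles.

Files follow ``<PRODUCT>.<VERSION>.AYYYYDDD.hHHvVV.yyyyddd.hdf``: product
family (GLASS13D01 for NDVI, GLASS14D01 for EVI), version, acquisition
year/day-of-year, MODIS sinusoidal tile indices, and the processing date.
Exported values use the MODIS scaled-integer convention (x10,000; the -0.2
sentinel maps to -2,000).
"""

from __future__ import annotations

import calendar
import re
from dataclasses import dataclass

#: scaled-integer export convention
SCALE_FACTOR = 10_000
SENTINEL_SCALED = -2_000

NDVI_PRODUCT = "GLASS13D01"
EVI_PRODUCT = "GLASS14D01"

_NAME_RE = re.compile(
    r"^(?P<product>GLASS1[34]D01)"
    r"\.(?P<version>V\d{2})"
    r"\.A(?P<year>\d{4})(?P<doy>\d{3})"
    r"\.h(?P<tile_h>\d{2})v(?P<tile_v>\d{2})"
    r"\.(?P<pyear>\d{4})(?P<pdoy>\d{3})"
    r"\.hdf$"
)


class ProductNameError(ValueError):
    pass


def _days_in_year(year: int) -> int:
    return 366 if calendar.isleap(year) else 365


@dataclass(frozen=True)
class ProductName:
    product: str
    version: str
    year: int
    doy: int
    tile_h: int
    tile_v: int
    processed_year: int
    processed_doy: int

    def __post_init__(self):
        if self.product not in (NDVI_PRODUCT, EVI_PRODUCT):
            raise ProductNameError(f"unknown product {self.product!r}")
        if not re.fullmatch(r"V\d{2}", self.version):
            raise ProductNameError(f"bad version {self.version!r}")
        if not 1 <= self.doy <= _days_in_year(self.year):
            raise ProductNameError(
                f"doy {self.doy} invalid for year {self.year}")
        if not 1 <= self.processed_doy <= _days_in_year(self.processed_year):
            raise ProductNameError(
                f"processing doy {self.processed_doy} invalid for year "
                f"{self.processed_year}")
        if not 0 <= self.tile_h <= 35:
            raise ProductNameError(f"tile_h {self.tile_h} outside 0-35")
        if not 0 <= self.tile_v <= 17:
            raise ProductNameError(f"tile_v {self.tile_v} outside 0-17")

    @property
    def index_kind(self) -> str:
        return "NDVI" if self.product == NDVI_PRODUCT else "EVI"


def parse_product_name(name: str) -> ProductName:
    """Parse a product filename; raises naming the failing field."""
    m = _NAME_RE.match(name)
    if m is None:
        # locate the failing field for a useful message
        parts = name.split(".")
        if len(parts) != 6 or parts[-1] != "hdf":
            raise ProductNameError(
                f"{name!r}: expected 6 dot-separated fields ending in .hdf")
        if not re.fullmatch(r"GLASS1[34]D01", parts[0]):
            raise ProductNameError(f"{name!r}: bad product field {parts[0]!r}")
        if not re.fullmatch(r"V\d{2}", parts[1]):
            raise ProductNameError(f"{name!r}: bad version field {parts[1]!r}")
        if not re.fullmatch(r"A\d{7}", parts[2]):
            raise ProductNameError(f"{name!r}: bad acquisition field {parts[2]!r}")
        if not re.fullmatch(r"h\d{2}v\d{2}", parts[3]):
            raise ProductNameError(f"{name!r}: bad tile field {parts[3]!r}")
        raise ProductNameError(f"{name!r}: bad processing-date field {parts[4]!r}")
    g = m.groupdict()
    return ProductName(
        product=g["product"], version=g["version"],
        year=int(g["year"]), doy=int(g["doy"]),
        tile_h=int(g["tile_h"]), tile_v=int(g["tile_v"]),
        processed_year=int(g["pyear"]), processed_doy=int(g["pdoy"]),
    )


def format_product_name(p: ProductName) -> str:
    """Inverse of :func:`parse_product_name`."""
    return (f"{p.product}.{p.version}.A{p.year:04d}{p.doy:03d}"
            f".h{p.tile_h:02d}v{p.tile_v:02d}"
            f".{p.processed_year:04d}{p.processed_doy:03d}.hdf")
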