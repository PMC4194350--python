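"""Plate-level summaries.

A plate hosts the excreta of a known number of flies over a fixed
period and is the unit of replication for statistics.  Its summary
reports, for all deposits and for the ROD / non-ROD subsets separately:

* per-fly totals — number of spots, total area and total IOD, each
  divided by the fly count entered by the user;
* unweighted arithmetic means of area, perimeter and circularity;
* pooled colour — the mean colour of all subset pixels analysed
  together as one object (equivalently, the area-weighted mean of the
  per-deposit mean RGB), then its HSL transform.

Empty subsets yield zero totals and *missing* (NaN) means — never zero —
so downstream statistics skip them rather than bias toward zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .detect import RgbImage
from .features import Deposit, rgb_to_hsl

__all__ = ["SubsetSummary", "PlateSummary", "pooled_colour", "summarize_plate"]

SUBSETS = ("all", "rod", "non_rod")


@dataclass
class SubsetSummary:
    """Aggregates over one deposit subset (all, ROD or non-ROD)."""

    n_spots: int
    n_spots_per_fly: float
    total_area_per_fly: float
    total_iod_per_fly: float
    mean_area: float
    mean_perimeter: float
    mean_circularity: float
    mean_r: float
    mean_g: float
    mean_b: float
    mean_h: float
    mean_s: float
    mean_l: float


@dataclass
class PlateSummary:
    plate_id: str
    n_flies: int
    image_filename: str = ""
    timestamp: str = ""
    protocol_params: Mapping[str, object] = field(default_factory=dict)
    all: SubsetSummary = None  # type: ignore[assignment]
    rod: SubsetSummary = None  # type: ignore[assignment]
    non_rod: SubsetSummary = None  # type: ignore[assignment]
    rod_fraction: float = math.nan

    def subset(self, name: str) -> SubsetSummary:
        if name not in SUBSETS:
            raise KeyError(f"unknown subset {name!r}")
        return getattr(self, "non_rod" if name == "non_rod" else name)

    def to_row(self) -> dict[str, object]:
        """Flatten to one table row; subset fields get all_/rod_/nonrod_ prefixes."""
        row: dict[str, object] = {
            "plate_id": self.plate_id,
            "image_filename": self.image_filename,
            "timestamp": self.timestamp,
            "n_flies": self.n_flies,
            "rod_fraction": self.rod_fraction,
        }
        for name, prefix in zip(SUBSETS, ("all_", "rod_", "nonrod_")):
            s = self.subset(name)
            for key, value in vars(s).items():
                row[prefix + key] = value
        return row


def pooled_colour(
    deposits: Iterable[Deposit], image: RgbImage | None = None
) -> tuple[float, float, float, float, float, float]:
    """Colour of all deposit pixels analysed together as a single object.

    Because per-deposit means are taken over disjoint pixel sets, the
    mean over the union equals the area-weighted mean of per-deposit
    mean RGB exactly; this also lets re-loaded tables (without pixel
    data) be re-summarised.  Returns (R, G, B, H, S, L); H is the hue of
    the pooled mean colour.  ``image`` is accepted for signature
    compatibility and unused.
    """
    deposits = list(deposits)
    if not deposits:
        raise ValueError("pooled colour is undefined for an empty deposit set")
    total = sum(d.area for d in deposits)
    r = sum(d.mean_r * d.area for d in deposits) / total
    g = sum(d.mean_g * d.area for d in deposits) / total
    b = sum(d.mean_b * d.area for d in deposits) / total
    h, s, ell = rgb_to_hsl(r, g, b)
    return r, g, b, h, s, ell


def _summarize_subset(deposits: list[Deposit], n_flies: int) -> SubsetSummary:
    n = len(deposits)
    if n == 0:
        nan = math.nan
        return SubsetSummary(0, 0.0, 0.0, 0.0, nan, nan, nan, nan, nan, nan, nan, nan, nan)
    total_area = sum(d.area for d in deposits)
    total_iod = sum(d.iod for d in deposits)
    r, g, b, h, s, ell = pooled_colour(deposits)
    return SubsetSummary(
        n_spots=n,
        n_spots_per_fly=n / n_flies,
        total_area_per_fly=total_area / n_flies,
        total_iod_per_fly=total_iod / n_flies,
        mean_area=total_area / n,
        mean_perimeter=sum(d.perimeter for d in deposits) / n,
        mean_circularity=sum(d.circularity for d in deposits) / n,
        mean_r=r, mean_g=g, mean_b=b, mean_h=h, mean_s=s, mean_l=ell,
    )


def summarize_plate(
    deposits: Iterable[Deposit],
    n_flies: int,
    *,
    plate_id: str | None = None,
    image: RgbImage | None = None,
    image_filename: str = "",
    timestamp: str = "",
    protocol_params: Mapping[str, object] | None = None,
) -> PlateSummary:
    """Aggregate the included deposits of one plate.

    Totals (spot count, area, IOD) are normalised by the fly count;
    means are unweighted arithmetic means over deposits.  Deposits with
    ``include=False`` (manually flagged artefacts) are dropped first.
    ``rod_fraction`` is n_rod / n_all, NaN on an empty plate.
    """
    if n_flies < 1:
        raise ValueError("n_flies must be >= 1")
    included = [d for d in deposits if d.include]
    if plate_id is None:
        plate_id = included[0].plate_id if included else ""
    rods = [d for d in included if d.is_rod]
    non_rods = [d for d in included if not d.is_rod]
    return PlateSummary(
        plate_id=plate_id,
        n_flies=n_flies,
        image_filename=image_filename,
        timestamp=timestamp,
        protocol_params=dict(protocol_params or {}),
        all=_summarize_subset(included, n_flies),
        rod=_summarize_subset(rods, n_flies),
        non_rod=_summarize_subset(non_rods, n_flies),
        rod_fraction=(len(rods) / len(included)) if included else math.nan,
    )
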