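"""Mitotic-arrest-front shape and proliferation-zone dynamics.

A growing leaf arrests cell division from the tip downwards; the transition
band where cells are ceasing to divide is the mitotic arrest front.  Its
medio-lateral shape is measured by tiling the band with 200 x 100 um
counting fields from midrib to margin and recording the percentage of
GUS-reporter-positive (mitotically competent) cells per field.  A profile
that falls off towards the margin means relatively more residual division
in the centre (convex front, promotes cup-shaped laminae); one that rises
towards the margin (concave front) promotes crinkly margins.

The proliferation zone is the basal region where cells still divide; its
length is defined operationally as the distance from the lamina base to
where the GUS-positive fraction adjacent to the midrib first drops to ~10%.
Regressing zone length on total leaf length across a developmental series
gives the zone-dynamics slope (negative when the zone shrinks as the leaf
grows, positive when it transiently widens).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .synthetic import CellMap

__all__ = [
    "DEFAULT_FIELD_SIZE_UM",
    "CellField",
    "FrontProfile",
    "FrontClassification",
    "ProliferationZoneRecord",
    "field_centers_um",
    "front_axis_span",
    "bin_fields",
    "fraction_profile",
    "average_profiles",
    "classify_front",
    "zone_length",
    "zone_slope",
]

#: Counting-field size (medio-lateral x proximo-distal extent), um.
DEFAULT_FIELD_SIZE_UM: tuple[float, float] = (200.0, 100.0)


@dataclass(frozen=True)
class CellField:
    """One counting rectangle of the arrest-front profile."""

    index_from_midrib: int
    x_center: float  # um from the midrib
    field_width: float  # um
    field_height: float  # um
    n_total: int
    n_gus: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_gus <= self.n_total):
            raise ValueError("need 0 <= n_gus <= n_total")

    @property
    def fraction(self) -> float:
        if self.n_total == 0:
            raise ValueError("empty counting field has no GUS fraction")
        return self.n_gus / self.n_total


@dataclass
class FrontProfile:
    """Ordered midrib-to-margin GUS-fraction profile."""

    fields: list[CellField]
    fractions: np.ndarray
    se: np.ndarray  # per-field binomial standard errors
    leaf_length_mm: float | None = None
    front_position: float | None = None  # fraction of leaf length from the tip
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.front_position is not None and not (0 <= self.front_position <= 1):
            raise ValueError("front_position must lie in [0, 1]")


@dataclass(frozen=True)
class FrontClassification:
    label: Literal["mild_convex", "strong_convex_with_midrib_dip", "concave", "flat"]
    central_mean: float
    marginal_mean: float
    peak_index: int


@dataclass(frozen=True)
class ProliferationZoneRecord:
    """(total leaf length, proliferation-zone length) for one leaf, mm."""

    leaf_length: float
    zone_length: float
    threshold: float = 0.10
    clipped: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.zone_length <= self.leaf_length):
            raise ValueError("need 0 <= zone_length <= leaf_length")


def _field_edges(width_um: float, field_width: float) -> np.ndarray:
    """Field bin edges tiling [0, width]; a trailing partial field is kept
    if at least half a field wide, otherwise merged into its neighbour."""
    n_full = int(width_um // field_width)
    remainder = width_um - n_full * field_width
    if n_full == 0:
        return np.array([0.0, width_um])
    edges = [i * field_width for i in range(n_full + 1)]
    if remainder >= 0.5 * field_width:
        edges.append(width_um)  # keep the partial field
    else:
        edges[-1] = width_um  # merge the sliver into the last full field
    return np.asarray(edges)


def field_centers_um(width_um: float, field_width: float = DEFAULT_FIELD_SIZE_UM[0]) -> np.ndarray:
    """Centres of the counting fields tiling a midrib-to-margin span."""
    edges = _field_edges(width_um, field_width)
    return 0.5 * (edges[:-1] + edges[1:])


def front_axis_span(
    width_um: float, field_width: float = DEFAULT_FIELD_SIZE_UM[0]
) -> tuple[float, float]:
    """(x0, x1) in um mapping to normalized profile coordinates 0 and 1.

    The published profiles plot per-field percentages against a midrib-to-
    margin axis whose first and last points are the centres of the first and
    last counting fields; anchoring the probability model's axis there makes
    binned recovery of linear profiles unbiased at the plotted positions.
    """
    centers = field_centers_um(width_um, field_width)
    return float(centers[0]), float(centers[-1])


def bin_fields(
    cell_map: CellMap,
    band: tuple[float, float] | None = None,
    field_size: tuple[float, float] = DEFAULT_FIELD_SIZE_UM,
) -> list[CellField]:
    """Tile the transition-zone band with counting fields, midrib to margin.

    ``band`` is the proximo-distal (y_lo, y_hi) strip in um within the cell
    map; default is the full map height (use a map generated as the band
    itself, or pass the strip of a larger map).  Cells belong to the field
    containing their centroid; a trailing partial field is kept if it is at
    least half a field wide, else merged.
    """
    fw, fh = field_size
    y_lo, y_hi = band if band is not None else (0.0, cell_map.height_um)
    if not (0 <= y_lo < y_hi <= cell_map.height_um):
        raise ValueError("band must lie within the cell map")
    cells = cell_map.cells
    in_band = (cells["y_um"] >= y_lo) & (cells["y_um"] < y_hi)
    sub = cells[in_band]
    edges = _field_edges(cell_map.width_um, fw)
    idx = np.clip(np.searchsorted(edges, sub["x_um"].to_numpy(), side="right") - 1,
                  0, len(edges) - 2)
    fields = []
    for i in range(len(edges) - 1):
        sel = sub[idx == i]
        fields.append(
            CellField(
                index_from_midrib=i,
                x_center=float((edges[i] + edges[i + 1]) / 2.0),
                field_width=float(edges[i + 1] - edges[i]),
                field_height=float(y_hi - y_lo),
                n_total=int(len(sel)),
                n_gus=int(sel["gus"].sum()),
            )
        )
    return fields


def fraction_profile(
    fields: Sequence[CellField],
    *,
    leaf_length_mm: float | None = None,
    front_position: float | None = None,
) -> FrontProfile:
    """GUS-positive fractions (with binomial SEs) over ordered fields."""
    if len(fields) < 3:
        raise ValueError("a front profile needs at least 3 fields")
    if any(f.n_total == 0 for f in fields):
        raise ValueError("empty counting field in profile")
    fields = sorted(fields, key=lambda f: f.index_from_midrib)
    frac = np.array([f.fraction for f in fields])
    n = np.array([f.n_total for f in fields], dtype=float)
    se = np.sqrt(frac * (1.0 - frac) / n)
    return FrontProfile(
        fields=list(fields),
        fractions=frac,
        se=se,
        leaf_length_mm=leaf_length_mm,
        front_position=front_position,
    )


def average_profiles(profiles: Sequence[FrontProfile]) -> FrontProfile:
    """Mean per-field profile over leaves, with pooled binomial SEs.

    Per-leaf profiles are binned first and then averaged field-by-field
    (the published curves are means over 11 wild-type / 5 mutant leaves);
    the pooled SE per field is sqrt(p_bar (1 - p_bar) / sum_n).
    """
    if not profiles:
        raise ValueError("no profiles to average")
    k = len(profiles[0].fields)
    if any(len(p.fields) != k for p in profiles):
        raise ValueError("profiles must have equal field counts to average")
    frac = np.mean([p.fractions for p in profiles], axis=0)
    n_pool = np.sum([[f.n_total for f in p.fields] for p in profiles], axis=0)
    se = np.sqrt(frac * (1.0 - frac) / n_pool)
    proto = profiles[0].fields
    fields = [
        CellField(
            index_from_midrib=f.index_from_midrib,
            x_center=f.x_center,
            field_width=f.field_width,
            field_height=f.field_height,
            n_total=int(n),
            n_gus=int(round(fr * n)),
        )
        for f, n, fr in zip(proto, n_pool, frac)
    ]
    out = FrontProfile(fields=fields, fractions=frac, se=se)
    out.meta["n_leaves"] = len(profiles)
    return out


def classify_front(profile: FrontProfile, delta: float = 0.05) -> FrontClassification:
    """Qualitative arrest-front shape from profile statistics.

    With c the mean fraction over the central (midrib-side) third of fields,
    m the mean over the marginal third and p* the argmax field:
    concave if m - c > delta; convex if c - m > delta, upgraded to
    strong_convex_with_midrib_dip when p* is interior and exceeds the
    midrib-adjacent field by more than delta; flat otherwise.  The default
    margin delta = 0.05 is about twice the binomial SE at 150 cells/field.
    """
    if len(profile.fields) < 4:
        raise ValueError("classification needs at least 4 fields")
    frac = profile.fractions
    k = len(frac)
    third = max(1, int(math.ceil(k / 3)))
    c = float(frac[:third].mean())
    m = float(frac[-third:].mean())
    p_star = int(np.argmax(frac))
    if m - c > delta:
        label = "concave"
    elif c - m > delta:
        if 0 < p_star < k - 1 and frac[p_star] - frac[0] > delta:
            label = "strong_convex_with_midrib_dip"
        else:
            label = "mild_convex"
    else:
        label = "flat"
    return FrontClassification(
        label=label, central_mean=c, marginal_mean=m, peak_index=p_star
    )


def zone_length(
    cell_map: CellMap,
    threshold: float = 0.10,
    *,
    column_width_um: float = DEFAULT_FIELD_SIZE_UM[0],
    window_um: float = 100.0,
    step_um: float = 10.0,
) -> float:
    """Proliferation-zone length (mm) from a midrib-adjacent cell column.

    The cell map's y axis runs base (y = 0) to tip; GUS status marks
    mitotically competent cells.  A ``window_um``-tall window slides up the
    midrib-adjacent column (x < ``column_width_um``) in ``step_um`` steps;
    the zone ends at the most-proximal window position where the GUS
    fraction first falls to <= ``threshold``.  Returns the full leaf length
    if the fraction never falls below threshold.
    """
    cells = cell_map.cells
    col = cells[cells["x_um"] < column_width_um]
    if len(col) == 0:
        raise ValueError("no cells in the midrib-adjacent column")
    y = col["y_um"].to_numpy()
    gus = col["gus"].to_numpy()
    length_um = cell_map.height_um
    starts = np.arange(0.0, length_um - window_um + step_um / 2.0, step_um)
    for y0 in starts:
        sel = (y >= y0) & (y < y0 + window_um)
        if not sel.any():
            continue
        if gus[sel].mean() <= threshold:
            return float(y0) / 1000.0
    return float(length_um) / 1000.0


def zone_slope(records: Sequence[ProliferationZoneRecord]) -> tuple[float, float]:
    """OLS slope (mm/mm) and R^2 of zone length on total leaf length."""
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    x = np.array([r.leaf_length for r in records])
    y = np.array([r.zone_length for r in records])
    if np.ptp(x) == 0:
        raise ValueError("all leaf lengths equal; slope undefined")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.rvalue**2)
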