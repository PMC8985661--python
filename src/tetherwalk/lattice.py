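"""Microtubule lattice geometry and exclusive site occupancy.

The microtubule is modelled as a 13-protofilament sheet of tubulin-dimer
sites (8 nm axial repeat).  The cylinder is unrolled into a plane: each
protofilament is a row offset laterally by 6 nm, and the 3-start helical
pitch shifts successive protofilaments axially by 12/13 nm, so that going
once around the tube accumulates the 12-nm (1.5-dimer) seam offset.

Every site holds exactly one occupant tag — EMPTY, MAP7, KINESIN or
DYNEIN.  Mutual exclusion is the core rule of the competition model
(MAP7's microtubule-binding domain and the motor footprint overlap on the
same dimer), so :func:`occupy` raises :class:`ExclusionError` rather than
ever silently overwriting a site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EMPTY",
    "MAP7",
    "KINESIN",
    "DYNEIN",
    "OCCUPANT_NAMES",
    "ExclusionError",
    "LatticeGeometry",
    "LatticeState",
    "site_position",
    "neighbors_within",
    "occupy",
    "vacate",
]

EMPTY, MAP7, KINESIN, DYNEIN = 0, 1, 2, 3
OCCUPANT_NAMES = {EMPTY: "EMPTY", MAP7: "MAP7", KINESIN: "KINESIN", DYNEIN: "DYNEIN"}


class ExclusionError(RuntimeError):
    """Attempt to place an occupant on a non-empty site (or to vacate the wrong tag)."""


@dataclass(frozen=True)
class LatticeGeometry:
    """Geometry of the unrolled dimer-site grid.

    Parameters
    ----------
    n_protofilaments:
        Number of protofilaments (rows); 13 for a canonical microtubule.
    n_sites:
        Tubulin-dimer sites per protofilament.
    axial_spacing:
        Axial dimer repeat in nm (8.0).
    lateral_rise:
        Axial shift between adjacent protofilaments in nm; 12/13 nm for a
        3-start helix so one full turn adds the 12-nm seam offset.
    pf_spacing:
        Off-axis distance between adjacent protofilaments in nm on the
        unrolled sheet (~6 nm, the inter-protofilament spacing seen in 2D
        image coordinates).
    seam_index:
        Protofilament index at which the lateral neighbour relation wraps
        with the 1.5-dimer offset.  Kept as metadata; sideways stepping is
        treated identically everywhere.
    """

    n_protofilaments: int = 13
    n_sites: int = 300
    axial_spacing: float = 8.0
    lateral_rise: float = 12.0 / 13.0
    pf_spacing: float = 6.0
    seam_index: int = 0

    def __post_init__(self) -> None:
        if self.n_protofilaments < 1 or self.n_sites < 1:
            raise ValueError("lattice must have at least one protofilament and one site")
        if self.axial_spacing <= 0 or self.pf_spacing <= 0:
            raise ValueError("spacings must be positive")
        if not 0 <= self.seam_index < self.n_protofilaments:
            raise ValueError("seam_index out of range")

    @property
    def total_sites(self) -> int:
        return self.n_protofilaments * self.n_sites

    def in_bounds(self, pf: int, axial: int) -> bool:
        return 0 <= pf < self.n_protofilaments and 0 <= axial < self.n_sites

    def check_bounds(self, pf: int, axial: int) -> None:
        if not self.in_bounds(pf, axial):
            raise IndexError(f"site ({pf}, {axial}) outside lattice "
                             f"{self.n_protofilaments}x{self.n_sites}")

    def site_position(self, pf: int, axial: int) -> tuple[float, float]:
        """(on-axis nm, off-axis nm) of a dimer site; injective over sites."""
        self.check_bounds(pf, axial)
        x = axial * self.axial_spacing + pf * self.lateral_rise
        y = pf * self.pf_spacing
        return (x, y)

    def positions(self) -> tuple[np.ndarray, np.ndarray]:
        """Coordinate arrays X, Y of shape (n_protofilaments, n_sites)."""
        pf = np.arange(self.n_protofilaments)[:, None]
        ax = np.arange(self.n_sites)[None, :]
        x = ax * self.axial_spacing + pf * self.lateral_rise
        y = np.broadcast_to(pf * self.pf_spacing, x.shape)
        return x, y.copy()


def site_position(geometry: LatticeGeometry, pf: int, axial: int) -> tuple[float, float]:
    """Module-level alias for :meth:`LatticeGeometry.site_position`."""
    return geometry.site_position(pf, axial)


@dataclass
class LatticeState:
    """Occupancy grid over a :class:`LatticeGeometry`.

    ``occupancy[pf, axial]`` is one of the occupant codes; exactly one tag
    per site at all times.
    """

    geometry: LatticeGeometry
    occupancy: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.occupancy is None:
            self.occupancy = np.full(
                (self.geometry.n_protofilaments, self.geometry.n_sites), EMPTY, dtype=np.int8
            )
        self.occupancy = np.asarray(self.occupancy, dtype=np.int8)
        if self.occupancy.shape != (self.geometry.n_protofilaments, self.geometry.n_sites):
            raise ValueError("occupancy shape does not match geometry")

    @classmethod
    def empty(cls, geometry: LatticeGeometry | None = None) -> "LatticeState":
        return cls(geometry or LatticeGeometry())

    def copy(self) -> "LatticeState":
        return LatticeState(self.geometry, self.occupancy.copy())

    # -- occupancy bookkeeping -------------------------------------------------
    def tag_at(self, site: tuple[int, int]) -> int:
        self.geometry.check_bounds(*site)
        return int(self.occupancy[site])

    def occupy(self, site: tuple[int, int], tag: int) -> "LatticeState":
        self.geometry.check_bounds(*site)
        if tag not in (MAP7, KINESIN, DYNEIN):
            raise ValueError(f"cannot occupy with tag {tag}")
        if self.occupancy[site] != EMPTY:
            raise ExclusionError(
                f"site {site} already holds {OCCUPANT_NAMES[int(self.occupancy[site])]}; "
                f"cannot bind {OCCUPANT_NAMES[tag]} (one occupant per tubulin dimer)"
            )
        self.occupancy[site] = tag
        return self

    def vacate(self, site: tuple[int, int], tag: int) -> "LatticeState":
        self.geometry.check_bounds(*site)
        if self.occupancy[site] != tag:
            raise ExclusionError(
                f"site {site} holds {OCCUPANT_NAMES[int(self.occupancy[site])]}, "
                f"not {OCCUPANT_NAMES.get(tag, tag)}"
            )
        self.occupancy[site] = EMPTY
        return self

    def counts(self) -> dict[str, int]:
        vals, cnts = np.unique(self.occupancy, return_counts=True)
        out = {name: 0 for name in OCCUPANT_NAMES.values()}
        for v, c in zip(vals, cnts):
            out[OCCUPANT_NAMES[int(v)]] = int(c)
        return out

    def fraction(self, tag: int) -> float:
        return float(np.mean(self.occupancy == tag))

    # -- export ----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        pf, ax = np.nonzero(np.ones_like(self.occupancy))
        return pd.DataFrame(
            {
                "protofilament": pf,
                "axial": ax,
                "occupant": [OCCUPANT_NAMES[int(t)] for t in self.occupancy[pf, ax]],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def occupy(state: LatticeState, site: tuple[int, int], tag: int) -> LatticeState:
    """Place ``tag`` on an EMPTY site; raises :class:`ExclusionError` otherwise."""
    return state.occupy(site, tag)


def vacate(state: LatticeState, site: tuple[int, int], tag: int) -> LatticeState:
    """Remove ``tag`` from a site it currently holds."""
    return state.vacate(site, tag)


def _window(geometry: LatticeGeometry, site: tuple[int, int], radius_nm: float):
    """Index bounds of the axial/pf sub-grid that can contain sites within radius."""
    pf0, ax0 = site
    d_ax = int(np.ceil((radius_nm + geometry.lateral_rise * geometry.n_protofilaments)
                       / geometry.axial_spacing)) + 1
    d_pf = int(np.ceil(radius_nm / geometry.pf_spacing)) + 1
    return (
        max(0, pf0 - d_pf),
        min(geometry.n_protofilaments, pf0 + d_pf + 1),
        max(0, ax0 - d_ax),
        min(geometry.n_sites, ax0 + d_ax + 1),
    )


def neighbors_within(
    state: LatticeState | LatticeGeometry,
    site: tuple[int, int],
    radius_nm: float,
) -> list[tuple[int, int]]:
    """All sites within Euclidean ``radius_nm`` of ``site`` on the unrolled sheet.

    The query site itself is excluded.  Order is deterministic: by distance,
    then protofilament, then axial index.
    """
    geometry = state.geometry if isinstance(state, LatticeState) else state
    if radius_nm < 0:
        raise ValueError("radius must be nonnegative")
    geometry.check_bounds(*site)
    x0, y0 = geometry.site_position(*site)
    pf_lo, pf_hi, ax_lo, ax_hi = _window(geometry, site, radius_nm)
    pf = np.arange(pf_lo, pf_hi)[:, None]
    ax = np.arange(ax_lo, ax_hi)[None, :]
    x = ax * geometry.axial_spacing + pf * geometry.lateral_rise
    y = pf * geometry.pf_spacing + np.zeros_like(x)
    d = np.hypot(x - x0, y - y0)
    mask = d <= radius_nm
    mask[site[0] - pf_lo, site[1] - ax_lo] = False
    pfs, axs = np.nonzero(mask)
    dists = d[pfs, axs]
    order = np.lexsort((axs, pfs, dists))
    return [(int(pfs[i] + pf_lo), int(axs[i] + ax_lo)) for i in order]
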