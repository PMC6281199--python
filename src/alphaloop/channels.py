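"""Electrode-array channel map: 10x10 grid with corners removed (96 sites).

Each recording array is a 96-electrode grid: a 10x10 layout whose four
corner positions are absent.  One adjacent electrode pair on the
stimulation-controlling array is designated the controller / controller
reference (the bipolar pair driving the feedback loop); a handful of
channels may be flagged bad (dead or high-impedance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ChannelMap", "GRID_SIZE", "CORNERS"]

GRID_SIZE = 10
CORNERS = {(0, 0), (0, GRID_SIZE - 1), (GRID_SIZE - 1, 0), (GRID_SIZE - 1, GRID_SIZE - 1)}


def _grid_positions() -> list[tuple[int, int]]:
    return [
        (r, c)
        for r in range(GRID_SIZE)
        for c in range(GRID_SIZE)
        if (r, c) not in CORNERS
    ]


@dataclass
class ChannelMap:
    """Table of channels: array id, grid (row, col), and status flags.

    The table has one row per channel with columns ``array`` (1-based id),
    ``row``, ``col``, ``controller``, ``controller_ref``, ``bad``.  A map is
    either a full-grid map (96 channels per array) or an explicit
    subsample of one (``full_grid=False``), used for scaled-down synthetic
    studies; structural invariants (valid positions, exactly one adjacent
    controller pair) hold in both cases.
    """

    table: pd.DataFrame
    full_grid: bool = True

    def __post_init__(self) -> None:
        t = self.table
        required = {"array", "row", "col", "controller", "controller_ref", "bad"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"channel map missing columns {sorted(missing)}")
        pos = list(zip(t["row"], t["col"]))
        if any(p in CORNERS for p in pos):
            raise ValueError("channel map contains removed corner positions")
        if any(
            not (0 <= r < GRID_SIZE and 0 <= c < GRID_SIZE) for r, c in pos
        ):
            raise ValueError("grid positions out of range")
        for arr, grp in t.groupby("array"):
            dup = grp.duplicated(subset=["row", "col"]).any()
            if dup:
                raise ValueError(f"array {arr}: duplicate grid positions")
            if self.full_grid and len(grp) != len(_grid_positions()):
                raise ValueError(
                    f"array {arr}: full-grid map must have 96 channels, got {len(grp)}"
                )
        n_ctrl = int(t["controller"].sum())
        n_ref = int(t["controller_ref"].sum())
        if n_ctrl > 1 or n_ref > 1 or n_ctrl != n_ref:
            raise ValueError(
                f"need exactly one controller/reference pair (or none, for a "
                f"derived subset), got {n_ctrl} and {n_ref}"
            )
        if self.full_grid and n_ctrl == 0:
            raise ValueError("full-grid map must contain the controller pair")
        if n_ctrl == 1:
            ctrl = t[t["controller"]].iloc[0]
            ref = t[t["controller_ref"]].iloc[0]
            if ctrl["array"] != ref["array"]:
                raise ValueError("controller pair must be on the same array")
            if abs(ctrl["row"] - ref["row"]) + abs(ctrl["col"] - ref["col"]) != 1:
                raise ValueError("controller pair must be adjacent on the grid")

    # -- construction --------------------------------------------------------

    @classmethod
    def grid(
        cls,
        arrays: tuple[int, ...] = (1, 2, 3),
        controller_array: int = 1,
        controller_pos: tuple[tuple[int, int], tuple[int, int]] = ((4, 4), (4, 5)),
        bad: list[tuple[int, int, int]] | None = None,
    ) -> "ChannelMap":
        """Full 96-electrode map per array; ``bad`` lists (array, row, col)."""
        bad = bad or []
        rows = []
        for arr in arrays:
            for r, c in _grid_positions():
                rows.append(
                    {
                        "array": arr,
                        "row": r,
                        "col": c,
                        "controller": arr == controller_array
                        and (r, c) == controller_pos[0],
                        "controller_ref": arr == controller_array
                        and (r, c) == controller_pos[1],
                        "bad": (arr, r, c) in set(bad),
                    }
                )
        return cls(pd.DataFrame(rows))

    def subsample(self, n_per_array: int, seed: int = 0) -> "ChannelMap":
        """Seeded subsample keeping the controller pair; for scaled-down runs."""
        rng = np.random.default_rng(seed)
        keep: list[int] = []
        for arr, grp in self.table.groupby("array"):
            fixed = grp.index[grp["controller"] | grp["controller_ref"]].tolist()
            rest = grp.index.difference(fixed).to_numpy()
            n_extra = max(0, n_per_array - len(fixed))
            chosen = rng.choice(rest, size=min(n_extra, len(rest)), replace=False)
            keep.extend(fixed + sorted(chosen.tolist()))
        sub = self.table.loc[sorted(keep)].reset_index(drop=True)
        return ChannelMap(sub, full_grid=False)

    # -- queries -------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.table)

    @property
    def arrays(self) -> list[int]:
        return sorted(self.table["array"].unique().tolist())

    @property
    def controller_pair(self) -> tuple[int, int]:
        """(controller, reference) channel indices."""
        ctrl = int(self.table.index[self.table["controller"]][0])
        ref = int(self.table.index[self.table["controller_ref"]][0])
        return ctrl, ref

    def indices(
        self,
        array: int | None = None,
        drop_controller: bool = False,
        drop_bad: bool = False,
    ) -> np.ndarray:
        """Channel indices matching the filters, in table order."""
        mask = np.ones(len(self.table), dtype=bool)
        if array is not None:
            mask &= (self.table["array"] == array).to_numpy()
        if drop_controller:
            mask &= ~(self.table["controller"] | self.table["controller_ref"]).to_numpy()
        if drop_bad:
            mask &= ~self.table["bad"].to_numpy()
        return np.flatnonzero(mask)

    def subset(self, indices: np.ndarray) -> "ChannelMap":
        """Positional subset as a new (non-full-grid) map."""
        sub = self.table.iloc[indices].reset_index(drop=True)
        return ChannelMap(sub, full_grid=False)

    # -- (de)serialization ---------------------------------------------------

    def to_records(self) -> list[dict]:
        recs = self.table.to_dict(orient="records")
        for r in recs:
            for k in ("array", "row", "col"):
                r[k] = int(r[k])
            for k in ("controller", "controller_ref", "bad"):
                r[k] = bool(r[k])
        return recs

    @classmethod
    def from_records(cls, records: list[dict]) -> "ChannelMap":
        table = pd.DataFrame(records)
        n_per = table.groupby("array").size()
        full = bool((n_per == len(_grid_positions())).all())
        return cls(table, full_grid=full)
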