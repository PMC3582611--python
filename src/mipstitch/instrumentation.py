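"""Counters instrumenting the streaming memory and I/O contracts.

The alignment step promises to keep at most (min{n_rows, n_cols} + 1)
substacks resident and to read every slice exactly once; the merge step
promises at most one slice group of fused output resident plus one tile
row's worth of input slices.  These counters let callers (and the test
suite) assert those contracts instead of trusting them.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class Counters:
    resident_substacks: int = 0
    peak_resident_substacks: int = 0
    resident_fused_slices: int = 0
    peak_resident_fused_slices: int = 0
    resident_tile_slices: int = 0
    peak_resident_tile_slices: int = 0
    opens: Counter = field(default_factory=Counter)

    # -- substacks (alignment) ------------------------------------------
    def substack_loaded(self) -> None:
        self.resident_substacks += 1
        self.peak_resident_substacks = max(
            self.peak_resident_substacks, self.resident_substacks
        )

    def substack_released(self) -> None:
        assert self.resident_substacks > 0
        self.resident_substacks -= 1

    # -- fused output slices (merge) ------------------------------------
    def fused_slices_resident(self, n: int) -> None:
        self.resident_fused_slices = n
        self.peak_resident_fused_slices = max(self.peak_resident_fused_slices, n)

    # -- input tile slices (merge) ---------------------------------------
    def tile_slices_resident(self, n: int) -> None:
        self.resident_tile_slices = n
        self.peak_resident_tile_slices = max(self.peak_resident_tile_slices, n)

    # -- file opens ------------------------------------------------------
    def record_open(self, path: Path) -> None:
        self.opens[Path(path)] += 1

    @property
    def total_opens(self) -> int:
        return sum(self.opens.values())

    @property
    def max_opens_per_file(self) -> int:
        return max(self.opens.values(), default=0)
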