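"""Projection and thresholding of redundant pairwise displacements.

Each adjacent tile pair carries one displacement estimate per substack
layer.  *Projection* collapses that redundancy by picking, independently
for each direction, the estimate with the highest reliability in that
direction (so the result may mix layers across directions).  *Thresholding*
then rejects pairs whose aggregate reliability falls below a threshold:
their offsets are reset to the stage-coordinate default, their
reliabilities zeroed, and the pair marked nonstitchable.  A tile all of
whose incident pairs are nonstitchable is itself nonstitchable and can only
be placed at its stage coordinates.

Good thresholds on well-contrasted data lie in [0.7, 0.8]; lower values may
be needed for low-contrast or noisy acquisitions.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, replace

from .volume_model import (
    PairDisplacement,
    PairKey,
    StitchState,
    ValidationError,
    pair_axis,
)

__all__ = [
    "ThresholdConfig",
    "project",
    "project_state",
    "threshold_pair",
    "threshold_state",
    "mark_tiles",
    "stitchability_report",
]


@dataclass(frozen=True)
class ThresholdConfig:
    """Reliability threshold and the per-pair aggregation rule.

    ``aggregate`` is ``min`` (conservative default: one bad axis misplaces
    the tile) or ``mean``.  A pair is kept when its aggregate reliability is
    >= ``reliability_threshold``.
    """

    reliability_threshold: float = 0.7
    aggregate: str = "min"

    def __post_init__(self) -> None:
        if not (0.0 < self.reliability_threshold < 1.0):
            raise ValidationError("reliability_threshold must be in (0, 1)")
        if self.aggregate not in ("min", "mean"):
            raise ValidationError("aggregate must be 'min' or 'mean'")

    def pair_reliability(self, pd: PairDisplacement) -> float:
        if self.aggregate == "min":
            return min(pd.reliabilities)
        return sum(pd.reliabilities) / 3.0


def project(per_substack: list[PairDisplacement]) -> PairDisplacement:
    """Collapse per-substack estimates of one pair to a single displacement.

    For each direction independently the layer with maximal reliability in
    that direction wins (ties: earliest layer), so the output may combine
    offsets from different layers.
    """
    if not per_substack:
        raise ValidationError("cannot project an empty displacement list")
    pair = per_substack[0].pair
    if any(pd.pair != pair for pd in per_substack):
        raise ValidationError("projection requires records of a single pair")
    offsets, rels = [], []
    for i in range(3):
        best = max(range(len(per_substack)), key=lambda k: per_substack[k].reliabilities[i])
        # max() keeps the earliest index on ties
        offsets.append(per_substack[best].offsets[i])
        rels.append(per_substack[best].reliabilities[i])
    return PairDisplacement(
        pair=pair,
        offsets=tuple(offsets),  # type: ignore[arg-type]
        reliabilities=tuple(rels),  # type: ignore[arg-type]
        z0=per_substack[0].z0,
        z1=per_substack[-1].z1,
    )


def project_state(state: StitchState) -> StitchState:
    """Apply :func:`project` to every pair; stage becomes 'projected'."""
    state.require_stage("displacements_computed")
    projected: dict[PairKey, PairDisplacement] = {}
    for key in sorted(state.pair_displacements):
        records = state.pair_displacements[key]
        projected[key] = project(records if isinstance(records, list) else [records])
    return StitchState(
        stage="projected",
        volume=state.volume,
        pair_displacements=projected,  # type: ignore[arg-type]
    )


def threshold_pair(
    pd: PairDisplacement, config: ThresholdConfig
) -> PairDisplacement:
    """Keep a projected displacement or fall back to stage coordinates.

    Offsets are stored relative to the nominal displacement, so restoring
    the stage default means zeroing all three; reliabilities are zeroed too
    and the pair marked nonstitchable.
    """
    if config.pair_reliability(pd) >= config.reliability_threshold:
        return pd
    return replace(
        pd,
        offsets=(0, 0, 0),
        reliabilities=(0.0, 0.0, 0.0),
        default_flag=True,
        stitchable=False,
    )


def mark_tiles(state: StitchState) -> StitchState:
    """Propagate pair stitchability to tiles (in place on the volume).

    A tile is nonstitchable iff *every* incident pair (4 in the interior, 2
    or 3 on borders/corners) is nonstitchable.
    """
    incident: dict[tuple[int, int], list[PairDisplacement]] = {}
    for key, entry in state.pair_displacements.items():
        pd = entry if isinstance(entry, PairDisplacement) else entry[-1]
        for node in key:
            incident.setdefault(node, []).append(pd)
    for node, tile in state.volume.tiles.items():
        pairs = incident.get(node, [])
        tile.stitchable = any(pd.stitchable for pd in pairs) if pairs else True
    return state


def threshold_state(state: StitchState, config: ThresholdConfig) -> StitchState:
    """Threshold every projected pair and mark tiles; stage 'thresholded'."""
    state.require_stage("projected", "thresholded")
    out: dict[PairKey, PairDisplacement] = {}
    for key in sorted(state.pair_displacements):
        entry = state.pair_displacements[key]
        if isinstance(entry, list):
            raise ValidationError("thresholding requires projected displacements")
        out[key] = threshold_pair(entry, config)
    new = StitchState(
        stage="thresholded",
        volume=state.volume,
        pair_displacements=out,  # type: ignore[arg-type]
    )
    return mark_tiles(new)


_PAIR_ROW_RE = re.compile(
    r"pair \((\d+),(\d+)\)-\((\d+),(\d+)\) (\w)\s+"
    r"offsets \(([-\d]+),([-\d]+),([-\d]+)\)\s+"
    r"reliability \(([.\d]+),([.\d]+),([.\d]+)\)\s+(\w+)"
)


def stitchability_report(state: StitchState) -> str:
    """Plain-text map of stitchable tiles and per-pair displacements.

    Meant for eyeballing before hand-editing the XML: a grid of ``S``
    (stitchable) / ``n`` (nonstitchable) tiles followed by one row per pair
    with offsets and reliabilities.  The pair rows are machine-parsable
    (see :func:`parse_report_pairs`).
    """
    vol = state.volume
    buf = io.StringIO()
    buf.write(f"tile grid {vol.n_rows}x{vol.n_cols} (S = stitchable, n = nonstitchable)\n")
    for r in range(vol.n_rows):
        row = " ".join(
            "S" if vol.tile(r, c).stitchable else "n" for c in range(vol.n_cols)
        )
        buf.write(f"  {row}\n")
    buf.write("\n")
    for key in sorted(state.pair_displacements):
        entry = state.pair_displacements[key]
        pd = entry if isinstance(entry, PairDisplacement) else entry[-1]
        (ar, ac), (br, bc) = key
        o, rl = pd.offsets, pd.reliabilities
        buf.write(
            f"pair ({ar},{ac})-({br},{bc}) {pair_axis(key)} "
            f"offsets ({o[0]},{o[1]},{o[2]}) "
            f"reliability ({rl[0]:.3f},{rl[1]:.3f},{rl[2]:.3f}) "
            f"{'stitchable' if pd.stitchable else 'nonstitchable'}\n"
        )
    return buf.getvalue()


def parse_report_pairs(report: str):
    """Parse the pair rows of a stitchability report back into tuples.

    Returns ``{pair_key: (offsets, reliabilities, stitchable)}``.
    """
    out = {}
    for m in _PAIR_ROW_RE.finditer(report):
        key = ((int(m.group(1)), int(m.group(2))), (int(m.group(3)), int(m.group(4))))
        offsets = tuple(int(m.group(i)) for i in (6, 7, 8))
        rels = tuple(float(m.group(i)) for i in (9, 10, 11))
        out[key] = (offsets, rels, m.group(12) == "stitchable")
    return out
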