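"""Split-unit randomisation for the image-based screening.

Seven rice lines are assigned to the seven main units of each of six
replicates by a 7 x 6 Youden square — an incomplete Latin rectangle
whose columns form a balanced incomplete block design with v = b = 7,
r = k = 6 and pairwise concurrence lambda = 5.  Within each main unit
(a 2 lane x 2 position grid of four carts) the four salt treatments are
split into two lane-blocks of two by a resolved incomplete block
design, balancing the six treatment pairs across the experiment.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "youden_square",
    "resolved_pair_blocks",
    "assemble_layout",
    "validate_layout",
    "concurrence_counts",
    "block_concurrence_counts",
    "DEFAULT_LINES",
    "DEFAULT_TREATMENTS",
    "DEFAULT_POSITIONS",
]

DEFAULT_LINES = ("Pokkali", "IR29", "Oa-VR", "Oa-D", "Oa-CH", "Oa-KR", "Om-T")
DEFAULT_TREATMENTS = ("0mM", "40mM", "80mM", "100mM")
#: usable conveyor positions on each lane (two gaps in the physical grid)
DEFAULT_POSITIONS = tuple(range(5, 13)) + tuple(range(15, 21))

#: the three ways to split four treatments into two unordered pairs
_PAIRINGS = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))


def youden_square(
    lines: tuple[str, ...] = DEFAULT_LINES,
    n_reps: int = 6,
    seed: int = 0,
) -> pd.DataFrame:
    """Randomised v x (v-1) Youden square assigning lines to main positions.

    Built by deleting one row of the cyclic Latin square of order v and
    randomising rows, columns and line labels with ``seed``.  Each row
    (replicate) is a permutation of the lines; each column (main
    position) misses exactly one line and every unordered pair of lines
    co-occurs in exactly v - 2 columns.

    Returns a DataFrame indexed by replicate 1..n_reps with columns
    main_unit 1..v.
    """
    v = len(lines)
    if n_reps != v - 1:
        raise ValueError(
            f"cyclic construction needs n_reps = len(lines) - 1; got {v} lines"
            f" and {n_reps} replicates")
    if len(set(lines)) != v:
        raise ValueError("line labels must be unique")
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    # cyclic Latin square, drop the last row
    square = (np.arange(v)[:, None] + np.arange(v)[None, :]) % v
    square = square[:v - 1, :]
    square = square[rng.permutation(v - 1), :]
    square = square[:, rng.permutation(v)]
    relabel = rng.permutation(v)
    labels = np.asarray(lines, dtype=object)[relabel[square]]
    return pd.DataFrame(labels, index=pd.RangeIndex(1, v, name="replicate"),
                        columns=pd.RangeIndex(1, v + 1, name="main_unit"))


def resolved_pair_blocks(
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS,
    n_main_units: int = 42,
    seed: int = 0,
) -> list[tuple[tuple[str, str], tuple[str, str]]]:
    """Partition of the four treatments into two blocks of two, per main unit.

    The three possible pairings are allocated equally across main units
    (each 14 times when there are 42), so every unordered treatment pair
    shares a block the same number of times over the experiment; the
    order of allocation and the within-pair order are randomised.
    """
    if len(treatments) != 4:
        raise ValueError("pair-block construction is defined for 4 treatments")
    rng = np.random.default_rng((int(seed) & 0x7FFFFFFF) ^ 0x5EED)
    q, r = divmod(n_main_units, 3)
    if r:
        import logging
        logging.getLogger(__name__).warning(
            "%d main units not divisible by 3: pairing counts will be as equal"
            " as possible", n_main_units)
    counts = [q + (1 if i < r else 0) for i in range(3)]
    pool = [i for i, c in enumerate(counts) for _ in range(c)]
    rng.shuffle(pool)
    t = np.asarray(treatments, dtype=object)
    out = []
    for idx in pool:
        (a, b), (c, d) = _PAIRINGS[idx]
        blocks = [[t[a], t[b]], [t[c], t[d]]]
        rng.shuffle(blocks)
        for blk in blocks:
            rng.shuffle(blk)
        out.append((tuple(blocks[0]), tuple(blocks[1])))
    return out


def assemble_layout(
    square: pd.DataFrame,
    blocks: list[tuple[tuple[str, str], tuple[str, str]]],
    n_lanes: int = 12,
    positions: tuple[int, ...] = DEFAULT_POSITIONS,
) -> pd.DataFrame:
    """Place the randomised design onto the lane x position cart grid.

    Each replicate occupies two consecutive lanes; each of its main
    units is a 2 lane x 2 position grid of four carts, one line and all
    four treatments per main unit, the two treatment blocks lying on the
    two lanes.  Validates the full layout before returning.
    """
    n_reps, n_units = square.shape
    if len(blocks) != n_reps * n_units:
        raise ValueError(
            f"{len(blocks)} block partitions != {n_reps * n_units} main units")
    if n_lanes < 2 * n_reps:
        raise ValueError(f"need {2 * n_reps} lanes, grid has {n_lanes}")
    if len(positions) < 2 * n_units:
        raise ValueError(
            f"need {2 * n_units} positions per lane, grid has {len(positions)}")
    rows = []
    cart = 0
    for ri, rep in enumerate(square.index):
        lanes = (2 * ri + 1, 2 * ri + 2)
        for ui, unit in enumerate(square.columns):
            line = square.loc[rep, unit]
            pos_pair = (positions[2 * ui], positions[2 * ui + 1])
            unit_blocks = blocks[ri * n_units + ui]
            for lane, blk in zip(lanes, unit_blocks):
                for pos, treatment in zip(pos_pair, blk):
                    cart += 1
                    rows.append({
                        "cart": cart, "lane": lane, "position": pos,
                        "replicate": int(rep), "main_unit": int(unit),
                        "line": line, "treatment": treatment,
                        "block": f"r{rep}u{unit}l{lane}",
                    })
    layout = pd.DataFrame(rows)
    problems = validate_layout(layout)
    if problems:
        raise ValueError("assembled layout invalid: " + "; ".join(problems))
    return layout


def validate_layout(layout: pd.DataFrame) -> list[str]:
    """Machine-check the split-unit invariants; returns a list of problems.

    Checks: every replicate contains each line x treatment combination
    exactly once; every main unit holds a single line and all
    treatments; every cart slot (lane, position) is used at most once.
    Usable on externally supplied layouts as well.
    """
    problems: list[str] = []
    required = {"lane", "position", "replicate", "main_unit", "line", "treatment"}
    missing = required - set(layout.columns)
    if missing:
        return [f"missing columns: {sorted(missing)}"]
    n_lines = layout["line"].nunique()
    n_treat = layout["treatment"].nunique()
    for rep, g in layout.groupby("replicate"):
        combos = g.groupby(["line", "treatment"]).size()
        if len(combos) != n_lines * n_treat or (combos != 1).any():
            problems.append(
                f"replicate {rep}: line x treatment combinations not each once")
    for (rep, unit), g in layout.groupby(["replicate", "main_unit"]):
        if g["line"].nunique() != 1:
            problems.append(f"main unit {rep}/{unit}: more than one line")
        if sorted(g["treatment"]) != sorted(layout["treatment"].unique()):
            problems.append(f"main unit {rep}/{unit}: treatments not all present")
    dup = layout.duplicated(subset=["lane", "position"])
    if dup.any():
        problems.append(f"{int(dup.sum())} duplicated lane/position slot(s)")
    return problems


def concurrence_counts(square: pd.DataFrame) -> dict[tuple[str, str], int]:
    """Number of columns in which each unordered line pair co-occurs."""
    counts: dict[tuple[str, str], int] = {}
    lines = sorted(set(square.to_numpy().ravel()))
    for a, b in combinations(lines, 2):
        n = 0
        for col in square.columns:
            col_lines = set(square[col])
            if a in col_lines and b in col_lines:
                n += 1
        counts[(a, b)] = n
    return counts


def block_concurrence_counts(
    blocks: list[tuple[tuple[str, str], tuple[str, str]]],
) -> dict[tuple[str, str], int]:
    """How often each unordered treatment pair shares a lane-block."""
    counts: dict[tuple[str, str], int] = {}
    for unit in blocks:
        for blk in unit:
            key = tuple(sorted(blk))
            counts[key] = counts.get(key, 0) + 1
    return counts
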