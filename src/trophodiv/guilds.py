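"""Dietary guild classification from per-species food-item score vectors.

Each species carries nine scores (invertebrates, fruits, nectar, seeds,
terrestrial vertebrates, fishes, carrion, non-reproductive plant material,
miscellaneous) summing to 10, each score being the approximate proportion of
that food type in the diet.  A species is a specialist of the guild mapped to
a food item when exactly one item's score strictly exceeds the threshold
(default 5); otherwise — no dominant item, or a tie — it is an omnivore.  The
"miscellaneous" item defines no specialist guild, so a dominant miscellaneous
score also yields omnivore.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from io import StringIO
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "FOOD_ITEMS",
    "GUILDS",
    "ITEM_TO_GUILD",
    "ClassifierConfig",
    "classify_species",
    "classify_table",
    "read_diet_table",
    "write_guild_assignment",
]

#: Fixed food-item order of a diet-score vector.
FOOD_ITEMS = (
    "invertebrates",
    "fruits",
    "nectar",
    "seeds",
    "vertebrates",
    "fish",
    "carrion",
    "plants",
    "misc",
)

#: Specialist guild per food item; ``misc`` maps to no guild.
ITEM_TO_GUILD = {
    "invertebrates": "insectivore",
    "fruits": "frugivore",
    "nectar": "nectarivore",
    "seeds": "granivore",
    "vertebrates": "carnivore",
    "fish": "piscivore",
    "carrion": "scavenger",
    "plants": "herbivore",
    "misc": None,
}

GUILDS = (
    "carnivore",
    "frugivore",
    "granivore",
    "herbivore",
    "insectivore",
    "nectarivore",
    "piscivore",
    "scavenger",
    "omnivore",
)

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class ClassifierConfig:
    """Specialist threshold ``t``: classify when a single score strictly
    exceeds ``t`` (default 5).  Larger ``t`` gives a more inclusive notion of
    omnivory (the sensitivity variant)."""

    threshold: float = 5.0

    def __post_init__(self):
        if not (0 < self.threshold < 10):
            raise ValueError("threshold must lie strictly between 0 and 10")


def _check_vector(v) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.shape != (9,):
        raise ValueError(f"diet-score vector must have exactly 9 entries, got {arr.shape}")
    if np.any(arr < 0):
        raise ValueError("diet scores must be non-negative")
    if abs(arr.sum() - 10.0) > _SUM_TOL:
        raise ValueError(f"diet scores must sum to 10 (got {arr.sum()!r})")
    return arr


def classify_species(v: Sequence[float], cfg: ClassifierConfig = ClassifierConfig()) -> str:
    """Guild of a single diet-score vector (fixed :data:`FOOD_ITEMS` order)."""
    arr = _check_vector(v)
    dominant = np.nonzero(arr > cfg.threshold)[0]
    if len(dominant) != 1:
        return "omnivore"
    guild = ITEM_TO_GUILD[FOOD_ITEMS[dominant[0]]]
    return guild if guild is not None else "omnivore"


def classify_table(
    table: Mapping[str, Sequence[float]] | pd.DataFrame,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> Tuple[Dict[str, str], Dict[str, int], Dict[str, float]]:
    """Classify every species; returns (assignment, counts, proportions).

    ``table`` maps species label -> 9-score vector, or is a DataFrame indexed
    by species with the :data:`FOOD_ITEMS` columns.  Counts cover all nine
    guilds (zeros included); proportions sum to 1.
    """
    if isinstance(table, pd.DataFrame):
        if table.index.has_duplicates:
            dups = sorted(table.index[table.index.duplicated()].unique())
            raise ValueError(f"duplicate species labels: {dups}")
        items = {sp: table.loc[sp, list(FOOD_ITEMS)].to_numpy() for sp in table.index}
    else:
        items = dict(table)
        if len(items) != len(table):
            raise ValueError("duplicate species labels")
    if not items:
        raise ValueError("empty diet table")
    assignment = {str(sp): classify_species(v, cfg) for sp, v in items.items()}
    counts = {g: 0 for g in GUILDS}
    for g in assignment.values():
        counts[g] += 1
    n = len(assignment)
    proportions = {g: c / n for g, c in counts.items()}
    return assignment, counts, proportions


def read_diet_table(source) -> pd.DataFrame:
    """Read a delimited diet-score table.

    Expected header: ``species,invertebrates,fruits,nectar,seeds,vertebrates,
    fish,carrion,plants,misc`` (comma or tab separated).
    """
    if isinstance(source, str) and "\n" in source:
        source = StringIO(source)
    df = pd.read_csv(source, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in ("species",) + FOOD_ITEMS if c not in df.columns]
    if missing:
        raise ValueError(f"diet table missing columns: {missing}")
    df = df.set_index("species")[list(FOOD_ITEMS)]
    df.index = df.index.map(lambda s: str(s).strip())
    return df


def write_guild_assignment(assignment: Mapping[str, str], counts: Mapping[str, int]):
    """Serialize an assignment as (CSV text, JSON summary text)."""
    lines = ["species,guild"] + [f"{sp},{g}" for sp, g in assignment.items()]
    n = sum(counts.values())
    summary = {
        "n_species": n,
        "counts": dict(counts),
        "proportions": {g: c / n for g, c in counts.items()},
    }
    return "\n".join(lines) + "\n", json.dumps(summary, indent=2)
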