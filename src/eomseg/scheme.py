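"""Label taxonomy for extraocular-muscle segmentation.

Nine classes: background plus the four rectus-muscle classes per side.  The
superior rectus and the levator palpebrae superioris are not reliably
separable on CT and form a single "superior group" class.  Thickness of the
medial/lateral recti is measured along the horizontal axis, of the superior
group and inferior rectus along the vertical axis; each class therefore
carries an axis tag in addition to its side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "BACKGROUND",
    "ClassScheme",
    "DEFAULT_SCHEME",
    "muscle_classes",
]

BACKGROUND = 0

# Canonical order: left side before right, medial/lateral/superior/inferior
# within a side.  This ordering is fixed so one-hot encodings and report rows
# are stable across the whole pipeline.
_CLASS_TABLE = (
    (0, "background", None, None),
    (1, "L-medial rectus", "L", "horizontal"),
    (2, "L-lateral rectus", "L", "horizontal"),
    (3, "L-superior group", "L", "vertical"),
    (4, "L-inferior rectus", "L", "vertical"),
    (5, "R-medial rectus", "R", "horizontal"),
    (6, "R-lateral rectus", "R", "horizontal"),
    (7, "R-superior group", "R", "vertical"),
    (8, "R-inferior rectus", "R", "vertical"),
)


@dataclass(frozen=True)
class ClassScheme:
    """Immutable mapping between integer labels, names, sides and axes."""

    index_to_name: Mapping[int, str]
    side: Mapping[int, str]
    axis: Mapping[int, str]

    @property
    def n_classes(self) -> int:
        return len(self.index_to_name)

    def name(self, index: int) -> str:
        return self.index_to_name[index]

    def index(self, name: str) -> int:
        for i, n in self.index_to_name.items():
            if n == name:
                return i
        raise KeyError(name)

    def muscle_classes(self) -> list[int]:
        """Non-background class indices in canonical order."""
        return [i for i in sorted(self.index_to_name) if i != BACKGROUND]

    def classes_for_side(self, side: str) -> list[int]:
        return [i for i in self.muscle_classes() if self.side[i] == side]

    def to_json(self) -> str:
        """Class table as JSON, for label-volume headers and reports."""
        rows = [
            {
                "index": i,
                "name": self.index_to_name[i],
                "side": self.side.get(i),
                "axis": self.axis.get(i),
            }
            for i in sorted(self.index_to_name)
        ]
        return json.dumps(rows, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ClassScheme":
        rows = json.loads(text)
        idx2name = {r["index"]: r["name"] for r in rows}
        side = {r["index"]: r["side"] for r in rows if r["side"]}
        axis = {r["index"]: r["axis"] for r in rows if r["axis"]}
        return cls(index_to_name=idx2name, side=side, axis=axis)


DEFAULT_SCHEME = ClassScheme(
    index_to_name={i: n for i, n, _, _ in _CLASS_TABLE},
    side={i: s for i, _, s, _ in _CLASS_TABLE if s is not None},
    axis={i: a for i, _, _, a in _CLASS_TABLE if a is not None},
)


def muscle_classes() -> list[int]:
    """The 8 muscle class indices of the default scheme, background excluded."""
    return DEFAULT_SCHEME.muscle_classes()
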