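"""Axis-aligned boxes in image coordinates.

Conventions: 0-based pixel indices, half-open intervals
[row_min, row_max) x [col_min, col_max).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["BoundingBox"]


@dataclass(frozen=True)
class BoundingBox:
    row_min: int
    col_min: int
    row_max: int
    col_max: int

    def __post_init__(self):
        if not (self.row_min < self.row_max and self.col_min < self.col_max):
            raise ValueError(f"degenerate box {self}")
        if self.row_min < 0 or self.col_min < 0:
            raise ValueError(f"negative box coordinates {self}")

    @property
    def height(self) -> int:
        return self.row_max - self.row_min

    @property
    def width(self) -> int:
        return self.col_max - self.col_min

    @property
    def area(self) -> int:
        return self.height * self.width

    def expand(self, margin_rows: int, margin_cols: int,
               frame_height: int, frame_width: int) -> "BoundingBox":
        """Grow by a pixel margin on each side, clipped to the frame."""
        return BoundingBox(
            max(0, self.row_min - margin_rows),
            max(0, self.col_min - margin_cols),
            min(frame_height, self.row_max + margin_rows),
            min(frame_width, self.col_max + margin_cols),
        )

    def intersection_over_union(self, other: "BoundingBox") -> float:
        ri = max(self.row_min, other.row_min)
        ci = max(self.col_min, other.col_min)
        ra = min(self.row_max, other.row_max)
        ca = min(self.col_max, other.col_max)
        inter = max(0, ra - ri) * max(0, ca - ci)
        union = self.area + other.area - inter
        return inter / union if union else 0.0

    def to_dict(self) -> dict:
        return {"row_min": self.row_min, "col_min": self.col_min,
                "row_max": self.row_max, "col_max": self.col_max}

    @classmethod
    def from_dict(cls, d: dict) -> "BoundingBox":
        return cls(d["row_min"], d["col_min"], d["row_max"], d["col_max"])
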