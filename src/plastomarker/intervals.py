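"""Circular intervals on a plastome.

Internally everything is 0-based, half-open. An interval that spans the
origin of the circular molecule carries ``wraps=True``; its ``end`` is then
smaller than (or equal to) its ``start``.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class CircularInterval:
    start: int
    end: int
    wraps: bool = False

    @staticmethod
    def from_span(start: int, length: int, seq_len: int) -> "CircularInterval":
        """Interval of ``length`` bases beginning at ``start`` (mod seq_len)."""
        if not 0 < length <= seq_len:
            raise ValueError(f"invalid interval length {length} on circle of {seq_len}")
        start = start % seq_len
        stop = start + length
        if stop <= seq_len:
            return CircularInterval(start, stop, False)
        return CircularInterval(start, stop - seq_len, True)

    def length(self, seq_len: int) -> int:
        if self.wraps:
            return seq_len - self.start + self.end
        return self.end - self.start

    def segments(self, seq_len: int) -> list[tuple[int, int]]:
        """Linear half-open pieces covering the interval."""
        if self.wraps:
            return [(self.start, seq_len), (0, self.end)]
        return [(self.start, self.end)]

    def contains(self, pos: int, seq_len: int) -> bool:
        pos = pos % seq_len
        return any(a <= pos < b for a, b in self.segments(seq_len))

    def overlap_length(self, other: "CircularInterval", seq_len: int) -> int:
        total = 0
        for a1, b1 in self.segments(seq_len):
            for a2, b2 in other.segments(seq_len):
                total += max(0, min(b1, b2) - max(a1, a2))
        return total

    def overlaps(self, other: "CircularInterval", seq_len: int) -> bool:
        return self.overlap_length(other, seq_len) > 0

    def shifted(self, offset: int, seq_len: int) -> "CircularInterval":
        return CircularInterval.from_span(
            (self.start + offset) % seq_len, self.length(seq_len), seq_len
        )
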