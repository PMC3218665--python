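"""SOLiD two-base (color-space) encoding and re-alignment scoring support.

Each color encodes a *pair* of adjacent bases; the code is the XOR of the
2-bit base codes (A=0, C=1, G=2, T=3).  A true base change therefore alters
two adjacent colors, while a single sequencing error alters exactly one —
which is what makes scoring in color space less reference-biased than
scoring the decoded bases.

During re-alignment the decoded sequence is constrained to match the bases
of a valid graph path exactly; the score compares the read's *original*
colors against the colors expected from consecutive path bases (and, for the
first base, from the known sequencing adapter).  Color data travels in SAM
via the SOLiD-community CS (color string, leading primer base) and CQ
(color qualities) tags.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: Sentinel color for pairs involving an ambiguous base; never matches a
#: real color, and mismatches against it are scored with quality 0.
AMBIGUOUS_COLOR = 4


def encode_color(base1: str, base2: str) -> int:
    """Color code of a dibase: XOR of the 2-bit base codes.

    Symmetric in its arguments, and ``encode_color(x, x) == 0``.  Any
    ambiguous base yields :data:`AMBIGUOUS_COLOR`.
    """
    a = _CODE.get(base1)
    b = _CODE.get(base2)
    if a is None or b is None:
        return AMBIGUOUS_COLOR
    return a ^ b


def decode_base(base1: str, color: int) -> str:
    """Second base of a dibase given its first base and the color."""
    a = _CODE.get(base1)
    if a is None or not 0 <= color <= 3:
        return "N"
    return "ACGT"[a ^ color]


def complement(base: str) -> str:
    return _COMP.get(base, "N")


def colors_from_bases(adapter: str, bases: str) -> list[int]:
    """Color sequence of ``bases`` anchored by the adapter's last base."""
    out = []
    prev = adapter[-1]
    for b in bases:
        out.append(encode_color(prev, b))
        prev = b
    return out


def bases_from_colors(adapter: str, colors: Sequence[int]) -> str:
    """Naive cumulative decode of a color sequence.

    A single color error corrupts every downstream base — the behaviour
    alignment-free decoding actually has, and the reason re-alignment keeps
    the original colors around.
    """
    out = []
    prev = adapter[-1]
    for c in colors:
        prev = decode_base(prev, c)
        out.append(prev)
    return "".join(out)


@dataclass(frozen=True)
class ColorRead:
    """Original color observations of one read (adapter-anchored).

    ``colors[i]`` encodes the transition into decoded base ``i``;
    ``colors[0]`` encodes adapter -> first base.
    """

    adapter: str
    colors: tuple[int, ...]
    color_qualities: tuple[int, ...]

    def __post_init__(self):
        if len(self.colors) != len(self.color_qualities):
            raise ValueError("colors and color_qualities lengths differ")


def parse_cs_cq(cs: str, cq: str, quality_offset: int = 33) -> ColorRead:
    """Build a :class:`ColorRead` from SAM CS/CQ tag payloads.

    CS starts with the primer base followed by digit colors ('.' for a
    missing call); CQ is a Phred+33 string with one character per color.
    """
    if not cs or cs[0] not in _CODE:
        raise ValueError(f"CS tag must start with a primer base: {cs!r}")
    adapter = cs[0]
    colors = tuple(
        int(ch) if ch.isdigit() else AMBIGUOUS_COLOR for ch in cs[1:]
    )
    quals = tuple(ord(ch) - quality_offset for ch in cq)
    return ColorRead(adapter, colors, quals)


def to_cs_cq(read: ColorRead, quality_offset: int = 33) -> tuple[str, str]:
    cs = read.adapter + "".join(
        str(c) if 0 <= c <= 3 else "." for c in read.colors
    )
    cq = "".join(chr(q + quality_offset) for q in read.color_qualities)
    return cs, cq


def score_color_extension(
    previous_score: float,
    expected_color: int,
    observed_color: int,
    color_quality: int,
    cap: int = 40,
) -> float:
    """Extend a path score by one color comparison.

    Matching colors add no penalty; a mismatch subtracts the color quality
    (capped).  Ambiguous colors on either side are treated as a mismatch at
    quality 0, i.e. free.
    """
    if expected_color == observed_color:
        return previous_score
    if expected_color == AMBIGUOUS_COLOR or observed_color == AMBIGUOUS_COLOR:
        return previous_score
    return previous_score - min(color_quality, cap)
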