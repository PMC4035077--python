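"""Restriction enzymes, in silico double digestion and size selection.

A ddRAD library samples the genome at fragments flanked by two different
restriction sites (a rare and a frequent cutter) whose total size — insert
plus adaptors/indices — falls inside a gel-selected window.  The defaults
model a SacI (GAGCTC) x MseI (TTAA) double digest with a 300-500 bp
selection window.
"""

from __future__ import annotations

from dataclasses import dataclass

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class EnzymeSpec:
    """A type-II restriction enzyme with a palindromic recognition site.

    Parameters
    ----------
    name : str
        Display name, e.g. ``"SacI"``.
    site : str
        Recognition site on the top strand, ``{A,C,G,T}`` only.
    cut_offset_top : int
        Bases from the start of the site at which the top strand is cut.
        Must satisfy ``1 <= cut_offset_top < len(site)``.
    """

    name: str
    site: str
    cut_offset_top: int

    def __post_init__(self) -> None:
        if not self.site or set(self.site) - set("ACGT"):
            raise ValueError(f"{self.name}: site must be a non-empty ACGT string")
        if not 1 <= self.cut_offset_top < len(self.site):
            raise ValueError(
                f"{self.name}: cut_offset_top must lie strictly inside the site"
            )

    @property
    def remnant(self) -> str:
        """Site bases a sequencing read crosses at a cut end.

        For a palindromic site cut at top-strand offset ``c`` the bottom
        strand is cut at ``len(site) - c``; after adaptor ligation every
        read entering the fragment reads the overhang plus the rest of
        the site, i.e. ``site[min(c, len-c):]`` (SacI -> ``AGCTC``,
        MseI -> ``TAA``).
        """
        c = self.cut_offset_top
        return self.site[min(c, len(self.site) - c):]


#: SacI: rare cutter, 6-bp site, GAGCT^C (3' overhang AGCT).
SACI = EnzymeSpec("SacI", "GAGCTC", 5)
#: MseI: frequent cutter, 4-bp site, T^TAA (5' overhang TA).
MSEI = EnzymeSpec("MseI", "TTAA", 1)


@dataclass(frozen=True)
class Fragment:
    """A digestion fragment on the input's top strand, 0-based half-open."""

    start: int
    end: int
    left_enzyme: str
    right_enzyme: str

    @property
    def length(self) -> int:
        return self.end - self.start


def _cut_positions(sequence: str, enzyme: EnzymeSpec) -> list[int]:
    """Top-strand cut coordinates for every site occurrence (may overlap)."""
    cuts = []
    start = 0
    while True:
        i = sequence.find(enzyme.site, start)
        if i < 0:
            break
        cuts.append(i + enzyme.cut_offset_top)
        start = i + 1
    return cuts


def digest_and_size_select(
    sequence: str,
    enz_a: EnzymeSpec = SACI,
    enz_b: EnzymeSpec = MSEI,
    window: tuple[int, int] = (300, 500),
    adaptor_length: int = 76,
) -> list[Fragment]:
    """Double-digest ``sequence`` and keep ddRAD-selectable fragments.

    A fragment is retained iff one end is an ``enz_a`` cut and the other
    an ``enz_b`` cut (either orientation) and its library size —
    fragment length plus ``adaptor_length`` — lies inside ``window``
    (inclusive).  Chromosome-terminal pieces have no enzyme end and are
    never retained.

    Returns fragments as 0-based half-open coordinates on the input.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    lo, hi = window
    if lo > hi:
        raise ValueError("window min must be <= max")

    cuts = sorted(
        [(pos, enz_a.name) for pos in _cut_positions(sequence, enz_a)]
        + [(pos, enz_b.name) for pos in _cut_positions(sequence, enz_b)]
    )
    out = []
    for (p0, e0), (p1, e1) in zip(cuts, cuts[1:]):
        if e0 == e1 or p0 == p1:
            continue
        if lo <= (p1 - p0) + adaptor_length <= hi:
            out.append(Fragment(p0, p1, e0, e1))
    return out
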