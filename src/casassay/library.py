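"""Randomized-PAM amplicon library geometry and IUPAC utilities.

The depletion assay interrogates an amplicon carrying a PAM cassette of the
form 5'-TTTTNNNN-3' on the non-target strand: four fixed T's followed by four
randomized positions labelled -5, -6, -7, -8 in the 5'->3' direction.  A
:class:`PamLibrarySpec` records the constant sequences flanking the randomized
tetramer (the anchors used for extraction) and the position labels; an
:class:`AmpliconDesign` additionally holds the full constant flanks of the
library fragment so that reads can be simulated.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement

DNA_ALPHABET = frozenset("ACGT")

#: IUPAC code -> frozenset of unambiguous bases (includes A, C, G, T themselves).
IUPAC_TO_BASES: dict[str, frozenset[str]] = {
    code: frozenset(bases)
    for code, bases in ambiguous_dna_values.items()
    if code != "X"  # X duplicates N; keep N canonical
}

#: frozenset of bases -> IUPAC code, the inverse of :data:`IUPAC_TO_BASES`.
BASES_TO_IUPAC: dict[frozenset[str], str] = {
    bases: code for code, bases in IUPAC_TO_BASES.items()
}


def expand_iupac(pattern: str) -> list[str]:
    """Enumerate every unambiguous DNA sequence matching an IUPAC pattern."""
    try:
        choices = [sorted(IUPAC_TO_BASES[c]) for c in pattern.upper()]
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code {exc.args[0]!r} in {pattern!r}") from exc
    return ["".join(p) for p in itertools.product(*choices)]


def matches_iupac(pattern: str, sequence: str) -> bool:
    """True if ``sequence`` (unambiguous) matches the IUPAC ``pattern``."""
    if len(pattern) != len(sequence):
        return False
    return all(b in IUPAC_TO_BASES[c] for c, b in zip(pattern.upper(), sequence.upper()))


def all_pams(length: int = 4) -> list[str]:
    """All ``4**length`` tetramers (or L-mers), lexicographically sorted."""
    return ["".join(p) for p in itertools.product("ACGT", repeat=length)]


@dataclass(frozen=True)
class PamLibrarySpec:
    """Geometry of the randomized-PAM cassette used for extraction.

    Parameters
    ----------
    upstream_anchor
        Constant sequence immediately 5' of the randomized positions on the
        non-target strand; its 3' end is the fixed TTTT of the cassette.
    downstream_anchor
        Constant sequence immediately 3' of the randomized positions.
    randomized_length
        Number of randomized positions (4 for the TTTTNNNN cassette).
    position_labels
        Labels assigned 5'->3' across the randomized positions; the assay
        numbers them -5, -6, -7, -8.
    """

    upstream_anchor: str
    downstream_anchor: str
    randomized_length: int = 4
    position_labels: tuple[int, ...] = (-5, -6, -7, -8)

    def __post_init__(self) -> None:
        for name, anchor in (
            ("upstream_anchor", self.upstream_anchor),
            ("downstream_anchor", self.downstream_anchor),
        ):
            if len(anchor) < 6:
                raise ValueError(f"{name} must be at least 6 nt, got {len(anchor)}")
            if not set(anchor) <= DNA_ALPHABET:
                raise ValueError(f"{name} contains non-ACGT characters: {anchor!r}")
        if self.randomized_length < 1:
            raise ValueError("randomized_length must be positive")
        if len(self.position_labels) != self.randomized_length:
            raise ValueError(
                f"{len(self.position_labels)} position labels for "
                f"{self.randomized_length} randomized positions"
            )

    @property
    def n_pams(self) -> int:
        return 4 ** self.randomized_length

    def pams(self) -> list[str]:
        return all_pams(self.randomized_length)

    def site_regex(self) -> re.Pattern[str]:
        """Compiled pattern matching anchor + randomized window + anchor."""
        return re.compile(
            re.escape(self.upstream_anchor)
            + f"([ACGTN]{{{self.randomized_length}}})"
            + re.escape(self.downstream_anchor)
        )


@dataclass(frozen=True)
class AmpliconDesign:
    """Full constant flanks of the library fragment (for simulation).

    ``upstream_constant`` + randomized tetramer + ``downstream_constant`` is
    the complete fragment as sequenced; ``anchor_length`` controls how much of
    each flank the extraction anchors use.
    """

    upstream_constant: str
    downstream_constant: str
    randomized_length: int = 4
    position_labels: tuple[int, ...] = (-5, -6, -7, -8)
    anchor_length: int = 12

    def __post_init__(self) -> None:
        for name, flank in (
            ("upstream_constant", self.upstream_constant),
            ("downstream_constant", self.downstream_constant),
        ):
            if not set(flank) <= DNA_ALPHABET:
                raise ValueError(f"{name} contains non-ACGT characters")
            if len(flank) < self.anchor_length:
                raise ValueError(f"{name} shorter than anchor_length")
        self._validate_anchor_uniqueness()

    @property
    def fragment_length(self) -> int:
        return (
            len(self.upstream_constant)
            + self.randomized_length
            + len(self.downstream_constant)
        )

    def fragment(self, pam: str) -> str:
        """The fragment carrying a given randomized tetramer."""
        if len(pam) != self.randomized_length or not set(pam) <= DNA_ALPHABET:
            raise ValueError(f"invalid PAM {pam!r}")
        return self.upstream_constant + pam + self.downstream_constant

    def library_spec(self) -> PamLibrarySpec:
        return PamLibrarySpec(
            upstream_anchor=self.upstream_constant[-self.anchor_length :],
            downstream_anchor=self.downstream_constant[: self.anchor_length],
            randomized_length=self.randomized_length,
            position_labels=self.position_labels,
        )

    def _validate_anchor_uniqueness(self) -> None:
        # each anchor must occur exactly once in every possible fragment,
        # and never on the opposite strand, or extraction would be ambiguous
        spec_up = self.upstream_constant[-self.anchor_length :]
        spec_down = self.downstream_constant[: self.anchor_length]
        # N-fragment is enough: anchors are in the constant flanks, and a
        # chance hit spanning the tetramer is checked per-PAM at simulation
        probe = self.upstream_constant + "A" * self.randomized_length + self.downstream_constant
        probe_rc = reverse_complement(probe)
        for name, anchor in (("upstream", spec_up), ("downstream", spec_down)):
            if probe.count(anchor) != 1 or probe_rc.count(anchor) != 0:
                raise ValueError(
                    f"{name} anchor {anchor!r} is not unique within the fragment"
                )


# Default 206-nt synthetic fragment.  The 5' constant region comprises a 98-nt
# adapter-side segment, a 58-nt filler, a 22-nt protospacer and the fixed TTTT
# of the PAM cassette (182 nt); the randomized tetramer follows, then a 20-nt
# 3' constant region: 182 + 4 + 20 = 206 nt.
_DEFAULT_UPSTREAM = (
    "GTTTTCGGTGGTCGGCTGACGTGACTGCACACTAGTATGCATTTCTGAGTTAATCAAGATTCTTGAATGT"
    "CTGTAGCCAGACCGGGCTCCTGAAGACTTATCTGGGTACGTAGAATAAGGTAAATAACCTAAGAATAAGC"
    "TTCCACGCTGGGCGTACCGGTCAGCGTCGTTGCCTCCATTTT"
)
_DEFAULT_DOWNSTREAM = "TTGAAATAAATTTTGGGGGG"


def default_design() -> AmpliconDesign:
    """The default 206-nt randomized-PAM amplicon design."""
    return AmpliconDesign(
        upstream_constant=_DEFAULT_UPSTREAM,
        downstream_constant=_DEFAULT_DOWNSTREAM,
    )


def default_library_spec() -> PamLibrarySpec:
    return default_design().library_spec()
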