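"""Synthetic *Neb*-like locus fixture and pseudoexon annotation.

The fixture emulates the exon 54–56 neighbourhood of mouse nebulin in three
allelic forms:

``WT``
    exon 54 — intron — exon 55 (105 bp, in frame) — intron — exon 56.
``dExon55``
    exon 55 deleted; the residual intron harbours a 202 bp cryptic segment
    (pseudoexon) bounded by canonical AG/GT dinucleotides whose translation in
    the frame carried in from exon 54 contains exactly two premature
    termination codons (PTCs).
``Hmz-dExon55``
    the 380 bp window around the pseudoexon replaced by a 58 bp humanized
    intron fragment, so no pseudoexon can be spliced in.

The true cryptic splice-site positions and pseudoexon sequence are not public;
sequences here are synthetic, generated under the constraints above.
Coordinates are 0-based half-open (BED convention) on the + strand throughout;
a junction's ``donor_end`` is the exclusive end of the upstream exonic segment
and ``acceptor_start`` the inclusive start of the downstream one.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Seq import Seq

__all__ = [
    "SpliceJunction",
    "GeneLocus",
    "PseudoexonAnnotation",
    "LocusFixture",
    "build_fixture_locus",
    "annotate_pseudoexon",
    "translate_in_frame",
    "write_locus_fasta",
    "write_locus_bed",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# Fixed segment layout (bp). Only the sequences are randomized per seed, so
# fixture coordinates are identical across seeds.
EXON54_LEN = 120
EXON55_LEN = 105
EXON56_LEN = 90
INTRON54_LEN = 160  # WT intron between exons 54 and 55
INTRON55_LEN = 140  # WT intron between exons 55 and 56
PSEUDOEXON_LEN = 202
PE_UPSTREAM_INTRON = 90   # dExon55: intron part between exon 54 and pseudoexon
PE_DOWNSTREAM_INTRON = 120  # dExon55: intron part between pseudoexon and exon 56
HUMANIZED_DELETION = 380  # window removed around the pseudoexon
HUMANIZED_INSERT = 58     # human intron 54 fragment put in its place
EXPECTED_PTC_COUNT = 2


@dataclass(frozen=True)
class SpliceJunction:
    """A splice junction: exclusive end of the upstream segment, inclusive
    start of the downstream segment, and its supporting read count."""

    donor_end: int
    acceptor_start: int
    read_count: int = 0

    def __post_init__(self) -> None:
        if self.donor_end >= self.acceptor_start:
            raise ValueError(
                f"donor_end ({self.donor_end}) must precede acceptor_start "
                f"({self.acceptor_start})"
            )
        if self.read_count < 0:
            raise ValueError("read_count must be non-negative")


@dataclass
class GeneLocus:
    """Minimal single-gene annotation: sequence plus ordered exons.

    ``reading_frame_entry`` is the number of bases of the current codon already
    consumed when translation enters the first modeled exon (0 means the exon
    starts on a codon boundary).
    """

    name: str
    sequence: str
    exons: list[tuple[str, int, int]]
    reading_frame_entry: int = 0
    pseudoexon: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.reading_frame_entry not in (0, 1, 2):
            raise ValueError("reading_frame_entry must be 0, 1 or 2")
        prev_end = 0
        for _, start, end in self.exons:
            if start < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            if not (0 <= start < end <= len(self.sequence)):
                raise ValueError("exon coordinates outside sequence")
            prev_end = end

    def exon(self, exon_id: str) -> tuple[str, int, int]:
        for e in self.exons:
            if e[0] == exon_id:
                return e
        raise KeyError(f"no exon named {exon_id!r} in locus {self.name!r}")

    def exon_sequence(self, exon_id: str) -> str:
        _, start, end = self.exon(exon_id)
        return self.sequence[start:end]

    def frame_into(self, position: int) -> int:
        """Frame offset at which the first complete codon starts within a
        segment beginning at ``position``, given all exonic sequence spliced
        in upstream of it."""
        consumed = self.reading_frame_entry + sum(
            end - start for _, start, end in self.exons if end <= position
        )
        return (-consumed) % 3


@dataclass(frozen=True)
class PseudoexonAnnotation:
    """Coordinates and coding consequences of an intronic cryptic exon."""

    start: int
    end: int
    length_bp: int
    frame_preserving: bool
    ptc_count: int
    ptc_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.length_bp != self.end - self.start:
            raise ValueError("length_bp inconsistent with coordinates")
        if self.frame_preserving != (self.length_bp % 3 == 0):
            raise ValueError("frame_preserving inconsistent with length_bp")
        if self.ptc_count != len(self.ptc_positions):
            raise ValueError("ptc_count inconsistent with ptc_positions")


@dataclass(frozen=True)
class LocusFixture:
    """One allele of the synthetic locus with its junction-read templates."""

    locus: GeneLocus
    junctions: tuple[SpliceJunction, ...]


def translate_in_frame(seq: str, frame: int) -> str:
    """Translate ``seq`` starting at offset ``frame``; complete codons only.

    Stop codons are rendered ``*``. Trailing 1–2 nt are ignored. Raises
    ``ValueError`` on non-ACGT characters or an invalid frame.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    seq = seq.upper()
    if set(seq) - set("ACGT"):
        raise ValueError(f"non-ACGT characters in sequence: {set(seq) - set('ACGT')}")
    coding = seq[frame:]
    coding = coding[: len(coding) - len(coding) % 3]
    return str(Seq(coding).translate())


def _count_stops(seq: str, frame: int) -> tuple[int, tuple[int, ...]]:
    aa = translate_in_frame(seq, frame)
    positions = tuple(i for i, a in enumerate(aa) if a == "*")
    return len(positions), positions


def _random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _random_orf(rng: random.Random, n: int) -> str:
    """Random sequence free of stop codons in frame 0 (used for exons)."""
    assert n % 3 == 0
    codons = []
    while len(codons) * 3 < n:
        c = _random_dna(rng, 3)
        if c not in STOP_CODONS:
            codons.append(c)
    return "".join(codons)


def _random_intron(rng: random.Random, n: int) -> str:
    """Random intron with canonical GT...AG boundary dinucleotides."""
    if n < 4:
        raise ValueError("intron too short for GT..AG")
    return "GT" + _random_dna(rng, n - 4) + "AG"


def _random_pseudoexon(rng: random.Random, frame: int, n_stops: int = EXPECTED_PTC_COUNT) -> str:
    """Random 202-mer with exactly ``n_stops`` stop codons in ``frame``.

    Rejection sampling; the constraint is mild (expected ~3 stops in 67
    codons), so a handful of draws suffices.
    """
    while True:
        candidate = _random_dna(rng, PSEUDOEXON_LEN)
        count, _ = _count_stops(candidate, frame)
        if count == n_stops:
            return candidate


def build_fixture_locus(seed: int) -> dict[str, LocusFixture]:
    """Build the three allele fixtures (``WT``, ``dExon55``, ``Hmz-dExon55``).

    Segment lengths are fixed, so coordinates are identical for every seed;
    only the sequences vary. Junction read counts are templates proportioned
    after the sequencing result (~94% pseudoexon inclusion in dExon55).
    """
    rng = random.Random(seed)

    exon54 = _random_orf(rng, EXON54_LEN)
    exon55 = _random_orf(rng, EXON55_LEN)
    exon56 = _random_orf(rng, EXON56_LEN)

    # --- WT allele -------------------------------------------------------
    wt_seq = (
        exon54
        + _random_intron(rng, INTRON54_LEN)
        + exon55
        + _random_intron(rng, INTRON55_LEN)
        + exon56
    )
    e54 = ("exon54", 0, EXON54_LEN)
    wt_e55_start = EXON54_LEN + INTRON54_LEN
    wt_e56_start = wt_e55_start + EXON55_LEN + INTRON55_LEN
    wt_locus = GeneLocus(
        name="Neb-like_WT",
        sequence=wt_seq,
        exons=[
            e54,
            ("exon55", wt_e55_start, wt_e55_start + EXON55_LEN),
            ("exon56", wt_e56_start, wt_e56_start + EXON56_LEN),
        ],
    )
    wt_junctions = (
        SpliceJunction(EXON54_LEN, wt_e55_start, 100),
        SpliceJunction(wt_e55_start + EXON55_LEN, wt_e56_start, 100),
    )

    # --- dExon55 allele --------------------------------------------------
    pe_start = EXON54_LEN + PE_UPSTREAM_INTRON
    pe_end = pe_start + PSEUDOEXON_LEN
    de_e56_start = pe_end + PE_DOWNSTREAM_INTRON
    # Frame into the pseudoexon: exon 54 is the only upstream exon.
    pe_frame = (-EXON54_LEN) % 3
    pseudoexon = _random_pseudoexon(rng, pe_frame)
    de_seq = (
        exon54
        + _random_intron(rng, PE_UPSTREAM_INTRON)
        + pseudoexon
        + _random_intron(rng, PE_DOWNSTREAM_INTRON)
        + exon56
    )
    de_locus = GeneLocus(
        name="Neb-like_dExon55",
        sequence=de_seq,
        exons=[e54, ("exon56", de_e56_start, de_e56_start + EXON56_LEN)],
        pseudoexon=(pe_start, pe_end),
    )
    de_junctions = (
        SpliceJunction(EXON54_LEN, pe_start, 94),
        SpliceJunction(pe_end, de_e56_start, 94),
        SpliceJunction(EXON54_LEN, de_e56_start, 6),
    )

    # --- humanized allele ------------------------------------------------
    # Replace a 380 bp window covering the pseudoexon with a 58 bp insert;
    # the window sits strictly inside the intron so GT..AG are preserved.
    de_intron_start = EXON54_LEN
    win_start = de_intron_start + 16
    win_end = win_start + HUMANIZED_DELETION
    assert win_start > de_intron_start + 2 and win_end < de_e56_start - 2
    assert win_start <= pe_start and pe_end <= win_end
    human_insert = _random_dna(rng, HUMANIZED_INSERT)
    hz_seq = de_seq[:win_start] + human_insert + de_seq[win_end:]
    hz_e56_start = de_e56_start - (HUMANIZED_DELETION - HUMANIZED_INSERT)
    hz_locus = GeneLocus(
        name="Neb-like_Hmz-dExon55",
        sequence=hz_seq,
        exons=[e54, ("exon56", hz_e56_start, hz_e56_start + EXON56_LEN)],
    )
    hz_junctions = (SpliceJunction(EXON54_LEN, hz_e56_start, 94),)

    return {
        "WT": LocusFixture(wt_locus, wt_junctions),
        "dExon55": LocusFixture(de_locus, de_junctions),
        "Hmz-dExon55": LocusFixture(hz_locus, hz_junctions),
    }


def annotate_pseudoexon(
    locus: GeneLocus, junctions: list[SpliceJunction] | tuple[SpliceJunction, ...]
) -> PseudoexonAnnotation | None:
    """Locate a cryptic exon implied by junctions into an annotated intron.

    Junctions whose two ends both coincide with annotated exon boundaries are
    ordinary splicing. A pair of junctions (annotated donor → intronic
    acceptor, intronic donor → annotated acceptor) delimits a pseudoexon; the
    included segment is translated in the frame carried in from the upstream
    exons and its stop codons (TAA/TAG/TGA) counted.

    Returns ``None`` when only annotated junctions are present. Raises
    ``ValueError`` for junctions matching no annotated boundary at all or for
    a one-sided/inconsistent cryptic pair.
    """
    donors = {end for _, _, end in locus.exons}
    acceptors = {start for _, start, _ in locus.exons}

    cryptic_starts: list[int] = []
    cryptic_ends: list[int] = []
    for j in junctions:
        donor_known = j.donor_end in donors
        acceptor_known = j.acceptor_start in acceptors
        if donor_known and acceptor_known:
            continue
        if donor_known:
            cryptic_starts.append(j.acceptor_start)
        elif acceptor_known:
            cryptic_ends.append(j.donor_end)
        else:
            raise ValueError(
                f"junction {j.donor_end}->{j.acceptor_start} matches no "
                "annotated exon boundary"
            )

    if not cryptic_starts and not cryptic_ends:
        return None
    if len(cryptic_starts) != 1 or len(cryptic_ends) != 1:
        raise ValueError(
            "cryptic junctions do not delimit a single pseudoexon "
            f"(acceptors at {sorted(cryptic_starts)}, donors at {sorted(cryptic_ends)})"
        )
    start, end = cryptic_starts[0], cryptic_ends[0]
    if start >= end:
        raise ValueError("cryptic acceptor does not precede cryptic donor")
    if not _inside_an_intron(locus, start, end):
        raise ValueError("candidate pseudoexon not strictly inside an intron")

    length = end - start
    frame = locus.frame_into(start)
    ptc_count, ptc_positions = _count_stops(locus.sequence[start:end], frame)
    return PseudoexonAnnotation(
        start=start,
        end=end,
        length_bp=length,
        frame_preserving=(length % 3 == 0),
        ptc_count=ptc_count,
        ptc_positions=ptc_positions,
    )


def _inside_an_intron(locus: GeneLocus, start: int, end: int) -> bool:
    for (_, _, up_end), (_, down_start, _) in zip(locus.exons, locus.exons[1:]):
        if up_end < start and end < down_start:
            return True
    return False


def write_locus_fasta(locus: GeneLocus, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f">{locus.name}\n")
        for i in range(0, len(locus.sequence), 70):
            fh.write(locus.sequence[i : i + 70] + "\n")


def write_locus_bed(locus: GeneLocus, path: str | Path) -> None:
    """Exon features, plus the pseudoexon when the allele has one (BED4)."""
    path = Path(path)
    with path.open("w") as fh:
        for exon_id, start, end in locus.exons:
            fh.write(f"{locus.name}\t{start}\t{end}\t{exon_id}\n")
        if locus.pseudoexon is not None:
            s, e = locus.pseudoexon
            fh.write(f"{locus.name}\t{s}\t{e}\tpseudoexon\n")
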