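"""Splice-junction tables and pseudoexon inclusion (PSI) estimation.

A junction table is a pandas DataFrame with columns
``chrom, donor_end, acceptor_start, count, sample`` — 0-based half-open
coordinates of the spliced-out interval, read support, and a sample id.
Tables are serialized as tab-delimited BED-like files with a one-line header;
the 9-column header-less splice-junction dialect produced by spliced aligners
is also accepted (columns beyond the first four ignored, column 4 read as the
count).

The inclusion fraction ψ of a cryptic segment is estimated from the three
informative junctions: upstream-exon→pseudoexon (J_up), pseudoexon→
downstream-exon (J_down) and the direct exon-skipping junction (J_skip):

    ψ̂ = I / (I + J_skip),   I = (J_up + J_down) / 2  (mean of flanks)

ψ̂ is invariant under uniform count scaling, so per-million normalization does
not affect it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .locus import GeneLocus, PseudoexonAnnotation, SpliceJunction

__all__ = [
    "COLUMNS",
    "InclusionEstimate",
    "junctions_to_table",
    "read_junctions",
    "write_junctions",
    "filter_junctions",
    "estimate_inclusion",
    "simulate_junction_reads",
]

COLUMNS = ["chrom", "donor_end", "acceptor_start", "count", "sample"]


@dataclass(frozen=True)
class InclusionEstimate:
    """PSI point estimate with its supporting junction counts."""

    psi_hat: float
    j_up: float
    j_down: float
    j_skip: float
    n_effective: float  # I + J_skip, the total junction evidence

    def __post_init__(self) -> None:
        if not (0.0 <= self.psi_hat <= 1.0):
            raise ValueError("psi_hat outside [0, 1]")


def junctions_to_table(
    junctions, chrom: str = "locus", sample: str = "template"
) -> pd.DataFrame:
    """Materialize ``SpliceJunction`` objects as a junction table."""
    rows = [
        (chrom, j.donor_end, j.acceptor_start, j.read_count, sample)
        for j in junctions
    ]
    return pd.DataFrame(rows, columns=COLUMNS)


def read_junctions(path: str | Path) -> pd.DataFrame:
    """Read a junction table; header-full 5-column or 9-column dialect.

    The 9-column dialect is detected by column count on the first line; its
    first four columns are taken as chrom/start/end/count and the sample id is
    derived from the file stem.
    """
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().rstrip("\n").split("\t")
    if first[:1] == ["chrom"]:
        df = pd.read_csv(path, sep="\t")
        missing = set(COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"junction table missing columns: {sorted(missing)}")
        df = df[COLUMNS]
    elif len(first) == 9:
        df = pd.read_csv(path, sep="\t", header=None, usecols=range(4),
                         names=COLUMNS[:4])
        df["sample"] = path.stem
    else:
        raise ValueError(
            f"unrecognized junction file format ({len(first)} columns, "
            "no header)"
        )
    df = df.astype({"donor_end": int, "acceptor_start": int, "count": int})
    if (df["count"] < 0).any():
        raise ValueError("negative junction counts")
    dup = df.duplicated(subset=["donor_end", "acceptor_start", "sample"])
    if dup.any():
        raise ValueError("duplicate (donor_end, acceptor_start) within a sample")
    return df.reset_index(drop=True)


def write_junctions(table: pd.DataFrame, path: str | Path) -> None:
    table[COLUMNS].to_csv(path, sep="\t", index=False)


def filter_junctions(table: pd.DataFrame, min_reads: int = 3) -> pd.DataFrame:
    """Drop junctions supported by fewer than ``min_reads`` reads.

    Boundary kept: a junction with exactly ``min_reads`` reads survives.
    Order-preserving and idempotent.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be non-negative")
    return table[table["count"] >= min_reads].reset_index(drop=True)


def _junction_count(table: pd.DataFrame, donor_end: int, acceptor_start: int) -> float:
    sel = (table["donor_end"] == donor_end) & (table["acceptor_start"] == acceptor_start)
    return float(table.loc[sel, "count"].sum())


def estimate_inclusion(
    table: pd.DataFrame,
    annotation: PseudoexonAnnotation,
    exon_up: tuple,
    exon_down: tuple,
    method: str = "mean",
) -> InclusionEstimate:
    """Estimate the pseudoexon inclusion fraction from a junction table.

    ``exon_up``/``exon_down`` are the flanking annotated exons as
    ``(id, start, end)`` tuples (or ``(start, end)``). ``method`` selects the
    inclusion-support summary across the two flanking junctions: ``"mean"``
    (default, equals sum/2) or ``"min"`` (conservative).

    Counts are summed over samples present in the table; use ``groupby`` on
    the sample column for per-sample estimates.
    """
    if method not in ("mean", "min"):
        raise ValueError(f"unknown inclusion method {method!r}")
    up_end = exon_up[-1]
    down_start = exon_down[-2] if len(exon_down) == 3 else exon_down[0]

    j_up = _junction_count(table, up_end, annotation.start)
    j_down = _junction_count(table, annotation.end, down_start)
    j_skip = _junction_count(table, up_end, down_start)

    inclusion = (j_up + j_down) / 2.0 if method == "mean" else float(min(j_up, j_down))
    denom = inclusion + j_skip
    if denom == 0:
        raise ValueError("no informative junction reads (inclusion + skip = 0)")
    return InclusionEstimate(
        psi_hat=inclusion / denom,
        j_up=j_up,
        j_down=j_down,
        j_skip=j_skip,
        n_effective=denom,
    )


def simulate_junction_reads(
    psi: float,
    n_transcripts: int = 10_000,
    depth_per_junction: float = 10_000.0,
    seed: int | None = None,
    annotation: PseudoexonAnnotation | None = None,
    exon_up: tuple | None = None,
    exon_down: tuple | None = None,
    chrom: str = "locus",
    sample: str = "sim",
) -> pd.DataFrame:
    """Simulate junction reads from a two-isoform mixture at inclusion ψ.

    Each of ``n_transcripts`` transcripts carries the pseudoexon with
    probability ``psi``; the realized isoform fractions then set Poisson read
    depths: both flanking junctions at ``depth_per_junction``·(inclusion
    fraction), the skip junction at ``depth_per_junction``·(1 − inclusion
    fraction). Junction coordinates default to the packaged dExon55 fixture
    (fixture coordinates are seed-independent).
    """
    if not (0.0 <= psi <= 1.0):
        raise ValueError("psi must lie in [0, 1]")
    if depth_per_junction <= 0:
        raise ValueError("depth_per_junction must be positive")
    if n_transcripts <= 0:
        raise ValueError("n_transcripts must be positive")

    if annotation is None or exon_up is None or exon_down is None:
        from .locus import build_fixture_locus, annotate_pseudoexon

        fixture = build_fixture_locus(0)["dExon55"]
        annotation = annotate_pseudoexon(fixture.locus, fixture.junctions)
        exon_up = fixture.locus.exon("exon54")
        exon_down = fixture.locus.exon("exon56")

    rng = np.random.default_rng(seed)
    n_inc = rng.binomial(n_transcripts, psi)
    frac = n_inc / n_transcripts
    j_up = int(rng.poisson(depth_per_junction * frac))
    j_down = int(rng.poisson(depth_per_junction * frac))
    j_skip = int(rng.poisson(depth_per_junction * (1.0 - frac)))

    up_end = exon_up[-1]
    down_start = exon_down[-2] if len(exon_down) == 3 else exon_down[0]
    rows = [
        (chrom, up_end, annotation.start, j_up, sample),
        (chrom, annotation.end, down_start, j_down, sample),
        (chrom, up_end, down_start, j_skip, sample),
    ]
    return pd.DataFrame(rows, columns=COLUMNS)
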