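"""Genome, interval and coverage I/O.

All coordinates in this package are 0-based half-open (BED-native).
1-based conventions (GFF, RegulonDB dumps) are converted at the file
boundary, never internally.  Bacterial/archaeal chromosomes are circular
by default; coverage of a fragment spanning the origin wraps around.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomeSeq",
    "IntervalSet",
    "FragmentSet",
    "CoverageTrack",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "select_tss",
    "read_tss_table",
    "coverage",
    "write_bedgraph",
    "gc_content",
]

_VALID_BASES = frozenset("ACGTN")
BED_COLUMNS = ["contig", "start", "end", "name", "score", "strand"]


@dataclass
class GenomeSeq:
    """Named nucleotide sequences with a per-contig circularity flag."""

    contigs: dict[str, str]
    circular: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, seq in self.contigs.items():
            if len(seq) == 0:
                raise ValueError(f"contig {cid!r} has zero length")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"contig {cid!r} contains non-IUPAC characters: {sorted(bad)}"
                )
            self.circular.setdefault(cid, True)

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Subsequence [start, end); wraps across the origin when circular."""
        seq = self.contigs[contig]
        L = len(seq)
        if 0 <= start and end <= L:
            return seq[start:end]
        if not self.circular.get(contig, True):
            raise IndexError(
                f"[{start}, {end}) outside linear contig {contig!r} of length {L}"
            )
        idx = np.arange(start, end) % L
        return "".join(seq[i] for i in idx)


class IntervalSet:
    """Sorted genomic intervals, 0-based half-open, strand in {+,-,.}.

    Thin wrapper over a pandas DataFrame with BED6 columns; construction
    validates and sorts by (contig, start).
    """

    def __init__(self, df: pd.DataFrame, genome: GenomeSeq | None = None):
        df = df.copy()
        for col, default in (("name", "."), ("score", 0.0), ("strand", ".")):
            if col not in df.columns:
                df[col] = default
        df = df[BED_COLUMNS]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        bad = df["start"] >= df["end"]
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            row = df.iloc[i]
            raise ValueError(
                f"empty or inverted interval at record {i}: "
                f"{row.contig} {row.start} {row.end}"
            )
        if (df["start"] < 0).any():
            raise ValueError("negative start coordinate")
        if not df["strand"].isin(["+", "-", "."]).all():
            raise ValueError("strand must be one of +, -, .")
        if genome is not None:
            for contig, sub in df.groupby("contig"):
                if contig not in genome:
                    raise ValueError(f"unknown contig {contig!r}")
                if int(sub["end"].max()) > genome.length(contig):
                    raise ValueError(
                        f"interval exceeds contig {contig!r} length "
                        f"{genome.length(contig)}"
                    )
        self.df = df.sort_values(["contig", "start"], kind="mergesort").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and self.df.equals(other.df)


class FragmentSet(IntervalSet):
    """Protected-fragment intervals: strand-less, with derived lengths in bp.

    Lengths >= 160 are permitted but flagged, matching a short-fragment
    (< 160 bp) sequencing design.
    """

    def __init__(self, df: pd.DataFrame, genome: GenomeSeq | None = None):
        super().__init__(df, genome=genome)
        self.df["strand"] = "."
        n_long = int((self.lengths >= 160).sum())
        if n_long:
            warnings.warn(
                f"{n_long} fragments are >= 160 bp (outside the short-fragment design)"
            )

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()


@dataclass
class CoverageTrack:
    """Per-base fragment coverage, one float vector per contig.

    ``sum(values) == sum of contributing fragment lengths`` whenever the
    track is raw (unnormalized) coverage.
    """

    values: dict[str, np.ndarray]
    size_class: object = None          # length filter applied, if any
    total_fragments: int = 0
    label: str = ""

    def get(self, contig: str) -> np.ndarray:
        return self.values[contig]

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def scaled(self, per: float = 1e6) -> "CoverageTrack":
        """Fragments-per-``per`` scaled copy (library-size normalization)."""
        if self.total_fragments <= 0:
            raise ValueError("cannot scale a track with no recorded fragments")
        f = per / self.total_fragments
        return CoverageTrack(
            {c: v * f for c, v in self.values.items()},
            size_class=self.size_class,
            total_fragments=self.total_fragments,
            label=self.label + "/scaled",
        )


def read_fasta(path) -> GenomeSeq:
    """Read a FASTA file into a :class:`GenomeSeq`.

    Contig ids are the first whitespace-delimited token of each header;
    sequence is upper-cased.  Duplicate ids, empty files and non-IUPAC
    characters are rejected.
    """
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate contig id {rec.id!r}")
        contigs[rec.id] = str(rec.seq).upper()
    if not contigs:
        raise ValueError(f"no FASTA records in {path}")
    return GenomeSeq(contigs)


def write_fasta(genome: GenomeSeq, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for cid, seq in genome.contigs.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path, kind: str = "annotation", genome: GenomeSeq | None = None):
    """Read BED3/BED6 into an :class:`IntervalSet` (or :class:`FragmentSet`).

    ``kind`` selects the semantics: ``"fragments"`` returns a FragmentSet
    (strand dropped), anything else an annotation IntervalSet.  Records
    are validated (start < end, known contig when a genome is supplied)
    and sorted.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    df = df.iloc[:, :6]
    df.columns = BED_COLUMNS[: df.shape[1]]
    cls = FragmentSet if kind == "fragments" else IntervalSet
    try:
        return cls(df, genome=genome)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_bed(intervals: IntervalSet, path) -> None:
    intervals.df.to_csv(path, sep="\t", header=False, index=False)


def read_tss_table(path) -> pd.DataFrame:
    """Read a RegulonDB-style TSS candidate table (TSV).

    Expected columns: broad_id, contig, position (0-based), strand,
    reads, gene.  Comment lines start with '#'.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"broad_id", "contig", "position", "strand", "reads"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing TSS columns {sorted(missing)}")
    if "gene" not in df.columns:
        df["gene"] = "."
    return df


def select_tss(raw: pd.DataFrame) -> pd.DataFrame:
    """Collapse each broad TSS region to a single position.

    The position with the most supporting reads wins; ties go to the
    smallest coordinate.  A broad TSS whose candidates all have zero
    support keeps its leftmost position, with a warning.
    """
    if (raw["reads"] < 0).to_numpy().any():
        raise ValueError("negative read support")
    rows = []
    zero_groups = 0
    for bid, grp in raw.groupby("broad_id", sort=True):
        grp = grp.sort_values("position", kind="mergesort")
        if (grp["reads"] == 0).all():
            zero_groups += 1
            best = grp.iloc[0]
        else:
            # idxmax on a position-sorted frame breaks ties leftmost
            best = grp.loc[grp["reads"].idxmax()]
        rows.append(
            {
                "broad_id": bid,
                "contig": best["contig"],
                "position": int(best["position"]),
                "strand": best["strand"],
                "reads": int(best["reads"]),
                "gene": best.get("gene", "."),
            }
        )
    if zero_groups:
        warnings.warn(f"{zero_groups} broad TSS groups had all-zero read support")
    return pd.DataFrame(rows)


def coverage(
    fragments: FragmentSet,
    genome: GenomeSeq,
    length_filter: tuple[int, int] | None = None,
    label: str = "",
) -> CoverageTrack:
    """Per-base coverage of (optionally length-filtered) fragments.

    Cell x counts the fragments overlapping x.  On circular contigs a
    fragment extending past the end wraps to the start, conserving total
    mass.  Metadata records the filter and the number of contributing
    fragments.
    """
    values = {c: np.zeros(genome.length(c)) for c in genome.contigs}
    df = fragments.df
    if length_filter is not None:
        lo, hi = length_filter
        lens = df["end"] - df["start"]
        df = df[(lens >= lo) & (lens <= hi)]
        if df.empty:
            warnings.warn(f"length filter [{lo}, {hi}] excluded all fragments")
    n_used = 0
    for contig, sub in df.groupby("contig"):
        if contig not in genome:
            raise ValueError(f"fragment on unknown contig {contig!r}")
        L = genome.length(contig)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if (ends > L).any() and not genome.circular.get(contig, True):
            raise ValueError(f"fragment past the end of linear contig {contig!r}")
        # difference-array accumulation, wrap handled by splitting
        diff = np.zeros(L + 1)
        inside = ends <= L
        np.add.at(diff, starts[inside], 1)
        np.add.at(diff, ends[inside], -1)
        w_starts, w_ends = starts[~inside], ends[~inside]
        np.add.at(diff, w_starts, 1)
        diff[L] -= len(w_starts)
        np.add.at(diff, np.zeros(len(w_ends), dtype=np.int64), 1)
        np.add.at(diff, w_ends - L, -1)
        values[contig] = np.cumsum(diff[:-1]).astype(float)
        n_used += len(sub)
    return CoverageTrack(
        values,
        size_class=tuple(length_filter) if length_filter else None,
        total_fragments=n_used,
        label=label,
    )


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Export a coverage track as bedGraph (runs of equal value merged)."""
    with open(path, "w") as fh:
        for contig, v in track.values.items():
            if len(v) == 0:
                continue
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(v)]])
            for s, e in zip(starts, ends):
                fh.write(f"{contig}\t{s}\t{e}\t{v[s]:g}\n")


def gc_content(seq: str) -> float:
    """GC fraction of a sequence (N ignored in the denominator)."""
    n = sum(1 for b in seq if b in "ACGT")
    if n == 0:
        return float("nan")
    return sum(1 for b in seq if b in "GC") / n
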