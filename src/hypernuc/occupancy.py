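"""Empty-vector-normalized occupancy tracks and correlational analyses.

Occupancy is defined per base as

    O(x) = c_strain(x) / (c_EV(x) + 1)

where c_strain is (size-class-resolved) histone-strain coverage and
c_EV is empty-vector coverage pooled across all fragment sizes; the +1
pseudocount keeps zero-coverage regions analyzable.  Dividing by the
matched MNase control cancels sequence-dependent cutting bias and
mappability, leaving protection attributable to histone binding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import (
    CoverageTrack,
    FragmentSet,
    GenomeSeq,
    IntervalSet,
    coverage,
    gc_content,
)

__all__ = [
    "SizeClass",
    "SIZE_CLASSES",
    "assign_size_class",
    "normalize",
    "windowed",
    "replicate_correlation",
    "tss_profile",
    "gene_gc_occupancy",
    "regional_modulation",
    "moving_gc_occupancy",
    "nap_delta",
]


@dataclass(frozen=True)
class SizeClass:
    """Fragment-length bin ``center +- tol`` (tetramer=60 ... decamer=150)."""

    center: int
    tol: int = 5

    @property
    def bounds(self) -> tuple[int, int]:
        return self.center - self.tol, self.center + self.tol

    def admits(self, length: int) -> bool:
        lo, hi = self.bounds
        return lo <= length <= hi


SIZE_CLASSES = tuple(SizeClass(c) for c in (60, 90, 120, 150))


def assign_size_class(length: int, classes=SIZE_CLASSES) -> SizeClass | None:
    """Size class admitting ``length``, or None (classes are disjoint)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    for sc in classes:
        if sc.admits(length):
            return sc
    return None


def normalize(
    strain: CoverageTrack,
    ev: CoverageTrack,
    scale_libraries: bool = False,
) -> CoverageTrack:
    """Empty-vector-normalized occupancy O(x) = c_s(x) / (c_EV(x) + 1).

    With ``scale_libraries`` both tracks are first scaled to
    fragments-per-million, so libraries of different depth are
    comparable; the pseudocount is applied after scaling.
    """
    if set(strain.values) != set(ev.values):
        raise ValueError("strain and EV tracks cover different contigs")
    s, e = strain, ev
    if scale_libraries:
        s, e = strain.scaled(), ev.scaled()
    values = {}
    for contig in s.values:
        cs, ce = s.values[contig], e.values[contig]
        if len(cs) != len(ce):
            raise ValueError(f"contig {contig!r} length mismatch between tracks")
        values[contig] = cs / (ce + 1.0)
    return CoverageTrack(
        values,
        size_class=strain.size_class,
        total_fragments=strain.total_fragments,
        label=f"{strain.label}/norm({ev.label})",
    )


def windowed(
    values: np.ndarray,
    width: int = 60,
    step: int = 30,
    circular: bool = False,
) -> pd.DataFrame:
    """Mean track value in windows of ``width`` bp stepped by ``step`` bp.

    On linear contigs the final partial window is dropped; on circular
    contigs windows wrap across the origin so every start position
    0, step, 2*step, ... below the contig length yields a window.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if width > n:
        raise ValueError(f"window width {width} exceeds track length {n}")
    cum = np.concatenate([[0.0], np.cumsum(np.concatenate([v, v]))])
    if circular:
        starts = np.arange(0, n, step)
    else:
        starts = np.arange(0, n - width + 1, step)
    ends = starts + width
    means = (cum[ends] - cum[starts]) / width
    return pd.DataFrame({"start": starts, "end": ends, "mean": means})


def replicate_correlation(
    a: FragmentSet,
    b: FragmentSet,
    genome: GenomeSeq,
    width: int = 60,
    step: int = 30,
) -> dict:
    """Spearman correlation of windowed coverage between two replicates.

    Each replicate's window coverage is expressed as a proportion of its
    total fragment count before correlating, so depth differences cancel.
    """
    rows_a, rows_b = [], []
    for contig in genome.contigs:
        circ = genome.circular.get(contig, True)
        ca = coverage(a, genome).values[contig]
        cb = coverage(b, genome).values[contig]
        rows_a.append(windowed(ca, width, step, circular=circ)["mean"].to_numpy())
        rows_b.append(windowed(cb, width, step, circular=circ)["mean"].to_numpy())
    wa = np.concatenate(rows_a) / max(len(a), 1)
    wb = np.concatenate(rows_b) / max(len(b), 1)
    if len(wa) < 2:
        raise ValueError("need at least 2 windows")
    if np.ptp(wa) == 0 or np.ptp(wb) == 0:
        warnings.warn("zero-variance window coverage; correlation undefined")
        return {"rho": np.nan, "p_value": np.nan, "n_windows": len(wa)}
    rho, p = stats.spearmanr(wa, wb)
    return {"rho": float(rho), "p_value": float(p), "n_windows": len(wa)}


def tss_profile(
    fragments: FragmentSet,
    tss: pd.DataFrame,
    genome: GenomeSeq,
    D: int = 500,
    size_bins=SIZE_CLASSES,
) -> pd.DataFrame:
    """Mean coverage by (signed distance to TSS) x (fragment size bin).

    Rows are distances in [-D, +D] (negative = upstream, strand-aware:
    minus-strand TSSs are mirrored); columns are size-bin centers.
    """
    if tss.empty:
        warnings.warn("no TSS supplied; empty profile")
        return pd.DataFrame(index=np.arange(-D, D + 1))
    out = {}
    for sc in size_bins:
        track = coverage(fragments, genome, length_filter=sc.bounds)
        profiles = []
        for _, row in tss.iterrows():
            contig = row["contig"]
            if contig not in genome:
                continue
            v = track.values[contig]
            L = len(v)
            pos = int(row["position"])
            idx = np.arange(pos - D, pos + D + 1)
            if genome.circular.get(contig, True):
                prof = v[idx % L]
            else:
                prof = np.full(2 * D + 1, np.nan)
                ok = (idx >= 0) & (idx < L)
                prof[ok] = v[idx[ok]]
            if row.get("strand", "+") == "-":
                prof = prof[::-1]
            profiles.append(prof)
        if not profiles:
            warnings.warn("no TSS in range")
            out[sc.center] = np.full(2 * D + 1, np.nan)
        else:
            out[sc.center] = np.nanmean(np.vstack(profiles), axis=0)
    return pd.DataFrame(out, index=pd.Index(np.arange(-D, D + 1), name="distance"))


def gene_gc_occupancy(
    genome: GenomeSeq,
    genes: IntervalSet,
    track: CoverageTrack,
) -> dict:
    """Per-gene GC fraction and mean normalized occupancy, with Spearman rho."""
    rows = []
    for _, g in genes.df.iterrows():
        if g["end"] - g["start"] <= 0:
            continue
        seq = genome.fetch(g["contig"], int(g["start"]), int(g["end"]))
        v = track.values[g["contig"]][int(g["start"]) : int(g["end"])]
        rows.append(
            {
                "gene": g["name"],
                "contig": g["contig"],
                "start": int(g["start"]),
                "end": int(g["end"]),
                "strand": g["strand"],
                "gc": gc_content(seq),
                "occupancy": float(np.mean(v)),
            }
        )
    table = pd.DataFrame(rows)
    if table.empty or np.ptp(table["occupancy"]) == 0 or np.ptp(table["gc"]) == 0:
        if not table.empty:
            warnings.warn("degenerate GC or occupancy; correlation undefined")
        return {"table": table, "rho": np.nan, "p_value": np.nan}
    rho, p = stats.spearmanr(table["gc"], table["occupancy"])
    return {"table": table, "rho": float(rho), "p_value": float(p)}


def _replichore_rightward(pos: np.ndarray, origin: int, terminus: int, L: int) -> np.ndarray:
    """True where replication proceeds in increasing coordinate.

    Replication runs from the origin toward the terminus on both
    replichores of a circular chromosome.
    """
    if origin <= terminus:
        return (pos >= origin) & (pos < terminus)
    return (pos >= origin) | (pos < terminus)


def regional_modulation(
    gene_table: pd.DataFrame,
    expression: pd.Series | dict,
    origin: int,
    terminus: int,
    genome_length: int,
    window: int = 200,
    step: int | None = None,
) -> dict:
    """Regional transcription vs the local GC-occupancy coupling.

    Genes (ordered by chromosomal position) are split by whether
    transcription is codirectional with replication, then grouped into
    ``window``-gene blocks (non-overlapping unless ``step`` is given).
    Per block: median expression and the within-block Spearman rho of
    gene GC vs gene occupancy.  The headline statistic is the
    across-block Spearman rho between the two, per stratum and pooled.
    """
    tab = gene_table.copy()
    expr = pd.Series(expression)
    tab["expression"] = tab["gene"].map(expr)
    tab = tab.dropna(subset=["expression"]).sort_values("start").reset_index(drop=True)
    mid = ((tab["start"] + tab["end"]) // 2).to_numpy()
    rightward = _replichore_rightward(mid, origin, terminus, genome_length)
    tab["codirectional"] = np.where(
        rightward, tab["strand"] == "+", tab["strand"] == "-"
    )
    step = step or window
    windows = []
    for stratum, sub in tab.groupby("codirectional"):
        sub = sub.reset_index(drop=True)
        for w0 in range(0, len(sub) - window + 1, step):
            blk = sub.iloc[w0 : w0 + window]
            if np.ptp(blk["gc"]) == 0 or np.ptp(blk["occupancy"]) == 0:
                rho = np.nan
            else:
                rho, _ = stats.spearmanr(blk["gc"], blk["occupancy"])
            windows.append(
                {
                    "codirectional": bool(stratum),
                    "median_expression": float(blk["expression"].median()),
                    "gc_occ_rho": float(rho),
                    "n_genes": len(blk),
                    "mid_position": float(blk["start"].median()),
                }
            )
    wt = pd.DataFrame(windows)
    result = {"windows": wt, "gene_table": tab}
    if len(wt) >= 2 and wt["gc_occ_rho"].notna().sum() >= 2:
        ok = wt["gc_occ_rho"].notna()
        rho, p = stats.spearmanr(wt.loc[ok, "median_expression"], wt.loc[ok, "gc_occ_rho"])
        result["rho"], result["p_value"] = float(rho), float(p)
    else:
        result["rho"], result["p_value"] = np.nan, np.nan
    return result


def moving_gc_occupancy(
    gene_table: pd.DataFrame,
    span: int = 500,
    step: int = 20,
) -> pd.DataFrame:
    """Positional profile of the GC-occupancy correlation.

    Spearman rho of gene GC vs gene occupancy over ``span`` neighbouring
    genes, advanced ``step`` genes at a time; anchored at the median
    coordinate of each window.  The span shrinks (with a warning) when
    fewer than ``span`` genes are available.
    """
    tab = gene_table.sort_values("start").reset_index(drop=True)
    n = len(tab)
    if n < span:
        warnings.warn(f"only {n} genes; shrinking span from {span}")
        span = n
    rows = []
    for w0 in range(0, n - span + 1, step):
        blk = tab.iloc[w0 : w0 + span]
        if np.ptp(blk["gc"]) == 0 or np.ptp(blk["occupancy"]) == 0:
            rho = np.nan
        else:
            rho, _ = stats.spearmanr(blk["gc"], blk["occupancy"])
        rows.append(
            {
                "window_index": w0 // step,
                "mid_position": float(blk["start"].median()),
                "rho": float(rho),
                "n_genes": span,
            }
        )
    return pd.DataFrame(rows)


def nap_delta(track: CoverageTrack, bound: IntervalSet) -> dict:
    """Occupancy difference between NAP-bound regions and downstream gaps.

    For each bound region, Delta = mean O(bound) - mean O(nearest
    unbound region immediately downstream), downstream meaning
    increasing coordinate.  The last bound region on a linear contig
    (no downstream complement) is skipped and counted.  Summary: two-
    sided Wilcoxon signed-rank over the Deltas.
    """
    rows = []
    skipped = 0
    for contig, sub in bound.df.groupby("contig"):
        v = track.values[contig]
        L = len(v)
        sub = sub.sort_values("start").reset_index(drop=True)
        for i, r in sub.iterrows():
            gap_start = int(r["end"])
            if i + 1 < len(sub):
                gap_end = int(sub.iloc[i + 1]["start"])
            else:
                gap_end = L
            if gap_end <= gap_start:
                skipped += 1
                continue
            if gap_start >= L:
                skipped += 1
                continue
            delta = float(
                np.mean(v[int(r["start"]) : int(r["end"])])
                - np.mean(v[gap_start:gap_end])
            )
            rows.append(
                {
                    "contig": contig,
                    "start": int(r["start"]),
                    "end": int(r["end"]),
                    "name": r["name"],
                    "delta": delta,
                }
            )
    table = pd.DataFrame(rows, columns=["contig", "start", "end", "name", "delta"])
    out = {"table": table, "n_skipped": skipped}
    deltas = table["delta"].to_numpy() if not table.empty else np.array([])
    if len(deltas) and np.any(deltas != 0):
        stat, p = stats.wilcoxon(deltas)
        out["statistic"], out["p_value"] = float(stat), float(p)
    else:
        if len(deltas):
            warnings.warn("all occupancy deltas are zero; test undefined")
        out["statistic"], out["p_value"] = np.nan, 1.0 if len(deltas) else np.nan
    return out
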