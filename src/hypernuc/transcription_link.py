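"""Joining histone occupancy to differential-expression tables.

Genes responding in the same direction in both the binding and the
non-binding (DNA-binding-deficient histone) comparison are excluded:
coincident changes reflect systemic responses to heterologous
expression, not occupancy.  Remaining genes are grouped by the binding
comparison (up / down / unchanged at adjusted p < alpha) and group
occupancy is compared across window types — the TSS base itself, a
TSS +- 25 bp window, the annotated promoter, the gene body, and a 51 bp
control window centered on the start codon — for each fragment size
class.  A transcriptome compendium is screened by dot-product
similarity between differential-expression vectors.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import CoverageTrack, GenomeSeq, IntervalSet

__all__ = [
    "exclusion_filter",
    "window_occupancy",
    "compendium_similarity",
    "direction_split",
]


def exclusion_filter(
    de_binding: pd.DataFrame,
    de_nonbinding: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Group genes by the binding comparison after the exclusion rule.

    A gene significantly (padj < alpha) up-regulated in both
    comparisons, or down-regulated in both, is excluded.  Remaining
    genes are "up" / "down" when significant in the binding comparison,
    else "unchanged".  Returns the binding table plus ``excluded`` and
    ``group`` columns; the operation is idempotent.
    """
    b = de_binding.set_index("gene")
    nb = de_nonbinding.set_index("gene")
    shared = b.index.intersection(nb.index)
    if len(shared) == 0:
        raise ValueError("no shared genes between the two comparisons")
    b = b.loc[shared]
    nb = nb.loc[shared]
    sig_b = b["padj"] < alpha
    sig_nb = nb["padj"] < alpha
    same_dir = np.sign(b["log2fc"]) == np.sign(nb["log2fc"])
    excluded = (sig_b & sig_nb & same_dir).to_numpy()
    group = np.where(
        excluded,
        "excluded",
        np.where(
            sig_b & (b["log2fc"] > 0),
            "up",
            np.where(sig_b & (b["log2fc"] < 0), "down", "unchanged"),
        ),
    )
    out = b.reset_index()
    out["excluded"] = excluded
    out["group"] = group
    return out


def _gene_windows(
    genes: IntervalSet,
    tss: pd.DataFrame,
    promoters: IntervalSet | None,
    half: int = 25,
) -> dict[str, pd.DataFrame]:
    """Per-gene analysis windows, all as (contig, start, end) frames.

    Window types: tss_point, tss_pm25, promoter, gene_body, and the
    51 bp start-codon control (the first transcribed codon for genes
    without a separate CDS annotation is taken as the gene 5' end plus
    any UTR implied by the TSS offset; here the control window is
    centered on the annotated gene start on the coding strand).
    """
    g = genes.df.set_index("name")
    t = tss.set_index("gene")
    windows: dict[str, list] = {k: [] for k in
                                ["tss_point", "tss_pm25", "promoter",
                                 "gene_body", "start_codon"]}
    prom = promoters.df.set_index("name") if promoters is not None else None
    for gene in g.index:
        row = g.loc[gene]
        if gene in t.index:
            p = int(t.loc[gene, "position"])
            windows["tss_point"].append((gene, row["contig"], p, p + 1))
            windows["tss_pm25"].append((gene, row["contig"], p - half, p + half + 1))
        windows["gene_body"].append((gene, row["contig"], row["start"], row["end"]))
        codon = int(row["start"]) if row["strand"] == "+" else int(row["end"]) - 1
        windows["start_codon"].append(
            (gene, row["contig"], codon - half, codon + half + 1)
        )
        if prom is not None and gene in prom.index:
            pr = prom.loc[gene]
            windows["promoter"].append(
                (gene, pr["contig"], int(pr["start"]), int(pr["end"]))
            )
    return {
        k: pd.DataFrame(v, columns=["gene", "contig", "start", "end"])
        for k, v in windows.items() if v
    }


def _mean_in_windows(track: CoverageTrack, win: pd.DataFrame) -> pd.Series:
    vals = {}
    for _, r in win.iterrows():
        v = track.values[r["contig"]]
        L = len(v)
        idx = np.arange(int(r["start"]), int(r["end"])) % L
        vals[r["gene"]] = float(v[idx].mean())
    return pd.Series(vals)


def window_occupancy(
    groups: pd.DataFrame,
    tracks: dict[str, CoverageTrack],
    tss: pd.DataFrame,
    genes: IntervalSet,
    promoters: IntervalSet | None = None,
    half: int = 25,
    min_group: int = 3,
) -> dict:
    """Group occupancy per window type per size class, with rank tests.

    ``tracks`` maps size-class labels (e.g. "60", "90", "pooled",
    "90plus") to normalized tracks sharing one EV denominator.  For
    every (window type, class) cell the down- and up-group occupancy
    distributions are compared with a two-sided Mann-Whitney U test
    (suppressed when either group has < ``min_group`` genes).

    Returns {"per_gene": long table, "tests": test table}.
    """
    wins = _gene_windows(genes, tss, promoters, half=half)
    grp = groups.loc[~groups["excluded"], ["gene", "group"]].set_index("gene")["group"]
    per_gene_rows, test_rows = [], []
    for cls, track in tracks.items():
        for wtype, win in wins.items():
            occ = _mean_in_windows(track, win)
            occ = occ[occ.index.isin(grp.index)]
            g = grp.loc[occ.index]
            for gene, val in occ.items():
                per_gene_rows.append(
                    {"gene": gene, "size_class": cls, "window": wtype,
                     "occupancy": val, "group": g.loc[gene]}
                )
            down = occ[g == "down"]
            up = occ[g == "up"]
            if len(down) >= min_group and len(up) >= min_group:
                stat, p = stats.mannwhitneyu(down, up, alternative="two-sided")
                test_rows.append(
                    {"size_class": cls, "window": wtype,
                     "n_down": len(down), "n_up": len(up),
                     "median_down": float(down.median()),
                     "median_up": float(up.median()),
                     "U": float(stat), "p_value": float(p)}
                )
            else:
                test_rows.append(
                    {"size_class": cls, "window": wtype,
                     "n_down": len(down), "n_up": len(up),
                     "median_down": float(down.median()) if len(down) else np.nan,
                     "median_up": float(up.median()) if len(up) else np.nan,
                     "U": np.nan, "p_value": np.nan}
                )
    return {
        "per_gene": pd.DataFrame(per_gene_rows),
        "tests": pd.DataFrame(test_rows),
    }


def compendium_similarity(
    de: pd.DataFrame,
    compendium: pd.DataFrame,
    min_shared: int = 1,
    split_directions: bool = False,
) -> pd.DataFrame:
    """Dot-product similarity of a DE vector against a compendium.

    For each comparison c, s_c = sum over shared genes of
    d_g * v_{g,c}; comparisons with fewer than ``min_shared`` shared
    genes are skipped.  Raw dot products are reported (no
    standardization) alongside a Spearman rho of the paired vectors and
    the shared-gene count; with ``split_directions`` the up- and
    down-restricted similarities of the DE vector are added.
    Sorted descending by similarity.
    """
    d = de.set_index("gene")["log2fc"]
    rows = []
    up, down = direction_split(de) if split_directions else (None, None)
    for col in compendium.columns:
        v = compendium[col].dropna()
        shared = d.index.intersection(v.index)
        if len(shared) < min_shared:
            warnings.warn(f"comparison {col!r} skipped: {len(shared)} shared genes")
            continue
        dv, vv = d.loc[shared], v.loc[shared]
        row = {
            "comparison": col,
            "similarity": float(dv @ vv),
            "n_shared": len(shared),
            "spearman_rho": float(stats.spearmanr(dv, vv)[0])
            if len(shared) > 2 and np.ptp(dv) > 0 and np.ptp(vv) > 0
            else np.nan,
        }
        if split_directions:
            row["similarity_up"] = float(up.loc[shared] @ vv)
            row["similarity_down"] = float(down.loc[shared] @ vv)
        rows.append(row)
    out = pd.DataFrame(rows).sort_values(
        "similarity", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def direction_split(de: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Split a DE vector into up (d > 0) and down (d < 0) sub-vectors.

    Entries outside each direction are zeroed, so up + down equals the
    original vector and dot products decompose additively.
    """
    d = de.set_index("gene")["log2fc"]
    up = d.where(d > 0, 0.0)
    down = d.where(d < 0, 0.0)
    return up, down
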