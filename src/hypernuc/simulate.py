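"""Synthetic data generator emulating histone chromatinization of a bacterium.

The generator plants every structure the analysis pipeline is meant to
detect: an AT-rich-promoter genome, GC-preferring oligomeric particle
assembly with AT-flank-inhibited dimer extension, MNase digestion with
end jitter and AT cut bias (yielding the 60/90/120/150 bp ladder), a
depth-matched empty-vector control with the same cut bias but no
footprint structure, occupancy-coupled differential expression with a
shared systemic component, and a transcriptome compendium containing
one comparison correlated with the planted response.

Every stage is deterministic given its seed; stage seeds are derived
from one global seed by hashing the stage name, so changing one stage's
seed perturbs only that stage.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_io import FragmentSet, GenomeSeq, IntervalSet

__all__ = [
    "SimConfig",
    "stage_seed",
    "simulate_genome",
    "simulate_placements",
    "true_occupancy_track",
    "tss_true_occupancy",
    "simulate_digest",
    "simulate_library",
    "simulate_ev",
    "simulate_nap_regions",
    "simulate_expression",
]


@dataclass
class SimConfig:
    """Free parameters of the simulator (units: bp unless noted).

    Defaults are desk-scale: a 200 kb circular chromosome, 100 genes,
    a visible oligomer ladder and detectable planted effects.
    """

    # genome
    length: int = 200_000
    contig: str = "chr"
    gc_background: float = 0.5        # g0
    gc_promoter: float = 0.3          # g_p < g0 (AT-rich promoters)
    n_genes: int = 100
    gene_length: int = 1_000
    promoter_width: int = 100
    utr_length: int = 60              # TSS to start codon distance
    # particle assembly
    beta_gc: float = 16.0             # GC weight in nucleation odds
    density: float = 8.0              # particles per kb
    tetramer_footprint: int = 60      # f0
    dimer_step: int = 30              # s
    r_max: int = 4
    p_ext: float = 0.9                # base extension probability p0
    alpha_at: float = 0.8             # AT-flank extension penalty
    # digestion
    sigma_end: float = 2.0            # fragment-end jitter sd
    w_at: float = 0.7                 # AT cut-bias strength
    mu_frags: float = 20.0            # fragments per particle (Poisson mean)
    min_fragment: int = 20
    n_cells: int = 300                # independent configurations per library
    library_fragments: int = 400_000  # default population-library depth
    # empty vector library
    ev_fragments: int | None = None   # default: depth-matched to the strain
    ev_length_shape: float = 3.0      # Gamma shape of EV lengths
    ev_length_scale: float = 20.0     # Gamma scale (lengths = 20 + Gamma)
    # expression coupling
    gamma: float = 1.0                # repression per sd of TSS occupancy
    lfc_noise_sd: float = 0.3
    systemic_fraction: float = 0.1    # genes with a shared systemic shift
    systemic_sd: float = 2.0
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.0
    n_replicates: int = 5
    phi: float = 0.2                  # negative-binomial dispersion
    # compendium
    n_comparisons: int = 50
    planted_rho: float = 0.5
    # NAP-like regions
    n_nap_regions: int = 40
    nap_region_width: int = 500
    # seeds
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.gc_promoter < self.gc_background < 1):
            raise ValueError("require 0 < promoter GC < background GC < 1")
        if self.dimer_step * (self.r_max - 1) + self.tetramer_footprint > 160:
            raise ValueError("largest footprint exceeds the <160 bp design")
        for name in ("p_ext", "alpha_at", "w_at", "systemic_fraction", "planted_rho"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.gamma < 0:
            raise ValueError("gamma < 0: sign convention is repression (gamma >= 0)")
        unit = self.gene_length + self.promoter_width + self.utr_length
        if self.n_genes * unit > self.length:
            raise ValueError("genes x (promoter + UTR + CDS length) exceeds genome length")

    def expected_particles(self) -> int:
        return int(round(self.density * self.length / 1000))

    def to_dict(self) -> dict:
        return asdict(self)


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed by hashing the stage name."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def _gc_indicator(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return ((arr == ord("G")) | (arr == ord("C"))).astype(float)


def _at_indicator(seq: str) -> np.ndarray:
    return 1.0 - _gc_indicator(seq)


def simulate_genome(config: SimConfig, seed: int | None = None):
    """Random genome with AT-rich promoters and annotated genes/TSSs.

    Bases are drawn independently with per-region GC (``gc_promoter``
    inside promoters, ``gc_background`` elsewhere).  Each gene is a
    CDS interval (as in standard bacterial annotation) preceded, in
    transcription direction, by a ``utr_length`` bp 5' UTR and the
    AT-rich promoter; the TSS sits at the promoter's 3' edge, so the
    start codon lies ``utr_length`` bp downstream of the TSS.

    Returns (genome, genes, promoters, tss_table); ``genes`` holds the
    CDS intervals.
    """
    config.validate()
    rng = np.random.default_rng(
        stage_seed(config.seed, "genome") if seed is None else seed
    )
    L, n = config.length, config.n_genes
    unit = config.gene_length + config.promoter_width + config.utr_length
    slack = L - n * unit
    gaps = np.sort(rng.integers(0, slack + 1, size=n))
    unit_starts = gaps + np.arange(n) * unit
    strands = rng.choice(["+", "-"], size=n)
    gc = np.full(L, config.gc_background)
    genes, promoters, tss_rows = [], [], []
    for i, (u, strand) in enumerate(zip(unit_starts, strands)):
        name = f"gene_{i:04d}"
        if strand == "+":
            prom = (u, u + config.promoter_width)
            gene = (u + config.promoter_width + config.utr_length, u + unit)
            tss_pos = u + config.promoter_width
        else:
            gene = (u, u + config.gene_length)
            prom = (u + unit - config.promoter_width, u + unit)
            tss_pos = prom[0] - 1
        gc[prom[0] : prom[1]] = config.gc_promoter
        genes.append(
            {"contig": config.contig, "start": gene[0], "end": gene[1],
             "name": name, "score": 0.0, "strand": strand}
        )
        promoters.append(
            {"contig": config.contig, "start": prom[0], "end": prom[1],
             "name": name, "score": 0.0, "strand": strand}
        )
        tss_rows.append(
            {"broad_id": f"btss_{i:04d}", "contig": config.contig,
             "position": tss_pos, "strand": strand,
             "reads": int(rng.poisson(50)) + 1, "gene": name}
        )
    is_gc = rng.random(L) < gc
    strong = rng.random(L) < 0.5  # G vs C, A vs T
    bases = np.where(is_gc, np.where(strong, "G", "C"), np.where(strong, "A", "T"))
    genome = GenomeSeq({config.contig: "".join(bases)}, {config.contig: True})
    return (
        genome,
        IntervalSet(pd.DataFrame(genes), genome=genome),
        IntervalSet(pd.DataFrame(promoters), genome=genome),
        pd.DataFrame(tss_rows),
    )


def simulate_placements(genome: GenomeSeq, config: SimConfig, seed: int | None = None):
    """Place oligomeric particles with GC-weighted nucleation.

    Tetramer nucleation centers are sampled with probability
    proportional to exp(beta_gc * GC61), rejecting overlaps, until the
    target density.  Each particle grows as it assembles: immediately
    after nucleating it attempts up to r_max - 1 dimer extensions,
    choosing a side uniformly each time and succeeding with probability
    p_ext * (1 - alpha_at * AT_flank) where AT_flank is the AT fraction
    of the adjacent ``dimer_step`` bp.  The first failure (Bernoulli or
    collision with an existing particle) is permanent.  Interleaving
    nucleation and extension lets early particles reach higher oligomer
    ranks before the genome crowds, reproducing a hexamer-and-larger-
    dominated ladder at high particle density; extending only after all
    tetramers are placed would freeze nearly every particle at rank 1.

    Returns (placements DataFrame with contig/start/end/rank,
    per-base true-occupancy array).
    """
    config.validate()
    rng = np.random.default_rng(
        stage_seed(config.seed, "placements") if seed is None else seed
    )
    contig = config.contig if config.contig in genome else next(iter(genome.contigs))
    seq = genome.contigs[contig]
    L = len(seq)
    gc = _gc_indicator(seq)
    # GC fraction of the 61 bp window centered at each position (circular)
    kern = np.ones(61) / 61
    pad = np.concatenate([gc[-30:], gc, gc[:30]])
    gc61 = np.convolve(pad, kern, mode="valid")
    logw = config.beta_gc * gc61
    w = np.exp(logw - logw.max())
    f0, s, r_max = config.tetramer_footprint, config.dimer_step, config.r_max
    margin = f0 // 2 + s * (r_max - 1)
    w[:margin] = 0.0
    w[L - margin :] = 0.0
    w /= w.sum()
    n_target = config.expected_particles()
    occupied = np.zeros(L, dtype=bool)
    at = _at_indicator(seq)
    records = []
    attempts, max_attempts = 0, 200 * n_target
    while len(records) < n_target and attempts < max_attempts:
        batch = rng.choice(L, size=n_target, p=w)
        for c in batch:
            attempts += 1
            a, b = c - f0 // 2, c - f0 // 2 + f0
            if occupied[a:b].any():
                continue
            occupied[a:b] = True
            rank = 1
            for _ in range(r_max - 1):
                left = rng.random() < 0.5
                if left:
                    fa, fb = a - s, a
                else:
                    fa, fb = b, b + s
                if fa < 0 or fb > L:
                    break
                at_flank = float(at[fa:fb].mean())
                if rng.random() >= config.p_ext * (1 - config.alpha_at * at_flank):
                    break
                if occupied[fa:fb].any():
                    break  # collision: permanent failure
                occupied[fa:fb] = True
                a, b = (fa, b) if left else (a, fb)
                rank += 1
            records.append({"contig": contig, "start": a, "end": b, "rank": rank})
            if len(records) == n_target:
                break
    if len(records) < n_target:
        warnings.warn(
            f"target density unattainable: placed {len(records)} of {n_target}"
        )
    placements = (
        pd.DataFrame(records).sort_values("start").reset_index(drop=True)
    )
    occ = np.zeros(L)
    for _, r in placements.iterrows():
        occ[r["start"] : r["end"]] = 1.0
    return placements, occ


def true_occupancy_track(placements: pd.DataFrame, length: int) -> np.ndarray:
    """Per-base protected indicator implied by a placement set."""
    occ = np.zeros(length)
    for _, r in placements.iterrows():
        occ[r["start"] : r["end"]] = 1.0
    return occ


def tss_true_occupancy(
    occ: np.ndarray, tss: pd.DataFrame, window: int = 25
) -> pd.Series:
    """Mean true occupancy in TSS +- window, indexed by gene."""
    L = len(occ)
    vals = {}
    for _, row in tss.iterrows():
        p = int(row["position"])
        idx = np.arange(p - window, p + window + 1) % L
        vals[row["gene"]] = float(occ[idx].mean())
    return pd.Series(vals)


def _snap_to_at(
    coords: np.ndarray,
    is_at: np.ndarray,
    snap_mask: np.ndarray,
    shift: int,
    max_offset: int = 4,
) -> np.ndarray:
    """Snap cut coordinates to the nearest position with an A/T flanking base.

    ``shift`` selects which base flanks the cut (-1 for fragment starts,
    0 for exclusive ends).  Coordinates not in ``snap_mask``, or with no
    A/T within ``max_offset`` bp, are left unchanged.
    """
    L = len(is_at)
    offsets = np.array(
        [0] + [v for d in range(1, max_offset + 1) for v in (d, -d)]
    )
    cand = (coords[:, None] + offsets[None, :] + shift) % L
    good = is_at[cand] > 0
    first = np.argmax(good, axis=1)
    found = good[np.arange(len(coords)), first]
    snapped = coords + np.where(found, offsets[first], 0)
    return np.where(snap_mask, snapped, coords)


def simulate_digest(
    placements: pd.DataFrame,
    genome: GenomeSeq,
    config: SimConfig,
    seed: int | None = None,
    n_fragments: int | None = None,
) -> FragmentSet:
    """MNase digestion of placed particles.

    Each particle emits Poisson(mu) fragments spanning its protected
    interval; both ends are independently jittered by rounded
    Normal(0, sigma) and, with probability ``w_at``, snapped to the
    nearest cut site flanked by A/T.  Lengths are clipped to
    >= ``min_fragment``.  ``n_fragments`` rescales mu so the expected
    total fragment count matches.
    """
    config.validate()
    rng = np.random.default_rng(
        stage_seed(config.seed, "digest") if seed is None else seed
    )
    contig = placements["contig"].iloc[0]
    seq = genome.contigs[contig]
    L = len(seq)
    mu = config.mu_frags
    if n_fragments is not None:
        mu = n_fragments / max(len(placements), 1)
    counts = rng.poisson(mu, size=len(placements))
    starts = np.repeat(placements["start"].to_numpy(), counts)
    ends = np.repeat(placements["end"].to_numpy(), counts)
    n = len(starts)
    if config.sigma_end > 0:
        starts = starts + np.rint(rng.normal(0, config.sigma_end, n)).astype(int)
        ends = ends + np.rint(rng.normal(0, config.sigma_end, n)).astype(int)
    if config.w_at > 0:
        is_at = _at_indicator(seq)
        starts = _snap_to_at(starts, is_at, rng.random(n) < config.w_at, shift=-1)
        ends = _snap_to_at(ends, is_at, rng.random(n) < config.w_at, shift=0)
    starts = np.clip(starts, 0, L - config.min_fragment)
    ends = np.clip(ends, starts + config.min_fragment, L)
    return FragmentSet(
        pd.DataFrame({"contig": contig, "start": starts, "end": ends}),
        genome=genome,
    )


def simulate_library(
    genome: GenomeSeq,
    config: SimConfig,
    seed: int | None = None,
    n_fragments: int | None = None,
) -> FragmentSet:
    """Population-level digest: fragments pooled over many cells.

    A sequencing library samples chromatin from a large population in
    which every cell carries its own particle configuration; per-base
    coverage therefore estimates the ensemble occupancy probability, not
    one quenched configuration.  This pools :func:`simulate_digest`
    output over ``n_cells`` independent placement configurations, each
    contributing mu / n_cells fragments per particle on average (total
    depth matches a single-configuration digest).

    Use :func:`simulate_digest` on one placement set when the analysis
    needs a ground-truth configuration (e.g. footprint recovery).
    """
    config.validate()
    base = stage_seed(config.seed, "library") if seed is None else seed
    if n_fragments is None:
        n_fragments = config.library_fragments
    n_per_cell = n_fragments / config.n_cells
    parts = []
    for k in range(config.n_cells):
        pl, _ = simulate_placements(genome, config, seed=stage_seed(base, f"cell{k}"))
        mu_cell = n_per_cell / max(len(pl), 1)
        cell_cfg = SimConfig(**{**config.to_dict(), "mu_frags": mu_cell})
        frags = simulate_digest(
            pl, genome, cell_cfg, seed=stage_seed(base, f"digest{k}")
        )
        parts.append(frags.df)
    df = pd.concat(parts, ignore_index=True)
    return FragmentSet(
        df.sort_values(["contig", "start"]).reset_index(drop=True), genome=genome
    )


def simulate_ev(
    genome: GenomeSeq,
    config: SimConfig,
    seed: int | None = None,
    n_fragments: int | None = None,
) -> FragmentSet:
    """Empty-vector control digest: cut bias without footprint structure.

    Fragment lengths follow a smooth 20 + Gamma(shape, scale)
    distribution clipped to [min_fragment, 160] (no 30 bp ladder);
    start positions are drawn with weight (1 - w_at) + w_at * AT(x),
    reproducing the nuclease's AT preference.
    """
    config.validate()
    rng = np.random.default_rng(
        stage_seed(config.seed, "ev") if seed is None else seed
    )
    contig = config.contig if config.contig in genome else next(iter(genome.contigs))
    seq = genome.contigs[contig]
    L = len(seq)
    if n_fragments is None:
        n_fragments = config.ev_fragments
    if n_fragments is None:
        n_fragments = config.library_fragments  # depth-matched control
    # redraw out-of-range lengths rather than clipping (clipping would
    # pile mass at 160 and fake a peak at the design boundary)
    lengths = np.full(n_fragments, -1, dtype=int)
    todo = np.arange(n_fragments)
    while len(todo):
        draw = config.min_fragment + rng.gamma(
            config.ev_length_shape, config.ev_length_scale, len(todo)
        )
        draw = np.rint(draw).astype(int)
        ok = draw < 160
        lengths[todo[ok]] = draw[ok]
        todo = todo[~ok]
    weights = (1 - config.w_at) + config.w_at * _at_indicator(seq)
    weights /= weights.sum()
    starts = rng.choice(L, size=n_fragments, p=weights)
    ends = np.minimum(starts + lengths, L)
    starts = np.minimum(starts, ends - config.min_fragment)
    return FragmentSet(
        pd.DataFrame({"contig": contig, "start": starts, "end": ends}),
        genome=genome,
    )


def simulate_nap_regions(
    genome: GenomeSeq, config: SimConfig, seed: int | None = None
) -> IntervalSet:
    """Non-overlapping NAP-like bound regions (for the delta-occupancy analysis)."""
    rng = np.random.default_rng(
        stage_seed(config.seed, "nap") if seed is None else seed
    )
    contig = config.contig if config.contig in genome else next(iter(genome.contigs))
    L = genome.length(contig)
    w = config.nap_region_width
    n = config.n_nap_regions
    slack = L - n * (2 * w)
    if slack < 0:
        raise ValueError("too many NAP regions for the genome length")
    gaps = np.sort(rng.integers(0, slack + 1, size=n))
    starts = gaps + np.arange(n) * 2 * w + w // 2
    df = pd.DataFrame(
        {"contig": contig, "start": starts, "end": starts + w,
         "name": [f"nap_{i:03d}" for i in range(n)]}
    )
    return IntervalSet(df, genome=genome)


def simulate_expression(
    tss_occupancy: pd.Series,
    config: SimConfig,
    seed: int | None = None,
) -> dict:
    """Occupancy-coupled differential expression plus a compendium.

    The binding strain's true log2 fold change is
    -gamma * standardized(O_TSS) plus, for a random ``systemic_fraction``
    of genes, a systemic shift shared with the non-binding strain
    (exercising the exclusion rule), plus Normal noise.  Replicate
    counts are negative-binomial; DE estimates are log2 ratios of
    replicate means with BH-adjusted two-sample t p-values on log
    counts.  The compendium holds ``n_comparisons`` random vectors plus
    one (named ``comp_planted``) correlated ~``planted_rho`` with the
    binding-strain estimate.

    Returns dict with de_binding, de_nonbinding, counts, compendium,
    true_lfc, systemic_genes, planted_column.
    """
    config.validate()
    rng = np.random.default_rng(
        stage_seed(config.seed, "expression") if seed is None else seed
    )
    genes = list(tss_occupancy.index)
    n = len(genes)
    o = tss_occupancy.to_numpy(dtype=float)
    z = (o - o.mean()) / (o.std() if o.std() > 0 else 1.0)
    systemic = np.zeros(n)
    sys_idx = rng.choice(n, size=int(round(config.systemic_fraction * n)), replace=False)
    systemic[sys_idx] = rng.normal(0, config.systemic_sd, len(sys_idx))
    lfc_bind = -config.gamma * z + systemic + rng.normal(0, config.lfc_noise_sd, n)
    lfc_nb = systemic + rng.normal(0, config.lfc_noise_sd, n)
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)

    def _counts(lfc: np.ndarray) -> np.ndarray:
        mean = 2.0 ** (baseline + lfc)
        r = 1.0 / config.phi
        p = r / (r + mean)
        return rng.negative_binomial(r, p, size=(config.n_replicates, n))

    counts = {"ev": _counts(np.zeros(n)), "binding": _counts(lfc_bind),
              "nonbinding": _counts(lfc_nb)}

    def _de(strain: str, label: str) -> pd.DataFrame:
        c, e = counts[strain], counts["ev"]
        d = np.log2((c.mean(axis=0) + 0.5) / (e.mean(axis=0) + 0.5))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = stats.ttest_ind(np.log2(c + 1.0), np.log2(e + 1.0), axis=0)
        p = np.where(np.isnan(p), 1.0, p)
        padj = multipletests(p, method="fdr_bh")[1]
        return pd.DataFrame(
            {"gene": genes, "log2fc": d, "p_value": p, "padj": padj,
             "base_mean": e.mean(axis=0), "comparison": label}
        )

    de_binding = _de("binding", "histone_vs_ev")
    de_nonbinding = _de("nonbinding", "nonbinding_vs_ev")
    d = de_binding["log2fc"].to_numpy()
    sd = d.std() if d.std() > 0 else 1.0
    comp = {
        f"comp_{i:03d}": rng.normal(0, sd, n) for i in range(config.n_comparisons)
    }
    zd = (d - d.mean()) / sd
    rho = config.planted_rho
    comp["comp_planted"] = sd * (
        rho * zd + np.sqrt(1 - rho**2) * rng.normal(0, 1, n)
    )
    compendium = pd.DataFrame(comp, index=pd.Index(genes, name="gene"))
    count_frames = []
    for strain, mat in counts.items():
        cf = pd.DataFrame(
            mat.T, index=genes,
            columns=[f"{strain}_rep{j+1}" for j in range(config.n_replicates)],
        )
        count_frames.append(cf)
    return {
        "de_binding": de_binding,
        "de_nonbinding": de_nonbinding,
        "counts": pd.concat(count_frames, axis=1),
        "compendium": compendium,
        "true_lfc": pd.Series(lfc_bind, index=genes),
        "systemic_genes": [genes[i] for i in sys_idx],
        "planted_column": "comp_planted",
    }
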