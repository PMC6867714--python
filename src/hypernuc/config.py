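"""Pipeline configuration, orchestration and fixture generation.

A run is driven by a :class:`PipelineConfig` holding either a
:class:`~hypernuc.simulate.SimConfig` (synthetic mode) or paths to real
inputs, plus every tunable of the analysis modules.  The config is
echoed verbatim (YAML) into the output directory and all TSV outputs
are bit-reproducible given the same config and seed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import footprints as fp
from . import occupancy as occ
from . import seqmodel as sm
from . import transcription_link as tl
from .genome_io import (
    FragmentSet,
    GenomeSeq,
    IntervalSet,
    coverage,
    read_bed,
    read_fasta,
    read_tss_table,
    write_bed,
    write_bedgraph,
    write_fasta,
)
from .simulate import (
    SimConfig,
    simulate_digest,
    simulate_ev,
    simulate_library,
    simulate_expression,
    simulate_genome,
    simulate_nap_regions,
    simulate_placements,
    stage_seed,
    tss_true_occupancy,
)

__all__ = ["PipelineConfig", "run", "make_fixtures", "schema"]


@dataclass
class InputPaths:
    """File inputs for a real-data run (all BED/FASTA/TSV)."""

    genome: str
    fragments: list[str] = field(default_factory=list)     # strain replicates
    ev_fragments: str | None = None
    genes: str | None = None
    promoters: str | None = None
    tss: str | None = None
    nap_regions: str | None = None
    de_binding: str | None = None
    de_nonbinding: str | None = None
    compendium: str | None = None


@dataclass
class PipelineConfig:
    """Everything a run needs; exactly one of ``simulate`` / ``paths``."""

    simulate: SimConfig | None = None
    paths: InputPaths | None = None
    # stage toggles
    run_footprints: bool = True
    run_seqmodel: bool = True
    run_profiles: bool = True
    run_link: bool = True
    # occupancy tunables
    size_centers: tuple = (60, 90, 120, 150)
    size_tol: int = 5
    window_width: int = 60
    window_step: int = 30
    tss_profile_halfspan: int = 500       # D
    scale_libraries: bool = True
    regional_window: int = 200
    moving_span: int = 500
    moving_step: int = 20
    origin: int = 0
    terminus: int | None = None           # default: genome midpoint
    # footprint tunables
    kappa: float = 0.02
    threshold_quantile: float = 0.75
    flank: int = 30
    # sequence-model tunables
    model_size_class: int = 120
    kmer_window: int = 121
    train_fraction: float = 1 / 6
    train_stride: int = 10
    eval_stride: int = 10
    cv_folds: int = 10
    log2_response: bool = False
    # transcription-link tunables
    exclusion_alpha: float = 0.05
    tss_half_window: int = 25
    min_group: int = 3
    # run control
    seed: int = 0
    outdir: str = "hypernuc_out"

    def validate(self) -> list[str]:
        errors = []
        if (self.simulate is None) == (self.paths is None):
            errors.append(
                "exactly one of 'simulate' and 'paths' must be set "
                "(got both or neither)"
            )
        if self.simulate is not None:
            try:
                self.simulate.validate()
            except ValueError as exc:
                errors.append(str(exc))
        if not 0 < self.kappa <= 1:
            errors.append("kappa must be in (0, 1]")
        if not 0 <= self.threshold_quantile <= 1:
            errors.append("threshold_quantile must be in [0, 1]")
        if not 0 < self.train_fraction < 1:
            errors.append("train_fraction must be in (0, 1)")
        if self.kmer_window % 2 == 0:
            errors.append("kmer_window must be odd")
        return errors

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def schema() -> dict:
    """All documented tunables and their defaults (pipeline + simulator)."""
    out = {}
    for f in fields(PipelineConfig):
        if f.name in ("simulate", "paths"):
            continue
        default = f.default if f.default is not f.default_factory else None
        out[f"pipeline.{f.name}"] = default
    for f in fields(SimConfig):
        out[f"simulate.{f.name}"] = f.default
    return out


def _size_classes(config: PipelineConfig):
    return tuple(occ.SizeClass(c, config.size_tol) for c in config.size_centers)


def _load_inputs(config: PipelineConfig) -> dict:
    """Materialize all inputs, from the simulator or from files."""
    if config.simulate is not None:
        sc = config.simulate
        genome, genes, promoters, tss = simulate_genome(sc)
        placements, true_occ = simulate_placements(genome, sc)
        frags = [
            simulate_library(genome, sc,
                             seed=stage_seed(sc.seed, f"library_rep{i}"),
                             n_fragments=sc.library_fragments // 2)
            for i in (1, 2)
        ]
        ev = simulate_ev(genome, sc)
        nap = simulate_nap_regions(genome, sc)
        expr = simulate_expression(tss_true_occupancy(true_occ, tss), sc)
        return {
            "genome": genome, "genes": genes, "promoters": promoters,
            "tss": tss, "placements": placements, "true_occupancy": true_occ,
            "fragments": frags, "ev": ev, "nap": nap, **expr,
        }
    p = config.paths
    genome = read_fasta(p.genome)
    out = {
        "genome": genome,
        "fragments": [read_bed(f, kind="fragments", genome=genome)
                      for f in p.fragments],
        "ev": read_bed(p.ev_fragments, kind="fragments", genome=genome)
        if p.ev_fragments else None,
        "genes": read_bed(p.genes, genome=genome) if p.genes else None,
        "promoters": read_bed(p.promoters, genome=genome) if p.promoters else None,
        "tss": read_tss_table(p.tss) if p.tss else None,
        "nap": read_bed(p.nap_regions, genome=genome) if p.nap_regions else None,
        "de_binding": pd.read_csv(p.de_binding, sep="\t")
        if p.de_binding else None,
        "de_nonbinding": pd.read_csv(p.de_nonbinding, sep="\t")
        if p.de_nonbinding else None,
        "compendium": pd.read_csv(p.compendium, sep="\t", index_col=0)
        if p.compendium else None,
        "placements": None, "true_occupancy": None,
    }
    return out


def run(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute the pipeline stages in dependency order.

    Stages: (simulate | load) -> coverage -> normalize -> footprints ->
    seqmodel -> profiles -> transcription link.  Outputs (TSV/bedGraph)
    and the config echo land in ``outdir``; returns the in-memory
    results dict.  Stage outputs already present for the same config
    hash are reused.
    """
    errors = config.validate()
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    outdir = Path(outdir or config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True)
    )
    hash_file = outdir / "config.hash"
    fresh = not (hash_file.exists() and hash_file.read_text() == config.config_hash())
    hash_file.write_text(config.config_hash())

    data = _load_inputs(config)
    genome = data["genome"]
    results: dict = {"config_hash": config.config_hash()}
    classes = _size_classes(config)

    # --- coverage & normalization -------------------------------------
    all_frags = FragmentSet(
        pd.concat([f.df for f in data["fragments"]], ignore_index=True),
        genome=genome,
    )
    strain_cov = coverage(all_frags, genome, label="strain")
    ev_cov = (
        coverage(data["ev"], genome, label="ev") if data["ev"] is not None else None
    )
    tracks: dict[str, object] = {}
    if ev_cov is not None:
        tracks["pooled"] = occ.normalize(strain_cov, ev_cov,
                                         scale_libraries=config.scale_libraries)
        for sc in classes:
            cls_cov = coverage(all_frags, genome, length_filter=sc.bounds,
                               label=f"strain{sc.center}")
            tracks[str(sc.center)] = occ.normalize(
                cls_cov, ev_cov, scale_libraries=False
            )
        big = FragmentSet(
            all_frags.df[
                (all_frags.lengths >= 90 - config.size_tol)
                & (all_frags.lengths <= 150 + config.size_tol)
            ],
            genome=genome,
        )
        tracks["90plus"] = occ.normalize(
            coverage(big, genome, label="strain90plus"), ev_cov,
            scale_libraries=False,
        )
    results["tracks"] = tracks
    if fresh and tracks:
        write_bedgraph(tracks["pooled"], outdir / "occupancy_pooled.bedgraph")

    # --- fragment-length ladder ---------------------------------------
    if data["ev"] is not None:
        results["ladder"] = fp.histone_specific_peaks(
            all_frags.lengths, data["ev"].lengths
        )

    # --- footprints ----------------------------------------------------
    if config.run_footprints:
        smoothed = fp.smooth_track(strain_cov, config.kappa)
        calls = fp.call_peaks(smoothed, config.threshold_quantile)
        results["calls"] = calls
        results["extension"] = fp.extension_vs_flank(
            calls, genome, flank=config.flank
        )
        if fresh:
            bed = calls.assign(
                start=calls["start"].astype(int), end=calls["end"].astype(int),
                name=calls["rank"].astype(str), score=calls["score"],
                strand=".",
            )[["contig", "start", "end", "name", "score", "strand"]]
            bed.to_csv(outdir / "footprints.bed", sep="\t",
                       header=False, index=False)

    # --- occupancy profiles -------------------------------------------
    if config.run_profiles and data["tss"] is not None:
        results["replicate_correlation"] = (
            occ.replicate_correlation(
                data["fragments"][0], data["fragments"][1], genome,
                config.window_width, config.window_step,
            )
            if len(data["fragments"]) >= 2 else None
        )
        results["tss_profile"] = occ.tss_profile(
            all_frags, data["tss"], genome,
            D=config.tss_profile_halfspan, size_bins=classes,
        )
        if fresh:
            results["tss_profile"].to_csv(outdir / "tss_profile.tsv", sep="\t")
    if config.run_profiles and data["genes"] is not None and tracks:
        gg = occ.gene_gc_occupancy(genome, data["genes"], tracks["pooled"])
        results["gene_gc"] = gg
        if fresh:
            gg["table"].to_csv(outdir / "gene_gc_occupancy.tsv",
                               sep="\t", index=False)
        results["moving_gc"] = occ.moving_gc_occupancy(
            gg["table"], span=config.moving_span, step=config.moving_step
        )
        if data.get("counts") is not None:
            ev_cols = [c for c in data["counts"].columns if c.startswith("ev_")]
            expr = np.log2(data["counts"][ev_cols].mean(axis=1) + 1.0)
            L0 = genome.length(next(iter(genome.contigs)))
            results["regional"] = occ.regional_modulation(
                gg["table"], expr,
                origin=config.origin,
                terminus=config.terminus if config.terminus is not None else L0 // 2,
                genome_length=L0,
                window=config.regional_window,
            )
    if config.run_profiles and data["nap"] is not None and tracks:
        results["nap_delta"] = occ.nap_delta(tracks["pooled"], data["nap"])
        if fresh:
            results["nap_delta"]["table"].to_csv(
                outdir / "nap_delta.tsv", sep="\t", index=False
            )

    # --- sequence model ------------------------------------------------
    if config.run_seqmodel and tracks:
        contig = next(iter(genome.contigs))
        L0 = genome.length(contig)
        t_end = sm.train_prefix_end(L0, config.train_fraction)
        track = tracks[str(config.model_size_class)]
        y_all = track.values[contig]
        half = config.kmer_window // 2
        train_pos = np.arange(half, t_end, config.train_stride)
        test_pos = np.arange(t_end + half, L0 - half, config.eval_stride)
        Xtr, names, vtr = sm.kmer_features(
            genome, contig, train_pos, window=config.kmer_window
        )
        model = sm.fit_sparse(
            Xtr, y_all[train_pos[vtr]], names,
            train_region=(0, t_end), n_folds=config.cv_folds,
            log2_response=config.log2_response,
        )
        Xte, _, vte = sm.kmer_features(
            genome, contig, test_pos, window=config.kmer_window
        )
        results["model"] = model
        results["model_eval"] = sm.evaluate(
            model, Xte, y_all[test_pos[vte]], region=(t_end, L0)
        )
        if fresh:
            model.coefficients().to_csv(
                outdir / "model_coefficients.tsv", sep="\t", index=False
            )
            results["model_eval"]["univariate"].to_csv(
                outdir / "kmer_univariate.tsv", sep="\t", index=False
            )

    # --- transcription link ---------------------------------------------
    if (
        config.run_link
        and data.get("de_binding") is not None
        and data.get("de_nonbinding") is not None
    ):
        groups = tl.exclusion_filter(
            data["de_binding"], data["de_nonbinding"], alpha=config.exclusion_alpha
        )
        results["groups"] = groups
        if data["genes"] is not None and data["tss"] is not None and tracks:
            results["association"] = tl.window_occupancy(
                groups, tracks, data["tss"], data["genes"], data["promoters"],
                half=config.tss_half_window, min_group=config.min_group,
            )
            if fresh:
                results["association"]["tests"].to_csv(
                    outdir / "occupancy_association.tsv", sep="\t", index=False
                )
        if data.get("compendium") is not None:
            results["similarity"] = tl.compendium_similarity(
                data["de_binding"], data["compendium"], split_directions=True
            )
            if fresh:
                results["similarity"].to_csv(
                    outdir / "compendium_similarity.tsv", sep="\t", index=False
                )
    if fresh:
        try:
            _report_figures(results, data, outdir)
        except Exception as exc:  # figures are best-effort
            warnings.warn(f"figure generation failed: {exc}")
    results["inputs"] = data
    return results


def _report_figures(results: dict, data: dict, outdir: Path) -> None:
    """Static report figures: ladder, TSS heatmap, k-mer ranking, association."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if data.get("ev") is not None:
        fig, ax = plt.subplots(figsize=(6, 3))
        frags = pd.concat([f.df for f in data["fragments"]])
        lens = (frags["end"] - frags["start"]).to_numpy()
        ax.hist(lens, bins=np.arange(20, 161), color="steelblue", alpha=0.7,
                label="histone strain", density=True)
        ev_lens = (data["ev"].df["end"] - data["ev"].df["start"]).to_numpy()
        ax.hist(ev_lens, bins=np.arange(20, 161), color="grey", alpha=0.5,
                label="empty vector", density=True)
        for c in (60, 90, 120, 150):
            ax.axvline(c, ls=":", c="k", lw=0.5)
        ax.set_xlabel("fragment length (bp)")
        ax.set_ylabel("density")
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(outdir / "fragment_lengths.png", dpi=120)
        plt.close(fig)
    if "tss_profile" in results:
        prof = results["tss_profile"]
        fig, ax = plt.subplots(figsize=(6, 3))
        im = ax.imshow(
            prof.T, aspect="auto", origin="lower",
            extent=[prof.index[0], prof.index[-1], 0, prof.shape[1]],
            cmap="viridis",
        )
        ax.set_yticks(np.arange(prof.shape[1]) + 0.5, prof.columns)
        ax.set_xlabel("distance to TSS (bp)")
        ax.set_ylabel("size class (bp)")
        fig.colorbar(im, ax=ax, label="mean coverage")
        fig.tight_layout()
        fig.savefig(outdir / "tss_heatmap.png", dpi=120)
        plt.close(fig)
    if "model_eval" in results:
        uni = results["model_eval"]["univariate"]
        sel = pd.concat([uni.head(20), uni.tail(20)])
        fig, ax = plt.subplots(figsize=(4, 8))
        colors = ["firebrick" if r > 0 else "steelblue" for r in sel["rho"]]
        ax.barh(np.arange(len(sel)), sel["rho"], color=colors)
        ax.set_yticks(np.arange(len(sel)), sel["feature"], fontsize=6)
        ax.invert_yaxis()
        ax.set_xlabel("univariate Spearman rho")
        fig.tight_layout()
        fig.savefig(outdir / "kmer_ranking.png", dpi=120)
        plt.close(fig)
    if "association" in results:
        tests = results["association"]["tests"]
        sub = tests[tests["window"] == "tss_pm25"]
        if not sub.empty:
            fig, ax = plt.subplots(figsize=(5, 3))
            x = np.arange(len(sub))
            ax.bar(x - 0.2, sub["median_down"], 0.4, label="down")
            ax.bar(x + 0.2, sub["median_up"], 0.4, label="up")
            ax.set_xticks(x, sub["size_class"])
            ax.set_ylabel("median occupancy (TSS +- 25 bp)")
            for i, p in enumerate(sub["p_value"]):
                if p == p and p < 0.05:
                    ax.text(i, ax.get_ylim()[1] * 0.95,
                            "*" * min(4, int(-np.log10(max(p, 1e-16)) // 1)),
                            ha="center")
            ax.legend(frameon=False)
            fig.tight_layout()
            fig.savefig(outdir / "association.png", dpi=120)
            plt.close(fig)


_TINY = dict(length=20_000, n_genes=15, gene_length=800, promoter_width=100,
             density=8.0, n_nap_regions=8, nap_region_width=300,
             n_cells=100, library_fragments=40_000)


def make_fixtures(out_dir: str | Path, scale: str = "tiny",
                  seed: int = 0, force: bool = False) -> Path:
    """Write a complete synthetic input tree (FASTA, BEDs, TSVs, config).

    ``scale`` is "tiny" (20 kb, seconds) or "default" (200 kb).  Refuses
    to write into an existing non-empty directory unless ``force``.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)
    kwargs = dict(_TINY) if scale == "tiny" else {}
    if scale not in ("tiny", "default"):
        raise ValueError("scale must be 'tiny' or 'default'")
    sc = SimConfig(seed=seed, **kwargs)
    genome, genes, promoters, tss = simulate_genome(sc)
    placements, true_occ = simulate_placements(genome, sc)
    write_fasta(genome, out / "genome.fasta")
    write_bed(genes, out / "genes.bed")
    write_bed(promoters, out / "promoters.bed")
    tss.to_csv(out / "tss.tsv", sep="\t", index=False)
    for i in (1, 2):
        frags = simulate_digest(
            placements, genome, sc, seed=stage_seed(sc.seed, f"digest_rep{i}")
        )
        write_bed(frags, out / f"fragments_rep{i}.bed")
    write_bed(simulate_ev(genome, sc), out / "fragments_ev.bed")
    write_bed(simulate_nap_regions(genome, sc), out / "nap_regions.bed")
    placements.to_csv(out / "placements.tsv", sep="\t", index=False)
    expr = simulate_expression(tss_true_occupancy(true_occ, tss), sc)
    expr["de_binding"].to_csv(out / "de_binding.tsv", sep="\t", index=False)
    expr["de_nonbinding"].to_csv(out / "de_nonbinding.tsv", sep="\t", index=False)
    expr["counts"].to_csv(out / "counts.tsv", sep="\t")
    expr["compendium"].to_csv(out / "compendium.tsv", sep="\t")
    (out / "sim_config.yaml").write_text(yaml.safe_dump(sc.to_dict()))
    return out
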