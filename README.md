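# hypernuc

Size-resolved MNase footprint mapping and downstream analysis of
archaeal histone occupancy on bacterial genomes.

## The problem

Archaeal histones (e.g. HMfA/HMfB from *Methanothermus fervidus*)
assemble on DNA as tetramers protecting ~60 bp and extend in histone
**dimer steps of ~30 bp** into hexamers, octamers, and decamers, so
micrococcal-nuclease (MNase) digestion of a chromatinized genome yields
a characteristic fragment-length ladder:

    L(r) = 60 + 30·(r − 1)  bp        r = 1 … 4  →  60, 90, 120, 150 bp

When such histones are expressed in a naive bacterial host, mapping the
protected fragments genome-wide answers where nucleosome-like particles
form, how sequence (GC content, AT-rich promoters) shapes occupancy,
and whether promoter-proximal occupancy represses transcription.
`hypernuc` implements that analysis as a reusable pipeline for anyone
working with MNase footprints of oligomerizing DNA-binding proteins in
bacteria or archaea:

- **genome_io** — FASTA/BED/TSV/bedGraph I/O, 0-based half-open
  coordinates throughout, circular-chromosome-aware per-base coverage.
- **simulate** — a synthetic-data generator that plants every effect
  the pipeline detects: AT-rich promoters, GC-weighted nucleation with
  AT-flank-inhibited dimer extension, biased MNase digestion with the
  30 bp ladder, a matched empty-vector (EV) control, occupancy-coupled
  differential expression, and a transcriptome compendium with one
  correlated comparison.
- **occupancy** — EV-normalized occupancy `O(x) = c_strain(x) /
  (c_EV(x) + 1)` per footprint size class (60/90/120/150 ± 5 bp),
  replicate and GC correlations, TSS × fragment-size profiles,
  regional/moving-window analyses, NAP Δ-occupancy.
- **footprints** — Fourier-filtered (NucleR-style) peak calling, width
  at half height, oligomer-rank assignment, extension-vs-flank
  statistics, and the fragment-length ladder scan.
- **seqmodel** — LASSO of occupancy on all 340 k-mers (k = 1–4) in
  61/91/121 bp windows, trained on a contiguous one-sixth genome
  prefix and evaluated on the rest; read-internal nucleotide
  enrichment profiles with a dyad-symmetry score.
- **transcription_link** — the dual-comparison exclusion rule,
  down- vs up-regulated group occupancy at TSS/promoter/gene-body and
  a 51 bp start-codon control window, dot-product compendium
  similarity.
- **cli / config** — a `hypernuc` command-line entry point and a
  YAML-configurable end-to-end `run`.

## Worked example

Simulate the default conditions (200 kb circular chromosome, 100 genes
with AT-rich promoters, 8 particles/kb), digest 200,000 fragments, and
ask for the histone-specific ladder:

```python
from hypernuc.simulate import (SimConfig, simulate_genome,
                               simulate_placements, simulate_digest,
                               simulate_ev)
from hypernuc.footprints import histone_specific_peaks

cfg = SimConfig(seed=1)
genome, genes, promoters, tss = simulate_genome(cfg)
placements, true_occ = simulate_placements(genome, cfg)
frags = simulate_digest(placements, genome, cfg, n_fragments=200_000)
ev = simulate_ev(genome, cfg, n_fragments=200_000)
ladder = histone_specific_peaks(frags.lengths, ev.lengths)
print("specific peaks:", ladder["specific_peaks"].tolist())
print("mean spacing :", ladder["mean_spacing"])
```

prints

```
specific peaks: [60, 90, 120, 150]
mean spacing : 30.0
```

— the four ladder rungs at exact multiples of the 30 bp dimer step,
none of which appear in the EV control.  Recovering the planted
particles from a clonal digest and correlating occupancy with gene GC:

```python
from hypernuc.footprints import recover_placements
from hypernuc import occupancy as occ
from hypernuc.genome_io import coverage

clonal = simulate_digest(placements, genome, cfg)      # mu = 20 frags/particle
rec = recover_placements(clonal, placements, genome)
print("rank-1 recall:", round(rec["rank1_recall"], 3))

track = occ.normalize(coverage(frags, genome), coverage(ev, genome),
                      scale_libraries=True)
res = occ.gene_gc_occupancy(genome, genes, track)
print("gene GC vs occupancy rho:", round(res["rho"], 3))
```

```
rank-1 recall: 0.943
gene GC vs occupancy rho: 0.515
```

94% of planted tetramer footprints are recovered within ±5 bp, and
GC-rich genes carry visibly higher normalized occupancy — the planted
sequence preference read back out of the digest.  The same chain runs
from the shell:

```sh
hypernuc fixtures --out demo --seed 1      # write a synthetic input tree
hypernuc run --simulate --seed 1 --out out # full pipeline, TSVs + figures
```

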