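"""Synthetic data following the barrier model of nucleosome organisation.

A toy genome is laid out with genes and "barrier" elements (stand-ins for
regulatory regions bound by proteins, i.e. future DNase I hypersensitive
sites). Each barrier nucleates a phased nucleosome array on both of its
edges: the k-th nucleosome core sits ``(k-1) * (core + linker)`` bp beyond
the first one, whose core abuts the barrier edge, and each dyad is jittered
by Normal(0, sigma0 + (k-1) * dsigma) — positional regularity decays with
distance from the barrier. MNase-seq fragments are drawn per dyad
(mono-nucleosome sized, Gaussian digestion noise) and DNase cut tags are
concentrated inside barriers over a uniform background. Every generated
feature is recorded in a ground-truth manifest so downstream stages can be
scored exactly.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Sequence, Tuple

import numpy as np

from . import io as nbio
from .types import ChromSizes, Fragment, GeneModel, GenomicInterval, Tag

CATEGORIES = ("proximal", "distal", "genic", "downstream", "intergenic")

# fixed offsets deriving one sub-generator per stage from the run seed
_STAGE_SEED = {"genome": 11, "dyads": 23, "mnase": 37, "dnase": 53}


@dataclass
class BarrierClassSpec:
    """Per-class barrier parameters: placement counts, size and array geometry."""

    count: int
    length_min: int
    length_max: int
    linker: int
    sigma0: float = 3.0
    dsigma: float = 2.0
    n_nucs: int = 5  # array length, nucleosomes per side

    def __post_init__(self) -> None:
        if self.count < 0 or self.length_min <= 0 or self.length_max < self.length_min:
            raise ValueError("invalid barrier length specification")
        if self.linker < 0 or self.sigma0 < 0 or self.dsigma < 0 or self.n_nucs < 1:
            raise ValueError("invalid barrier array specification")


def default_classes() -> Dict[str, BarrierClassSpec]:
    """Study conditions: short linkers (8 bp) at gene-associated barriers,
    long linkers (35 bp) at intergenic ones; proximal barriers have the most
    variable lengths."""
    return {
        "proximal": BarrierClassSpec(8, 80, 400, linker=8),
        "distal": BarrierClassSpec(6, 60, 160, linker=8),
        "genic": BarrierClassSpec(8, 60, 160, linker=8),
        "downstream": BarrierClassSpec(6, 60, 160, linker=8),
        "intergenic": BarrierClassSpec(14, 60, 160, linker=35),
    }


@dataclass
class SimulationConfig:
    chrom_sizes: Dict[str, int] = field(default_factory=lambda: {"chr1": 1_000_000})
    n_genes: int = 40
    gene_length_min: int = 1200
    gene_length_max: int = 2500
    classes: Dict[str, BarrierClassSpec] = field(default_factory=default_classes)
    core: int = 147
    digestion_sigma: float = 10.0  # sd of fragment length around the core
    center_noise: float = 2.0  # sd of fragment centre around its dyad
    depth: float = 50.0  # mean fragments per phased dyad
    dnase_rate_in: float = 0.5  # DNase cut tags per bp inside barriers
    dnase_rate_bg: float = 0.01  # ... and in the background
    minus1_occupancy: float = 0.2  # fragment fraction of the intra-barrier nucleosome
    background_dyads_per_kb: float = 0.05  # unphased nucleosomes elsewhere
    frac_silent_genes: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for c, n in self.chrom_sizes.items():
            if n <= 0:
                raise ValueError(f"chromosome {c} has non-positive size")
        if self.core <= 0 or self.depth < 0:
            raise ValueError("core length must be > 0 and depth >= 0")
        if not (0.0 <= self.minus1_occupancy <= 1.0):
            raise ValueError("minus1_occupancy must be in [0, 1]")
        if self.dnase_rate_in < 0 or self.dnase_rate_bg < 0:
            raise ValueError("DNase rates must be >= 0")
        unknown = set(self.classes) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown barrier classes: {sorted(unknown)}")


@dataclass(frozen=True)
class TrueDyad:
    """One ground-truth nucleosome dyad.

    ``array_index`` counts outward from the barrier (1 = abutting core),
    is 0 for the intra-barrier "-1" nucleosome and -1 for unphased
    background nucleosomes; ``side`` is 'L', 'R', 'C' or 'bg'.
    """

    chrom: str
    pos: int
    klass: str
    barrier_id: int
    side: str
    array_index: int
    weight: float = 1.0


@dataclass
class GroundTruth:
    barriers: List[GenomicInterval]
    barrier_classes: List[str]
    dyads: List[TrueDyad] = field(default_factory=list)
    genes: List[GeneModel] = field(default_factory=list)
    class_linker: Dict[str, int] = field(default_factory=dict)
    class_spacing: Dict[str, int] = field(default_factory=dict)

    def phased_dyads(self) -> List[TrueDyad]:
        return [d for d in self.dyads if d.array_index >= 1]


class PlacementError(RuntimeError):
    pass


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([_STAGE_SEED[stage], int(config.seed)])


def build_toy_genome(
    config: SimulationConfig,
) -> Tuple[ChromSizes, List[GeneModel], GroundTruth]:
    """Lay out genes and barrier elements on the toy genome.

    Features are placed left to right in shuffled "units" (a gene, possibly
    carrying one gene-associated barrier, or a lone intergenic barrier) with
    generous gaps, so that every barrier's genomic category under the
    midpoint/precedence classification rule is its generated class label by
    construction. Deterministic for a given seed.
    """
    rng = _rng(config, "genome")
    sizes = dict(config.chrom_sizes)
    classes = config.classes

    gene_classes = [k for k in ("proximal", "distal", "genic", "downstream") if k in classes]
    n_attached = sum(classes[k].count for k in gene_classes)
    if n_attached > config.n_genes:
        raise PlacementError(
            f"{n_attached} gene-associated barriers but only {config.n_genes} genes; "
            "increase n_genes"
        )

    # assign barrier classes to gene slots, pad with unadorned genes, add
    # intergenic units, then shuffle the order along the genome
    units: List[str] = []
    for k in gene_classes:
        units += [f"gene:{k}"] * classes[k].count
    units += ["gene:"] * (config.n_genes - n_attached)
    units += ["intergenic"] * (classes["intergenic"].count if "intergenic" in classes else 0)
    units = [units[i] for i in rng.permutation(len(units))]

    max_linker = max(c.linker for c in classes.values()) if classes else 0
    max_nucs = max(c.n_nucs for c in classes.values()) if classes else 0
    array_span = max_nucs * (config.core + max_linker) + config.core  # one side
    pad = array_span + 120  # clearance so arrays stay on-chromosome

    chroms = list(sizes)
    chrom_weights = np.array([sizes[c] for c in chroms], dtype=float)
    chrom_weights /= chrom_weights.sum()
    # distribute units over chromosomes proportionally to length
    unit_chrom = [chroms[i] for i in rng.choice(len(chroms), size=len(units), p=chrom_weights)]

    genes: List[GeneModel] = []
    barriers: List[GenomicInterval] = []
    barrier_classes: List[str] = []
    cursor = {c: pad for c in chroms}

    def place_barrier(chrom: str, mid: int, klass: str) -> None:
        spec = classes[klass]
        length = int(rng.integers(spec.length_min, spec.length_max + 1))
        start = mid - length // 2
        bid = len(barriers)
        barriers.append(
            GenomicInterval(chrom, start, start + length, name=f"{klass}_{bid}")
        )
        barrier_classes.append(klass)

    for unit, chrom in zip(units, unit_chrom):
        gap = int(rng.integers(2500, 3500))
        if unit == "intergenic":
            mid = cursor[chrom] + 1100
            place_barrier(chrom, mid, "intergenic")
            cursor[chrom] = mid + 1100 + gap
            continue

        klass = unit.split(":", 1)[1]
        glen = int(rng.integers(config.gene_length_min, config.gene_length_max + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        upstream_space, downstream_space = 1100, 400
        if strand == "+":
            gstart = cursor[chrom] + upstream_space
            cursor_next = gstart + glen + downstream_space
        else:
            gstart = cursor[chrom] + downstream_space
            cursor_next = gstart + glen + upstream_space
        gend = gstart + glen
        silent = rng.random() < config.frac_silent_genes
        fpkm = 0.0 if silent else float(np.round(rng.lognormal(mean=2.0, sigma=1.0), 3))
        gene = GeneModel(
            GenomicInterval(chrom, gstart, gend, strand=strand, name=f"g{len(genes)}"),
            id=f"g{len(genes)}",
            expression=fpkm,
        )
        genes.append(gene)

        if klass:
            tss, tes = gene.tss, gene.tes
            sgn = 1 if strand == "+" else -1
            if klass == "proximal":
                off = int(rng.integers(20, 181))  # midpoint 20-180 bp upstream of TSS
                mid = tss - sgn * off
            elif klass == "distal":
                off = int(rng.integers(250, 951))
                mid = tss - sgn * off
            elif klass == "genic":
                mid = int(rng.integers(gstart + 120, gend - 120))
            else:  # downstream
                off = int(rng.integers(20, 181))
                mid = tes + sgn * off
            place_barrier(chrom, mid, klass)
        cursor[chrom] = cursor_next + gap

    for chrom in chroms:
        if cursor[chrom] + pad > sizes[chrom]:
            raise PlacementError(
                f"features overflow chromosome {chrom} "
                f"(need ~{cursor[chrom] + pad} bp, have {sizes[chrom]}); "
                "use a larger genome or fewer features"
            )

    truth = GroundTruth(
        barriers=barriers,
        barrier_classes=barrier_classes,
        genes=genes,
        class_linker={k: classes[k].linker for k in classes},
        class_spacing={k: config.core + classes[k].linker for k in classes},
    )
    return sizes, genes, truth


def true_nucleosome_map(truth: GroundTruth, config: SimulationConfig) -> GroundTruth:
    """Populate ``truth.dyads`` with barrier-phased arrays plus extras.

    The first core on the right of a barrier occupies ``[end, end+core)``
    (dyad at ``end + core//2``); the first on the left occupies
    ``[start-core, start)`` (dyad at ``start - (core - core//2)``).
    Successive dyads step by ``core + linker`` outward, each displaced by
    Normal(0, sigma0 + (k-1) * dsigma). A single optional dyad at the
    barrier centre models the intra-barrier "-1" nucleosome, at reduced
    occupancy. Unphased background dyads are scattered uniformly.
    """
    rng = _rng(config, "dyads")
    core = config.core
    dyads: List[TrueDyad] = []
    for bid, (barrier, klass) in enumerate(zip(truth.barriers, truth.barrier_classes)):
        spec = config.classes[klass]
        step = core + spec.linker
        for k in range(1, spec.n_nucs + 1):
            sigma = spec.sigma0 + (k - 1) * spec.dsigma
            for side in ("L", "R"):
                if side == "R":
                    base = barrier.end + core // 2 + (k - 1) * step
                else:
                    base = barrier.start - (core - core // 2) - (k - 1) * step
                jitter = int(np.rint(rng.normal(0.0, sigma))) if sigma > 0 else 0
                dyads.append(
                    TrueDyad(barrier.chrom, base + jitter, klass, bid, side, k)
                )
        if config.minus1_occupancy > 0:
            dyads.append(
                TrueDyad(
                    barrier.chrom,
                    barrier.midpoint,
                    klass,
                    bid,
                    "C",
                    0,
                    weight=config.minus1_occupancy,
                )
            )
    # unphased background nucleosomes
    for chrom, size in config.chrom_sizes.items():
        n_bg = rng.poisson(config.background_dyads_per_kb * size / 1000.0)
        for pos in np.sort(rng.integers(core, size - core, size=n_bg)):
            dyads.append(TrueDyad(chrom, int(pos), "background", -1, "bg", -1))
    truth.dyads = dyads
    return truth


def emit_mnase_fragments(truth: GroundTruth, config: SimulationConfig) -> List[Fragment]:
    """Draw mono-nucleosome MNase fragments from the true dyad map.

    Each dyad yields Poisson(depth * weight) fragments centred at
    dyad + Normal(0, center_noise) with length round(Normal(core,
    digestion_sigma)) clipped to [100, 250]; a fragment of length L at
    centre d spans ``[d - L//2, d - L//2 + L)``, so an exact-core fragment
    covers ``[d-73, d+74)``.
    """
    rng = _rng(config, "mnase")
    sizes = config.chrom_sizes
    fragments: List[Fragment] = []
    for dyad in truth.dyads:
        n = rng.poisson(config.depth * dyad.weight)
        if n == 0:
            continue
        centers = dyad.pos + np.rint(rng.normal(0.0, config.center_noise, size=n)).astype(int)
        lengths = np.clip(
            np.rint(rng.normal(config.core, config.digestion_sigma, size=n)).astype(int),
            100,
            250,
        )
        starts = centers - lengths // 2
        ends = starts + lengths
        size = sizes[dyad.chrom]
        for s, e in zip(starts, ends):
            if s >= 0 and e <= size:
                fragments.append(Fragment(dyad.chrom, int(s), int(e)))
    fragments.sort(key=lambda f: (f.chrom, f.start, f.end))
    return fragments


def fragments_to_tags(fragments: Sequence[Fragment]) -> List[Tag]:
    """Single-end view of a fragment set: both ends of every fragment.

    Each fragment contributes a forward tag at its start and a reverse tag
    at ``end - 1``, mimicking strand-balanced single-end sequencing of the
    same nucleosomal DNA.
    """
    tags: List[Tag] = []
    for f in fragments:
        tags.append(Tag(f.chrom, f.start, "+"))
        tags.append(Tag(f.chrom, f.end - 1, "-"))
    tags.sort(key=lambda t: (t.chrom, t.pos5, t.strand))
    return tags


def emit_dnase_tags(truth: GroundTruth, config: SimulationConfig) -> List[Tag]:
    """DNase cut tags: Poisson inside barriers at ``dnase_rate_in`` per bp,
    uniform background at ``dnase_rate_bg`` per bp, strands Bernoulli(1/2)."""
    rng = _rng(config, "dnase")
    tags: List[Tag] = []
    for barrier in truth.barriers:
        n = rng.poisson(config.dnase_rate_in * barrier.length)
        positions = rng.integers(barrier.start, barrier.end, size=n)
        strands = rng.random(n) < 0.5
        for pos, fwd in zip(positions, strands):
            tags.append(Tag(barrier.chrom, int(pos), "+" if fwd else "-"))
    for chrom, size in config.chrom_sizes.items():
        n = rng.poisson(config.dnase_rate_bg * size)
        positions = rng.integers(0, size, size=n)
        strands = rng.random(n) < 0.5
        for pos, fwd in zip(positions, strands):
            tags.append(Tag(chrom, int(pos), "+" if fwd else "-"))
    tags.sort(key=lambda t: (t.chrom, t.pos5, t.strand))
    return tags


@dataclass
class SimulationResult:
    config: SimulationConfig
    sizes: ChromSizes
    genes: List[GeneModel]
    truth: GroundTruth
    fragments: List[Fragment]
    mnase_tags: List[Tag]
    dnase_tags: List[Tag]


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run the full generator: genome, dyad map, MNase and DNase read sets."""
    sizes, genes, truth = build_toy_genome(config)
    truth = true_nucleosome_map(truth, config)
    fragments = emit_mnase_fragments(truth, config)
    return SimulationResult(
        config=config,
        sizes=sizes,
        genes=genes,
        truth=truth,
        fragments=fragments,
        mnase_tags=fragments_to_tags(fragments),
        dnase_tags=emit_dnase_tags(truth, config),
    )


def write_simulation(result: SimulationResult, outdir: str) -> Dict[str, str]:
    """Write the standard file set; returns {logical name: path}."""
    nbio.ensure_dir(outdir)
    paths = {
        "sizes": os.path.join(outdir, "genome.sizes"),
        "genes": os.path.join(outdir, "genes.bed"),
        "barriers": os.path.join(outdir, "barriers.bed"),
        "fragments": os.path.join(outdir, "mnase_fragments.bed"),
        "mnase_tags": os.path.join(outdir, "mnase_tags.bed"),
        "dnase_tags": os.path.join(outdir, "dnase_tags.bed"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    nbio.write_chrom_sizes(result.sizes, paths["sizes"])
    nbio.write_genes(result.genes, paths["genes"])
    nbio.write_intervals(result.truth.barriers, paths["barriers"])
    nbio.write_fragments(result.fragments, paths["fragments"])
    nbio.write_tags(result.mnase_tags, paths["mnase_tags"])
    nbio.write_tags(result.dnase_tags, paths["dnase_tags"])
    truth = result.truth
    manifest = {
        "seed": result.config.seed,
        "class_linker": truth.class_linker,
        "class_spacing": truth.class_spacing,
        "barriers": [
            {
                "chrom": b.chrom,
                "start": b.start,
                "end": b.end,
                "class": k,
                "name": b.name,
            }
            for b, k in zip(truth.barriers, truth.barrier_classes)
        ],
        "dyads": [asdict(d) for d in truth.dyads],
        "genes": [
            {
                "chrom": g.interval.chrom,
                "start": g.interval.start,
                "end": g.interval.end,
                "strand": g.interval.strand,
                "id": g.id,
                "fpkm": g.expression,
            }
            for g in truth.genes
        ],
    }
    with open(paths["truth"], "w") as fh:
        json.dump(manifest, fh, indent=1)
    return paths
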